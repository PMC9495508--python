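"""Training of the sequence-to-hyperbolic-space encoder.

The objective is the mean, over distinct leaf pairs, of the squared
relative distance error

    cost(phi, s) = E[ ( s * d(phi(s_i), phi(s_j)) / dT(v_i, v_j) - 1 )^2 ]

where ``d`` is the unit-curvature distance of the active geometry and the
positive scale ``s`` encodes the curvature (C = -1/s^2).  For a fixed
embedding the cost is convex in ``s`` with the closed-form minimiser
``s* = E[rho] / E[rho^2]`` over the ratios ``rho = d/dT``; training
alternates stochastic gradient steps on the encoder with relaxed
closed-form updates ``s_{k+1} = s_k + alpha_k (s* - s_k)``.

Numerical safeguards follow from the precision analysis of hyperbolic
distances: tree distances are normalised to a maximum of 1 before
training (the factor is absorbed into the scale and restored when
distances are reported), and the learning rate decays exponentially,
``alpha_k = alpha_0 * p^floor(k/K)`` with ``K = 10`` epochs per block and
``p = 0.95``, so that both large and small distances are eventually fit.

Gradients of the loss with respect to the encoder's tangent outputs are
computed in closed form for all three geometries and then propagated
through the network by :func:`hyperplace.encoder.encoder_backward`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import dendropy
import numpy as np

from .alignio import Alignment
from .encoder import EmbeddingModel, encoder_backward, encoder_forward
from .geometry import GeometryMode, pairwise_unit_distances, embed_tangent
from .trees import TreeDistances, leaf_distance_matrix

__all__ = [
    "TrainingConfig",
    "normalize_tree_distances",
    "add_terminal_pseudocounts",
    "weighted_cost",
    "optimal_scale",
    "scale_step",
    "lr_schedule",
    "make_batches",
    "loss_and_tangent_grad",
    "train",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the alternating optimisation.

    ``alpha0`` is the initial learning rate of the exponential decay
    schedule; ``scale_lr_coupled`` reuses the same schedule for the scale
    relaxation.  ``scale_per`` chooses whether the closed-form scale update
    runs after every batch (default) or once per epoch.  ``pseudo_count``
    is added to every terminal branch before distances are computed, which
    removes near-zero leaf distances.  ``optimizer`` is "adam" or "sgd".
    """

    batch_size: int = 32
    epochs: int = 1000
    alpha0: float = 1e-3
    decay_p: float = 0.95
    decay_K: int = 10
    scale_lr_coupled: bool = True
    seed: int = 0
    pseudo_count: float = 0.0
    optimizer: str = "adam"
    scale_per: str = "batch"
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not 0 < self.decay_p < 1:
            raise ValueError("decay_p must be in (0, 1)")
        if self.decay_K < 1:
            raise ValueError("decay_K must be >= 1")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.scale_per not in ("batch", "epoch"):
            raise ValueError(f"scale_per must be 'batch' or 'epoch'")


def normalize_tree_distances(D: TreeDistances) -> TreeDistances:
    """Divide by the maximum entry so distances are at most 1.

    The factor is stored on the result for later de-normalisation.  An
    already-normalised matrix passes through with factor 1.
    """
    mx = float(D.matrix.max())
    if mx <= 0:
        raise ValueError("all-zero distance matrix cannot be normalized")
    return TreeDistances(list(D.labels), D.matrix / mx, normalization_factor=mx)


def add_terminal_pseudocounts(tree: dendropy.Tree, eps: float) -> dendropy.Tree:
    """Increase every leaf-incident branch by ``eps`` (a copy is returned).

    Every leaf-pair distance grows by exactly 2*eps, which lifts zero
    distances between duplicate taxa off zero.
    """
    if eps < 0:
        raise ValueError("pseudo count must be >= 0")
    out = tree.clone(depth=1)
    if eps:
        for lf in out.leaf_node_iter():
            lf.edge.length = (lf.edge.length or 0.0) + eps
    return out


def weighted_cost(
    embedded: np.ndarray,
    s: float,
    Dtree: TreeDistances,
    pairs: np.ndarray,
    mode: str = "loid",
) -> float:
    """Mean over ``pairs`` of (s*d(x_i, x_j)/dT(i, j) - 1)^2.

    ``embedded`` are tangent vectors (N, d); ``pairs`` is an (m, 2) array of
    distinct index pairs into ``embedded`` / ``Dtree.labels``.
    """
    pairs = np.asarray(pairs, dtype=int)
    i, j = pairs.T
    t = Dtree.matrix[i, j]
    if np.any(t <= 0):
        raise ValueError(
            "zero tree distance among evaluated pairs (duplicate taxa?); "
            "deduplicate the alignment or add terminal pseudo-counts"
        )
    D = pairwise_unit_distances(np.asarray(embedded, dtype=float), mode)
    return float(np.mean((s * D[i, j] / t - 1.0) ** 2))


def optimal_scale(embedded_d: np.ndarray, tree_d: np.ndarray) -> float:
    """Closed-form minimiser of the weighted cost over the scale.

    For ratios rho = d/dT the cost is convex in s and minimised at
    E[rho] / E[rho^2].
    """
    d = np.asarray(embedded_d, dtype=float)
    t = np.asarray(tree_d, dtype=float)
    if d.shape != t.shape:
        raise ValueError("distance lists must have equal length")
    if np.any(t <= 0):
        raise ValueError("tree distances must be positive")
    rho = d / t
    m2 = float(np.mean(rho**2))
    if m2 == 0.0:
        raise ValueError("all embedded distances are zero (collapsed embedding)")
    return float(np.mean(rho)) / m2


def scale_step(s_k: float, s_star: float, alpha_k: float) -> float:
    """Relaxed scale update s_{k+1} = s_k + alpha_k (s* - s_k)."""
    if s_k <= 0 or s_star <= 0:
        raise ValueError("scales must be positive")
    if not 0 < alpha_k <= 1:
        raise ValueError("alpha_k must be in (0, 1]")
    return s_k + alpha_k * (s_star - s_k)


def lr_schedule(k: int, alpha0: float, K: int = 10, p_decay: float = 0.95) -> float:
    """Piecewise-constant exponential decay: alpha0 * p^floor(k/K)."""
    if k < 0:
        raise ValueError("epoch index must be >= 0")
    return alpha0 * p_decay ** (k // K)


def make_batches(
    ids: list[str], B: int, seed: int = 0, epoch: int = 0
) -> list[list[str]]:
    """Fresh uniform random partition of ``ids`` into batches of size ``B``.

    The last batch may be smaller.  Every id appears exactly once per
    epoch; the partition is deterministic given (seed, epoch).
    """
    if B < 2:
        raise ValueError("batch size must be >= 2")
    rng = np.random.default_rng([int(seed) % (2**31), int(epoch)])
    perm = rng.permutation(len(ids))
    return [[ids[k] for k in perm[i : i + B]] for i in range(0, len(ids), B)]


# ---------------------------------------------------------------------------
# analytic loss gradients w.r.t. the tangent outputs


def _pair_mask(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def loss_and_tangent_grad(
    V: np.ndarray, T: np.ndarray, s: float, mode: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and its exact gradient w.r.t. the tangent vectors of one batch.

    ``V``: (B, d) encoder outputs; ``T``: (B, B) normalised tree distances
    (positive off the diagonal).  Returns (loss, dL/dV, unit-curvature
    distance matrix).  The loss is the mean over the B*(B-1)/2 distinct
    pairs of (s*d_ij/t_ij - 1)^2.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    iu, ju = _pair_mask(n)
    n_pairs = iu.size
    t = T[iu, ju]
    if np.any(t <= 0):
        raise ValueError("zero tree distance within a batch; see weighted_cost")

    if mode == "euclidean":
        D = pairwise_unit_distances(V, mode)
        resid = s * D[iu, ju] / t - 1.0
        loss = float(np.mean(resid**2))
        # dL/dD_ij for the unordered pair, spread symmetrically
        M = np.zeros((n, n))
        M[iu, ju] = 2.0 * s * resid / t / n_pairs
        M = M + M.T
        # dD_ij/dv_i = 2 (v_i - v_j)
        row = M.sum(axis=1)
        dV = 2.0 * (row[:, None] * V - M @ V)
        return loss, dV, D

    r = np.linalg.norm(V, axis=1)
    safe = np.where(r == 0.0, 1.0, r)

    if mode == "loid":
        f = np.where(r < 1e-12, 1.0, np.sinh(safe) / safe)
        c = np.cosh(r)
        U = f[:, None] * V
        G = np.outer(c, c) - U @ U.T
        np.fill_diagonal(G, 1.0)
        G = np.maximum(G, 1.0)
        D = np.arccosh(G)
        np.fill_diagonal(D, 0.0)

        resid = s * D[iu, ju] / t - 1.0
        loss = float(np.mean(resid**2))
        dLdD = np.zeros((n, n))
        dLdD[iu, ju] = 2.0 * s * resid / t / n_pairs
        dLdD = dLdD + dLdD.T
        # d acosh(g)/dg, zero where points coincide (g == 1)
        root = np.sqrt(np.maximum(G**2 - 1.0, 0.0))
        dDdG = np.where(root > 1e-12, 1.0 / np.where(root > 0, root, 1.0), 0.0)
        M = dLdD * dDdG  # dL/dG, symmetric, zero diagonal
        np.fill_diagonal(M, 0.0)

        # g_ij = cosh r_i cosh r_j - f(r_i) f(r_j) v_i.v_j with f = sinh(r)/r
        # d g_ij / d v_i = f_i [cosh r_j] v_i - w1_i (v_i.v_j) f_j v_i - f_i f_j v_j
        # where w1 = f'(r)/r -> 1/3 as r -> 0
        fprime = np.where(r < 1e-6, r / 3.0, (c - f) / safe)
        w1 = np.where(r < 1e-6, 1.0 / 3.0, fprime / safe)
        P = V @ V.T
        term1 = (M @ c) * f
        term2 = ((M * P) @ f) * w1
        dV = (term1 - term2)[:, None] * V - f[:, None] * (M @ U)
        return loss, dV, D

    if mode == "poincare":
        h = np.where(r < 1e-12, 1.0, np.tanh(safe) / safe)
        Z = h[:, None] * V
        zsq = np.einsum("ij,ij->i", Z, Z)
        num = np.maximum(zsq[:, None] + zsq[None, :] - 2.0 * (Z @ Z.T), 0.0)
        A = 1.0 - zsq
        den = np.outer(A, A)
        Q = num / den
        G = 1.0 + 2.0 * Q
        np.fill_diagonal(G, 1.0)
        D = np.arccosh(np.maximum(G, 1.0))
        np.fill_diagonal(D, 0.0)

        resid = s * D[iu, ju] / t - 1.0
        loss = float(np.mean(resid**2))
        dLdD = np.zeros((n, n))
        dLdD[iu, ju] = 2.0 * s * resid / t / n_pairs
        dLdD = dLdD + dLdD.T
        root = np.sqrt(np.maximum(G**2 - 1.0, 0.0))
        dDdG = np.where(root > 1e-12, 1.0 / np.where(root > 0, root, 1.0), 0.0)
        M = dLdD * dDdG
        np.fill_diagonal(M, 0.0)

        # G = 1 + 2 |z_i - z_j|^2 / (A_i A_j):
        # dG/dz_i = 4 (z_i - z_j)/(A_i A_j) + 4 Q_ij z_i / A_i
        W = M / den  # symmetric
        row = W.sum(axis=1)
        dZ = 4.0 * (row[:, None] * Z - W @ Z) + 4.0 * (((M * Q).sum(axis=1)) / A)[:, None] * Z
        # chain through z = h(r) v: dv = h dz + (h'(r)/r) (v.dz) v
        sech2 = 1.0 / np.cosh(r) ** 2
        hprime = np.where(r < 1e-6, -2.0 * r / 3.0, (sech2 - h) / safe)
        w1 = np.where(r < 1e-6, -2.0 / 3.0, hprime / safe)
        vdz = np.einsum("ij,ij->i", V, dZ)
        dV = h[:, None] * dZ + (w1 * vdz)[:, None] * V
        return loss, dV, D

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# optimiser states


class _SGD:
    def __init__(self, params: dict[str, np.ndarray]) -> None:
        pass

    def step(self, params: dict, grads: dict, lr: float) -> None:
        for k in params:
            params[k] -= lr * grads[k]


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2, self.eps = b1, b2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop


def train(
    model: EmbeddingModel,
    aln: Alignment,
    tree: dendropy.Tree,
    cfg: TrainingConfig,
) -> tuple[EmbeddingModel, list[dict]]:
    """Fit the encoder and scale to reproduce backbone tree distances.

    Per epoch the leaves are partitioned into random batches; for every
    batch all within-batch pairs enter the loss, a gradient step updates
    the encoder, and the scale takes one relaxed closed-form step.  Returns
    a trained copy of ``model`` and a log with one record per epoch
    (epoch, loss, s, lr).  Deterministic given ``cfg.seed``.
    """
    from .trees import leaf_labels as _leaf_labels

    ids = list(aln.ids)
    tree_ids = set(_leaf_labels(tree))
    if set(ids) != tree_ids:
        only_a = sorted(set(ids) - tree_ids)[:5]
        only_t = sorted(tree_ids - set(ids))[:5]
        raise ValueError(
            f"alignment ids and tree leaf labels differ (alignment-only: {only_a}, "
            f"tree-only: {only_t})"
        )
    if not cfg.allow_duplicates:
        dups = aln.duplicate_groups()
        if dups:
            raise ValueError(
                f"duplicate sequences present (e.g. {dups[0]}); deduplicate or set "
                "allow_duplicates together with a positive pseudo_count"
            )

    work_tree = add_terminal_pseudocounts(tree, cfg.pseudo_count)
    Dfull = normalize_tree_distances(leaf_distance_matrix(work_tree))
    index = {lab: i for i, lab in enumerate(Dfull.labels)}
    off = ~np.eye(len(ids), dtype=bool)
    if np.any(Dfull.matrix[off] <= 0):
        raise ValueError(
            "zero tree distance between distinct leaves; deduplicate the taxa "
            "or use a positive pseudo_count"
        )

    model = model.copy()
    model.normalization_factor = Dfull.normalization_factor
    model.backbone_ids = list(ids)
    mode = model.geometry.mode
    X_all = aln.one_hot()
    row_of = {sid: k for k, sid in enumerate(ids)}

    log: list[dict] = []
    if cfg.epochs == 0:
        return model, log

    # initial scale: closed-form optimum on the untrained embedding
    V0 = encoder_forward(model, X_all)
    D0 = pairwise_unit_distances(V0, mode)
    iu, ju = np.triu_indices(len(ids), k=1)
    tfull = Dfull.matrix[
        [index[i] for i in ids], :][:, [index[i] for i in ids]]
    s = optimal_scale(D0[iu, ju], tfull[iu, ju])
    if not s > 0:
        s = 1.0

    opt = (_Adam if cfg.optimizer == "adam" else _SGD)(model.params)

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg.alpha0, cfg.decay_K, cfg.decay_p)
        scale_alpha = min(lr, 1.0) if cfg.scale_lr_coupled else 1.0
        batches = make_batches(ids, cfg.batch_size, cfg.seed, epoch)
        epoch_losses = []
        epoch_ratios: list[np.ndarray] = []
        for batch in batches:
            if len(batch) < 2:
                continue
            rows = [row_of[b] for b in batch]
            X = X_all[rows]
            tidx = [index[b] for b in batch]
            T = Dfull.matrix[np.ix_(tidx, tidx)]
            V, cache = encoder_forward(model, X, want_cache=True)
            loss, dV, Dunit = loss_and_tangent_grad(V, T, s, mode)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lower alpha0 or check for "
                    "collapsed embeddings"
                )
            grads = encoder_backward(model, cache, dV)
            opt.step(model.params, grads, lr)
            epoch_losses.append(loss)
            bi, bj = np.triu_indices(len(batch), k=1)
            ratios = Dunit[bi, bj] / T[bi, bj]
            epoch_ratios.append(ratios)
            if cfg.scale_per == "batch":
                m2 = float(np.mean(ratios**2))
                if m2 > 0:
                    s = scale_step(s, float(np.mean(ratios)) / m2, scale_alpha)
        if cfg.scale_per == "epoch" and epoch_ratios:
            allr = np.concatenate(epoch_ratios)
            m2 = float(np.mean(allr**2))
            if m2 > 0:
                s = scale_step(s, float(np.mean(allr)) / m2, scale_alpha)
        log.append(
            {"epoch": epoch, "loss": float(np.mean(epoch_losses)), "s": s, "lr": lr}
        )

    model.geometry = dc_replace(model.geometry, scale=s)
    return model, log


def write_training_log(log: list[dict], path: str) -> None:
    """Tab-separated training log: epoch, loss, s, lr."""
    with open(path, "w") as fh:
        fh.write("epoch\tloss\ts\tlr\n")
        for rec in log:
            fh.write(f"{rec['epoch']}\t{rec['loss']:.10g}\t{rec['s']:.10g}\t{rec['lr']:.10g}\n")
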