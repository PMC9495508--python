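"""Constant-curvature geometry for tree-metric embedding.

Two models of d-dimensional hyperbolic space are supported, plus a Euclidean
baseline:

* the Poincare ball ``I_C^d = {x : -C ||x||^2 < 1}`` for curvature ``C < 0``;
* the 'Loid (hyperboloid / Lorentz) model ``L_C^d = {x in R^{d+1} :
  x^T H x = 1/C, x_0 > 0}`` with ``H = diag(-1, 1, ..., 1)``;
* Euclidean mode, where the *squared* Euclidean distance plays the role of
  the metric (the convention used when matching squared distances of
  embedded points to additive tree distances).

All internal computation happens at unit curvature (C = -1); an arbitrary
curvature ``C = -1/s**2`` is expressed through the positive scale ``s`` that
multiplies unit-curvature distances.  This is numerically preferable to
carrying the curvature through ``acosh`` arguments: the domain of every
function below is then independent of the curvature.

Points are plain NumPy arrays in double precision.  Poincare points are
length-``d`` vectors of squared norm < 1; 'Loid points are length-``d+1``
vectors satisfying the Minkowski constraint; tangent vectors (the raw
encoder outputs) are length-``d`` vectors lifted onto the manifold by the
exponential maps :func:`poincare_exp0` and :func:`loid_exp`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryMode",
    "MODES",
    "poincare_distance",
    "loid_distance",
    "euclidean_sq_distance",
    "poincare_exp0",
    "loid_exp",
    "rescale_to_unit_ball",
    "scaled_distance",
    "loid_to_poincare",
    "max_distance_bound",
    "pairwise_unit_distances",
    "embed_tangent",
]

MODES = ("poincare", "loid", "euclidean")

#: slack allowed before an acosh argument < 1 is treated as an invariant
#: violation rather than round-off
ACOSH_CLAMP_TOL = 1e-9

#: tolerance on the Minkowski constraint x^T H x = -1 for 'Loid points
LOID_CONSTRAINT_TOL = 1e-6


@dataclass(frozen=True)
class GeometryMode:
    """Geometry used for embedding: model, scale and dimension.

    ``scale`` is the positive factor ``s`` multiplying unit-curvature
    distances; in the hyperbolic modes it corresponds to curvature
    ``C = -1/s**2``.  In euclidean mode ``s`` multiplies the squared
    Euclidean distance so that the three modes share one API.
    """

    mode: str = "loid"
    scale: float = 1.0
    dimension: int = 2

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown geometry mode {self.mode!r}; expected one of {MODES}")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")

    @property
    def curvature(self) -> float:
        """Curvature C = -1/s**2 (hyperbolic modes); 0 in euclidean mode."""
        if self.mode == "euclidean":
            return 0.0
        return -1.0 / self.scale**2


def _sqrt_neg_c(C: float) -> float:
    if not C < 0:
        raise ValueError(f"curvature must be negative, got {C}")
    return np.sqrt(-C)


def _clamped_acosh(arg: float | np.ndarray) -> np.ndarray:
    """acosh with round-off guard: arguments in [1 - tol, 1) snap to 1."""
    arg = np.asarray(arg, dtype=float)
    below = arg < 1.0
    if np.any(arg < 1.0 - ACOSH_CLAMP_TOL):
        worst = float(np.min(arg))
        raise ValueError(
            f"acosh argument {worst} is below 1 by more than {ACOSH_CLAMP_TOL}: "
            "input points violate the model constraints"
        )
    return np.arccosh(np.where(below, 1.0, arg))


def poincare_distance(x: np.ndarray, y: np.ndarray, C: float = -1.0) -> float:
    """Geodesic distance between two Poincare-ball points at curvature C.

    d(x, y) = (1/sqrt(-C)) * acosh(1 + 2 q / ((1 - q_x)(1 - q_y))) with
    q = -C ||x - y||^2 and q_x = -C ||x||^2 (and similarly q_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = -float(C)
    _sqrt_neg_c(C)
    for name, p in (("x", x), ("y", y)):
        nrm = k * float(p @ p)
        if nrm >= 1.0:
            raise ValueError(
                f"point {name} lies on or outside the curvature-{C} ball: -C*||{name}||^2 = {nrm}"
            )
    dx = x - y
    num = 2.0 * k * float(dx @ dx)
    den = (1.0 - k * float(x @ x)) * (1.0 - k * float(y @ y))
    return float(_clamped_acosh(1.0 + num / den)) / np.sqrt(k)


def _minkowski_inner(x: np.ndarray, y: np.ndarray) -> float:
    return float(-x[0] * y[0] + x[1:] @ y[1:])


def check_loid_point(x: np.ndarray, C: float = -1.0, tol: float = LOID_CONSTRAINT_TOL) -> None:
    """Raise if ``x`` is not on the curvature-C hyperboloid within ``tol``."""
    x = np.asarray(x, dtype=float)
    q = _minkowski_inner(x, x)
    if abs(q - 1.0 / C) > tol:
        raise ValueError(f"point violates the hyperboloid constraint: x^T H x = {q}, expected {1.0 / C}")
    if x[0] <= 0:
        raise ValueError(f"hyperboloid point must have positive first coordinate, got {x[0]}")


def loid_distance(x: np.ndarray, y: np.ndarray, C: float = -1.0) -> float:
    """Geodesic distance on the 'Loid model: (1/sqrt(-C)) * acosh(C * x^T H y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sc = _sqrt_neg_c(C)
    tol = LOID_CONSTRAINT_TOL * max(1.0, 1.0 / -C)
    check_loid_point(x, C, tol)
    check_loid_point(y, C, tol)
    return float(_clamped_acosh(float(C) * _minkowski_inner(x, y))) / sc


def euclidean_sq_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Euclidean distance ||x - y||^2 (not a metric; no triangle inequality)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(d @ d)


def poincare_exp0(v: np.ndarray, C: float = -1.0) -> np.ndarray:
    """Exponential map at the origin of the Poincare ball.

    exp0(v) = tanh(sqrt(-C) ||v||) / (sqrt(-C) ||v||) * v; the zero vector
    maps to the origin.  Output always lies strictly inside the ball.
    """
    v = np.asarray(v, dtype=float)
    sc = _sqrt_neg_c(C)
    r = float(np.linalg.norm(v))
    if r == 0.0:
        return np.zeros_like(v)
    return (np.tanh(sc * r) / (sc * r)) * v


def loid_exp(v: np.ndarray, C: float = -1.0) -> np.ndarray:
    """Exponential map at the apex p0 = (1/sqrt(-C), 0, ..., 0) of the 'Loid model.

    exp_{p0}(v) = cosh(sqrt(-C) ||v||) p0 + sinh(sqrt(-C) ||v||)/(sqrt(-C) ||v||)
    * (0, v).  The zero vector maps to p0.
    """
    v = np.asarray(v, dtype=float)
    sc = _sqrt_neg_c(C)
    r = float(np.linalg.norm(v))
    out = np.zeros(v.size + 1, dtype=float)
    if r == 0.0:
        out[0] = 1.0 / sc
        return out
    out[0] = np.cosh(sc * r) / sc
    out[1:] = (np.sinh(sc * r) / (sc * r)) * v
    return out


def rescale_to_unit_ball(x: np.ndarray, C: float) -> np.ndarray:
    """Map a curvature-C Poincare point onto the unit-curvature ball: x' = sqrt(-C) x."""
    x = np.asarray(x, dtype=float)
    sc = _sqrt_neg_c(C)
    nrm = -float(C) * float(x @ x)
    if nrm >= 1.0:
        raise ValueError(f"point outside the curvature-{C} ball: -C*||x||^2 = {nrm}")
    return sc * x


def scaled_distance(x: np.ndarray, y: np.ndarray, mode: GeometryMode) -> float:
    """Distance s * d_unit(x, y) in the given mode (s * ||x-y||^2 in euclidean mode)."""
    if mode.mode == "poincare":
        return mode.scale * poincare_distance(x, y, -1.0)
    if mode.mode == "loid":
        return mode.scale * loid_distance(x, y, -1.0)
    return mode.scale * euclidean_sq_distance(x, y)


def loid_to_poincare(x: np.ndarray) -> np.ndarray:
    """Stereographic projection from the unit-curvature 'Loid model onto the ball.

    Projection from (-1, 0, ..., 0): spatial part divided by (1 + x_0).
    Unit-curvature distances are preserved (the two models are isometric).
    """
    x = np.asarray(x, dtype=float)
    check_loid_point(x, -1.0)
    return x[1:] / (1.0 + x[0])


def max_distance_bound(p: int) -> float:
    """Largest unit-curvature Poincare distance at p decimal digits of headroom.

    Among points with ||x||^2 <= 1 - 10^-p the distance is bounded by
    ``2 * acosh(1 + 2 (1 - 10^-p) / 10^-p)``, which grows almost linearly in
    p (approximately ``4 ln 2 + 2 p ln 10``).  This motivates normalising
    tree distances before embedding: a fixed floating-point precision only
    accommodates a bounded tree diameter.
    """
    if p < 1:
        raise ValueError(f"p must be a positive integer, got {p}")
    eps = 10.0 ** (-p)
    return 2.0 * float(np.arccosh(1.0 + 2.0 * (1.0 - eps) / eps))


# ---------------------------------------------------------------------------
# batched helpers used by training and placement


def embed_tangent(V: np.ndarray, mode: str) -> np.ndarray:
    """Lift a batch of tangent vectors (N, d) onto the manifold of ``mode``.

    loid -> (N, d+1) hyperboloid points; poincare -> (N, d) ball points;
    euclidean -> identity.
    """
    V = np.asarray(V, dtype=float)
    if mode == "euclidean":
        return V
    r = np.linalg.norm(V, axis=1)
    safe = np.where(r == 0.0, 1.0, r)
    if mode == "poincare":
        return (np.tanh(r) / safe)[:, None] * V
    if mode == "loid":
        out = np.empty((V.shape[0], V.shape[1] + 1), dtype=float)
        out[:, 0] = np.cosh(r)
        out[:, 1:] = (np.sinh(r) / safe)[:, None] * V
        return out
    raise ValueError(f"unknown mode {mode!r}")


def pairwise_unit_distances(V: np.ndarray, mode: str) -> np.ndarray:
    """Unit-curvature pairwise distance matrix from tangent vectors (N, d).

    In euclidean mode this is the matrix of squared Euclidean distances.
    The hyperbolic modes compose the appropriate exponential map with the
    closed-form distance; everything is vectorised and symmetric with an
    exactly zero diagonal.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    if mode == "euclidean":
        sq = np.einsum("ij,ij->i", V, V)
        D = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)
    if mode == "loid":
        r = np.linalg.norm(V, axis=1)
        safe = np.where(r == 0.0, 1.0, r)
        f = np.sinh(r) / safe  # sinh(r)/r, -> 1 as r -> 0
        c = np.cosh(r)
        U = f[:, None] * V
        G = np.outer(c, c) - U @ U.T  # -x^T H y >= 1
        np.fill_diagonal(G, 1.0)
        D = np.arccosh(np.maximum(G, 1.0))
        np.fill_diagonal(D, 0.0)
        return D
    if mode == "poincare":
        r = np.linalg.norm(V, axis=1)
        safe = np.where(r == 0.0, 1.0, r)
        Z = (np.tanh(r) / safe)[:, None] * V
        zsq = np.einsum("ij,ij->i", Z, Z)
        num = zsq[:, None] + zsq[None, :] - 2.0 * (Z @ Z.T)
        num = np.maximum(num, 0.0)
        den = np.outer(1.0 - zsq, 1.0 - zsq)
        G = 1.0 + 2.0 * num / den
        np.fill_diagonal(G, 1.0)
        D = np.arccosh(np.maximum(G, 1.0))
        np.fill_diagonal(D, 0.0)
        return D
    raise ValueError(f"unknown mode {mode!r}")
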