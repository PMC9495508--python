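"""Model / Results interface for sequence-to-tree-distance embedding.

:class:`TreeEmbedding` binds the data (a backbone tree and the matching
aligned sequences) to the geometry and encoder configuration;
:meth:`TreeEmbedding.fit` runs the alternating optimisation and returns a
:class:`TreeEmbeddingResults` carrying the trained encoder, the learned
scale (hence curvature), the training log and evaluation helpers::

    model = TreeEmbedding(alignment, tree, mode="loid", embed_dim=2)
    res = model.fit(epochs=1000, seed=0)
    print(res.summary())
    table = res.query_distances(query_alignment)

The Results object is the unit of persistence: ``res.save(path)`` writes a
checkpoint that :meth:`TreeEmbeddingResults.load` restores.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignio import Alignment, read_fasta
from .encoder import (
    EmbeddingModel,
    EncoderSpec,
    embed_sequences,
    encoder_forward,
    encoder_init,
    load_checkpoint,
    save_checkpoint,
)
from .evaluation import DistortionReport, distortion_report
from .geometry import pairwise_unit_distances
from .placement import QueryDistanceTable, query_distances
from .trees import TreeDistances, leaf_distance_matrix, read_newick
from .training import TrainingConfig, train

__all__ = ["TreeEmbedding", "TreeEmbeddingResults"]


class TreeEmbedding:
    """Embedding model for a backbone tree and its aligned sequences.

    Parameters
    ----------
    alignment : Alignment
        Aligned backbone sequences; ids must match tree leaf labels.
    tree : dendropy.Tree
        Backbone tree with branch lengths (the distance ground truth).
    mode : {"loid", "poincare", "euclidean"}
        Geometry of the embedding space.  The 'Loid (hyperboloid) model is
        the default: its distance function is non-singular away from any
        boundary, which makes optimisation the most stable of the three.
    embed_dim : int
        Embedding dimension d.
    channels, activation : encoder architecture knobs (see EncoderSpec).
    """

    def __init__(
        self,
        alignment: Alignment,
        tree: dendropy.Tree,
        *,
        mode: str = "loid",
        embed_dim: int = 128,
        channels: tuple[int, int, int] = (16, 16, 16),
        activation: bool = True,
        init_seed: int = 0,
    ) -> None:
        self.alignment = alignment
        self.tree = tree
        self.mode = mode
        self.spec = EncoderSpec(
            input_length=alignment.length,
            embed_dim=embed_dim,
            channels=tuple(channels),
            activation=activation,
            seed=init_seed,
        )

    @classmethod
    def from_files(cls, fasta_path: str | Path, newick_path: str | Path, **kw) -> "TreeEmbedding":
        return cls(read_fasta(fasta_path), read_newick(newick_path), **kw)

    def fit(
        self,
        epochs: int = 1000,
        seed: int = 0,
        batch_size: int = 32,
        alpha0: float = 1e-3,
        **cfg_kw,
    ) -> "TreeEmbeddingResults":
        """Run the alternating optimisation and return the results object."""
        cfg = TrainingConfig(
            epochs=epochs, seed=seed, batch_size=batch_size, alpha0=alpha0, **cfg_kw
        )
        start = encoder_init(self.spec, mode=self.mode)
        fitted, log = train(start, self.alignment, self.tree, cfg)
        return TreeEmbeddingResults(self, fitted, log, cfg)


class TreeEmbeddingResults:
    """Trained embedding: encoder parameters, scale, diagnostics."""

    def __init__(
        self,
        model: TreeEmbedding | None,
        fitted: EmbeddingModel,
        log: list[dict],
        config: TrainingConfig | None = None,
    ) -> None:
        self.model = model
        self.embedding_model = fitted
        self.config = config
        self.log = pd.DataFrame(log, columns=["epoch", "loss", "s", "lr"])

    # -- core quantities ---------------------------------------------------

    @property
    def scale_(self) -> float:
        """Learned scale s on normalised distances."""
        return self.embedding_model.geometry.scale

    @property
    def curvature_(self) -> float:
        """Learned curvature of the embedding space, C = -1/s_eff**2.

        Uses the effective scale (scale x normalisation factor) so the
        curvature refers to original tree-distance units.
        """
        if self.embedding_model.geometry.mode == "euclidean":
            return 0.0
        s_eff = self.scale_ * self.embedding_model.normalization_factor
        return -1.0 / s_eff**2

    @property
    def normalization_factor_(self) -> float:
        return self.embedding_model.normalization_factor

    def embed(self, alignment: Alignment | None = None) -> np.ndarray:
        """Manifold coordinates of an alignment (default: training data)."""
        aln = alignment if alignment is not None else self._training_alignment()
        return embed_sequences(self.embedding_model, aln)

    def _training_alignment(self) -> Alignment:
        if self.model is None:
            raise ValueError("results were loaded without the training data")
        return self.model.alignment

    def training_distances(self) -> tuple[np.ndarray, TreeDistances]:
        """(estimated, true) distances between backbone leaves, tree units."""
        aln = self._training_alignment()
        V = encoder_forward(self.embedding_model, aln.one_hot())
        factor = self.scale_ * self.normalization_factor_
        D_est = pairwise_unit_distances(V, self.embedding_model.geometry.mode) * factor
        D_true = leaf_distance_matrix(self.model.tree).submatrix(list(aln.ids))
        return D_est, D_true

    def training_distortion(self, **kw) -> DistortionReport:
        """Distortion of backbone-pair distances (all distinct pairs)."""
        D_est, D_true = self.training_distances()
        iu, ju = np.triu_indices(len(D_true.labels), k=1)
        return distortion_report(D_est[iu, ju], D_true.matrix[iu, ju], **kw)

    def query_distances(self, query_alignment: Alignment) -> QueryDistanceTable:
        """Query x backbone distance table in tree-distance units."""
        return query_distances(
            self.embedding_model, self._training_alignment(), query_alignment
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        m = self.embedding_model
        lines = [
            "Tree embedding results",
            "=" * 46,
            f"geometry mode        {m.geometry.mode}",
            f"embedding dim        {m.geometry.dimension}",
            f"taxa                 {len(m.backbone_ids)}",
            f"alignment length     {m.spec.input_length}",
            f"epochs trained       {len(self.log)}",
            f"scale s (normalised) {self.scale_:.6g}",
            f"normalisation factor {self.normalization_factor_:.6g}",
            f"curvature C          {self.curvature_:.6g}",
        ]
        if len(self.log):
            lines += [
                f"first-epoch loss     {self.log['loss'].iloc[0]:.6g}",
                f"final-epoch loss     {self.log['loss'].iloc[-1]:.6g}",
            ]
        if self.model is not None:
            rep = self.training_distortion()
            lines += [
                "-" * 46,
                "training-pair distortion (tree-distance units)",
                str(rep),
            ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.embedding_model, str(path))

    @classmethod
    def load(
        cls,
        path: str | Path,
        alignment: Alignment | None = None,
        tree: dendropy.Tree | None = None,
    ) -> "TreeEmbeddingResults":
        fitted = load_checkpoint(str(path))
        model = None
        if alignment is not None and tree is not None:
            model = TreeEmbedding(
                alignment,
                tree,
                mode=fitted.geometry.mode,
                embed_dim=fitted.spec.embed_dim,
                channels=fitted.spec.channels,
                activation=fitted.spec.activation,
                init_seed=fitted.spec.seed,
            )
        return cls(model, fitted, [])
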