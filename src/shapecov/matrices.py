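"""Symmetric pairwise similarity matrices over a labelled protein set.

A :class:`SimilarityMatrix` is the common currency of the pipeline: protein
BLOSUM similarity, PFM Pearson similarity and the four shape similarities all
produce one, and the covariation statistics consume pairs of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: metric names with their diagonal/off-diagonal contracts
METRICS = {
    "protein_blosum": None,
    "dna_pfm_pcc": "correlation",  # diagonal 1, values in [-1, 1]
    "shape_mgw": "neg_distance",  # diagonal 0, off-diagonal <= 0
    "shape_prot": "neg_distance",
    "shape_roll": "neg_distance",
    "shape_helt": "neg_distance",
}


@dataclass
class SimilarityMatrix:
    labels: list[str]
    values: np.ndarray
    metric_name: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        finite = self.values[np.isfinite(self.values)]
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        kind = METRICS.get(self.metric_name)
        if kind == "correlation":
            if not np.allclose(np.diag(self.values), 1.0):
                raise ValueError("correlation similarity requires unit diagonal")
            if finite.size and (finite.max() > 1 + 1e-9 or finite.min() < -1 - 1e-9):
                raise ValueError("correlation similarity must lie in [-1, 1]")
        elif kind == "neg_distance":
            if not np.allclose(np.diag(self.values), 0.0):
                raise ValueError("negative-distance similarity requires zero diagonal")
            if finite.size and finite.max() > 1e-9:
                raise ValueError("negative-distance similarity must be <= 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major (the pairwise scores)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def pair_index(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.n, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def reordered(self, labels: list[str]) -> "SimilarityMatrix":
        pos = {lab: i for i, lab in enumerate(self.labels)}
        idx = np.array([pos[lab] for lab in labels])
        return SimilarityMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.metric_name, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path: str | Path, metric_name: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), metric_name)
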