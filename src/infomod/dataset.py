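"""Expression-matrix container and TSV round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")


@dataclass
class ExpressionDataset:
    """A log2 expression matrix (genes x samples) with condition labels.

    Invariants checked at construction: unique gene/sample ids, matrix
    dimensions matching the id lists, and a condition label
    (``"tumor"`` or ``"normal"``) for every sample.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: list[str]
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.condition = list(self.condition)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (genes x samples)")
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.condition) != len(self.sample_ids):
            raise ValueError("every sample needs a condition label")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        return self.matrix[self._gene_index[gene]]

    def condition_mask(self, label: str) -> np.ndarray:
        return np.array([c == label for c in self.condition], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)

    # -- TSV interchange ---------------------------------------------------

    def write_tsv(self, expr_path: str | Path, labels_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (first column ``gene``, header = sample ids)
        and, optionally, the condition labels as a two-column TSV."""
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(expr_path, sep="\t", float_format="%.6f")
        if labels_path is not None:
            pd.DataFrame({"sample": self.sample_ids, "condition": self.condition}).to_csv(
                labels_path, sep="\t", index=False
            )

    @classmethod
    def read_tsv(cls, expr_path: str | Path, labels_path: str | Path) -> "ExpressionDataset":
        frame = pd.read_csv(expr_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)["condition"]
        missing = [s for s in frame.columns if s not in labels.index]
        if missing:
            raise ValueError(f"samples without condition labels: {missing[:5]}")
        return cls(
            matrix=frame.to_numpy(dtype=float),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            condition=[str(labels[s]) for s in frame.columns],
        )
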