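"""Labelled species × species matrices ("layers") shared across the pipeline.

Each layer of the multi-layer network — alarm relevance R, diet overlap O,
habitat difference H, movement similarity J, phylogenetic relatedness E,
affinity W/w, directed affinity, competition k — is a square matrix over the
same ordered species list. The diagonal carries a species' value against
itself and is excluded from all dyadic regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["DyadLayer"]

#: layer roles that are inherently asymmetric (directed)
DIRECTED_ROLES = {"R", "k", "w_directed"}


@dataclass
class DyadLayer:
    labels: tuple
    values: np.ndarray
    role: str = ""
    symmetric: bool = False

    def __post_init__(self):
        self.labels = tuple(str(s) for s in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(f"layer {self.role!r}: matrix must be square")
        if self.values.shape[0] != len(self.labels):
            raise ValidationError(
                f"layer {self.role!r}: {len(self.labels)} labels for "
                f"{self.values.shape[0]}x{self.values.shape[1]} matrix"
            )
        if self.symmetric:
            v = self.values
            mask = np.isfinite(v) & np.isfinite(v.T)
            if not np.allclose(v[mask], v.T[mask], atol=1e-8):
                raise ValidationError(f"layer {self.role!r} declared symmetric but is not")

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Off-diagonal entries, row-major (the dyadic observation vector)."""
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path):
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, role: str = "", symmetric: bool = False):
        if list(frame.index) != list(frame.columns):
            raise ValidationError(f"layer {role!r}: row and column labels differ")
        return cls(tuple(frame.index), frame.to_numpy(dtype=float), role, symmetric)

    @classmethod
    def from_csv(cls, path, role: str = "", symmetric: bool = False):
        frame = pd.read_csv(path, index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return cls.from_frame(frame, role, symmetric)

    def reorder(self, labels) -> "DyadLayer":
        """Return the layer re-indexed to ``labels`` (error on missing species)."""
        labels = tuple(str(s) for s in labels)
        missing = [s for s in labels if s not in self.labels]
        if missing:
            raise ValidationError(f"layer {self.role!r} missing species: {missing}")
        idx = [self.labels.index(s) for s in labels]
        return DyadLayer(labels, self.values[np.ix_(idx, idx)], self.role, self.symmetric)
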