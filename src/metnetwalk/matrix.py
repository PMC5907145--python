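"""Symmetric entity-by-entity similarity matrices with TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix"]


@dataclass
class SimilarityMatrix:
    """A square symmetric similarity matrix over a fixed entity ordering.

    Invariants: unit diagonal, symmetry, and all entries in [0, 1].
    ``validate()`` checks them; constructors in this package guarantee
    them, but matrices read from disk are validated on load.
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.ids)} ids"
            )
        self._index = {e: i for i, e in enumerate(self.ids)}

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity matrix diagonal is not 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")

    def loc(self, a: str, b: str) -> float:
        """Similarity between two entities by id."""
        return float(self.values[self._index[a], self._index[b]])

    def index_of(self, entity: str) -> int:
        return self._index[entity]

    def __contains__(self, entity: str) -> bool:
        return entity in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ids differ")
        mat = cls(ids=tuple(df.index), values=df.to_numpy(dtype=float))
        mat.validate(atol=1e-6)
        return mat
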