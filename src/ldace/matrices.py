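"""Square similarity matrices over a fixed, ordered set of entity ids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimilarityMatrix:
    """Symmetric similarity matrix with an ordered id index.

    Parameters
    ----------
    values
        Square array, entries in [0, 1], symmetric.
    index
        Ordered entity identifiers; ``values[i, j]`` is the similarity
        between ``index[i]`` and ``index[j]``.
    defined_mask
        Optional boolean flag per entity.  Used by semantic similarity to
        mark diseases that have a vocabulary entry; rows/columns of
        unflagged entities hold placeholder zeros and must not be read as
        similarities.
    """

    values: np.ndarray
    index: list[str]
    defined_mask: np.ndarray | None = None
    _pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.values.shape[0] != len(self.index):
            raise ValueError("index length does not match matrix dimension")
        if self.defined_mask is not None:
            self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
            if self.defined_mask.shape != (len(self.index),):
                raise ValueError("defined_mask length does not match index")
        self._pos = {e: i for i, e in enumerate(self.index)}

    @property
    def n(self) -> int:
        return len(self.index)

    def position(self, entity_id: str) -> int:
        try:
            return self._pos[entity_id]
        except KeyError:
            raise KeyError(f"unknown entity id: {entity_id!r}") from None

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.position(entity_id)]

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.position(i), self.position(j)])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.index, columns=self.index)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(dtype=float), index=[str(c) for c in df.columns])
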