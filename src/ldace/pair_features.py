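"""Pair feature vectors: concatenated similarity-matrix rows with labels.

A (disease, lncRNA) pair is represented by the disease's row of the
integrated disease similarity matrix DS followed by the lncRNA's row of
the lncRNA similarity matrix RS, giving a vector of length
``n_diseases + n_lncrnas`` (1209 at the scale of the reference corpus of
328 diseases and 881 lncRNAs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AssociationTable
from .matrices import SimilarityMatrix


@dataclass
class LabeledPairSet:
    vectors: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not (
            self.vectors.shape[0] == self.labels.shape[0] == len(self.provenance)
        ):
            raise ValueError("vectors, labels and provenance lengths disagree")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.vectors.shape[0]

    def subset(self, idx: np.ndarray) -> "LabeledPairSet":
        idx = np.asarray(idx)
        return LabeledPairSet(
            self.vectors[idx],
            self.labels[idx],
            [self.provenance[int(i)] for i in idx],
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.vectors)
        df.insert(0, "label", self.labels)
        df.insert(0, "lncrna", [r for _, r in self.provenance])
        df.insert(0, "disease", [d for d, _ in self.provenance])
        df.to_csv(path, sep="\t", index=False)


def make_pair_vector(
    ds: SimilarityMatrix, rs: SimilarityMatrix, disease_id: str, lncrna_id: str
) -> np.ndarray:
    """Concatenate the DS row of a disease with the RS row of a lncRNA."""
    return np.concatenate([ds.row(disease_id), rs.row(lncrna_id)])


def build_dataset(
    ds: SimilarityMatrix,
    rs: SimilarityMatrix,
    positives: AssociationTable,
    negatives: list[tuple[str, str]],
) -> LabeledPairSet:
    """Stack labeled pair vectors: positives (label 1) then negatives (label 0)."""
    overlap = set(positives.records) & set(negatives)
    if overlap:
        raise ValueError(f"positive/negative sets overlap: {sorted(overlap)[:3]}")
    pairs = list(positives.records) + list(negatives)
    vectors = np.stack([make_pair_vector(ds, rs, d, r) for d, r in pairs])
    labels = np.concatenate(
        [np.ones(len(positives.records)), np.zeros(len(negatives))]
    )
    return LabeledPairSet(vectors, labels, pairs)
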