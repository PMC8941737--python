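"""Association tables, the binary adjacency matrix, and vocabulary files.

File dialects
-------------
Association table: two columns ``disease<TAB>lncrna`` (comma also accepted),
UTF-8, ``#`` comment lines ignored, optional header auto-detected.

Vocabulary: ``term<TAB>treenum[;treenum...]`` where each tree number is a
dot-separated hierarchical code such as ``C17.300.480``; dropping the last
segment of a tree number names the parent position in the hierarchy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")
_HEADER_DISEASE = {"disease", "disease_id", "disease_name"}
_HEADER_LNCRNA = {"lncrna", "lncrna_id", "lncrna_name", "rna", "rna_id"}


class ParseError(ValueError):
    """Raised for malformed association or vocabulary files."""


def normalize_id(raw: str) -> str:
    """Lowercase, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", raw.strip().lower())


@dataclass
class AssociationTable:
    """Deduplicated (disease, lncRNA) pairs in first-occurrence order."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.records)) != len(self.records):
            raise ValueError("association table contains duplicate pairs")
        for d, r in self.records:
            if not d or not r:
                raise ValueError("association identifiers must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def diseases(self) -> list[str]:
        return sorted({d for d, _ in self.records})

    @property
    def lncrnas(self) -> list[str]:
        return sorted({r for _, r in self.records})

    def without_disease(self, disease_id: str) -> "AssociationTable":
        """Copy with every pair of one disease removed (cold-start setup)."""
        return AssociationTable([(d, r) for d, r in self.records if d != disease_id])


@dataclass
class AdjacencyMatrix:
    """Binary disease x lncRNA matrix A with stable row/column indexes."""

    values: np.ndarray
    disease_index: dict[str, int]
    lncrna_index: dict[str, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("adjacency must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def diseases(self) -> list[str]:
        return list(self.disease_index)

    @property
    def lncrnas(self) -> list[str]:
        return list(self.lncrna_index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positive_pairs(self) -> list[tuple[str, str]]:
        ds, rs = self.diseases, self.lncrnas
        return [(ds[i], rs[j]) for i, j in zip(*np.nonzero(self.values))]


@dataclass
class MeshVocabulary:
    """Map from a normalized disease term to its set of tree numbers."""

    term_to_treenums: dict[str, set[str]]
    treenum_to_term: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.treenum_to_term = {}
        for term, tns in self.term_to_treenums.items():
            for tn in tns:
                if not _TREE_NUMBER_RE.match(tn):
                    raise ParseError(
                        f"invalid tree number {tn!r} for term {term!r}"
                    )
                self.treenum_to_term[tn] = term

    def __contains__(self, term: str) -> bool:
        return term in self.term_to_treenums

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MeshVocabulary)
            and self.term_to_treenums == other.term_to_treenums
        )


def _split_fields(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)]


def read_associations(path) -> AssociationTable:
    """Parse a two-column association file, normalizing and deduplicating.

    The first non-comment line is treated as a header when both of its
    fields are recognizable column names (e.g. ``disease``/``lncrna``).
    """
    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    first_data_line = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = _split_fields(line)
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 fields, got {len(fields)}"
                )
            d, r = normalize_id(fields[0]), normalize_id(fields[1])
            if first_data_line:
                first_data_line = False
                if d in _HEADER_DISEASE and r in _HEADER_LNCRNA:
                    continue
            if not d or not r:
                raise ParseError(f"line {lineno}: empty identifier")
            if (d, r) not in seen:
                seen.add((d, r))
                records.append((d, r))
    if not records:
        raise ParseError(f"no association records found in {path}")
    return AssociationTable(records)


def write_associations(table: AssociationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\tlncrna\n")
        for d, r in table.records:
            fh.write(f"{d}\t{r}\n")


def build_adjacency(
    table: AssociationTable,
    diseases: list[str] | None = None,
    lncrnas: list[str] | None = None,
) -> AdjacencyMatrix:
    """Build the binary matrix A with A(i,j)=1 iff (disease i, lncRNA j) is known.

    Row/column order is lexicographic in the identifiers so that every
    downstream matrix inherits a deterministic index.  Explicit entity
    universes may be supplied to keep rows for entities whose pairs were
    withheld (cold-start evaluation).
    """
    if not table.records:
        raise ValueError("association table is empty")
    ds = sorted(set(table.diseases) | set(diseases or []))
    rs = sorted(set(table.lncrnas) | set(lncrnas or []))
    disease_index = {d: i for i, d in enumerate(ds)}
    lncrna_index = {r: j for j, r in enumerate(rs)}
    values = np.zeros((len(ds), len(rs)), dtype=np.int8)
    for d, r in table.records:
        values[disease_index[d], lncrna_index[r]] = 1
    return AdjacencyMatrix(values, disease_index, lncrna_index)


def read_mesh_vocabulary(path) -> MeshVocabulary:
    """Parse a flat ``term<TAB>treenum[;treenum...]`` vocabulary file."""
    term_to_treenums: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            term = normalize_id(fields[0])
            if lineno == 1 and term == "term":
                continue
            tns = {tn.strip() for tn in fields[1].split(";") if tn.strip()}
            if not tns:
                raise ParseError(f"line {lineno}: term {term!r} has no tree numbers")
            for tn in tns:
                if not _TREE_NUMBER_RE.match(tn):
                    raise ParseError(
                        f"line {lineno}: invalid tree number {tn!r} for term {term!r}"
                    )
            term_to_treenums.setdefault(term, set()).update(tns)
    if not term_to_treenums:
        raise ParseError(f"no vocabulary entries found in {path}")
    return MeshVocabulary(term_to_treenums)


def write_mesh_vocabulary(vocab: MeshVocabulary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(vocab.term_to_treenums):
            tns = ";".join(sorted(vocab.term_to_treenums[term]))
            fh.write(f"{term}\t{tns}\n")


def sample_negatives(
    adj: AdjacencyMatrix, n: int, rng_seed: int
) -> list[tuple[str, str]]:
    """Draw n unlabeled (disease, lncRNA) pairs uniformly without replacement.

    The draw is over all zero cells of the adjacency matrix — the standard
    down-sampling scheme that pairs each validated positive with a random
    unlabeled pair.  Identical seed gives an identical list.
    """
    flat_zeros = np.flatnonzero(adj.values.ravel() == 0)
    if n > flat_zeros.size:
        raise ValueError(
            f"requested {n} negatives but only {flat_zeros.size} unlabeled pairs exist"
        )
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(flat_zeros, size=n, replace=False)
    n_r = adj.values.shape[1]
    ds, rs = adj.diseases, adj.lncrnas
    return [(ds[int(c) // n_r], rs[int(c) % n_r]) for c in chosen]
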