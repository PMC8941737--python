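"""Gaussian interaction-profile (GIP) kernel similarity.

Each entity is represented by its binary interaction profile — the row
(disease) or column (lncRNA) of the adjacency matrix — and compared with
an RBF kernel ``K(i, j) = exp(-alpha * ||p_i - p_j||^2)``.  The bandwidth
``alpha`` is a raw parameter ``alpha_prime`` rescaled by the mean squared
profile norm, so the kernel adapts to the density of the association
matrix.  The canonical rescaling divides by the mean squared norm;
``bandwidth_rule="multiply"`` is kept as a sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .data_io import AdjacencyMatrix
from .matrices import SimilarityMatrix


@dataclass
class InteractionProfile:
    """One entity's binary association vector."""

    entity_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector)
        if not np.isin(self.vector, (0, 1)).all():
            raise ValueError("interaction profile entries must be 0 or 1")


def _kernel(profiles: np.ndarray, alpha_prime: float, bandwidth_rule: str) -> np.ndarray:
    mean_sq_norm = float(np.mean((profiles**2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    if bandwidth_rule == "divide":
        alpha = alpha_prime / mean_sq_norm
    elif bandwidth_rule == "multiply":
        alpha = alpha_prime * mean_sq_norm
    else:
        raise ValueError(f"unknown bandwidth_rule: {bandwidth_rule!r}")
    sq_dists = squareform(pdist(profiles.astype(float), "sqeuclidean"))
    values = np.exp(-alpha * sq_dists)
    np.fill_diagonal(values, 1.0)
    return values


def gip_kernel_matrix(
    profiles: list[InteractionProfile],
    alpha_prime: float = 0.5,
    bandwidth_rule: str = "divide",
) -> SimilarityMatrix:
    """RBF kernel matrix over binary interaction profiles.

    Requires at least one profile with a nonzero entry, otherwise the
    adaptive bandwidth is undefined.
    """
    if not profiles:
        raise ValueError("no profiles given")
    lengths = {p.vector.shape[0] for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have inconsistent lengths")
    mat = np.stack([p.vector for p in profiles]).astype(float)
    values = _kernel(mat, alpha_prime, bandwidth_rule)
    return SimilarityMatrix(values, [p.entity_id for p in profiles])


def disease_gip(
    adj: AdjacencyMatrix, alpha_prime: float = 0.5, bandwidth_rule: str = "divide"
) -> SimilarityMatrix:
    """GIP kernel between diseases (profiles = rows of A over lncRNAs)."""
    values = _kernel(adj.values.astype(float), alpha_prime, bandwidth_rule)
    return SimilarityMatrix(values, adj.diseases)


def lncrna_gip(
    adj: AdjacencyMatrix, alpha_prime: float = 0.5, bandwidth_rule: str = "divide"
) -> SimilarityMatrix:
    """GIP kernel between lncRNAs (profiles = columns of A over diseases).

    With no other lncRNA annotation available this kernel is used directly
    as the lncRNA similarity matrix RS.
    """
    values = _kernel(adj.values.T.astype(float), alpha_prime, bandwidth_rule)
    return SimilarityMatrix(values, adj.lncrnas)


def integrate_disease_similarity(
    ds1: SimilarityMatrix,
    ds2: SimilarityMatrix,
    dg: SimilarityMatrix,
    rule: str = "presence",
) -> SimilarityMatrix:
    """Final disease similarity DS: semantic average where defined, else GIP.

    ``DS(i,j) = (DS1(i,j) + DS2(i,j)) / 2`` when both diseases have
    semantic similarity, otherwise the GIP value ``DG(i,j)``.  With the
    default ``rule="presence"`` a pair counts as semantic when both
    diseases have vocabulary entries; ``rule="nonzero"`` additionally
    requires the pair to share at least one ancestor (DS1 > 0).
    """
    if not (ds1.index == ds2.index == dg.index):
        raise ValueError("similarity matrices have mismatched indexes")
    if ds1.defined_mask is None or ds2.defined_mask is None:
        raise ValueError("semantic matrices must carry a defined_mask")
    if not np.array_equal(ds1.defined_mask, ds2.defined_mask):
        raise ValueError("semantic matrices disagree on the defined_mask")
    mask = ds1.defined_mask
    pair_defined = np.outer(mask, mask)
    if rule == "nonzero":
        pair_defined &= ds1.values > 0
    elif rule != "presence":
        raise ValueError(f"unknown integration rule: {rule!r}")
    values = np.where(pair_defined, (ds1.values + ds2.values) / 2.0, dg.values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ds1.index), defined_mask=mask.copy())
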