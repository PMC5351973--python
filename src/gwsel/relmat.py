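"""Genomic relationship matrix (VanRaden), IBS distance, and classical MDS.

``compute_grm`` implements VanRaden's method 1,

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

with Z the column-centered allele-dose matrix and p_j the observed allele
frequencies.  ``compute_ibs_distance`` gives the identity-by-state
dissimilarity used for the diversity analysis, and ``classical_mds`` the
principal-coordinates embedding of that distance (the first two axes are what
gets plotted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .io import DOMINANT, MarkerMatrix

logger = logging.getLogger("gwsel")


@dataclass
class RelationshipMatrix:
    """Symmetric n x n plant-by-plant matrix (GRM or IBS distance)."""

    values: np.ndarray
    plant_ids: list
    kind: str                           # "grm" | "ibs_distance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.plant_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.plant_ids, columns=self.plant_ids)


@dataclass
class MDSResult:
    """Principal-coordinates embedding: top-k axes plus the full spectrum."""

    coordinates: np.ndarray             # n x k, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray             # full spectrum, descending
    plant_ids: list


def centered_doses(geno: MarkerMatrix):
    """Column-centered dose matrix Z and the VanRaden denominator.

    Dominant markers enter as dose equivalents {0, 2}; the denominator is
    2 * sum_j p_j (1 - p_j) over observed allele frequencies.
    """
    doses = geno.doses()
    if np.isnan(doses).any():
        raise ValueError("missing genotypes: impute before computing relationships")
    p = doses.mean(axis=0) / 2.0
    Z = doses - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    return Z, denom, p


def compute_grm(geno: MarkerMatrix, ridge: float = 1e-6) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    A small ``ridge`` (default 1e-6) is added to the diagonal so the result
    is safely invertible for downstream solves; pass ``ridge=0`` for the
    exact formula.
    """
    Z, denom, _ = centered_doses(geno)
    if denom <= 0.0:
        raise ZeroDivisionError(
            "all markers monomorphic: VanRaden denominator is zero"
        )
    if (geno.marker_type == DOMINANT).any():
        logger.debug(
            "GRM includes %d dominant markers as {0,2} dose equivalents",
            int((geno.marker_type == DOMINANT).sum()),
        )
    G = (Z @ Z.T) / denom
    G[np.diag_indices_from(G)] += ridge
    return RelationshipMatrix(G, list(geno.plant_ids), "grm")


def compute_ibs_distance(geno: MarkerMatrix) -> RelationshipMatrix:
    """Identity-by-state dissimilarity d_ij = 1 - mean marker allele sharing.

    Codominant markers share ``1 - |dose_i - dose_j| / 2``; dominant markers
    contribute 1 when the presence/absence calls agree and 0 otherwise.
    """
    if geno.n_markers == 0:
        raise ValueError("cannot compute IBS distance with zero markers")
    vals = geno.values
    if np.isnan(vals).any():
        raise ValueError("missing genotypes: impute before computing IBS distance")
    dom = geno.marker_type == DOMINANT
    n = geno.n_plants
    D = np.zeros((n, n))
    codom_vals = vals[:, ~dom]
    dom_vals = vals[:, dom]
    for i in range(n):
        # vectorized over the pairs (i, *)
        share_codom = 1.0 - np.abs(codom_vals[i] - codom_vals) / 2.0
        share_dom = (dom_vals[i] == dom_vals).astype(float)
        D[i] = 1.0 - (share_codom.sum(axis=1) + share_dom.sum(axis=1)) / geno.n_markers
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return RelationshipMatrix(D, list(geno.plant_ids), "ibs_distance")


def classical_mds(dist: RelationshipMatrix, k: int = 2) -> MDSResult:
    """Principal-coordinates analysis (classical/metric MDS).

    Eigendecomposes the double-centered squared-distance matrix
    ``-1/2 J D^2 J``; coordinates are the top-k eigenvectors scaled by the
    square root of their (positive) eigenvalues.  Negative eigenvalues are
    reported in the spectrum but their axes are never returned.
    """
    if dist.kind != "ibs_distance":
        logger.warning("classical_mds expects an IBS distance matrix")
    D2 = dist.values ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    w, V = eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    n_pos = int((w > 1e-12).sum())
    if k > n_pos:
        logger.warning(
            "requested %d MDS axes but only %d positive eigenvalues; returning %d",
            k, n_pos, n_pos,
        )
        k = n_pos
    coords = V[:, :k] * np.sqrt(w[:k])
    coords = coords - coords.mean(axis=0)   # numerically exact centering
    return MDSResult(coords, w, list(dist.plant_ids))
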