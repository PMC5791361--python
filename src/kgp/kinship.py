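"""Relationship matrices: pedigree A (tabular method) and genomic G (VanRaden).

The numerator relationship matrix A holds expected additive
relationships from the pedigree: A_ii = 1 + F_i (F = inbreeding
coefficient, half the relationship of the parents) and, for j earlier
in a topological order than i with parents (s, d),
A_ij = 0.5·(A_js + A_jd).

The genomic matrix follows VanRaden's first method: dosages centered by
twice the observed allele frequency, G = φ·WW′ with the normalisation
constant φ = 1/Σ_j 2p_j(1−p_j) over polymorphic markers.  Under this
scaling Var(g) = Gσ²_g with σ²_g the additive genetic variance, and the
diagonal of G averages ~1 in an outbred sample.  A small ridge (1e-6)
is added to the diagonal so G is strictly positive definite before any
downstream inversion.
"""

from __future__ import annotations

import numpy as np

from .data_model import GenotypeMatrix, KinshipMatrix, Pedigree
from .marker_stats import allele_frequencies

__all__ = [
    "numerator_relationship_matrix",
    "genomic_relationship_matrix",
    "center_dosages",
]

G_RIDGE = 1e-6


def numerator_relationship_matrix(p: Pedigree) -> KinshipMatrix:
    """Pedigree numerator relationship matrix A via the tabular method."""
    order = p.topological_order()
    pos = {ind: i for i, ind in enumerate(order)}
    parents = {
        r.id: (r.sire, r.dam) for r in p.records.itertuples()
    }
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        si = pos[s] if s is not None else None
        di = pos[d] if d is not None else None
        if i > 0:
            row = np.zeros(i)
            if si is not None:
                row += A[si, :i]
            if di is not None:
                row += A[di, :i]
            A[i, :i] = 0.5 * row
            A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # return in the pedigree's record order
    perm = np.array([pos[i] for i in p.ids])
    return KinshipMatrix(p.ids, A[np.ix_(perm, perm)], kind="pedigree")


def center_dosages(
    X: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Center a complete dosage array by 2p (columns with NaN p -> 0)."""
    p = np.where(np.isnan(p), 0.0, p)
    return np.asarray(X, dtype=float) - 2.0 * p


def _vanraden(X: np.ndarray, freqs: np.ndarray | None = None, ridge: float = G_RIDGE):
    """Return (G, phi, polymorphic mask, W) for a NaN-free or NaN-coded array."""
    X = np.asarray(X, dtype=float)
    p = allele_frequencies(X) if freqs is None else np.asarray(freqs, dtype=float)
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if poly.sum() < 1:
        raise ValueError("all markers monomorphic: genomic matrix undefined")
    Xp = X[:, poly]
    pp = p[poly]
    # mean-impute any remaining missing calls at 2p before centering
    Xp = np.where(np.isnan(Xp), 2.0 * pp, Xp)
    W = Xp - 2.0 * pp
    phi = 1.0 / float(np.sum(2.0 * pp * (1.0 - pp)))
    G = phi * (W @ W.T)
    G[np.diag_indices_from(G)] += ridge
    return G, phi, poly, W

def genomic_relationship_matrix(
    g: GenotypeMatrix, method: str = "vanraden1", ridge: float = G_RIDGE
) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed (at 2p) before centering;
    monomorphic markers are excluded from both W and the φ sum.
    Requires at least two polymorphic markers.
    """
    if method != "vanraden1":
        raise ValueError(f"unknown GRM method {method!r}")
    X = g.to_float()
    G, phi, poly, _ = _vanraden(X, ridge=ridge)
    return KinshipMatrix(g.individual_ids, G, kind="genomic", phi=phi)
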