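"""Numerator, genomic and combined relationship matrices and their inverses.

The additive (numerator) relationship matrix A collects expected additive
genetic relationships implied by a pedigree; its inverse is very sparse,
with nonzero off-diagonals only between mates and between parents and
offspring, and is assembled animal-by-animal with Henderson's rules from
the Mendelian-sampling variances.  Exact Mendelian-sampling variances
require inbreeding coefficients, computed here with the Meuwissen–Luo
algorithm.  The dense tabular A serves as the independent oracle for the
sparse machinery on small pedigrees.

For single-step evaluations, the genomic relationship matrix G (VanRaden
method 1, blended with the pedigree block for positive definiteness)
replaces the pedigree prior on genotyped animals through the standard
H-inverse correction, which is dense only on the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree, TierPartition, extract_subpedigree

DENSE_CAP = 4000  # guard: tabular A is a test oracle, not a production path


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by the Meuwissen–Luo algorithm.

    Founders (unknown both parents) get 0.  F_i = a(sire, dam)/2 is
    accumulated from the Cholesky row L_i of A without forming A:
    walking the ancestor list of animal i from youngest to oldest,
    ``L[j] += L[child]/2`` for each known parent j, and
    ``F_i + 1 = Σ_j L_j² d_j`` with d_j the Mendelian-sampling variance.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.zeros(n)  # Mendelian-sampling variance of each animal, filled in order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, m = sire[i], dam[i]
        if s < 0 and m < 0:
            d[i] = 1.0
            F[i] = 0.0
            continue
        if s < 0 or m < 0:
            k = s if s >= 0 else m
            d[i] = 0.75 - 0.25 * F[k]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        # accumulate L row over ancestors of i
        L = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F


def build_A_tabular(ped: Pedigree, cap: int = DENSE_CAP) -> np.ndarray:
    """Dense A by the recursive tabular method (oracle for small pedigrees).

    a_ij (j younger) = (a_i,sire(j) + a_i,dam(j)) / 2, zero for unknown;
    a_jj = 1 + a_sire(j),dam(j) / 2.
    """
    n = ped.n
    if n > cap:
        raise ValueError(f"dense A capped at {cap} animals, pedigree has {n}")
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for j in range(n):
        s, m = sire[j], dam[j]
        A[j, j] = 1.0 + (0.5 * A[s, m] if (s >= 0 and m >= 0) else 0.0)
        for i in range(j):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[i, s]
            if m >= 0:
                val += 0.5 * A[i, m]
            A[i, j] = A[j, i] = val
    return A


def _mendelian_ratio(ped: Pedigree, with_inbreeding: bool) -> np.ndarray:
    """Per-animal inverse Mendelian-sampling variance m_i = 1/d_i."""
    sire, dam = ped.sire, ped.dam
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    if with_inbreeding:
        F = inbreeding_coefficients(ped)
        d = np.ones(ped.n)
        d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
        known = np.where(sire >= 0, sire, dam)
        d[one] = 0.75 - 0.25 * F[known[one]]
        return 1.0 / d
    m = np.ones(ped.n)
    m[both] = 2.0
    m[one] = 4.0 / 3.0
    return m


def build_A_inverse(ped: Pedigree, with_inbreeding: bool = True) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules.

    For each animal i with inverse Mendelian-sampling variance m_i: add
    m_i at (i,i), −m_i/2 at (i,parent), and m_i/4 at (parent,parent)
    cells for every ordered pair of known parents.  With
    ``with_inbreeding=False`` the classic 2 / 4⁄3 / 1 constants are used.
    """
    m = _mendelian_ratio(ped, with_inbreeding)
    rows, cols, vals = [], [], []
    sire, dam = ped.sire, ped.dam
    for i in range(ped.n):
        par = [p for p in (sire[i], dam[i]) if p >= 0]
        mi = m[i]
        rows.append(i); cols.append(i); vals.append(mi)
        for p in par:
            rows += [i, p]; cols += [p, i]; vals += [-mi / 2, -mi / 2]
        for p in par:
            for q in par:
                rows.append(p); cols.append(q); vals.append(mi / 4)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()


def build_external_inverse(
    ped: Pedigree, part: TierPartition, with_inbreeding: bool = True
) -> sp.csr_matrix:
    """A-inverse E of the external pedigree (d ∪ a, parents clipped).

    Returned in the order of ``part.e_idx`` (internal order restricted to
    the external animals), so its aa-block aligns with ``part.a_idx``.
    """
    e_idx = part.e_idx
    sub = extract_subpedigree(ped, [ped.labels[i] for i in e_idx], mode="clip-parents")
    return build_A_inverse(sub, with_inbreeding=with_inbreeding)


def block(mat: sp.spmatrix, rows: np.ndarray, cols: np.ndarray) -> sp.csr_matrix:
    """Extract a block by index arrays from a sparse matrix."""
    return mat.tocsr()[rows, :][:, cols]


def faa_minus_eaa(
    ped: Pedigree, part: TierPartition, with_inbreeding: bool = True
) -> sp.csr_matrix:
    """F^aa − E^aa in a single pass through the current animals.

    The full-pedigree inverse F⁻¹ and the external-pedigree inverse E
    receive identical Henderson contributions from every external animal
    (their parents lie in the external set), so the difference on the
    a × a block is exactly the sum of the (parent, parent) contributions
    m_i/4 of current animals whose parents lie in set a.
    """
    m = _mendelian_ratio(ped, with_inbreeding)
    in_a = np.zeros(ped.n, dtype=bool)
    in_a[part.a_idx] = True
    apos = {int(g): k for k, g in enumerate(part.a_idx)}
    na = len(part.a_idx)
    rows, cols, vals = [], [], []
    for i in part.c_idx:
        par = [p for p in ped.parents_of(i) if p >= 0 and in_a[p]]
        for p in par:
            for q in par:
                rows.append(apos[p]); cols.append(apos[q]); vals.append(m[i] / 4)
    return sp.coo_matrix((vals, (rows, cols)), shape=(na, na)).tocsr()


@dataclass
class GenomicRelationship:
    """VanRaden method-1 G over genotyped animals, blended for invertibility."""

    G: np.ndarray
    ids: list
    freqs: np.ndarray
    blend: float


def build_grm(
    genotypes: np.ndarray,
    ids: list,
    freqs: np.ndarray | None = None,
    blend: float = 0.95,
    A_gg: np.ndarray | None = None,
) -> GenomicRelationship:
    """VanRaden method-1 genomic relationship matrix.

    Centers the 0/1/2 genotype matrix by twice the allele frequencies and
    scales by 2 Σ p(1−p); the result is blended as
    ``blend·G + (1−blend)·A_gg`` (identity if ``A_gg`` is None and
    blend < 1) so downstream inverses exist.
    """
    M = np.asarray(genotypes, dtype=float)
    if M.ndim != 2 or M.shape[0] != len(ids):
        raise ValueError("genotypes must be animals × markers matching ids")
    if freqs is None:
        freqs = M.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom <= 0:
        raise ValueError("all markers monomorphic: G denominator is zero")
    W = M - 2.0 * freqs
    G = (W @ W.T) / denom
    if blend < 1.0:
        base = np.eye(len(ids)) if A_gg is None else np.asarray(A_gg)
        G = blend * G + (1.0 - blend) * base
    return GenomicRelationship(G=G, ids=list(ids), freqs=freqs, blend=blend)


@dataclass
class HInverse:
    """Single-step H⁻¹: sparse F⁻¹ plus a dense correction on genotyped animals."""

    matrix: sp.csr_matrix
    genotyped_idx: np.ndarray


def build_H_inverse(
    Finv: sp.spmatrix,
    grm: GenomicRelationship,
    ped: Pedigree,
    A: np.ndarray | None = None,
) -> HInverse:
    """H⁻¹ = F⁻¹ + pad(G⁻¹ − A_gg⁻¹) on the genotyped block.

    ``grm.ids`` must all be pedigree animals; A over the genotyped
    animals is taken from the dense tabular A (computed here if not
    supplied).  Raises on numerically singular G or A_gg, suggesting
    stronger blending.
    """
    gidx = np.array([ped.index[str(g)] for g in grm.ids], dtype=np.int64)
    if A is None:
        A = build_A_tabular(ped)
    Agg = A[np.ix_(gidx, gidx)]
    try:
        Ginv = np.linalg.inv(grm.G)
        Agg_inv = np.linalg.inv(Agg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "G or A_gg is singular; use a smaller blend weight (stronger "
            "blending toward the pedigree block)"
        ) from exc
    for M, nm in ((Ginv, "G"), (Agg_inv, "A_gg")):
        c = np.linalg.cond(M)
        if not np.isfinite(c) or c > 1e12:
            raise np.linalg.LinAlgError(
                f"{nm} is numerically singular (cond={c:.2e}); "
                "use stronger blending"
            )
    corr = sp.coo_matrix(
        (
            (Ginv - Agg_inv).ravel(),
            (np.repeat(gidx, gidx.size), np.tile(gidx, gidx.size)),
        ),
        shape=Finv.shape,
    )
    return HInverse(matrix=(sp.csr_matrix(Finv) + corr.tocsr()), genotyped_idx=gidx)
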