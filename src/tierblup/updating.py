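"""Exact Bayesian updating of an external BLUP / SS-GBLUP evaluation.

The core of the package.  An *external* evaluation of the nucleus tier
(animals d ∪ a) is summarized by the posterior means of its breeding
values for the set a of parents of current animals — together with any
fixed effects shared with the current model — and their joint posterior
covariance C, plus the aa-block E^aa of the inverse numerator
relationship matrix of the external pedigree.  The *current* evaluation
of the commercial tier (set c) combines its own least-squares equations
with the inverse of C as prior precision and the sparse blocks
F^aa − E^aa, F^ac, F^cc of the full-pedigree inverse:

    [ X'X/σ²ₑ + Cᵝᵝ     Cᵝᵃ                        X'Z/σ²ₑ          ] [β̂ ]
    [ Cᵃᵝ               Cᵃᵃ + (F^aa−E^aa)/σ²ᵤ      F^ac/σ²ᵤ          ] [ûₐ]
    [ Z'X/σ²ₑ           F^ca/σ²ᵤ                   Z'Z/σ²ₑ + F^cc/σ²ᵤ ] [û꜀]

      = [ X'y/σ²ₑ + Cᵝᵝβ̃ + Cᵝᵃũₐ ;  Cᵃᵝβ̃ + Cᵃᵃũₐ ;  Z'y/σ²ₑ ]

Provided no current animal has a parent or mate-with-common-offspring in
the distant set d, the solutions and their posterior covariances are
*identical* to a joint analysis of all data — including the single-step
case where genotyping is confined to the external set, in which the
current analysis needs neither genotypes nor the genomic relationship
matrix of any ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import mme
from .pedigree import Pedigree, TierPartition, PedigreeError
from .relatedness import (
    GenomicRelationship,
    build_A_inverse,
    build_external_inverse,
    build_H_inverse,
    block,
)


@dataclass
class PhenotypeData:
    """Single-trait records: response, named fixed-effect design, animal labels."""

    y: np.ndarray
    X: np.ndarray
    x_names: list
    animals: list

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size:
            self.X = self.X.T
        if self.X.shape != (self.y.size, len(self.x_names)):
            raise ValueError("X shape inconsistent with y and x_names")
        if len(self.animals) != self.y.size:
            raise ValueError("one animal label per record required")
        self.animals = [str(a) for a in self.animals]


@dataclass
class ExternalPosterior:
    """The complete information channel from the external to the current analysis.

    Means and joint covariance of (common fixed effects, u_a) under the
    external posterior, plus the aa-block of the external-pedigree
    A-inverse.  External-only fixed effects and breeding values of
    distant ancestors are marginalized out — they never cross the
    boundary, and neither do external phenotypes or genotypes.
    """

    a_ids: list
    common_effect_names: list
    mean_beta: np.ndarray
    mean_ua: np.ndarray
    C: np.ndarray
    Eaa: sp.csr_matrix
    sigma_u: float
    sigma_e: float

    def __post_init__(self):
        nb, na = len(self.common_effect_names), len(self.a_ids)
        self.mean_beta = np.asarray(self.mean_beta, dtype=float).ravel()
        self.mean_ua = np.asarray(self.mean_ua, dtype=float).ravel()
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (nb + na, nb + na):
            raise ValueError("C must be (n_common + n_a) square")
        self.Eaa = sp.csr_matrix(self.Eaa)
        if self.Eaa.shape != (na, na):
            raise ValueError("Eaa must be n_a square")


@dataclass
class UpdateReport:
    """Max absolute discrepancies between updated and joint solutions."""

    max_ebv_diff: float
    max_beta_diff: float
    max_pev_diff: float
    tolerance: float
    scale: float

    @property
    def passed(self) -> bool:
        thr = self.tolerance * self.scale
        return max(self.max_ebv_diff, self.max_beta_diff, self.max_pev_diff) <= thr


def _incidence(animals: list, scope_index: dict, n_scope: int) -> sp.csr_matrix:
    rows = np.arange(len(animals))
    cols = np.array([scope_index[a] for a in animals], dtype=np.int64)
    return sp.csr_matrix(
        (np.ones(len(animals)), (rows, cols)), shape=(len(animals), n_scope)
    )


def run_external(
    ped: Pedigree,
    part: TierPartition,
    data_e: PhenotypeData,
    sigma_u: float,
    sigma_e: float,
    common_effect_names: list | None = None,
    kinv_mode: str = "pedigree",
    grm: GenomicRelationship | None = None,
    cov_method: str = "direct",
    gibbs: dict | None = None,
) -> ExternalPosterior:
    """Run the external evaluation and package its posterior.

    Solves the MME of the external tier (pedigree prior, or single-step
    H prior when ``kinv_mode='single-step'``), extracts the posterior
    means of the common fixed effects and u_a, their joint covariance C
    (a block of the coefficient-matrix inverse — or its MCMC estimate
    when ``gibbs`` options are given), and the aa-block of the
    external-pedigree A-inverse.
    """
    common_effect_names = list(common_effect_names or [])
    for nm in common_effect_names:
        if nm not in data_e.x_names:
            raise ValueError(f"common effect {nm!r} absent from external design")
    from .pedigree import extract_subpedigree

    e_idx = part.e_idx
    e_labels = [ped.labels[i] for i in e_idx]
    ped_e = extract_subpedigree(ped, e_labels, mode="clip-parents")
    bad = set(data_e.animals) - set(ped_e.index)
    if bad:
        raise PedigreeError(
            f"external records on animals outside the external pedigree: {sorted(bad)[:5]}"
        )
    Einv = build_A_inverse(ped_e)
    if kinv_mode == "single-step":
        if grm is None:
            raise ValueError("single-step external analysis requires a GRM")
        missing = set(map(str, grm.ids)) - set(ped_e.index)
        if missing:
            raise PedigreeError(
                f"genotyped animals outside the external set: {sorted(missing)[:5]}"
            )
        Kinv = build_H_inverse(Einv, grm, ped_e).matrix
    elif kinv_mode == "pedigree":
        Kinv = Einv
    else:
        raise ValueError(f"unknown kinv_mode {kinv_mode!r}")

    Z = _incidence(data_e.animals, ped_e.index, ped_e.n)
    sys = mme.build_joint_mme(
        data_e.y, data_e.X, Z, Kinv, sigma_u, sigma_e,
        fixed_names=data_e.x_names, animal_labels=ped_e.labels,
    )
    # target coordinates: common fixed effects then a-animals, in stated order
    fixed_cols = {nm: j for j, nm in enumerate(data_e.x_names)}
    a_labels = part.labels("a")
    nf = len(data_e.x_names)
    tcoords = np.array(
        [fixed_cols[nm] for nm in common_effect_names]
        + [nf + ped_e.index[lab] for lab in a_labels],
        dtype=np.int64,
    )
    if gibbs:
        mean_all, Call, _ = mme.gibbs_sample(
            sys, n_iter=gibbs["n_iter"], burn_in=gibbs["burn_in"],
            thin=gibbs.get("thin", 1), seed=gibbs["seed"],
        )
        mean_t = mean_all[tcoords]
        C = Call[np.ix_(tcoords, tcoords)]
    else:
        res = mme.solve(sys, method="direct")
        mean_t = res.solution[tcoords]
        C = _columns_inverse(sys, tcoords, cov_method)

    nb = len(common_effect_names)
    # pedigree-based E^aa regardless of kinv_mode: the current analysis is
    # pedigree-only on its side of the boundary
    a_pos_in_e = np.searchsorted(e_idx, part.a_idx)
    Eaa = block(Einv, a_pos_in_e, a_pos_in_e)
    return ExternalPosterior(
        a_ids=a_labels,
        common_effect_names=common_effect_names,
        mean_beta=mean_t[:nb],
        mean_ua=mean_t[nb:],
        C=C,
        Eaa=Eaa,
        sigma_u=sigma_u,
        sigma_e=sigma_e,
    )


def _columns_inverse(sys: mme.MMESystem, idx: np.ndarray, method: str) -> np.ndarray:
    """Rows/cols ``idx`` of the coefficient-matrix inverse."""
    import scipy.sparse.linalg as spla

    A = sys.lhs.tocsc()
    n = sys.n
    out = np.zeros((idx.size, idx.size))
    if method == "direct":
        lu = spla.splu(A)
        cols = np.zeros((n, idx.size))
        for k, j in enumerate(idx):
            e = np.zeros(n)
            e[j] = 1.0
            cols[:, k] = lu.solve(e)
        out = cols[idx, :]
    elif method == "pcg":
        diag = A.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        cols = np.zeros((n, idx.size))
        for k, j in enumerate(idx):
            e = np.zeros(n)
            e[j] = 1.0
            x, info = spla.cg(A, e, rtol=1e-12, atol=0.0, M=M, maxiter=50000)
            if info != 0:
                raise RuntimeError("PCG failed on a unit right-hand side")
            cols[:, k] = x
        out = cols[idx, :]
    else:
        raise ValueError(f"unknown method {method!r}")
    return 0.5 * (out + out.T)


def invert_posterior(ext: ExternalPosterior, cond_bound: float = 1e12) -> dict:
    """Invert C into the precision blocks Cᵝᵝ, Cᵝᵃ, Cᵃᵝ, Cᵃᵃ.

    With no common effects this reduces to the plain inverse of the PEV
    of u_a.  Ill-conditioned C triggers a warning, not an error.
    """
    c = np.linalg.cond(ext.C)
    if c > cond_bound:
        warnings.warn(
            f"posterior covariance C is ill-conditioned (cond ≈ {c:.2e})",
            stacklevel=2,
        )
    Cinv = np.linalg.inv(ext.C)
    Cinv = 0.5 * (Cinv + Cinv.T)
    nb = len(ext.common_effect_names)
    return {
        "bb": Cinv[:nb, :nb],
        "ba": Cinv[:nb, nb:],
        "ab": Cinv[nb:, :nb],
        "aa": Cinv[nb:, nb:],
    }


def build_update_mme(
    ext: ExternalPosterior,
    ped: Pedigree,
    part: TierPartition,
    data_c: PhenotypeData,
    sigma_u: float | None = None,
    sigma_e: float | None = None,
) -> mme.MMESystem:
    """Assemble the current-tier MME that consumes the external posterior.

    Unknowns are ordered (current-only fixed effects, common fixed
    effects, u_a, u_c).  Current records must be on c-animals only — a
    record on an a-animal would violate the conditional-independence
    assumption the exactness rests on, and is rejected.
    """
    sigma_u = ext.sigma_u if sigma_u is None else sigma_u
    sigma_e = ext.sigma_e if sigma_e is None else sigma_e
    a_labels = part.labels("a")
    if list(ext.a_ids) != a_labels:
        raise ValueError("external posterior a_ids do not match the partition's set a")
    c_labels = part.labels("c")
    c_set = set(c_labels)
    offenders = [a for a in data_c.animals if a not in c_set]
    if offenders:
        raise PedigreeError(
            "current records must be on current (c) animals only; offending "
            f"animals: {sorted(set(offenders))[:5]}"
        )
    for nm in ext.common_effect_names:
        if nm not in data_c.x_names:
            raise ValueError(f"common effect {nm!r} absent from current design")

    # column order: current-only then common
    only = [nm for nm in data_c.x_names if nm not in ext.common_effect_names]
    xcols = {nm: j for j, nm in enumerate(data_c.x_names)}
    order = [xcols[nm] for nm in only] + [xcols[nm] for nm in ext.common_effect_names]
    X = data_c.X[:, order]
    mme.check_full_rank(X, only + list(ext.common_effect_names))
    n0, n1 = len(only), len(ext.common_effect_names)
    nf = n0 + n1
    na, nc = len(a_labels), len(c_labels)

    c_index = {lab: k for k, lab in enumerate(c_labels)}
    Zc = _incidence(data_c.animals, c_index, nc)

    le, lu = 1.0 / sigma_e, 1.0 / sigma_u
    Finv = build_A_inverse(ped)
    Fac = block(Finv, part.a_idx, part.c_idx)
    Fcc = block(Finv, part.c_idx, part.c_idx)
    # F^aa − E^aa with E^aa taken from the posterior package: the external
    # analysis is authoritative for its own pedigree inverse, and the
    # updated solutions are sharply sensitive to this block.  The
    # single-pass construction (relatedness.faa_minus_eaa) produces the
    # same matrix and serves as the independent cross-check in the tests.
    dFaa = block(Finv, part.a_idx, part.a_idx) - ext.Eaa

    prec = invert_posterior(ext)

    XtX = X.T @ X * le
    XtZ = X.T @ Zc.toarray() * le
    ZtZ = (Zc.T @ Zc) * le

    lhs = np.zeros((nf + na + nc, nf + na + nc))
    sl_f = slice(0, nf)
    sl_b1 = slice(n0, nf)
    sl_a = slice(nf, nf + na)
    sl_c = slice(nf + na, nf + na + nc)
    lhs[sl_f, sl_f] = XtX
    lhs[sl_b1, sl_b1] += prec["bb"]
    lhs[sl_b1, sl_a] = prec["ba"]
    lhs[sl_a, sl_b1] = prec["ab"]
    lhs[sl_a, sl_a] = prec["aa"] + lu * dFaa.toarray()
    lhs[sl_a, sl_c] = lu * Fac.toarray()
    lhs[sl_c, sl_a] = lhs[sl_a, sl_c].T
    lhs[sl_c, sl_c] = ZtZ.toarray() + lu * Fcc.toarray()
    lhs[sl_f, sl_c] = XtZ
    lhs[sl_c, sl_f] = XtZ.T

    rhs = np.zeros(nf + na + nc)
    rhs[sl_f] = X.T @ data_c.y * le
    rhs[sl_b1] += prec["bb"] @ ext.mean_beta + prec["ba"] @ ext.mean_ua
    rhs[sl_a] = prec["ab"] @ ext.mean_beta + prec["aa"] @ ext.mean_ua
    rhs[sl_c] += Zc.T @ data_c.y * le

    blocks = {
        "fixed_current": np.arange(n0),
        "fixed_common": np.arange(n0, nf),
        "u_a": np.arange(nf, nf + na),
        "u_c": np.arange(nf + na, nf + na + nc),
    }
    labels = {
        "fixed_current": only,
        "fixed_common": list(ext.common_effect_names),
        "u_a": a_labels,
        "u_c": c_labels,
    }
    return mme.MMESystem(
        lhs=sp.csr_matrix(lhs), rhs=rhs, blocks=blocks,
        sigma_u=sigma_u, sigma_e=sigma_e, labels=labels,
    )


def merge_designs(data_e: PhenotypeData, data_c: PhenotypeData,
                  common_names: list) -> PhenotypeData:
    """Stack external and current records into one joint design.

    Columns with a name in ``common_names`` are shared; all others are
    dataset-specific and zero-padded on the other dataset's rows.
    """
    common = list(common_names)
    e_only = [nm for nm in data_e.x_names if nm not in common]
    c_only = [nm for nm in data_c.x_names if nm not in common]
    clash = set(e_only) & set(c_only)
    if clash:
        raise ValueError(
            f"effect name(s) {sorted(clash)} appear in both data sets but are "
            "not declared common; declare them common or rename per data set"
        )
    names = e_only + common + c_only
    ne, nc = data_e.y.size, data_c.y.size
    X = np.zeros((ne + nc, len(names)))
    for j, nm in enumerate(names):
        if nm in data_e.x_names:
            X[:ne, j] = data_e.X[:, data_e.x_names.index(nm)]
        if nm in data_c.x_names:
            X[ne:, j] = data_c.X[:, data_c.x_names.index(nm)]
    return PhenotypeData(
        y=np.concatenate([data_e.y, data_c.y]),
        X=X,
        x_names=names,
        animals=list(data_e.animals) + list(data_c.animals),
    )


def run_joint(
    ped: Pedigree,
    data: PhenotypeData,
    sigma_u: float,
    sigma_e: float,
    kinv_mode: str = "pedigree",
    grm: GenomicRelationship | None = None,
) -> tuple:
    """Joint analysis of all data over the full pedigree.

    Returns (system, result).  The reference every updated analysis is
    checked against.
    """
    Finv = build_A_inverse(ped)
    if kinv_mode == "single-step":
        if grm is None:
            raise ValueError("single-step analysis requires a GRM")
        Kinv = build_H_inverse(Finv, grm, ped).matrix
    elif kinv_mode == "pedigree":
        Kinv = Finv
    else:
        raise ValueError(f"unknown kinv_mode {kinv_mode!r}")
    Z = _incidence(data.animals, ped.index, ped.n)
    sys = mme.build_joint_mme(
        data.y, data.X, Z, Kinv, sigma_u, sigma_e,
        fixed_names=data.x_names, animal_labels=ped.labels,
    )
    return sys, mme.solve(sys, method="direct")


def verify_equivalence(
    joint_sys: mme.MMESystem,
    joint_res: mme.EvaluationResult,
    upd_sys: mme.MMESystem,
    upd_res: mme.EvaluationResult,
    part: TierPartition,
    tol: float = 1e-8,
    compare_pev: bool = True,
) -> UpdateReport:
    """Compare updated against joint solutions (and PEV) over a ∪ c.

    The pass threshold is ``tol`` relative to the largest PEV diagonal
    (or to 1 when PEV is not compared).
    """
    ped = part.ped
    nf_j = len(joint_sys.labels.get("fixed", []))
    jfix = {nm: j for j, nm in enumerate(joint_sys.labels.get("fixed", []))}
    anim_lab = joint_sys.labels["animals"]
    jpos = {lab: nf_j + k for k, lab in enumerate(anim_lab)}

    ua_labels = upd_sys.labels["u_a"]
    uc_labels = upd_sys.labels["u_c"]
    up_idx = upd_sys.indices("u_a", "u_c")
    jt_idx = np.array([jpos[lab] for lab in ua_labels + uc_labels], dtype=np.int64)
    if len(set(ua_labels + uc_labels)) != len(ua_labels) + len(uc_labels):
        raise ValueError("a and c id sets overlap")

    ebv_diff = float(
        np.max(np.abs(joint_res.solution[jt_idx] - upd_res.solution[up_idx]))
    )
    common = upd_sys.labels.get("fixed_common", [])
    if common:
        jc = np.array([jfix[nm] for nm in common], dtype=np.int64)
        uc = upd_sys.indices("fixed_common")
        beta_diff = float(
            np.max(np.abs(joint_res.solution[jc] - upd_res.solution[uc]))
        )
    else:
        beta_diff = 0.0

    pev_diff = 0.0
    scale = 1.0
    if compare_pev:
        Cj = _columns_inverse(joint_sys, jt_idx, "direct")
        Cu = _columns_inverse(upd_sys, up_idx, "direct")
        pev_diff = float(np.max(np.abs(Cj - Cu)))
        scale = float(max(np.max(np.diag(Cj)), 1.0))
    return UpdateReport(
        max_ebv_diff=ebv_diff,
        max_beta_diff=beta_diff,
        max_pev_diff=pev_diff,
        tolerance=tol,
        scale=scale,
    )
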