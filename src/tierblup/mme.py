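"""Henderson mixed-model-equation systems: assembly, solving, PEV, absorption, Gibbs.

The single-trait animal model is y = Xβ + Zu + e with u ~ N(0, K σ²_u)
and e ~ N(0, I σ²_e), K the pedigree (A) or combined pedigree-genomic (H)
relationship matrix.  The mixed-model equations

    [ X'X/σ²_e          X'Z/σ²_e              ] [β̂]   [X'y/σ²_e]
    [ Z'X/σ²_e   Z'Z/σ²_e + K⁻¹/σ²_u          ] [û] = [Z'y/σ²_e]

have as solution the posterior means of (β, u) under a flat prior on β,
and the inverse of the coefficient matrix is their posterior covariance
(the prediction-error covariance, PEV, for u).  Variance components are
taken as known inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class MMESystem:
    """Symmetric sparse coefficient matrix + right-hand side + effect map.

    ``blocks`` maps effect-block names (fixed-effect groups, breeding-value
    blocks) to integer index arrays partitioning the equation space.
    """

    lhs: sp.csr_matrix
    rhs: np.ndarray
    blocks: dict
    sigma_u: float
    sigma_e: float
    labels: dict = field(default_factory=dict)  # block name -> per-equation labels

    def __post_init__(self):
        self.lhs = sp.csr_matrix(self.lhs)
        self.rhs = np.asarray(self.rhs, dtype=float).ravel()
        if self.lhs.shape[0] != self.lhs.shape[1] or self.lhs.shape[0] != self.rhs.size:
            raise ValueError("lhs/rhs dimension mismatch")
        cover = np.concatenate([np.asarray(ix) for ix in self.blocks.values()]) \
            if self.blocks else np.array([], dtype=np.int64)
        if np.sort(cover).tolist() != list(range(self.rhs.size)):
            raise ValueError("effect-map blocks must partition the index space")

    @property
    def n(self) -> int:
        return self.rhs.size

    def indices(self, *names: str) -> np.ndarray:
        return np.concatenate([np.asarray(self.blocks[nm], dtype=np.int64) for nm in names])


@dataclass
class SolverReport:
    method: str
    iterations: int
    residual: float


@dataclass
class EvaluationResult:
    """Solutions (and optionally PEV blocks) of an MME system."""

    solution: np.ndarray
    system: MMESystem
    report: SolverReport
    pev: dict = field(default_factory=dict)  # frozenset(block names) -> dense block

    def block_solution(self, *names: str) -> np.ndarray:
        return self.solution[self.system.indices(*names)]


def check_full_rank(X: np.ndarray, names=None, tol: float = 1e-8) -> None:
    """Raise if the fixed-effect design is column-rank deficient."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return
    r = np.linalg.matrix_rank(X, tol=tol * max(1.0, np.abs(X).max()))
    if r < X.shape[1]:
        # name one dependent column via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        dep = piv[r]
        nm = names[dep] if names is not None else f"column {dep}"
        raise ValueError(f"fixed-effect design is rank deficient (dependent: {nm})")


def build_joint_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: sp.spmatrix,
    Kinv: sp.spmatrix,
    sigma_u: float,
    sigma_e: float,
    fixed_names: list | None = None,
    animal_labels: list | None = None,
    fixed_block: str = "fixed",
    animal_block: str = "animals",
) -> MMESystem:
    """Assemble the Henderson MME for one fixed block and one animal block.

    ``Kinv`` is the (sparse) inverse relationship matrix over the full
    animal scope; ``Z`` maps records to animals in that scope.  ``X`` may
    have zero columns (no fixed effects).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Z = sp.csr_matrix(Z)
    Kinv = sp.csr_matrix(Kinv)
    nf, na = X.shape[1], Kinv.shape[0]
    if Z.shape != (y.size, na):
        raise ValueError("Z must be records × animals")
    if X.shape[0] != y.size:
        raise ValueError("X rows must match records")
    check_full_rank(X, fixed_names)

    le, lu = 1.0 / sigma_e, 1.0 / sigma_u
    XtX = sp.csr_matrix(X.T @ X) * le
    XtZ = sp.csr_matrix(X.T @ Z.toarray()) * le if nf else sp.csr_matrix((0, na))
    ZtZ = (Z.T @ Z) * le
    lhs = sp.bmat(
        [[XtX, XtZ], [XtZ.T, ZtZ + Kinv * lu]], format="csr"
    ) if nf else sp.csr_matrix(ZtZ + Kinv * lu)
    rhs = np.concatenate([X.T @ y * le, Z.T @ y * le])
    blocks = {}
    if nf:
        blocks[fixed_block] = np.arange(nf)
    blocks[animal_block] = np.arange(nf, nf + na)
    labels = {}
    if fixed_names is not None and nf:
        labels[fixed_block] = list(fixed_names)
    if animal_labels is not None:
        labels[animal_block] = list(animal_labels)
    return MMESystem(lhs=lhs, rhs=rhs, blocks=blocks,
                     sigma_u=sigma_u, sigma_e=sigma_e, labels=labels)


def solve(sys: MMESystem, method: str = "direct", tol: float = 1e-10,
          maxiter: int = 20000) -> EvaluationResult:
    """Solve the MME by sparse LU ("direct") or Jacobi-preconditioned CG ("pcg")."""
    A = sys.lhs.tocsc()
    if method == "direct":
        lu = spla.splu(A)
        x = lu.solve(sys.rhs)
        res = np.linalg.norm(A @ x - sys.rhs) / max(np.linalg.norm(sys.rhs), 1e-300)
        rep = SolverReport("direct", 1, float(res))
    elif method == "pcg":
        diag = A.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        iters = 0

        def cb(_):
            nonlocal iters
            iters += 1

        x, info = spla.cg(A, sys.rhs, rtol=tol, atol=0.0, M=M,
                          maxiter=maxiter, callback=cb)
        if info != 0:
            raise RuntimeError(f"PCG failed to converge within {maxiter} iterations")
        res = np.linalg.norm(A @ x - sys.rhs) / max(np.linalg.norm(sys.rhs), 1e-300)
        rep = SolverReport("pcg", iters, float(res))
    else:
        raise ValueError(f"unknown method {method!r}")
    return EvaluationResult(solution=x, system=sys, report=rep)


def posterior_covariance(
    sys: MMESystem, targets: tuple, method: str = "direct", tol: float = 1e-12
) -> np.ndarray:
    """Dense posterior-covariance (PEV) block for the named effect blocks.

    Columns of the coefficient-matrix inverse restricted to the target
    indices, obtained either from one sparse factorization ("direct") or
    by repeated conjugate-gradient solves against unit right-hand sides
    ("pcg" — the one-column-at-a-time reconstruction practical when few
    columns are needed).  The result is symmetrized.
    """
    idx = sys.indices(*targets)
    A = sys.lhs.tocsc()
    n = sys.n
    cols = np.zeros((n, idx.size))
    if method == "direct":
        lu = spla.splu(A)
        for k, j in enumerate(idx):
            e = np.zeros(n)
            e[j] = 1.0
            cols[:, k] = lu.solve(e)
    elif method == "pcg":
        diag = A.diagonal()
        M = sp.diags(1.0 / np.where(diag > 0, diag, 1.0))
        for k, j in enumerate(idx):
            e = np.zeros(n)
            e[j] = 1.0
            x, info = spla.cg(A, e, rtol=tol, atol=0.0, M=M, maxiter=50000)
            if info != 0:
                raise RuntimeError("PCG failed on a unit right-hand side")
            cols[:, k] = x
    else:
        raise ValueError(f"unknown method {method!r}")
    C = cols[idx, :]
    return 0.5 * (C + C.T)


def absorb(sys: MMESystem, victim: str) -> MMESystem:
    """Absorb (eliminate by Schur complement) one effect block.

    The remaining equations keep identical solutions:
    lhs_rr − lhs_rv P⁻¹ lhs_vr and rhs_r − lhs_rv P⁻¹ rhs_v, with P the
    victim's diagonal block.
    """
    if victim not in sys.blocks:
        raise KeyError(victim)
    v = np.asarray(sys.blocks[victim], dtype=np.int64)
    rest_names = [nm for nm in sys.blocks if nm != victim]
    r = sys.indices(*rest_names) if rest_names else np.array([], dtype=np.int64)
    if v.size == 0:
        newblocks, newlabels = _renumber(sys, rest_names, r)
        return replace(sys, blocks=newblocks, labels=newlabels)
    A = sys.lhs.tocsc()
    P = A[v, :][:, v]
    Arv = A[r, :][:, v]
    try:
        lu = spla.splu(P.tocsc())
    except RuntimeError as exc:
        raise np.linalg.LinAlgError(f"victim block {victim!r} is singular") from exc
    Pinv_Avr = lu.solve(A[v, :][:, r].toarray())
    new_lhs = A[r, :][:, r].toarray() - Arv.toarray() @ Pinv_Avr
    new_rhs = sys.rhs[r] - Arv.toarray() @ lu.solve(sys.rhs[v])
    new_lhs = 0.5 * (new_lhs + new_lhs.T)
    newblocks, newlabels = _renumber(sys, rest_names, r)
    return MMESystem(
        lhs=sp.csr_matrix(new_lhs), rhs=new_rhs, blocks=newblocks,
        sigma_u=sys.sigma_u, sigma_e=sys.sigma_e, labels=newlabels,
    )


def _renumber(sys: MMESystem, rest_names, r):
    """Rebuild block index arrays after restricting equations to ``r``."""
    pos = {int(old): new for new, old in enumerate(r)}
    blocks, labels = {}, {}
    for nm in rest_names:
        blocks[nm] = np.array([pos[int(i)] for i in sys.blocks[nm]], dtype=np.int64)
        if nm in sys.labels:
            labels[nm] = sys.labels[nm]
    return blocks, labels


def gibbs_sample(
    sys: MMESystem,
    n_iter: int,
    burn_in: int,
    thin: int = 1,
    seed: int = 0,
    targets: tuple | None = None,
    return_samples: bool = False,
):
    """Single-site Gibbs sampler over location effects at fixed variances.

    Each coordinate is drawn from its full conditional
    N((rhs_i − Σ_{j≠i} lhs_ij x_j)/lhs_ii, 1/lhs_ii).  Returns
    (mean, covariance, n_samples) of the retained draws restricted to
    ``targets`` (all equations if None).  Deterministic given ``seed``.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    A = sys.lhs.tocsr()
    n = sys.n
    idx = sys.indices(*targets) if targets else np.arange(n)
    x = np.zeros(n)
    diag = A.diagonal()
    if np.any(diag <= 0):
        raise ValueError("non-positive diagonal in coefficient matrix")
    k = idx.size
    s1 = np.zeros(k)
    s2 = np.zeros((k, k))
    kept = 0
    draws = [] if return_samples else None
    indptr, indices, data = A.indptr, A.indices, A.data
    sd = 1.0 / np.sqrt(diag)
    rhs = sys.rhs
    for it in range(n_iter):
        for i in range(n):
            lo, hi = indptr[i], indptr[i + 1]
            row_idx = indices[lo:hi]
            dot = data[lo:hi] @ x[row_idx] - diag[i] * x[i]
            x[i] = (rhs[i] - dot) / diag[i] + rng.standard_normal() * sd[i]
        if it >= burn_in and (it - burn_in) % thin == 0:
            xi = x[idx]
            s1 += xi
            s2 += np.outer(xi, xi)
            kept += 1
            if draws is not None:
                draws.append(xi.copy())
    mean = s1 / kept
    cov = s2 / kept - np.outer(mean, mean)
    cov *= kept / max(kept - 1, 1)
    if return_samples:
        return mean, cov, kept, np.asarray(draws)
    return mean, cov, kept
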