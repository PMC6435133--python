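"""Low-rank completion of the read matrix.

The noiseless read matrix is a masked version of a rank-2 (rank-1 in the
all-heterozygous case) sign matrix whose two distinct rows are the parental
haplotypes.  Completion estimates the unobserved cells under the model

    min_H  sum_{(i,j) in Omega} (H_ij - R_ij)^2   s.t.  rank(H) = r,

for which three solvers are provided:

``SVTCompleter``
    Singular value thresholding: alternate the singular-value shrinkage
    operator D_tau with re-injection of the observed data,
    X^k = D_tau(Y^{k-1}),  Y^k = Y^{k-1} + delta * P_Omega(R - X^k),
    from Y^0 = R until ||P_Omega(X^k - R)||_F <= eps * ||R||_F.

``NuclearNormCompleter``
    The convex relaxation  min ||H||_*  s.t.  ||P_Omega(H - R)||_F <= eps,
    solved by Douglas–Rachford splitting (the nuclear-norm prox is exactly
    the shrinkage operator; projection onto the data constraint is
    closed-form on Omega).

``OptSpaceCompleter``
    Trimming of over-observed rows/columns, rank-r spectral projection
    scaled by N*l/|Omega|, then "cleaning": minimize the observed-cell
    squared error over factor matrices X (N×r), Y (l×r) with orthonormal
    columns, the inner r×r factor S solved exactly by least squares, the
    outer problem by gradient descent with backtracking.

All three are fit-once estimators in the scikit-learn style: ``fit(R)``
stores the completed matrix and diagnostics as trailing-underscore
attributes and ``fit_transform(R)`` returns the dense completed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.base import BaseEstimator

from .io import ReadMatrix

__all__ = [
    "SVTParams",
    "FactorTriple",
    "shrink_singular_values",
    "SVTCompleter",
    "NuclearNormCompleter",
    "OptSpaceCompleter",
    "complete_svt",
    "complete_nuclear",
    "complete_optspace",
    "trim",
    "project_rank_r",
    "optspace_clean",
    "as_read_matrix",
]

#: switch from full to truncated SVD above this min-dimension
_FULL_SVD_MAX = 400


class CompletionError(RuntimeError):
    """A solver could not produce a completion (infeasible / bad input)."""


def as_read_matrix(R) -> ReadMatrix:
    """Coerce ReadMatrix / sparse / dense (0 = unobserved) input."""
    if isinstance(R, ReadMatrix):
        return R
    if sp.issparse(R):
        return ReadMatrix(R.tocsr())
    return ReadMatrix.from_dense(np.asarray(R, dtype=float))


@dataclass(frozen=True)
class SVTParams:
    """Hyperparameters of the SVT iteration.

    When left ``None``, ``tau`` defaults to 5*sqrt(N*l) and ``delta`` to
    min(1.2*N*l/|Omega|, 1.9) — the standard matrix-completion choices,
    with the step capped below 2 for stability on dense observation sets.
    """

    tau: float | None = None
    delta: float | None = None
    eps: float = 1e-4
    max_iter: int = 5000

    def __post_init__(self):
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0 < self.eps < 1):
            raise ValueError("eps must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def resolved(self, n: int, l: int, n_obs: int) -> tuple[float, float]:
        tau = self.tau if self.tau is not None else 5.0 * np.sqrt(n * l)
        if self.delta is not None:
            delta = self.delta
        else:
            # 1.2/sampling-density, capped below 2: the uncapped value
            # oscillates on densely observed matrices
            delta = min(1.2 * n * l / max(n_obs, 1), 1.9)
        return tau, delta


@dataclass
class FactorTriple:
    """Rank-r factorization X (N×r, orthonormal) · S (r×r) · Y^T (r×l)."""

    X: np.ndarray
    S: np.ndarray
    Y: np.ndarray
    rank_deficient: bool = False

    @property
    def r(self) -> int:
        return self.X.shape[1]

    def full(self) -> np.ndarray:
        return self.X @ self.S @ self.Y.T


def _svd(M: np.ndarray, k: int | None = None):
    """SVD returning (U, s, Vt); truncated to k when the matrix is large."""
    if k is None or min(M.shape) <= _FULL_SVD_MAX or k >= min(M.shape) - 1:
        return np.linalg.svd(M, full_matrices=False)
    U, s, Vt = spla.svds(sp.csr_matrix(M) if not sp.issparse(M) else M, k=k)
    order = np.argsort(s)[::-1]
    return U[:, order], s[order], Vt[order]


def shrink_singular_values(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value shrinkage D_tau(M) = U diag(max(s_i - tau, 0)) V^H.

    This is the unique minimizer of (1/2)||M - Z||_F^2 + tau*||Z||_*.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    M = np.asarray(M, dtype=float)
    if min(M.shape) > _FULL_SVD_MAX:
        # only the singular values above tau survive; find them iteratively
        k = 6
        while True:
            U, s, Vt = _svd(M, k)
            if s[-1] < tau or k >= min(M.shape) - 1:
                break
            k = min(2 * k, min(M.shape) - 1)
    else:
        U, s, Vt = _svd(M)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _omega_values(M: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return M[rows, cols]


class SVTCompleter(BaseEstimator):
    """Complete a read matrix by singular value thresholding.

    Parameters
    ----------
    tau : float, optional
        Shrinkage threshold; default ``5 * sqrt(N * l)``.
    delta : float, optional
        Step size; default ``min(1.2 * N * l / |Omega|, 1.9)``.
    eps : float
        Relative residual stopping tolerance on ``||P_Omega(X - R)||_F``.
    max_iter : int
        Iteration cap; hitting it sets ``converged_ = False`` (no exception).

    Attributes
    ----------
    completed_ : ndarray of shape (N, l)
        The last iterate X^k.
    n_iter_ : int
    residuals_ : list of float
        ``||P_Omega(X^k - R)||_F`` per iteration.
    converged_ : bool
    """

    def __init__(self, tau: float | None = None, delta: float | None = None,
                 eps: float = 1e-4, max_iter: int = 5000):
        self.tau = tau
        self.delta = delta
        self.eps = eps
        self.max_iter = max_iter

    def fit(self, R, y=None) -> "SVTCompleter":
        rm = as_read_matrix(R)
        if rm.n_observed == 0:
            raise CompletionError("cannot complete a matrix with no observed entries")
        params = SVTParams(self.tau, self.delta, self.eps, self.max_iter)
        tau, delta = params.resolved(rm.n_reads, rm.n_sites, rm.n_observed)
        rows, cols = rm.omega()
        r_vals = rm.matrix.tocoo().data  # aligned with rows/cols
        r_norm = np.linalg.norm(r_vals)
        Y = rm.densify()
        X = np.zeros_like(Y)
        residuals: list[float] = []
        converged = False
        k = 0
        for k in range(1, params.max_iter + 1):
            X = shrink_singular_values(Y, tau)
            resid = np.linalg.norm(_omega_values(X, rows, cols) - r_vals)
            residuals.append(float(resid))
            if resid <= params.eps * r_norm:
                converged = True
                break
            Y[rows, cols] += delta * (r_vals - _omega_values(X, rows, cols))
        self.completed_ = X
        self.n_iter_ = k
        self.residuals_ = residuals
        self.converged_ = converged
        return self

    def fit_transform(self, R, y=None) -> np.ndarray:
        return self.fit(R).completed_


class NuclearNormCompleter(BaseEstimator):
    """Complete a read matrix by nuclear-norm minimization.

    Solves ``min ||H||_*  s.t.  ||P_Omega(H - R)||_F <= eps`` with
    Douglas–Rachford splitting; the returned point satisfies the constraint
    to within ``feas_tol``.

    Parameters
    ----------
    eps : float
        Frobenius slack of the data constraint (0 demands interpolation).
    gamma : float, optional
        Prox step; default ``0.2 * ||R||_2``.
    max_iter, tol : iteration cap and fixed-point tolerance.
    size_cap : int
        Refuse problems with ``N * l`` above this (use per-block solving).

    Attributes
    ----------
    completed_ : ndarray
    n_iter_ : int
    converged_ : bool
    feasibility_ : float
        ``||P_Omega(H - R)||_F`` at the returned point.
    """

    def __init__(self, eps: float = 1e-3, gamma: float | None = None,
                 max_iter: int = 2000, tol: float = 1e-7,
                 feas_tol: float = 1e-5, size_cap: int = 250_000):
        self.eps = eps
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol
        self.feas_tol = feas_tol
        self.size_cap = size_cap

    def fit(self, R, y=None) -> "NuclearNormCompleter":
        rm = as_read_matrix(R)
        if rm.n_observed == 0:
            raise CompletionError("cannot complete a matrix with no observed entries")
        if rm.n_reads * rm.n_sites > self.size_cap:
            raise CompletionError(
                f"problem size {rm.n_reads}x{rm.n_sites} exceeds the convex-solver "
                f"cap ({self.size_cap} cells); solve per haplotype block instead"
            )
        if self.eps < 0:
            raise ValueError("eps must be non-negative")
        rows, cols = rm.omega()
        r_vals = rm.matrix.tocoo().data
        gamma = self.gamma
        if gamma is None:
            gamma = 0.2 * float(spla.svds(rm.matrix, k=1, return_singular_vectors=False)[0]) \
                if min(rm.matrix.shape) > 2 else 0.2 * np.linalg.norm(rm.densify(), 2)
            gamma = max(gamma, 1e-8)

        def proj_constraint(Z: np.ndarray) -> np.ndarray:
            out = Z.copy()
            resid = _omega_values(Z, rows, cols) - r_vals
            nrm = np.linalg.norm(resid)
            if nrm > self.eps:
                scale = self.eps / nrm if nrm > 0 else 0.0
                out[rows, cols] = r_vals + scale * resid
            return out

        Z = rm.densify()
        H = proj_constraint(Z)
        converged = False
        k = 0
        for k in range(1, self.max_iter + 1):
            W = shrink_singular_values(2.0 * H - Z, gamma)
            Z = Z + W - H
            H_new = proj_constraint(Z)
            step = np.linalg.norm(H_new - H) / max(1.0, np.linalg.norm(H))
            H = H_new
            if step < self.tol:
                converged = True
                break
        feas = float(np.linalg.norm(_omega_values(H, rows, cols) - r_vals))
        if feas > self.eps + self.feas_tol:
            raise CompletionError(
                f"nuclear-norm solver did not reach feasibility: "
                f"||P_Omega(H-R)||_F = {feas:.3g} > eps = {self.eps:.3g}"
            )
        self.completed_ = H
        self.n_iter_ = k
        self.converged_ = converged
        self.feasibility_ = feas
        return self

    def fit_transform(self, R, y=None) -> np.ndarray:
        return self.fit(R).completed_


def trim(read_matrix: ReadMatrix) -> ReadMatrix:
    """Zero out over-observed columns and rows.

    Columns with degree > 2|Omega|/l and rows with degree > 2|Omega|/N are
    removed from Omega (both thresholds use the original |Omega|).  The
    input is untouched.
    """
    rm = read_matrix
    n, l, n_obs = rm.n_reads, rm.n_sites, rm.n_observed
    if n_obs == 0:
        return ReadMatrix(rm.matrix.copy(), rm.read_ids)
    coo = rm.matrix.tocoo()
    col_deg = np.bincount(coo.col, minlength=l)
    row_deg = np.bincount(coo.row, minlength=n)
    keep = (col_deg[coo.col] <= 2.0 * n_obs / l) & (row_deg[coo.row] <= 2.0 * n_obs / n)
    trimmed = sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=(n, l)
    ).tocsr()
    return ReadMatrix(trimmed, rm.read_ids)


def project_rank_r(read_matrix: ReadMatrix, r: int) -> FactorTriple:
    """Rank-r spectral projection scaled by N*l/|Omega|.

    SVD of the (trimmed) matrix, keeping the top r factors with the middle
    factor scaled by ``N*l/|Omega|``; this is the gradient-descent
    initialization of the cleaning step.  If the matrix has numerical rank
    below r the missing directions are padded with zero singular values and
    orthonormal complements, and ``rank_deficient`` is flagged.
    """
    if r < 1:
        raise ValueError("rank must be >= 1")
    rm = read_matrix
    if rm.n_observed == 0:
        raise CompletionError("cannot project an all-zero matrix")
    n, l = rm.n_reads, rm.n_sites
    scale = n * l / rm.n_observed
    dense_needed = min(n, l) <= _FULL_SVD_MAX
    if dense_needed:
        U, s, Vt = np.linalg.svd(rm.densify(), full_matrices=False)
    else:
        U, s, Vt = spla.svds(rm.matrix, k=min(r, min(n, l) - 1))
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    tol = max(n, l) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    eff_rank = int(np.sum(s > tol))
    rank_deficient = eff_rank < r
    U, s, Vt = U[:, :r], s[:r].copy(), Vt[:r]
    if U.shape[1] < r:  # truncated SVD returned fewer than r factors
        pad = r - U.shape[1]
        U = np.hstack([U, np.zeros((n, pad))])
        Vt = np.vstack([Vt, np.zeros((pad, l))])
        s = np.concatenate([s, np.zeros(pad)])
    s[eff_rank:] = 0.0
    return FactorTriple(U, scale * np.diag(s), Vt.T, rank_deficient=rank_deficient)


def _solve_inner_s(X, Y, rows, cols, r_vals) -> tuple[np.ndarray, float]:
    """Exact least-squares solve of the inner r×r factor on observed cells."""
    r = X.shape[1]
    A = (X[rows][:, :, None] * Y[cols][:, None, :]).reshape(len(rows), r * r)
    s_vec, res, *_ = np.linalg.lstsq(A, r_vals, rcond=None)
    pred = A @ s_vec
    obj = float(np.sum((pred - r_vals) ** 2))
    return s_vec.reshape(r, r), obj


def optspace_clean(read_matrix: ReadMatrix, init: FactorTriple,
                   max_iter: int = 200, tol: float = 1e-6) -> tuple[FactorTriple, dict]:
    """Cleaning step: minimize the observed squared error over the factors.

    The inner minimization over S is solved exactly each step; the outer one
    descends the gradient of the factors with backtracking halving, with
    orthonormality re-imposed by QR after every step.  The objective trace
    is non-increasing by construction.
    """
    rm = read_matrix
    rows, cols = rm.omega()
    r_vals = rm.matrix.tocoo().data
    if len(rows) == 0:
        raise CompletionError("cannot clean with an empty observed set")
    X = np.linalg.qr(init.X)[0] if init.X.shape[1] else init.X
    Y = np.linalg.qr(init.Y)[0] if init.Y.shape[1] else init.Y
    n, l = rm.n_reads, rm.n_sites
    S, obj = _solve_inner_s(X, Y, rows, cols, r_vals)
    trace = [obj]
    obj_floor = 1e-12 * float(np.sum(r_vals**2))  # machine-noise level
    step = None  # rescaled from the first gradient
    stalled = False
    for _ in range(max_iter):
        if obj <= obj_floor:
            break
        pred = np.einsum("kr,kr->k", X[rows] @ S, Y[cols])
        err = pred - r_vals
        E = sp.coo_matrix((err, (rows, cols)), shape=(n, l)).tocsr()
        GX = 2.0 * (E @ Y) @ S.T
        GY = 2.0 * (E.T @ X) @ S
        gnorm2 = np.sum(GX**2) + np.sum(GY**2)
        if gnorm2 <= 1e-300:
            break
        if step is None:
            # for a quadratic along -G the exact step is ~ obj / |G|^2
            step = obj / gnorm2
        accepted = False
        t = step
        for _bt in range(60):
            Xc = np.linalg.qr(X - t * GX)[0]
            Yc = np.linalg.qr(Y - t * GY)[0]
            Sc, obj_c = _solve_inner_s(Xc, Yc, rows, cols, r_vals)
            if obj_c <= obj - 1e-4 * t * gnorm2:  # Armijo sufficient decrease
                accepted = True
                break
            t *= 0.5
        if not accepted:
            stalled = True
            break
        X, Y, S = Xc, Yc, Sc
        rel_drop = (obj - obj_c) / max(obj, 1e-300)
        trace.append(obj_c)
        obj = obj_c
        step = t * 2.0
        if rel_drop < tol:
            break
    diagnostics = {
        "objective_trace": trace,
        "n_iter": len(trace) - 1,
        "stalled": stalled,
        "final_objective": obj,
    }
    return FactorTriple(X, S, Y, init.rank_deficient), diagnostics


class OptSpaceCompleter(BaseEstimator):
    """Complete a read matrix by trimming, spectral projection and cleaning.

    Parameters
    ----------
    rank : {1, 2}
        Target rank: 2 for the general diploid model, 1 for the
        all-heterozygous case (the two haplotypes are negatives).
    max_iter, tol : cleaning-step gradient-descent controls.
    use_trimmed_omega : bool
        If True the cleaning objective is restricted to the trimmed observed
        set; by default it uses the full original Omega (trimming only
        shapes the spectral initialization).

    Attributes
    ----------
    completed_ : ndarray
    factors_ : FactorTriple
    diagnostics_ : dict with the objective trace of the cleaning step.
    """

    def __init__(self, rank: int = 2, max_iter: int = 200, tol: float = 1e-6,
                 use_trimmed_omega: bool = False):
        self.rank = rank
        self.max_iter = max_iter
        self.tol = tol
        self.use_trimmed_omega = use_trimmed_omega

    def fit(self, R, y=None) -> "OptSpaceCompleter":
        if self.rank not in (1, 2):
            raise ValueError("rank must be 1 or 2 for diploid assembly")
        rm = as_read_matrix(R)
        if rm.n_observed == 0:
            raise CompletionError("cannot complete a matrix with no observed entries")
        trimmed = trim(rm)
        # trimming everything away (degenerate tiny input) falls back to raw
        basis = trimmed if trimmed.n_observed else rm
        init = project_rank_r(basis, self.rank)
        clean_on = trimmed if (self.use_trimmed_omega and trimmed.n_observed) else rm
        factors, diagnostics = optspace_clean(
            clean_on, init, max_iter=self.max_iter, tol=self.tol
        )
        self.factors_ = factors
        self.diagnostics_ = diagnostics
        self.completed_ = factors.full()
        return self

    def fit_transform(self, R, y=None) -> np.ndarray:
        return self.fit(R).completed_


# ---------------------------------------------------------------------------
# thin functional wrappers

def complete_svt(R, params: SVTParams | None = None) -> np.ndarray:
    p = params or SVTParams()
    return SVTCompleter(p.tau, p.delta, p.eps, p.max_iter).fit_transform(R)


def complete_nuclear(R, eps: float = 1e-3, **kwargs) -> np.ndarray:
    return NuclearNormCompleter(eps=eps, **kwargs).fit_transform(R)


def complete_optspace(R, rank: int = 2, **kwargs) -> np.ndarray:
    return OptSpaceCompleter(rank=rank, **kwargs).fit_transform(R)


SOLVERS = {
    "svt": SVTCompleter,
    "nuc": NuclearNormCompleter,
    "nuclear": NuclearNormCompleter,
    "opt": OptSpaceCompleter,
    "optspace": OptSpaceCompleter,
}


def make_completer(solver: str, rank: int = 2, **params) -> BaseEstimator:
    """Instantiate a completer by name (``svt``, ``nuc``/``nuclear``, ``opt``/``optspace``)."""
    try:
        cls = SOLVERS[solver]
    except KeyError:
        raise ValueError(
            f"unknown solver {solver!r}; choose from svt, nuc, opt"
        ) from None
    if cls is OptSpaceCompleter:
        params.setdefault("rank", rank)
    return cls(**params)
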