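"""Block-coordinate minimization of the joint tri-factorization objective.

The model couples an expression matrix X (features × spots) and a spatial
adjacency W (spots × spots) through a shared symmetric core factor C:

    min  ‖X − Bₑ C Fₑ‖² + ‖W − Bₛ C Fₛ‖²
       + α·Tr(Fₑ L Fₑᵀ)
       + β·(‖Fₑ − Fₑ Z‖² + ‖Fₛ − Fₛ Z‖²) + γ·‖Z‖₁
    s.t. Bₑ, Bₛ, Fₑ, Fₛ ≥ 0,  C = Cᵀ,  Z = Zᵀ,  diag(Z) = 0,

where L = D − W is the graph Laplacian (local preservation) and Z is the
learned spot–spot affinity (sparse self-representation). Each block is
solved to (near-)optimality in turn:

* Bₑ, Bₛ, Fₑ, Fₛ — non-negative quadratic subproblems by monotone
  accelerated projected gradient (FISTA with restart, best-iterate
  tracking);
* C — the exact minimizer over the symmetric subspace by conjugate
  gradient on the operator C ↦ sym(BₑᵀBₑ·C·FₑFₑᵀ + BₛᵀBₛ·C·FₛFₛᵀ);
* Z — ADMM with the split Z = J, where the J-step applies the exact
  proximal map of γ‖·‖₁ restricted to {J = Jᵀ, diag(J) = 0}
  (soft-threshold of the symmetrized point at γ/ρ, diagonal zeroed).

Every accepted block update is safeguarded to be non-increasing, so the
outer objective trace is monotone up to floating-point rounding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.decomposition import NMF

logger = logging.getLogger("stscsr")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TriFactorModel:
    """The five factor matrices of the joint tri-factorization."""

    B_e: np.ndarray  # m × k, ≥ 0 (expression basis)
    B_s: np.ndarray  # n × k, ≥ 0 (spatial basis)
    C: np.ndarray    # k × k, symmetric shared core
    F_e: np.ndarray  # k × n, ≥ 0 (expression coefficients)
    F_s: np.ndarray  # k × n, ≥ 0 (spatial coefficients)
    k: int

    def check_constraints(self, tol_sym: float = 1e-9) -> None:
        for name in ("B_e", "B_s", "F_e", "F_s"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} violates non-negativity")
        if np.abs(self.C - self.C.T).max() > tol_sym:
            raise ValueError("C violates symmetry")


@dataclass
class AffinityGraph:
    """Learned spot–spot affinity Z plus solver metadata."""

    Z: np.ndarray
    alpha: float
    beta: float
    gamma: float
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    dual: np.ndarray | None = None  # ADMM scaled dual, kept for warm starts

    def check_constraints(self, tol_sym: float = 1e-9) -> None:
        if np.abs(self.Z - self.Z.T).max() > tol_sym:
            raise ValueError("Z violates symmetry")
        if np.abs(np.diag(self.Z)).max() > 0:
            raise ValueError("Z has nonzero diagonal")


@dataclass
class SolverConfig:
    """Hyperparameters of the joint objective and its solver.

    Defaults α=2, β=1, γ=50, k=50 are the settings under which the method
    is stable across datasets; ``rho`` is the ADMM penalty (adapted by
    residual balancing), ``tol`` the relative objective-change stopping
    rule, ``fix_C`` freezes C at the identity (reducing the model to two
    independent NMFs when α=β=γ=0). ``inner_tol``/``z_tol`` set the block
    and ADMM accuracies inside the outer loop; every block update is
    safeguarded to be non-increasing, so moderate inner accuracy cannot
    break descent.
    """

    alpha: float = 2.0
    beta: float = 1.0
    gamma: float = 50.0
    k: int = 50
    max_outer: int = 200
    tol: float = 1e-5
    rho: float = 1.0
    seed: int = 0
    init: str = "nndsvd"
    max_inner: int = 300
    inner_tol: float = 1e-6
    z_tol: float = 1e-4
    fix_C: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.init not in ("nndsvd", "random"):
            raise ValueError("init must be 'nndsvd' or 'random'")


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective(X: np.ndarray, W: np.ndarray, L: np.ndarray,
              model: TriFactorModel, Z: np.ndarray,
              alpha: float, beta: float, gamma: float) -> float:
    """Value of the joint objective at the given factors and affinity."""
    m, n = X.shape
    if W.shape != (n, n) or L.shape != (n, n):
        raise ValueError("W and L must be n × n with n = X.shape[1]")
    if model.B_e.shape != (m, model.k) or model.F_e.shape != (model.k, n):
        raise ValueError("expression factor shapes inconsistent with X")
    if model.B_s.shape != (n, model.k) or model.F_s.shape != (model.k, n):
        raise ValueError("spatial factor shapes inconsistent with W")
    if Z.shape != (n, n):
        raise ValueError("Z must be n × n")

    Re = X - model.B_e @ model.C @ model.F_e
    Rs = W - model.B_s @ model.C @ model.F_s
    val = float(np.sum(Re * Re) + np.sum(Rs * Rs))
    if alpha:
        val += alpha * float(np.sum((model.F_e @ L) * model.F_e))
    if beta:
        De = model.F_e - model.F_e @ Z
        Ds = model.F_s - model.F_s @ Z
        val += beta * float(np.sum(De * De) + np.sum(Ds * Ds))
    if gamma:
        val += gamma * float(np.abs(Z).sum())
    return val


# ---------------------------------------------------------------------------
# non-negative quadratic block solver
# ---------------------------------------------------------------------------

def _specnorm_sym(M: np.ndarray, iters: int = 60) -> float:
    """Upper estimate of the spectral norm of a symmetric PSD matrix."""
    n = M.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    nrm = 0.0
    for _ in range(iters):
        v = M @ v
        nrm = float(np.linalg.norm(v))
        if nrm == 0.0:
            return 0.0
        v /= nrm
    return 1.05 * nrm


def _project(F: np.ndarray, col_norm_max: float | None) -> np.ndarray:
    """Project onto {F ≥ 0} (optionally ∩ {‖column‖₂ ≤ col_norm_max}).

    For the orthant ∩ ball intersection the exact projection is clip-then-
    radially-scale per column.
    """
    F = np.maximum(F, 0.0)
    if col_norm_max is not None:
        norms = np.linalg.norm(F, axis=0)
        over = norms > col_norm_max
        if over.any():
            F = F.copy()
            F[:, over] *= col_norm_max / norms[over]
    return F


def _nnq_solve(F0: np.ndarray, left: np.ndarray | None, right: np.ndarray | None,
               P: np.ndarray, max_iter: int = 300, tol: float = 1e-10,
               col_norm_max: float | None = None) -> np.ndarray:
    """Minimize tr(Fᵀ·left·F) + tr(F·right·Fᵀ) − 2⟨F, P⟩ over F ≥ 0.

    ``left`` multiplies from the left (rows of F couple), ``right`` from the
    right (columns couple); either may be None; ``col_norm_max`` adds a
    per-column norm cap (used for the basis blocks to pin the scale
    ambiguity between basis and coefficients). FISTA with adaptive restart;
    the best iterate seen (including the feasible start) is returned, so the
    block objective never increases.
    """

    def f_and_g(F: np.ndarray) -> tuple[float, np.ndarray]:
        G = -P.copy()
        val = -2.0 * float(np.sum(F * P))
        if left is not None:
            LF = left @ F
            val += float(np.sum(F * LF))
            G += LF
        if right is not None:
            FR = F @ right
            val += float(np.sum(F * FR))
            G += FR
        return val, 2.0 * G

    lip = 2.0 * ((_specnorm_sym(left) if left is not None else 0.0)
                 + (_specnorm_sym(right) if right is not None else 0.0))
    F = _project(F0, col_norm_max)
    if lip == 0.0:
        return F
    step = 1.0 / lip

    best = F
    best_val, _ = f_and_g(F)
    Y = F
    t = 1.0
    prev_val = best_val
    for _ in range(max_iter):
        _, gY = f_and_g(Y)
        Fn = _project(Y - step * gY, col_norm_max)
        val, _ = f_and_g(Fn)
        if val < best_val:
            best, best_val = Fn, val
        if val > prev_val:  # adaptive restart
            Y, t = Fn, 1.0
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            Y = Fn + ((t - 1.0) / t_next) * (Fn - F)
            t = t_next
        delta = float(np.abs(Fn - F).max())
        F, prev_val = Fn, val
        if delta <= tol * (1.0 + float(np.abs(F).max())):
            break
        if not np.isfinite(val):
            raise FloatingPointError("non-finite value in block update")
    return best


def update_Be(model: TriFactorModel, X: np.ndarray,
              max_inner: int = 300, tol: float = 1e-10) -> np.ndarray:
    """Non-negative least-squares update of the expression basis.

    Basis columns are constrained to unit ℓ2 norm, which pins the scale
    ambiguity between basis and coefficients (otherwise the regularizers on
    Fₑ could be driven to zero by inflating Bₑ·C).
    """
    A = model.C @ model.F_e
    return _nnq_solve(model.B_e, None, A @ A.T, X @ A.T, max_iter=max_inner,
                      tol=tol, col_norm_max=1.0)


def update_Bs(model: TriFactorModel, W: np.ndarray,
              max_inner: int = 300, tol: float = 1e-10) -> np.ndarray:
    """Non-negative least-squares update of the spatial basis (unit columns)."""
    A = model.C @ model.F_s
    return _nnq_solve(model.B_s, None, A @ A.T, W @ A.T, max_iter=max_inner,
                      tol=tol, col_norm_max=1.0)


def update_Fe(model: TriFactorModel, X: np.ndarray, Z: np.ndarray,
              L: np.ndarray, alpha: float, beta: float,
              max_inner: int = 300, tol: float = 1e-10) -> np.ndarray:
    """Non-negative update of the expression coefficients.

    Minimizes ‖X − BₑCFₑ‖² + α·Tr(Fₑ L Fₑᵀ) + β‖Fₑ − FₑZ‖² over Fₑ ≥ 0.
    """
    Q = model.B_e @ model.C
    n = X.shape[1]
    right = None
    if alpha or beta:
        right = np.zeros((n, n))
        if alpha:
            right += alpha * L
        if beta:
            IZ = np.eye(n) - Z
            right += beta * (IZ @ IZ.T)
    return _nnq_solve(model.F_e, Q.T @ Q, right, Q.T @ X, max_iter=max_inner,
                      tol=tol)


def update_Fs(model: TriFactorModel, W: np.ndarray, Z: np.ndarray,
              beta: float, max_inner: int = 300, tol: float = 1e-10) -> np.ndarray:
    """Non-negative update of the spatial coefficients (no Laplacian term)."""
    Q = model.B_s @ model.C
    n = W.shape[1]
    right = None
    if beta:
        IZ = np.eye(n) - Z
        right = beta * (IZ @ IZ.T)
    return _nnq_solve(model.F_s, Q.T @ Q, right, Q.T @ W, max_iter=max_inner,
                      tol=tol)


# ---------------------------------------------------------------------------
# shared core C
# ---------------------------------------------------------------------------

def _sym(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + M.T)


def _project_C(C: np.ndarray, norm_max: float | None) -> np.ndarray:
    """Exact projection onto {C = Cᵀ} (∩ {‖C‖_F ≤ norm_max} if capped).

    For a subspace through the origin intersected with a centered ball the
    projection is symmetrize-then-radially-scale.
    """
    C = _sym(C)
    if norm_max is not None:
        nrm = float(np.linalg.norm(C))
        if nrm > norm_max:
            C = C * (norm_max / nrm)
    return C


def update_C(model: TriFactorModel, X: np.ndarray, W: np.ndarray,
             norm_max: float | None = None, max_iter: int = 500,
             tol: float = 1e-12) -> np.ndarray:
    """Minimize the two reconstruction terms over symmetric (norm-capped) C.

    Solves min ‖X − BₑCFₑ‖² + ‖W − BₛCFₛ‖² s.t. C = Cᵀ (and optionally
    ‖C‖_F ≤ norm_max, which together with the unit-norm basis columns pins
    the scale ambiguity between the core and the coefficients) by FISTA
    with exact projection, warm-started at the current C. The best iterate
    is returned, so the block objective never increases.
    """
    A1 = model.B_e.T @ model.B_e
    B1 = model.F_e @ model.F_e.T
    A2 = model.B_s.T @ model.B_s
    B2 = model.F_s @ model.F_s.T
    E = model.B_e.T @ X @ model.F_e.T + model.B_s.T @ W @ model.F_s.T

    def f_and_g(C: np.ndarray) -> tuple[float, np.ndarray]:
        T1 = A1 @ C @ B1
        T2 = A2 @ C @ B2
        val = float(np.sum(C * T1) + np.sum(C * T2) - 2.0 * np.sum(C * E))
        return val, 2.0 * (T1 + T2 - E)

    lip = 2.0 * (_specnorm_sym(A1) * _specnorm_sym(B1)
                 + _specnorm_sym(A2) * _specnorm_sym(B2))
    C = _project_C(model.C, norm_max)
    if lip == 0.0:
        return C
    step = 1.0 / lip

    best = C
    best_val, _ = f_and_g(C)
    Y, t, prev_val = C, 1.0, best_val
    for _ in range(max_iter):
        _, gY = f_and_g(Y)
        Cn = _project_C(Y - step * gY, norm_max)
        val, _ = f_and_g(Cn)
        if val < best_val:
            best, best_val = Cn, val
        if val > prev_val:
            Y, t = Cn, 1.0
        else:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            Y = Cn + ((t - 1.0) / t_next) * (Cn - C)
            t = t_next
        delta = float(np.abs(Cn - C).max())
        C, prev_val = Cn, val
        if delta <= tol * (1.0 + float(np.abs(C).max())):
            break
    return _sym(best)


# ---------------------------------------------------------------------------
# affinity Z
# ---------------------------------------------------------------------------

def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _prox_J(V: np.ndarray, thresh: float, zero_diag: bool) -> np.ndarray:
    """Exact prox of γ‖·‖₁ + indicator{symmetric, zero diagonal} at V."""
    J = _soft(_sym(V), thresh)
    if zero_diag:
        np.fill_diagonal(J, 0.0)
    return J


def update_Z(F_e: np.ndarray, F_s: np.ndarray, beta: float, gamma: float,
             rho: float = 1.0, Z0: np.ndarray | None = None,
             dual0: np.ndarray | None = None, zero_diag: bool = True,
             max_inner: int = 500, tol: float = 1e-6) -> AffinityGraph:
    """Solve the affinity subproblem by ADMM.

    Minimizes β(‖Fₑ − FₑZ‖² + ‖Fₛ − FₛZ‖²) + γ‖Z‖₁ subject to Z = Zᵀ and
    diag(Z) = 0 via the split Z = J: the Z-step is a linear solve in
    (2βG + ρI) with G = FₑᵀFₑ + FₛᵀFₛ (Woodbury identity when the rank 2k
    is small against n), the J-step the combined ℓ1/constraint prox, with
    residual-balancing adaptation of ρ. The returned ``Z`` is the feasible
    iterate J.
    """
    n = F_e.shape[1]
    if F_s.shape[1] != n:
        raise ValueError("F_e and F_s must have the same number of columns")
    if beta == 0.0:
        # objective reduces to γ‖Z‖₁ (plus nothing): Z = 0
        return AffinityGraph(np.zeros((n, n)), 0.0, beta, gamma,
                             converged=True, n_iter=0)

    H = np.hstack([F_e.T, F_s.T])           # n × 2k
    G = H @ H.T
    use_woodbury = H.shape[1] * 2 < n

    def make_solver(rho_val: float):
        if use_woodbury:
            Cmat = (rho_val / (2.0 * beta)) * np.eye(H.shape[1]) + H.T @ H
            cho = scipy.linalg.cho_factor(Cmat)

            def solve(M: np.ndarray) -> np.ndarray:
                return (M - H @ scipy.linalg.cho_solve(cho, H.T @ M)) / rho_val
        else:
            A = 2.0 * beta * G + rho_val * np.eye(n)
            cho = scipy.linalg.cho_factor(A)

            def solve(M: np.ndarray) -> np.ndarray:
                return scipy.linalg.cho_solve(cho, M)
        return solve

    J = np.zeros((n, n)) if Z0 is None else Z0.copy()
    U = np.zeros((n, n)) if dual0 is None else dual0.copy()
    solve = make_solver(rho)
    R2bG = 2.0 * beta * G

    converged = False
    it = 0
    for it in range(1, max_inner + 1):
        Zq = solve(R2bG + rho * (J - U))
        J_prev = J
        J = _prox_J(Zq + U, gamma / rho, zero_diag)
        U = U + Zq - J
        r = float(np.linalg.norm(Zq - J))
        s = rho * float(np.linalg.norm(J - J_prev))
        eps = tol * max(float(np.linalg.norm(Zq)), float(np.linalg.norm(J)), 1.0)
        if r <= eps and s <= eps:
            converged = True
            break
        # residual balancing keeps the primal/dual progress comparable;
        # adapting only every few sweeps lets the iteration settle in between
        if it % 10 == 0:
            if r > 10.0 * s:
                rho *= 2.0
                U /= 2.0
                solve = make_solver(rho)
            elif s > 10.0 * r:
                rho /= 2.0
                U *= 2.0
                solve = make_solver(rho)
    if not converged:
        logger.info("update_Z: ADMM stopped after %d iterations "
                    "(primal residual %.2e); best feasible iterate returned", it, r)
    return AffinityGraph(J, 0.0, beta, gamma, converged=converged,
                         n_iter=it, dual=U)


def _z_block_objective(F_e: np.ndarray, F_s: np.ndarray, Z: np.ndarray,
                       beta: float, gamma: float) -> float:
    De = F_e - F_e @ Z
    Ds = F_s - F_s @ Z
    return beta * float(np.sum(De * De) + np.sum(Ds * Ds)) + gamma * float(np.abs(Z).sum())


# ---------------------------------------------------------------------------
# initialization and driver
# ---------------------------------------------------------------------------

def initialize(X: np.ndarray, W: np.ndarray, k: int, init: str = "nndsvd",
               seed: int = 0) -> tuple[TriFactorModel, AffinityGraph]:
    """Warm start: independent rank-k NMFs of X and W, C = I, Z = 0."""
    m, n = X.shape
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n) = {min(m, n)}")
    sk_init = "nndsvda" if init == "nndsvd" else "random"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nmf_e = NMF(n_components=k, init=sk_init, random_state=seed,
                    max_iter=400, tol=1e-5)
        B_e = nmf_e.fit_transform(X)
        F_e = nmf_e.components_
        nmf_s = NMF(n_components=k, init=sk_init, random_state=seed,
                    max_iter=400, tol=1e-5)
        B_s = nmf_s.fit_transform(W)
        F_s = nmf_s.components_
    # move scale from basis columns (capped at unit norm) into coefficients;
    # C = I so the reconstructions are unchanged
    for B, F in ((B_e, F_e), (B_s, F_s)):
        norms = np.linalg.norm(B, axis=0)
        pos = norms > 0
        B[:, pos] /= norms[pos]
        F[pos, :] *= norms[pos, None]
    model = TriFactorModel(B_e, B_s, np.eye(k), F_e, F_s, k)
    aff = AffinityGraph(np.zeros((n, n)), 0.0, 0.0, 0.0)
    return model, aff


def solve(X: np.ndarray, W: np.ndarray, L: np.ndarray,
          config: SolverConfig) -> tuple[TriFactorModel, AffinityGraph]:
    """Minimize the joint objective by cyclic block-coordinate descent.

    Block order: Bₑ → Bₛ → C → Fₑ → Fₛ → Z. Stops when the relative
    objective change drops below ``config.tol`` or after
    ``config.max_outer`` cycles. The objective trace is recorded per cycle
    and is guaranteed non-increasing (a rise beyond 1e-6 relative raises,
    as it would indicate a defective update).
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    L = np.asarray(L, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    empty = np.flatnonzero(X.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(f"X has all-zero columns (empty spots): {empty[:5].tolist()}")
    if np.abs(W - W.T).max() > 1e-8 or (W < 0).any():
        raise ValueError("W must be symmetric and non-negative")

    k = config.k
    if k > min(X.shape):
        logger.warning("rank k=%d clipped to min(m, n)=%d", k, min(X.shape))
        k = min(X.shape)

    model, aff = initialize(X, W, k, config.init, config.seed)
    Z = aff.Z
    dual = None
    alpha, beta, gamma = config.alpha, config.beta, config.gamma

    trace = [objective(X, W, L, model, Z, alpha, beta, gamma)]
    converged = False
    n_outer = 0
    for n_outer in range(1, config.max_outer + 1):
        model.B_e = update_Be(model, X, config.max_inner, config.inner_tol)
        model.B_s = update_Bs(model, W, config.max_inner, config.inner_tol)
        if not config.fix_C:
            C_new = update_C(model, X, W, norm_max=np.sqrt(k),
                             max_iter=config.max_inner)
            # exact minimizer over a set containing the current C; accept
            # only if it did not lose to rounding
            old = model.C
            model.C = C_new
            if (objective(X, W, L, model, Z, alpha, beta, gamma)
                    > trace[-1] * (1 + 1e-12) + 1e-12):
                model.C = old
        model.F_e = update_Fe(model, X, Z, L, alpha, beta, config.max_inner,
                              config.inner_tol)
        model.F_s = update_Fs(model, W, Z, beta, config.max_inner,
                              config.inner_tol)
        if beta > 0:
            cand = update_Z(model.F_e, model.F_s, beta, gamma, config.rho,
                            Z0=Z, dual0=dual, max_inner=config.max_inner,
                            tol=config.z_tol)
            if (_z_block_objective(model.F_e, model.F_s, cand.Z, beta, gamma)
                    <= _z_block_objective(model.F_e, model.F_s, Z, beta, gamma)):
                Z, dual = cand.Z, cand.dual
        obj = objective(X, W, L, model, Z, alpha, beta, gamma)
        prev = trace[-1]
        trace.append(obj)
        if obj > prev * (1 + 1e-6) + 1e-12:
            raise RuntimeError(
                f"objective increased at outer iteration {n_outer}: "
                f"{prev:.6e} -> {obj:.6e} (update defect)"
            )
        if abs(prev - obj) <= config.tol * max(1.0, abs(prev)):
            converged = True
            break

    model.check_constraints()
    result = AffinityGraph(Z, alpha, beta, gamma, objective_trace=trace,
                           converged=converged, n_iter=n_outer, dual=dual)
    result.check_constraints()
    return model, result
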