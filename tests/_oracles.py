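"""Independent reference solvers and formulas used by the test suite.

Everything here is deliberately written from first principles (generic
constrained optimizers, pair counting, contingency entropies) so that it
shares no code path with the package implementation it checks.
"""

from itertools import combinations
from math import comb, log

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# generic solvers for the block subproblems
# ---------------------------------------------------------------------------

def oracle_basis(X, A, shape, col_norm_max=1.0):
    """min ‖X − B A‖² s.t. B ≥ 0, ‖B[:, j]‖ ≤ col_norm_max, via SLSQP."""
    m, k = shape

    def f(v):
        B = v.reshape(m, k)
        R = X - B @ A
        return float(np.sum(R * R))

    def grad(v):
        B = v.reshape(m, k)
        return (-2.0 * (X - B @ A) @ A.T).ravel()

    cons = [{"type": "ineq",
             "fun": (lambda v, j=j: col_norm_max ** 2
                     - float(np.sum(v.reshape(m, k)[:, j] ** 2)))}
            for j in range(k)]
    x0 = np.full(m * k, 0.1)
    res = minimize(f, x0, jac=grad, bounds=[(0, None)] * (m * k),
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    return f(res.x), res.x.reshape(m, k)


def oracle_coefficients(P_mat, right, P_lin, shape):
    """min tr(FᵀP_mat F) + tr(F right Fᵀ) − 2⟨F, P_lin⟩ s.t. F ≥ 0 (L-BFGS-B).

    Covers the coefficient blocks: P_mat = QᵀQ, right = αL + β(I−Z)(I−Z)ᵀ.
    """
    k, n = shape

    def f(v):
        F = v.reshape(k, n)
        val = float(np.sum(F * (P_mat @ F))) - 2.0 * float(np.sum(F * P_lin))
        if right is not None:
            val += float(np.sum(F * (F @ right)))
        return val

    def grad(v):
        F = v.reshape(k, n)
        G = P_mat @ F - P_lin
        if right is not None:
            G = G + F @ right
        return (2.0 * G).ravel()

    res = minimize(f, np.full(k * n, 0.1), jac=grad,
                   bounds=[(0, None)] * (k * n), method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    return f(res.x), res.x.reshape(k, n)


def oracle_core(X, W, B_e, B_s, F_e, F_s, k, norm_max):
    """min ‖X−B_e C F_e‖² + ‖W−B_s C F_s‖² over symmetric C, ‖C‖_F ≤ norm_max.

    Parametrized by the upper triangle (symmetry exact by construction),
    solved with SLSQP under the ball constraint.
    """
    iu = np.triu_indices(k)

    def unpack(v):
        C = np.zeros((k, k))
        C[iu] = v
        return C + np.triu(C, 1).T

    def f(v):
        C = unpack(v)
        R1 = X - B_e @ C @ F_e
        R2 = W - B_s @ C @ F_s
        return float(np.sum(R1 * R1) + np.sum(R2 * R2))

    cons = [{"type": "ineq",
             "fun": lambda v: norm_max ** 2 - float(np.sum(unpack(v) ** 2))}]
    res = minimize(f, np.zeros(len(iu[0])), constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-14})
    return f(res.x), unpack(res.x)


def oracle_affinity(F_e, F_s, beta, gamma):
    """min β(‖F_e−F_eZ‖² + ‖F_s−F_sZ‖²) + γ‖Z‖₁, Z = Zᵀ, diag(Z) = 0.

    The off-diagonal upper triangle is split into positive and negative
    parts so the ℓ1 term becomes linear and L-BFGS-B applies.
    """
    n = F_e.shape[1]
    iu = np.triu_indices(n, 1)
    p = len(iu[0])

    def unpack(v):
        z = v[:p] - v[p:]
        Z = np.zeros((n, n))
        Z[iu] = z
        return Z + Z.T

    def f(v):
        Z = unpack(v)
        De = F_e - F_e @ Z
        Ds = F_s - F_s @ Z
        return (beta * float(np.sum(De * De) + np.sum(Ds * Ds))
                + gamma * float(np.sum(v)) * 2.0)

    res = minimize(f, np.zeros(2 * p), bounds=[(0, None)] * (2 * p),
                   method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12})
    return f(res.x), unpack(res.x)


# ---------------------------------------------------------------------------
# clustering metrics from first principles
# ---------------------------------------------------------------------------

def ari_pair_counting(a, b):
    """Adjusted Rand index by explicit pair enumeration over all C(n,2) pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    n11 = n00 = n10 = n01 = 0
    for i, j in combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    total = comb(n, 2)
    sum_a = n11 + n10
    sum_b = n11 + n01
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if n11 == expected else 0.0
    return (n11 - expected) / (max_index - expected)


def nmi_contingency(a, b):
    """NMI (arithmetic normalization) from the contingency table directly."""
    a, b = np.asarray(a), np.asarray(b)
    n = a.size
    ua, ub = np.unique(a), np.unique(b)
    mi = 0.0
    for x in ua:
        for y in ub:
            nij = np.sum((a == x) & (b == y))
            if nij:
                mi += (nij / n) * log(nij * n / (np.sum(a == x) * np.sum(b == y)))
    ha = -sum((np.sum(a == x) / n) * log(np.sum(a == x) / n) for x in ua)
    hb = -sum((np.sum(b == y) / n) * log(np.sum(b == y) / n) for y in ub)
    denom = 0.5 * (ha + hb)
    if denom == 0.0:
        return 1.0
    return mi / denom
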