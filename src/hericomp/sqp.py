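"""Sequential quadratic programming for heritability maximization.

The program being solved (in the split variables gamma = (u, v, mu_m, mu_f),
with w = u - v absorbing the l1 penalty into a linear term) is

    min_gamma  gamma' A gamma + lambda * sum(gamma[:2d])
    s.t.       gamma' G gamma - n = 0          (unit trait variance)
               b_m' gamma = 0,  b_f' gamma = 0 (means pinned to sex means)
               gamma[:2d] >= 0                 (nonnegative split)

where A = sum_i K_i Phi_i^{-1} K_i' and G = K K'.  The quadratic equality
makes the problem nonconvex; each iteration solves a convex QP built from the
Lagrangian's (eigenvalue-clipped) Hessian and the linearized constraints,
line-searches an l1-penalty merit function, and moves the multipliers toward
the subproblem's.  Linearizing the bounds gives simple bounds on the step
(p_j >= -gamma_j), which the primal-dual active-set QP solver exploits;
scipy's SLSQP is the fallback when the active-set iteration cycles, with
multipliers recovered from the stationarity system.

Two structural properties keep the iteration stable.  All constraints except
the variance constraint are homogeneous in gamma, so scaling gamma onto the
surface gamma' G gamma = n is an exact retraction that preserves the mean
constraints and the bounds: every trial point of the line search is retracted
before the merit test, which removes the second-order constraint violation
that otherwise forces tiny steps along the curved surface.  And the
subproblem is solved in row-equilibrated, magnitude-scaled form, since the
raw gradients differ by orders of magnitude (the variance row scales with
n^{3/2}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["SQPState", "solve_qp", "qp_subproblem", "line_search", "sqp_solve"]


class QPInfeasibleError(RuntimeError):
    """The linearized subproblem has no solution."""


# ---------------------------------------------------------------------------
# convex QP:  min 1/2 p'Bp + g'p  s.t.  A p = b,  p_j >= lo_j (j < n_bound)


def _kkt_solve(B, g, A, b, lo, active):
    """Solve the equality-constrained QP with the given active bound set."""
    m = B.shape[0]
    n_eq = A.shape[0]
    act = np.flatnonzero(active)
    n_act = len(act)
    dim = m + n_eq + n_act
    K = np.zeros((dim, dim))
    K[:m, :m] = B
    K[:m, m : m + n_eq] = -A.T
    K[m : m + n_eq, :m] = A
    for t, j in enumerate(act):
        K[j, m + n_eq + t] = -1.0
        K[m + n_eq + t, j] = 1.0
    rhs = np.concatenate([-g, b, lo[act]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    p = sol[:m]
    q_eq = sol[m : m + n_eq]
    mu = np.zeros(len(lo))
    mu[act] = sol[m + n_eq :]
    return p, q_eq, mu


def solve_qp(B, g, A, b, n_bound, lo, active0=None, max_iter=100):
    """Strictly convex QP with equality constraints and lower bounds.

    Returns ``(p, q_eq, mu)`` where ``q_eq`` are the equality multipliers and
    ``mu >= 0`` the bound multipliers, in the convention
    ``B p + g = A' q_eq + sum_j mu_j e_j``.

    Uses a primal-dual active-set iteration; if the active set cycles, falls
    back to SLSQP and recovers multipliers by least squares on the
    stationarity conditions.
    """
    m = B.shape[0]
    lo_full = np.full(m, -np.inf)
    lo_full[:n_bound] = lo
    active = np.zeros(m, dtype=bool)
    if active0 is not None and len(active0) >= n_bound:
        active[:n_bound] = active0[:n_bound]
    seen = set()
    for _ in range(max_iter):
        p, q_eq, mu = _kkt_solve(B, g, A, b, lo_full, active)
        resid = lo_full[:n_bound] - p[:n_bound]  # > 0 where a bound is violated
        new_active = (mu[:n_bound] + resid) > 1e-12
        mask = np.zeros(m, dtype=bool)
        mask[:n_bound] = new_active
        if (mask == active).all():
            feas_ok = (p[:n_bound] >= lo_full[:n_bound] - 1e-7).all()
            dual_ok = (mu[:n_bound] >= -1e-7).all()
            eq_ok = np.abs(A @ p - b).max() <= 1e-6 if len(b) else True
            if feas_ok and dual_ok and eq_ok:
                return p, q_eq, np.maximum(mu[:n_bound], 0.0)
            break
        key = mask.tobytes()
        if key in seen:
            break
        seen.add(key)
        active = mask
    return _solve_qp_slsqp(B, g, A, b, n_bound, lo)


def _solve_qp_slsqp(B, g, A, b, n_bound, lo):
    m = B.shape[0]

    def fun(p):
        return 0.5 * p @ B @ p + g @ p, B @ p + g

    cons = [{"type": "eq", "fun": lambda p: A @ p - b, "jac": lambda p: A}]
    bounds = [(lo[j], None) for j in range(n_bound)] + [(None, None)] * (m - n_bound)
    res = optimize.minimize(
        fun, np.zeros(m), jac=True, method="SLSQP", bounds=bounds, constraints=cons,
        options={"maxiter": 500, "ftol": 1e-14},
    )
    p = res.x
    feasible = (
        (p[:n_bound] >= lo - 1e-6).all()
        and (np.abs(A @ p - b).max() <= 1e-5 if len(b) else True)
    )
    if not feasible:
        raise QPInfeasibleError(str(res.message))
    # recover multipliers from stationarity over the active set
    act = np.flatnonzero(p[:n_bound] <= lo + 1e-7)
    cols = [A.T] + [np.eye(m)[:, [j]] for j in act]
    M = np.hstack(cols)
    coef, *_ = np.linalg.lstsq(M, B @ p + g, rcond=None)
    q_eq = coef[: A.shape[0]]
    mu = np.zeros(n_bound)
    mu[act] = np.maximum(coef[A.shape[0] :], 0.0)
    return p, q_eq, mu


# ---------------------------------------------------------------------------
# problem evaluation helpers


def _c_vector(d: int) -> np.ndarray:
    c = np.zeros(2 * d + 2)
    c[: 2 * d] = 1.0
    return c


def _objective(blocks, gamma, lam):
    return float(gamma @ blocks.A @ gamma + lam * gamma[: 2 * blocks.d].sum())


def _grad_f(blocks, gamma, lam):
    return 2.0 * blocks.A @ gamma + lam * _c_vector(blocks.d)


def _constraints(blocks, gamma):
    g1 = float(gamma @ blocks.G @ gamma - blocks.n)
    g2 = float(blocks.b_m @ gamma)
    g3 = float(blocks.b_f @ gamma)
    return g1, g2, g3


def _violation(blocks, gamma):
    g1, g2, g3 = _constraints(blocks, gamma)
    neg = np.minimum(gamma[: 2 * blocks.d], 0.0)
    return abs(g1) / blocks.n + abs(g2) + abs(g3) - neg.sum()


def _merit(blocks, gamma, lam, rho):
    return _objective(blocks, gamma, lam) + rho * _violation(blocks, gamma)


def canonical_split(blocks, gamma: np.ndarray) -> np.ndarray:
    """Collapse (u, v) to the complementary pair (w+, w-).

    Leaves w, the derived trait and every constraint value unchanged while
    never increasing the l1 term, so it may be applied to any iterate.
    """
    d = blocks.d
    w = gamma[:d] - gamma[d : 2 * d]
    return np.concatenate([np.maximum(w, 0.0), np.maximum(-w, 0.0), gamma[2 * d :]])


def retract(blocks, gamma: np.ndarray) -> np.ndarray:
    """Scale gamma onto the unit-variance surface gamma' G gamma = n.

    Scaling preserves the homogeneous mean constraints and the nonnegativity
    bounds, so this is an exact retraction for every constraint but the one
    it solves.
    """
    q = float(gamma @ blocks.G @ gamma)
    if q <= 0:
        return gamma
    return gamma * np.sqrt(blocks.n / q)


def kkt_residual(blocks, gamma, alpha, lam):
    """Scaled max of stationarity, feasibility and complementarity errors."""
    d2 = 2 * blocks.d
    grad = _grad_f(blocks, gamma, lam)
    g1, g2, g3 = _constraints(blocks, gamma)
    stat = grad - alpha[0] * 2.0 * blocks.G @ gamma - alpha[1] * blocks.b_m - alpha[2] * blocks.b_f
    stat[:d2] -= alpha[3:]
    scale = max(1.0, np.abs(grad).max())
    comp = np.abs(alpha[3:] * gamma[:d2]).max() if d2 else 0.0
    dual_neg = max(0.0, -(alpha[3:].min() if d2 else 0.0))
    return max(
        np.abs(stat).max() / scale,
        abs(g1) / max(blocks.n, 1.0),
        abs(g2),
        abs(g3),
        comp / scale,
        dual_neg / scale,
    )


@dataclass
class SQPState:
    """Iterate of the SQP loop: gamma = (u, v, mu_m, mu_f) and multipliers."""

    gamma: np.ndarray
    alpha: np.ndarray
    iteration: int = 0
    objective: float = np.nan
    kkt: float = np.inf
    converged: bool = False
    rho: float = 1.0
    active: np.ndarray | None = None
    merit_trace: list = field(default_factory=list)


def qp_subproblem(state: SQPState, blocks, lam: float):
    """Solve the linearized subproblem at the current iterate.

    Returns the step ``p`` for gamma and the subproblem multipliers ``q_hat``
    ordered as (variance constraint, male mean, female mean, bounds).  The
    Lagrangian Hessian 2A - 2*alpha_1*G is generally indefinite, so its
    eigenvalues are clipped at a small positive floor before the QP; the
    subproblem is solved with unit-norm equality rows and a magnitude-scaled
    Hessian, and the multipliers are mapped back to the original scaling.
    """
    gamma, alpha = state.gamma, state.alpha
    d2 = 2 * blocks.d
    grad = _grad_f(blocks, gamma, lam)
    g1, g2, g3 = _constraints(blocks, gamma)
    H = 2.0 * blocks.A - 2.0 * alpha[0] * blocks.G
    H = 0.5 * (H + H.T)
    evals, evecs = np.linalg.eigh(H)
    scale = max(1.0, np.abs(evals).max())
    B = (evecs * np.maximum(evals, 1e-6 * scale)) @ evecs.T
    # the split directions e_j + e_{d+j} are exact null directions of both
    # quadratic forms (they leave w = u - v unchanged); give them real
    # curvature so the subproblem cannot drift along them
    d = blocks.d
    idx = np.arange(d)
    N = np.zeros((2 * d + 2, d))
    N[idx, idx] = N[idx + d, idx] = np.sqrt(0.5)
    B = B + 1e-2 * scale * (N @ N.T)
    A_eq = np.vstack([2.0 * blocks.G @ gamma, blocks.b_m, blocks.b_f])
    b_eq = -np.array([g1, g2, g3])
    row_norm = np.linalg.norm(A_eq, axis=1)
    row_norm[row_norm == 0] = 1.0
    obj_scale = max(1.0, np.abs(B).max())
    lo = -gamma[:d2]
    p, q_eq, mu = solve_qp(
        B / obj_scale,
        grad / obj_scale,
        A_eq / row_norm[:, None],
        b_eq / row_norm,
        d2,
        lo,
        active0=state.active,
    )
    q_eq = q_eq * obj_scale / row_norm
    mu = mu * obj_scale
    state.active = np.abs(p[:d2] - lo) <= 1e-9
    q_hat = np.concatenate([q_eq, mu])
    return p, q_hat


def line_search(
    state: SQPState,
    p: np.ndarray,
    q_hat: np.ndarray,
    blocks,
    lam: float,
    c1: float = 1e-4,
    backtrack: float = 0.5,
    min_step: float = 1e-12,
):
    """Armijo backtracking on the l1-penalty merit function.

    Every trial point is retracted onto the variance-constraint surface
    before the merit test.  The penalty weight rho is kept above the largest
    multiplier magnitude so the subproblem direction is a descent direction
    for the merit function.  Returns ``(step, new_gamma)`` or raises
    ``FloatingPointError`` on stall.
    """
    gamma = state.gamma
    grad = _grad_f(blocks, gamma, lam)
    viol = _violation(blocks, gamma)
    rho = max(state.rho, 1.1 * np.abs(q_hat).max() + 1e-2)
    deriv = float(grad @ p) - rho * viol
    state.rho = rho
    phi0 = _merit(blocks, gamma, lam, rho)
    s = 1.0
    while s >= min_step:
        cand = retract(blocks, gamma + s * p)
        phi = _merit(blocks, cand, lam, rho)
        if phi <= phi0 + c1 * s * min(deriv, 0.0):
            state.merit_trace.append((phi0, phi))
            return s, cand
        s *= backtrack
    raise FloatingPointError("line search stalled")


def initial_gamma(blocks) -> tuple[np.ndarray, np.ndarray]:
    """Algorithm start: u = 1, v = 0, means of the w = 1 trait, alpha = 1.

    The iterate is then retracted onto the unit-variance constraint surface.
    """
    d = blocks.d
    gamma = np.zeros(2 * d + 2)
    gamma[:d] = 1.0
    gamma[2 * d] = blocks.xbar_m.sum()
    gamma[2 * d + 1] = blocks.xbar_f.sum()
    gamma = retract(blocks, gamma)
    alpha = np.ones(2 * d + 3)
    return gamma, alpha


def sqp_solve(
    blocks,
    lam: float = 0.0,
    gamma0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SQPState:
    """Run the SQP loop to a KKT point of the split-variable program."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if gamma0 is None:
        gamma, alpha = initial_gamma(blocks)
    else:
        gamma = retract(blocks, np.array(gamma0, dtype=float))
        alpha = np.ones(2 * blocks.d + 3)
    state = SQPState(gamma=gamma, alpha=alpha)
    restarts = 0
    for it in range(1, max_iter + 1):
        state.iteration = it
        state.kkt = kkt_residual(blocks, state.gamma, state.alpha, lam)
        if state.kkt < tol:
            state.converged = True
            break
        try:
            p, q_hat = qp_subproblem(state, blocks, lam)
        except QPInfeasibleError:
            if restarts >= 3:
                break
            restarts += 1
            state.gamma = retract(blocks, state.gamma)
            state.alpha = np.ones_like(state.alpha)
            state.active = None
            continue
        if np.abs(p).max() < 1e-12:
            state.alpha = q_hat
            state.kkt = kkt_residual(blocks, state.gamma, state.alpha, lam)
            state.converged = state.kkt < tol
            break
        try:
            s, new_gamma = line_search(state, p, q_hat, blocks, lam)
        except FloatingPointError:
            break
        step_size = np.abs(new_gamma - state.gamma).max()
        state.gamma = canonical_split(blocks, new_gamma)
        state.alpha = state.alpha + s * (q_hat - state.alpha)
        if step_size < 1e-11:
            state.alpha = q_hat
            state.kkt = kkt_residual(blocks, state.gamma, state.alpha, lam)
            state.converged = state.kkt < tol
            break
    state.objective = _objective(blocks, state.gamma, lam)
    return state
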