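"""Henderson mixed-model equations and EM-REML for a single response.

The coefficient matrix is

    C = M' R^-1 M + diag(0_p, K_1^-1/s2_1, K_2^-1/s2_2, ...),

with M = [X, Z_1, Z_2, ...] and R = diag(sigma2_e / w_i) for per-observation
residual weights w_i.  Solutions are BLUE/BLUP; the inverse of C is the
prediction-error (co)variance of all solutions, which EM-REML uses for its
trace corrections:

    s2_k   <- (u_k' K_k^-1 u_k + tr(K_k^-1 C^{kk})) / q_k
    s2_e   <- (e' W e + tr(C^-1 M' W M)) / n

Both updates are conditional expectations of the complete-data sufficient
statistics, so the REML log-likelihood never decreases along the EM path.
Aitken extrapolation on the log variance components is attempted every few
steps and kept only when it improves the log-likelihood.

Problem sizes here are the desk scale of a research analysis (thousands of
records, around a thousand equations), so the coefficient matrix is
assembled sparse but factorised dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RandomTerm",
    "MMEState",
    "MixedSolution",
    "solve_mixed_model",
    "reml_update",
    "fit_univariate_reml",
    "hat_values_from",
]

_MIN_VAR = 1e-8


def spd_inv(C: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky
    (dpotrf/dpotri), falling back to LU for borderline matrices."""
    return spd_inv_logdet(C)[0]


def spd_inv_logdet(C: np.ndarray) -> tuple[np.ndarray, float]:
    """(C^-1, log det C) from a single Cholesky factorisation."""
    from scipy.linalg import lapack

    L, info = lapack.dpotrf(C, lower=1)
    if info == 0:
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Ci, info = lapack.dpotri(L, lower=1)
        if info == 0:
            return np.tril(Ci) + np.tril(Ci, -1).T, logdet
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError("coefficient matrix not positive definite")
    return np.linalg.inv(C), logdet


@dataclass
class RandomTerm:
    """One random effect: design Z (n x q) and the inverse covariance kernel.

    ``K_inv`` is the inverse of the relationship/covariance kernel among the
    q levels (None = identity).  ``logdet_K`` is log|K| (0 for identity),
    needed only for likelihood reporting.
    """

    name: str
    Z: sp.csr_matrix
    K_inv: np.ndarray | None = None
    logdet_K: float | None = None

    def __post_init__(self) -> None:
        self.Z = sp.csr_matrix(self.Z)
        if self.K_inv is not None:
            self.K_inv = np.asarray(self.K_inv, dtype=float)
            if self.K_inv.shape != (self.q, self.q):
                raise ValueError(
                    f"K_inv shape {self.K_inv.shape} does not match q={self.q}"
                )
            if self.logdet_K is None:
                sign, ld = np.linalg.slogdet(self.K_inv)
                if sign <= 0:
                    raise ValueError(f"K_inv for term {self.name!r} not positive definite")
                self.logdet_K = -ld
        elif self.logdet_K is None:
            self.logdet_K = 0.0

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class MMEState:
    """Immutable data side of the equations; variance components vary."""

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    weights: np.ndarray | None = None  # residual variance sigma2_e / w_i

    M: sp.csr_matrix = field(init=False, repr=False)
    S: np.ndarray = field(init=False, repr=False)  # M' W M (dense)
    MWy: np.ndarray = field(init=False, repr=False)
    yWy: float = field(init=False, repr=False)
    sum_log_w: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.weights is None:
            w = np.ones(n)
        else:
            w = np.asarray(self.weights, dtype=float)
            if (w <= 0).any():
                raise ValueError("residual weights must be positive")
        self._w = w
        blocks = [sp.csr_matrix(self.X)] + [t.Z for t in self.terms]
        self.M = sp.hstack(blocks, format="csr")
        Wm = sp.diags(w)
        self.S = (self.M.T @ Wm @ self.M).toarray()
        self.MWy = self.M.T @ (w * self.y)
        self.yWy = float(self.y @ (w * self.y))
        self.sum_log_w = float(np.log(w).sum())

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def block_slices(self) -> list[slice]:
        out = []
        start = self.p
        for t in self.terms:
            out.append(slice(start, start + t.q))
            start += t.q
        return out


@dataclass
class MixedSolution:
    fixed: np.ndarray
    random: dict[str, np.ndarray]
    residuals: np.ndarray
    hat_values: np.ndarray
    fitted: np.ndarray
    C_inv: np.ndarray | None = None


def _assemble(state: MMEState, variances: dict[str, float], sigma2_e: float):
    C = state.S / sigma2_e
    for sl, term in zip(state.block_slices(), state.terms):
        s2 = max(float(variances[term.name]), _MIN_VAR)
        if term.K_inv is None:
            C[sl, sl] += np.eye(term.q) / s2
        else:
            C[sl, sl] += term.K_inv / s2
    rhs = state.MWy / sigma2_e
    return C, rhs


def hat_values_from(state: MMEState, C_inv: np.ndarray, sigma2_e: float) -> np.ndarray:
    """Leverages of the full mixed-model projection (fixed + random).

    h_i = (m_i' C^-1 m_i) * w_i / sigma2_e, the diagonal of M C^-1 M' R^-1.
    """
    P = state.M @ C_inv  # dense n x dim
    diag = np.asarray(state.M.multiply(P).sum(axis=1)).ravel()
    return diag * state._w / sigma2_e


def solve_mixed_model(
    y,
    X,
    random_terms: list[RandomTerm],
    variances: dict[str, float],
    sigma2_e: float,
    residual_weights=None,
    return_C_inv: bool = False,
) -> MixedSolution:
    """Solve Henderson's equations at fixed variance components.

    ``residual_weights`` w_i give per-observation residual variance
    sigma2_e / w_i.  Residuals are y - fitted with fitted = Xb + sum Z_k u_k;
    hat values are the diagonal of the projection from y to fitted values.
    """
    state = MMEState(y=y, X=X, terms=random_terms, weights=residual_weights)
    C, rhs = _assemble(state, variances, sigma2_e)
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular mixed-model coefficient matrix: fixed or random effects "
            "are confounded (e.g. a factor level nested in another)"
        ) from exc
    theta = C_inv @ rhs
    fitted = state.M @ theta
    sol = MixedSolution(
        fixed=theta[: state.p],
        random={
            t.name: theta[sl] for sl, t in zip(state.block_slices(), state.terms)
        },
        residuals=state.y - fitted,
        hat_values=hat_values_from(state, C_inv, sigma2_e),
        fitted=fitted,
        C_inv=C_inv if return_C_inv else None,
    )
    return sol


def _reml_loglik(
    state: MMEState,
    log_C: float,
    theta: np.ndarray,
    variances: dict[str, float],
    sigma2_e: float,
) -> float:
    """-2 log L_REML up to an additive constant, negated and halved."""
    n = state.n
    log_R = n * np.log(sigma2_e) - state.sum_log_w
    log_G = 0.0
    for term in state.terms:
        s2 = max(float(variances[term.name]), _MIN_VAR)
        log_G += term.q * np.log(s2) + term.logdet_K
    yPy = (state.yWy - theta @ state.MWy) / sigma2_e
    return -0.5 * (log_R + log_G + log_C + yPy)


def reml_update(
    state: MMEState, variances: dict[str, float], sigma2_e: float
) -> tuple[dict[str, float], float, float, dict]:
    """One EM-REML step.

    Returns (new term variances, new sigma2_e, REML log-likelihood at the
    *current* components, info dict with solutions and pinned components).
    """
    C, rhs = _assemble(state, variances, sigma2_e)
    C_inv, log_C = spd_inv_logdet(C)
    theta = C_inv @ rhs
    loglik = _reml_loglik(state, log_C, theta, variances, sigma2_e)

    new_vars: dict[str, float] = {}
    pinned: list[str] = []
    for sl, term in zip(state.block_slices(), state.terms):
        u = theta[sl]
        Cb = C_inv[sl, sl]
        if term.K_inv is None:
            quad = float(u @ u) + float(np.trace(Cb))
        else:
            quad = float(u @ term.K_inv @ u) + float(np.sum(term.K_inv * Cb.T))
        s2 = quad / term.q
        if s2 < _MIN_VAR:
            s2 = _MIN_VAR
            pinned.append(term.name)
        new_vars[term.name] = s2

    e = state.y - state.M @ theta
    eWe = float(e @ (state._w * e))
    new_sigma2_e = (eWe + float(np.sum(C_inv * state.S.T))) / state.n
    info = {"theta": theta, "pinned": pinned, "C_inv": C_inv}
    return new_vars, new_sigma2_e, loglik, info


def fit_univariate_reml(
    y,
    X,
    random_terms: list[RandomTerm],
    start_variances: dict[str, float] | None = None,
    start_sigma2_e: float | None = None,
    residual_weights=None,
    tol: float = 1e-6,
    max_iter: int = 200,
    accelerate: bool = True,
):
    """EM-REML to convergence of the log-likelihood.

    Returns (variances, sigma2_e, MixedSolution, loglik_trace, converged).
    """
    state = MMEState(y=y, X=X, terms=random_terms, weights=residual_weights)
    vy = float(np.var(np.asarray(y, dtype=float), ddof=1)) or 1.0
    variances = dict(start_variances) if start_variances else {
        t.name: 0.2 * vy for t in random_terms
    }
    sigma2_e = float(start_sigma2_e) if start_sigma2_e else 0.5 * vy

    trace: list[float] = []
    history: list[np.ndarray] = []
    converged = False
    names = [t.name for t in random_terms]
    for it in range(max_iter):
        new_vars, new_s2e, loglik, info = reml_update(state, variances, sigma2_e)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        variances, sigma2_e = new_vars, new_s2e

        if accelerate:
            history.append(
                np.log(np.array([variances[n] for n in names] + [sigma2_e]))
            )
            if len(history) >= 3 and it % 4 == 3:
                acc = _aitken(history[-3], history[-2], history[-1])
                if acc is not None:
                    cand_vars = {n: float(np.exp(v)) for n, v in zip(names, acc[:-1])}
                    cand_s2e = float(np.exp(acc[-1]))
                    C, rhs = _assemble(state, cand_vars, cand_s2e)
                    try:
                        from scipy.linalg import cho_factor, cho_solve

                        fac = cho_factor(C, lower=True)
                        theta = cho_solve(fac, rhs)
                        log_C = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
                    except np.linalg.LinAlgError:
                        theta = None
                    if theta is not None:
                        cand_ll = _reml_loglik(state, log_C, theta, cand_vars, cand_s2e)
                        if cand_ll > trace[-1]:
                            variances, sigma2_e = cand_vars, cand_s2e
                            history.clear()

    # final solve at the converged components
    sol = solve_mixed_model(
        y,
        X,
        random_terms,
        variances,
        sigma2_e,
        residual_weights=residual_weights,
        return_C_inv=True,
    )
    return variances, sigma2_e, sol, trace, converged


def _aitken(x0: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray | None:
    """Componentwise Aitken delta-squared extrapolation of an EM sequence."""
    d1 = x1 - x0
    d2 = x2 - x1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(np.abs(d1) > 1e-12, d2 / np.where(d1 == 0, 1, d1), 0.0)
    rate = np.clip(rate, -0.95, 0.95)
    acc = x2 + d2 * rate / (1.0 - rate)
    if not np.all(np.isfinite(acc)):
        return None
    return acc
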