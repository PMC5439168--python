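"""Double hierarchical GLM for the mean and residual variance of body weight.

The model couples two sub-models sharing one record per animal:

* mean:        y    = X b   + (Z_s + Z_d) u   + Q c   + e
* dispersion:  psi  = X_v b_v + (Z_s + Z_d) u_v + Q c_v + e_v

where psi is the linearized working response for the log residual variance,

    psi_i = log(s2_i) + (e_i^2 / (1 - h_i) - s2_i) / s2_i,

built from the current squared residual e_i^2, leverage h_i, and fitted
per-observation residual variance s2_i = exp(dispersion linear predictor).
The genetic effect pairs (u, u_v) are correlated with covariance
Sigma_u (x) K, where K is the pedigree (A) or combined (H) relationship over
the genetic ids; under the sire-dam parameterization Sigma_u is 1/4 of the
additive (co)variance because sire and dam each transmit half the genes and
the Mendelian-sampling half stays in the residual.  Full-sib common
environment pairs (c, c_v) are iid across families with covariance Sigma_c.
The two residuals are independent, weighted by W = diag(1/s2_i) and
W_v = diag((1-h_i)/2), each with a scaled variance expected to be 1.

Fitting alternates (i) a bivariate mixed-model solve, (ii) EM-REML updates of
all (co)variance blocks, and (iii) a refresh of psi and the weights, until
the REML log-likelihood is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp

from .mme import RandomTerm, fit_univariate_reml, spd_inv_logdet
from .pedigree import UNKNOWN, Pedigree
from .relationships import RelationshipStructure
from .transforms import PhenotypeTable

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "DhglmFit",
    "BlupResult",
    "fit_dhglm",
    "blup_full_fit",
    "predict_breeding_values",
    "compute_dispersion_response",
    "genetic_design",
    "fixed_effects_design",
    "common_env_design",
    "parent_ids",
]

_MIN_VAR = 1e-8
_MIN_EIG = 1e-8
_MAX_CORR = 0.999


@dataclass
class ModelSpec:
    """Choice of genetic parameterization, relationship source and scale."""

    genetic_param: Literal["sire_dam", "animal"] = "sire_dam"
    relationship: Literal["A", "H"] = "A"
    transform: Literal["standardized", "log"] = "standardized"
    include_common_env: bool = True


@dataclass
class VarianceComponents:
    """Converged (co)variance components of the bivariate fit.

    ``genetic`` and ``common`` are 2x2 covariance matrices over the (mean,
    dispersion) effect pairs, on the scale at which they were fitted: per
    sire-dam effect (a quarter of the additive variance each) when
    ``genetic_param == "sire_dam"``, the full additive scale for the animal
    model.  Dispersion entries are on the exponential (log-variance) scale.
    """

    genetic: np.ndarray
    common: np.ndarray
    sigma2_e: float  # baseline residual variance of the mean trait
    scaled_eps: tuple[float, float]  # (sigma2_eps, sigma2_eps_v), expected ~ 1
    genetic_param: Literal["sire_dam", "animal"] = "sire_dam"

    def __post_init__(self) -> None:
        self.genetic = np.asarray(self.genetic, dtype=float).reshape(2, 2)
        self.common = np.asarray(self.common, dtype=float).reshape(2, 2)
        for name, m in (("genetic", self.genetic), ("common", self.common)):
            if np.diag(m).min() < -1e-12:
                raise ValueError(f"negative variance in {name} block")
            if np.linalg.eigvalsh(m).min() < -1e-8:
                raise ValueError(f"{name} covariance block not positive semi-definite")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be non-negative")

    @property
    def _factor(self) -> float:
        # sire + dam variances jointly cover half the additive variance
        return 4.0 if self.genetic_param == "sire_dam" else 1.0

    @property
    def sigma2_u(self) -> float:
        return float(self.genetic[0, 0])

    @property
    def sigma2_a(self) -> float:
        """Additive genetic variance of the mean trait."""
        return self._factor * float(self.genetic[0, 0])

    @property
    def sigma2_av_exp(self) -> float:
        """Additive genetic variance of uniformity on the exponential scale."""
        return self._factor * float(self.genetic[1, 1])

    @property
    def sigma_a_av_exp(self) -> float:
        return self._factor * float(self.genetic[0, 1])

    @property
    def sigma2_c(self) -> float:
        return float(self.common[0, 0])

    @property
    def sigma2_cv_exp(self) -> float:
        return float(self.common[1, 1])

    @property
    def sigma_c_cv_exp(self) -> float:
        return float(self.common[0, 1])

    def to_animal(self) -> "VarianceComponents":
        """Components converted to the animal parameterization (sigma2_a = 4 sigma2_u)."""
        if self.genetic_param == "animal":
            return self
        return VarianceComponents(
            genetic=4.0 * self.genetic,
            common=self.common.copy(),
            sigma2_e=self.sigma2_e,
            scaled_eps=self.scaled_eps,
            genetic_param="animal",
        )


@dataclass
class DhglmFit:
    """Everything the downstream modules need from a converged fit."""

    spec: ModelSpec
    varcomps: VarianceComponents
    fixed_mean: np.ndarray
    fixed_disp: np.ndarray
    genetic_ids: list[str]
    ebv_mean: np.ndarray
    ebv_disp: np.ndarray
    family_ids: list[str]
    common_mean: np.ndarray
    common_disp: np.ndarray
    residuals: np.ndarray
    residuals_disp: np.ndarray
    hat_values: np.ndarray
    fitted_resid_var: np.ndarray
    psi: np.ndarray
    loglik_trace: list[float]
    converged: bool
    animals: list[str]
    _designs: dict = field(default_factory=dict, repr=False)

    def animal_ebv(self, pedigree: Pedigree, trait: str = "mean") -> dict[str, float]:
        """Per-animal EBV; sire-dam parameterization returns u_sire + u_dam
        (the parent-average part; Mendelian sampling is not estimable there)."""
        vec = self.ebv_mean if trait == "mean" else self.ebv_disp
        idx = {g: i for i, g in enumerate(self.genetic_ids)}
        if self.spec.genetic_param == "animal":
            return {g: float(vec[i]) for g, i in idx.items()}
        out: dict[str, float] = {}
        for a in pedigree.ids:
            s, d = pedigree.parents_of(a)
            val = 0.0
            if a in idx:
                val = float(vec[idx[a]])
            else:
                if s in idx:
                    val += float(vec[idx[s]])
                if d in idx:
                    val += float(vec[idx[d]])
            out[a] = val
        return out


# -- design builders -------------------------------------------------------


def fixed_effects_design(
    phenotypes: PhenotypeTable, min_level_count: int = 2
) -> tuple[np.ndarray, list[str]]:
    """Intercept, centred age covariate, tank and year-class dummies.

    Factor levels with fewer than ``min_level_count`` records are merged into
    the reference level (with a warning) to keep the equations full rank.
    """
    df = phenotypes.df
    n = len(df)
    cols = [np.ones(n)]
    names = ["intercept"]
    age = df["age"].to_numpy(dtype=float)
    cols.append(age - age.mean())
    names.append("age")
    for cat in ("tank", "year_class"):
        values = df[cat].astype(str).to_numpy()
        counts = {lv: int((values == lv).sum()) for lv in np.unique(values)}
        small = [lv for lv, c in counts.items() if c < min_level_count]
        if small:
            warnings.warn(
                f"{cat} levels {small} have <{min_level_count} records; "
                "merged into the reference level",
                stacklevel=2,
            )
        levels = sorted(lv for lv in counts if lv not in small)
        for lv in levels[1:]:
            cols.append((values == lv).astype(float))
            names.append(f"{cat}:{lv}")
    return np.column_stack(cols), names


def parent_ids(pedigree: Pedigree) -> list[str]:
    """Ids appearing as sire or dam anywhere in the pedigree, pedigree order."""
    used = set(pedigree.sire[pedigree.sire != UNKNOWN]) | set(
        pedigree.dam[pedigree.dam != UNKNOWN]
    )
    return [pedigree.ids[i] for i in sorted(used)]


def genetic_design(
    phenotypes: PhenotypeTable, pedigree: Pedigree, spec: ModelSpec, genetic_ids
) -> sp.csr_matrix:
    """Observation -> genetic-effect incidence.

    Animal model: one 1 per row at the animal's own effect.  Sire-dam model:
    Z_s + Z_d, a 1 at the sire and a 1 at the dam of each record's animal.
    """
    index = {g: j for j, g in enumerate(genetic_ids)}
    rows, cols, vals = [], [], []
    for i, a in enumerate(phenotypes.animals):
        if spec.genetic_param == "animal":
            if a not in index:
                raise KeyError(f"phenotyped animal {a!r} missing from genetic ids")
            rows.append(i)
            cols.append(index[a])
            vals.append(1.0)
        else:
            s, d = pedigree.parents_of(a)
            for p in (s, d):
                if p is None:
                    raise KeyError(
                        f"animal {a!r} has an unknown parent; the sire-dam model "
                        "needs both parents"
                    )
                if p not in index:
                    raise KeyError(f"parent {p!r} missing from genetic ids")
                rows.append(i)
                cols.append(index[p])
                vals.append(1.0)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(phenotypes), len(genetic_ids))
    )


def common_env_design(
    phenotypes: PhenotypeTable, pedigree: Pedigree | None = None
) -> tuple[sp.csr_matrix, list[str]]:
    """Observation -> full-sib family incidence (family = sire x dam pair)."""
    df = phenotypes.df
    if "family" in df.columns:
        fam = df["family"].astype(str).to_numpy()
    elif pedigree is not None:
        fam = np.array(
            ["x".join(map(str, pedigree.parents_of(a))) for a in phenotypes.animals]
        )
    else:
        raise ValueError("need a 'family' column or a pedigree to build Q")
    levels = sorted(np.unique(fam))
    index = {f: j for j, f in enumerate(levels)}
    Q = sp.csr_matrix(
        (
            np.ones(len(fam)),
            (np.arange(len(fam)), [index[f] for f in fam]),
        ),
        shape=(len(fam), len(levels)),
    )
    return Q, levels


# -- dispersion response ---------------------------------------------------


def compute_dispersion_response(
    residuals: np.ndarray, hat_values: np.ndarray, fitted_resid_var: np.ndarray
) -> np.ndarray:
    """psi_i = log(s2_i) + (e_i^2/(1-h_i) - s2_i)/s2_i."""
    e = np.asarray(residuals, dtype=float)
    h = np.asarray(hat_values, dtype=float)
    s2 = np.asarray(fitted_resid_var, dtype=float)
    if (h >= 1.0).any() or (h < 0.0).any():
        raise ValueError("hat values must lie in [0, 1) (degenerate leverage)")
    if (s2 <= 0).any():
        raise ValueError("fitted residual variances must be positive")
    return np.log(s2) + (e**2 / (1.0 - h) - s2) / s2


# -- bivariate machinery ---------------------------------------------------


class _BivariateMME:
    """Assembled designs for the two coupled sub-models.

    Effect order: b, b_v, u, u_v, c, c_v.  Weights (and psi) change between
    outer iterations; the incidence pattern does not.
    """

    def __init__(self, X, X_v, T, Q):
        n = X.shape[0]
        self.n = n
        self.p, self.pv = X.shape[1], X_v.shape[1]
        self.q = T.shape[1]
        self.f = Q.shape[1] if Q is not None else 0
        Xs, Xvs = sp.csr_matrix(X), sp.csr_matrix(X_v)
        Zp = [Xs, None, T, None] + ([Q, None] if self.f else [])
        Zd = [None, Xvs, None, T] + ([None, Q] if self.f else [])
        shapes = [self.p, self.pv, self.q, self.q] + ([self.f, self.f] if self.f else [])
        self.dim = sum(shapes)
        self.M1 = sp.hstack(
            [b if b is not None else sp.csr_matrix((n, s)) for b, s in zip(Zp, shapes)],
            format="csr",
        )
        self.M2 = sp.hstack(
            [b if b is not None else sp.csr_matrix((n, s)) for b, s in zip(Zd, shapes)],
            format="csr",
        )
        off = np.cumsum([0] + shapes)
        self.sl_b = slice(off[0], off[1])
        self.sl_bv = slice(off[1], off[2])
        self.sl_u = slice(off[2], off[3])
        self.sl_uv = slice(off[3], off[4])
        if self.f:
            self.sl_c = slice(off[4], off[5])
            self.sl_cv = slice(off[5], off[6])

    def set_data(self, y, psi, w1, w2):
        self.y, self.psi = y, psi
        self.w1, self.w2 = w1, w2
        W1 = sp.diags(w1)
        W2 = sp.diags(w2)
        self.S1 = (self.M1.T @ W1 @ self.M1).toarray()
        self.S2 = (self.M2.T @ W2 @ self.M2).toarray()
        self.r1 = self.M1.T @ (w1 * y)
        self.r2 = self.M2.T @ (w2 * psi)
        self.yWy = float(y @ (w1 * y))
        self.pWp = float(psi @ (w2 * psi))
        self.sum_log_w = float(np.log(w1).sum() + np.log(w2).sum())

    def assemble(self, Sig_u, Sig_c, eps, eps_v, K_inv):
        C = self.S1 / eps + self.S2 / eps_v
        Su_inv = _safe_inv2(Sig_u)
        blocks = [(self.sl_u, self.sl_uv, Su_inv, K_inv)]
        if self.f:
            Sc_inv = _safe_inv2(Sig_c)
            blocks.append((self.sl_c, self.sl_cv, Sc_inv, None))
        for s1, s2, Sinv, Kin in blocks:
            eye = np.eye(s1.stop - s1.start) if Kin is None else Kin
            C[s1, s1] += Sinv[0, 0] * eye
            C[s1, s2] += Sinv[0, 1] * eye
            C[s2, s1] += Sinv[0, 1] * eye
            C[s2, s2] += Sinv[1, 1] * eye
        rhs = self.r1 / eps + self.r2 / eps_v
        return C, rhs


def _safe_inv2(S: np.ndarray) -> np.ndarray:
    """Inverse of a 2x2 covariance with an eigenvalue floor and capped correlation."""
    S = S.copy()
    S[0, 0] = max(S[0, 0], _MIN_VAR)
    S[1, 1] = max(S[1, 1], _MIN_VAR)
    cap = _MAX_CORR * np.sqrt(S[0, 0] * S[1, 1])
    S[0, 1] = S[1, 0] = np.clip(S[0, 1], -cap, cap)
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, _MIN_EIG)
    return V @ np.diag(1.0 / w) @ V.T


def _psd_project(S: np.ndarray) -> np.ndarray:
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    if w.min() >= 0:
        return S
    return V @ np.diag(np.maximum(w, 0.0)) @ V.T


def _biv_loglik(mme, log_C, theta, rhs, Sig_u, Sig_c, eps, eps_v, logdet_K):
    n = mme.n
    log_R = n * (np.log(eps) + np.log(eps_v)) - mme.sum_log_w
    _, ld_u = np.linalg.slogdet(Sig_u + np.eye(2) * _MIN_EIG)
    log_G = mme.q * ld_u + 2.0 * logdet_K
    if mme.f:
        _, ld_c = np.linalg.slogdet(Sig_c + np.eye(2) * _MIN_EIG)
        log_G += mme.f * ld_c
    yPy = mme.yWy / eps + mme.pWp / eps_v - float(theta @ rhs)
    return -0.5 * (log_R + log_G + log_C + yPy)


def _biv_em_step(mme, Sig_u, Sig_c, eps, eps_v, K_inv, logdet_K):
    C, rhs = mme.assemble(Sig_u, Sig_c, eps, eps_v, K_inv)
    C_inv, log_C = spd_inv_logdet(C)
    theta = C_inv @ rhs
    loglik = _biv_loglik(mme, log_C, theta, rhs, Sig_u, Sig_c, eps, eps_v, logdet_K)

    def block_update(s1, s2, Kin, q):
        U = np.column_stack([theta[s1], theta[s2]])
        S = np.empty((2, 2))
        sls = (s1, s2)
        for j in range(2):
            for k in range(j, 2):
                Cb = C_inv[sls[j], sls[k]]
                if Kin is None:
                    quad = float(U[:, j] @ U[:, k]) + float(np.trace(Cb))
                else:
                    quad = float(U[:, j] @ Kin @ U[:, k]) + float(np.sum(Kin * Cb.T))
                S[j, k] = S[k, j] = quad / q
        return _psd_project(S)

    new_Su = block_update(mme.sl_u, mme.sl_uv, K_inv, mme.q)
    new_Sc = block_update(mme.sl_c, mme.sl_cv, None, mme.f) if mme.f else Sig_c

    e1 = mme.y - mme.M1 @ theta
    e2 = mme.psi - mme.M2 @ theta
    new_eps = (float(e1 @ (mme.w1 * e1)) + float(np.sum(C_inv * mme.S1.T))) / mme.n
    new_eps_v = (float(e2 @ (mme.w2 * e2)) + float(np.sum(C_inv * mme.S2.T))) / mme.n
    return new_Su, new_Sc, max(new_eps, _MIN_VAR), max(new_eps_v, _MIN_VAR), loglik, theta, C_inv, e1, e2


def _hat_from(mme, C_inv, eps):
    P = mme.M1 @ C_inv
    diag = np.asarray(mme.M1.multiply(P).sum(axis=1)).ravel()
    h = diag * mme.w1 / eps
    return np.clip(h, 0.0, 1.0 - 1e-8)


# -- fitting ---------------------------------------------------------------


def _pack(Sig_u, Sig_c, eps, eps_v) -> np.ndarray:
    """Log variances, raw covariances: the scale Aitken extrapolates on."""
    return np.array(
        [
            np.log(max(Sig_u[0, 0], _MIN_VAR)),
            np.log(max(Sig_u[1, 1], _MIN_VAR)),
            Sig_u[0, 1],
            np.log(max(Sig_c[0, 0], _MIN_VAR)),
            np.log(max(Sig_c[1, 1], _MIN_VAR)),
            Sig_c[0, 1],
            np.log(eps),
            np.log(eps_v),
        ]
    )


def _unpack(v: np.ndarray):
    Su = np.array([[np.exp(v[0]), v[2]], [v[2], np.exp(v[1])]])
    Sc = np.array([[np.exp(v[3]), v[5]], [v[5], np.exp(v[4])]])
    return _psd_project(Su), _psd_project(Sc), float(np.exp(v[6])), float(np.exp(v[7]))


def _aitken_vec(x0, x1, x2):
    d1, d2 = x1 - x0, x2 - x1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(np.abs(d1) > 1e-12, d2 / np.where(d1 == 0, 1, d1), 0.0)
    rate = np.clip(rate, -0.95, 0.95)
    acc = x2 + d2 * rate / (1.0 - rate)
    return acc if np.all(np.isfinite(acc)) else None


def fit_dhglm(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    kinship_inv: RelationshipStructure,
    pedigree: Pedigree,
    response: np.ndarray | None = None,
    tol: float = 1e-6,
    param_tol: float = 1e-4,
    max_outer: int = 200,
    inner_steps: int = 3,
    disp_start: float = 0.05,
    estimate_dispersion: bool = True,
) -> DhglmFit:
    """Fit the bivariate DHGLM by iterated REML.

    Parameters
    ----------
    phenotypes
        One record per animal; ``response`` overrides the (possibly
        transformed) trait vector, else the ``weight`` column is used as-is.
    spec
        Genetic parameterization and relationship choice; ``kinship_inv``
        must be the matching inverse relationship over the genetic ids
        (parents for sire-dam, all pedigree members for the animal model).
    kinship_inv
        RelationshipStructure of kind ``A_inverse`` or ``H_inverse``.
    pedigree
        Used to resolve parents for the sire-dam incidence.

    Non-convergence within ``max_outer`` outer iterations returns the fit
    with ``converged=False`` and the log-likelihood trace (the analysis of
    this design is known to be capable of that, e.g. an animal
    parameterization with genomic relationships).
    """
    y = (
        np.asarray(response, dtype=float)
        if response is not None
        else phenotypes.weight
    )
    X, _ = fixed_effects_design(phenotypes)
    T = genetic_design(phenotypes, pedigree, spec, kinship_inv.ids)
    if spec.include_common_env:
        Q, family_ids = common_env_design(phenotypes, pedigree)
    else:
        Q, family_ids = None, []
    K_inv = kinship_inv.values
    _, ld_Kinv = np.linalg.slogdet(K_inv)
    logdet_K = -ld_Kinv

    # initial homoscedastic REML fit of the mean model
    terms = [RandomTerm("u", T, K_inv)]
    if Q is not None:
        terms.append(RandomTerm("c", Q))
    init_vars, init_s2e, init_sol, _, _ = fit_univariate_reml(
        y, X, terms, tol=1e-4, max_iter=100
    )

    X_v = X if estimate_dispersion else X[:, :1]  # intercept-only dispersion
    mme = _BivariateMME(X, X_v, T, Q)
    s2_hat = np.full(mme.n, init_s2e)
    h = np.clip(init_sol.hat_values, 0.0, 1.0 - 1e-8)
    resid = init_sol.residuals

    Sig_u = np.array([[max(init_vars["u"], _MIN_VAR), 0.0], [0.0, disp_start]])
    Sig_c = np.array(
        [[max(init_vars.get("c", _MIN_VAR), _MIN_VAR), 0.0], [0.0, disp_start]]
    )
    eps = eps_v = 1.0

    lo, hi = np.log(init_s2e) - 8.0, np.log(init_s2e) + 8.0
    trace: list[float] = []
    history: list[np.ndarray] = []
    raw_history: list[np.ndarray] = []
    converged = False
    theta = None
    for outer in range(max_outer):
        psi = compute_dispersion_response(resid, h, s2_hat)
        w1 = 1.0 / s2_hat
        w2 = (1.0 - h) / 2.0
        mme.set_data(y, psi, w1, w2)

        # the first outer pass carries most of the EM burden; later passes
        # only track the (small) drift in the working response
        budget = 25 if outer == 0 else inner_steps
        last_inner = None
        inner_hist: list[np.ndarray] = []
        for step in range(budget):
            (Sig_u, Sig_c, eps, eps_v, ll, theta, C_inv, e1, e2) = _biv_em_step(
                mme, Sig_u, Sig_c, eps, eps_v, K_inv, logdet_K
            )
            if not estimate_dispersion:
                # dispersion sub-model reduced to its fixed effects: random
                # dispersion (co)variances pinned at the floor
                Sig_u = np.array([[Sig_u[0, 0], 0.0], [0.0, _MIN_VAR]])
                Sig_c = np.array([[Sig_c[0, 0], 0.0], [0.0, _MIN_VAR]])
            if last_inner is not None and abs(ll - last_inner) < tol:
                last_inner = ll
                break
            last_inner = ll
            inner_hist.append(_pack(Sig_u, Sig_c, eps, eps_v))
            if len(inner_hist) >= 3 and step % 4 == 3:
                acc = _aitken_vec(inner_hist[-3], inner_hist[-2], inner_hist[-1])
                if acc is not None:
                    cand = _unpack(acc)
                    Cc, rc = mme.assemble(cand[0], cand[1], cand[2], cand[3], K_inv)
                    try:
                        from scipy.linalg import cho_factor, cho_solve

                        fac = cho_factor(Cc, lower=True)
                        th = cho_solve(fac, rc)
                        log_Cc = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
                        cand_ll = _biv_loglik(
                            mme, log_Cc, th, rc, cand[0], cand[1], cand[2], cand[3],
                            logdet_K,
                        )
                    except np.linalg.LinAlgError:
                        cand_ll = -np.inf
                    if cand_ll > last_inner:
                        Sig_u, Sig_c, eps, eps_v = cand
                        inner_hist.clear()
        trace.append(last_inner)

        # Aitken extrapolation of the outer (refresh-to-refresh) component
        # sequence.  The extrapolated point anticipates where the slowly
        # moving fixed point is heading, so it is accepted on boundedness
        # alone; the subsequent EM steps correct any overshoot.
        raw = np.array(
            [Sig_u[0, 0], Sig_u[1, 1], Sig_u[0, 1],
             Sig_c[0, 0], Sig_c[1, 1], Sig_c[0, 1], eps, eps_v]
        )
        raw_history.append(raw)
        history.append(_pack(Sig_u, Sig_c, eps, eps_v))
        if len(history) >= 3 and outer % 3 == 2:
            acc = _aitken_vec(history[-3], history[-2], history[-1])
            if acc is not None and np.max(np.abs(acc - history[-1])) < 2.0:
                Sig_u, Sig_c, eps, eps_v = _unpack(np.clip(acc, -18.0, 5.0))
                history.clear()

        # refresh working response ingredients
        disp_lin = mme.M2 @ theta  # dispersion linear predictor (on psi rows)
        s2_hat = np.exp(np.clip(disp_lin, lo, hi))
        h = _hat_from(mme, C_inv, eps)
        resid = e1
        # converged when the likelihood is stable across a refresh of the
        # working response, or the components themselves have stopped moving
        # (the refresh perturbs the likelihood at a level its tolerance alone
        # cannot always reach)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        if (
            len(raw_history) > 1
            and np.max(np.abs(raw_history[-1] - raw_history[-2])) < param_tol
        ):
            converged = True
            break

    psi = mme.psi
    varcomps = VarianceComponents(
        genetic=Sig_u,
        common=Sig_c if mme.f else np.zeros((2, 2)),
        sigma2_e=float(np.mean(s2_hat) * eps),
        scaled_eps=(float(eps), float(eps_v)),
        genetic_param=spec.genetic_param,
    )
    fit = DhglmFit(
        spec=spec,
        varcomps=varcomps,
        fixed_mean=theta[mme.sl_b],
        fixed_disp=theta[mme.sl_bv],
        genetic_ids=list(kinship_inv.ids),
        ebv_mean=theta[mme.sl_u],
        ebv_disp=theta[mme.sl_uv],
        family_ids=family_ids,
        common_mean=theta[mme.sl_c] if mme.f else np.zeros(0),
        common_disp=theta[mme.sl_cv] if mme.f else np.zeros(0),
        residuals=e1,
        residuals_disp=e2,
        hat_values=h,
        fitted_resid_var=s2_hat,
        psi=psi,
        loglik_trace=trace,
        converged=converged,
        animals=phenotypes.animals,
        _designs={"X": X, "T": T, "Q": Q, "y": y, "w1": mme.w1, "w2": mme.w2},
    )
    return fit


def blup_full_fit(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    varcomps: VarianceComponents,
    kinship_inv: RelationshipStructure,
    pedigree: Pedigree,
    response: np.ndarray | None = None,
    n_irwls: int = 4,
) -> DhglmFit:
    """Full-data solve of the bivariate model at fixed variance components.

    Iterates the working response, weights and leverages a few times (no
    REML updates), so the returned fit carries the *model's own* residuals,
    fitted residual variances and psi — the ingredients cross-validation
    needs for adjusted phenotypes and fold weights.  This matters because
    residual estimates differ between parameterizations and relationship
    matrices: an animal model with genomic relationships separates genetic
    from environmental deviations of genotyped animals far more than a
    sire-dam model does, and that separation is what the dispersion part of
    the evaluation feeds on.
    """
    if varcomps.genetic_param != spec.genetic_param:
        raise ValueError(
            "varcomps parameterization does not match the model; "
            "use VarianceComponents.to_animal() for the animal model"
        )
    y = (
        np.asarray(response, dtype=float)
        if response is not None
        else phenotypes.weight
    )
    X, _ = fixed_effects_design(phenotypes)
    T = genetic_design(phenotypes, pedigree, spec, kinship_inv.ids)
    if spec.include_common_env:
        Q, family_ids = common_env_design(phenotypes, pedigree)
    else:
        Q, family_ids = None, []
    K_inv = kinship_inv.values
    mme = _BivariateMME(X, X, T, Q)
    Sig_u = varcomps.genetic
    Sig_c = varcomps.common if spec.include_common_env else np.zeros((2, 2))
    eps, eps_v = varcomps.scaled_eps

    s2 = np.full(mme.n, max(varcomps.sigma2_e, _MIN_VAR))
    h = np.zeros(mme.n)
    resid = y - y.mean()
    lo = np.log(s2[0]) - 8.0
    hi = np.log(s2[0]) + 8.0
    theta = psi = None
    for _ in range(max(n_irwls, 1)):
        psi = compute_dispersion_response(resid, h, s2)
        mme.set_data(y, psi, 1.0 / s2, (1.0 - h) / 2.0)
        C, rhs = mme.assemble(Sig_u, Sig_c, eps, eps_v, K_inv)
        C_inv, _ = spd_inv_logdet(C)
        theta = C_inv @ rhs
        resid = y - mme.M1 @ theta
        s2 = np.exp(np.clip(mme.M2 @ theta, lo, hi))
        h = _hat_from(mme, C_inv, eps)
    return DhglmFit(
        spec=spec,
        varcomps=varcomps,
        fixed_mean=theta[mme.sl_b],
        fixed_disp=theta[mme.sl_bv],
        genetic_ids=list(kinship_inv.ids),
        ebv_mean=theta[mme.sl_u],
        ebv_disp=theta[mme.sl_uv],
        family_ids=family_ids,
        common_mean=theta[mme.sl_c] if mme.f else np.zeros(0),
        common_disp=theta[mme.sl_cv] if mme.f else np.zeros(0),
        residuals=resid,
        residuals_disp=psi - mme.M2 @ theta,
        hat_values=h,
        fitted_resid_var=s2,
        psi=psi,
        loglik_trace=[],
        converged=True,
        animals=phenotypes.animals,
        _designs={"X": X, "T": T, "Q": Q, "y": y,
                  "w1": 1.0 / s2, "w2": (1.0 - h) / 2.0},
    )


# -- BLUP-only prediction --------------------------------------------------


@dataclass
class BlupResult:
    genetic_ids: list[str]
    ebv_mean: np.ndarray
    ebv_disp: np.ndarray
    fixed_mean: np.ndarray
    fixed_disp: np.ndarray
    spec: ModelSpec

    def animal_ebv(self, pedigree: Pedigree, trait: str = "mean") -> dict[str, float]:
        proxy = DhglmFit.__new__(DhglmFit)
        proxy.spec = self.spec
        proxy.genetic_ids = self.genetic_ids
        proxy.ebv_mean = self.ebv_mean
        proxy.ebv_disp = self.ebv_disp
        return DhglmFit.animal_ebv(proxy, pedigree, trait)


def predict_breeding_values(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    varcomps: VarianceComponents,
    kinship_inv: RelationshipStructure,
    pedigree: Pedigree,
    response: np.ndarray | None = None,
    mask=None,
    psi: np.ndarray | None = None,
    resid_var: np.ndarray | None = None,
    hat: np.ndarray | None = None,
    n_irwls: int = 4,
) -> BlupResult:
    """BLUP solve of the bivariate model at fixed variance components.

    ``mask`` is a boolean vector (True = record excluded from both
    sub-models) or a collection of animal ids to mask.  If the working
    response ``psi`` and weights (``resid_var``, ``hat``) from a full-data
    fit are supplied they are used as-is (single solve); otherwise they are
    built by a few IRWLS passes at the fixed components.

    The components must match ``spec.genetic_param``: pass
    ``varcomps.to_animal()`` when predicting with the animal model from a
    sire-dam fit.
    """
    if varcomps.genetic_param != spec.genetic_param:
        raise ValueError(
            "varcomps parameterization does not match the prediction model; "
            "use VarianceComponents.to_animal() for animal-model prediction"
        )
    y_full = (
        np.asarray(response, dtype=float)
        if response is not None
        else phenotypes.weight
    )
    n = len(phenotypes)
    if mask is None:
        keep = np.ones(n, dtype=bool)
    elif isinstance(mask, np.ndarray) and mask.dtype == bool:
        keep = ~mask
    else:
        masked = set(map(str, mask))
        keep = np.array([a not in masked for a in phenotypes.animals])

    X_full, _ = fixed_effects_design(phenotypes)
    T_full = genetic_design(phenotypes, pedigree, spec, kinship_inv.ids)
    Q_full, _ = (
        common_env_design(phenotypes, pedigree)
        if spec.include_common_env
        else (None, [])
    )

    X = X_full[keep]
    # fixed-effect columns with no surviving records would make C singular
    dead = (X != 0).sum(axis=0) == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} fixed-effect level(s) lost all records under the "
            "mask; dropped",
            stacklevel=2,
        )
        X = X[:, ~dead]
    T = T_full[keep]
    Q = Q_full[keep] if Q_full is not None else None
    y = y_full[keep]

    K_inv = kinship_inv.values
    mme = _BivariateMME(X, X, T, Q)
    Sig_u = varcomps.genetic
    Sig_c = varcomps.common if spec.include_common_env else np.zeros((2, 2))
    eps, eps_v = varcomps.scaled_eps

    have_carryover = psi is not None and resid_var is not None and hat is not None
    if have_carryover:
        psi_k = np.asarray(psi, dtype=float)[keep]
        s2_k = np.asarray(resid_var, dtype=float)[keep]
        h_k = np.asarray(hat, dtype=float)[keep]
        passes = 1
    else:
        s2_k = np.full(int(keep.sum()), max(varcomps.sigma2_e, _MIN_VAR))
        h_k = np.zeros(int(keep.sum()))
        resid = y - y.mean()
        psi_k = None
        passes = max(n_irwls, 1)

    lo = np.log(max(varcomps.sigma2_e, _MIN_VAR)) - 8.0
    hi = np.log(max(varcomps.sigma2_e, _MIN_VAR)) + 8.0
    theta = None
    for it in range(passes):
        if psi_k is None:
            psi_k = compute_dispersion_response(resid, h_k, s2_k)
        w1 = 1.0 / s2_k
        w2 = (1.0 - h_k) / 2.0
        mme.set_data(y, psi_k, w1, w2)
        C, rhs = mme.assemble(Sig_u, Sig_c, eps, eps_v, K_inv)
        need_hat = not have_carryover and it < passes - 1
        try:
            if need_hat:
                C_inv = np.linalg.inv(C)
                theta = C_inv @ rhs
            else:
                theta = np.linalg.solve(C, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular coefficient matrix in BLUP prediction"
            ) from exc
        if need_hat:
            resid = y - mme.M1 @ theta
            s2_k = np.exp(np.clip(mme.M2 @ theta, lo, hi))
            h_k = _hat_from(mme, C_inv, eps)
            psi_k = None  # rebuild from refreshed residuals next pass

    return BlupResult(
        genetic_ids=list(kinship_inv.ids),
        ebv_mean=theta[mme.sl_u],
        ebv_disp=theta[mme.sl_uv],
        fixed_mean=theta[mme.sl_b],
        fixed_disp=theta[mme.sl_bv],
        spec=spec,
    )
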