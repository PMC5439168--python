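"""Derived genetic parameters for body weight and its uniformity.

Pure functions from (co)variance components to the ratios reported in a
sire-dam analysis of micro-environmental sensitivity:

* phenotypic variance    sigma2_P = 2 sigma2_u + sigma2_c + sigma2_e
* heritability           h2  = sigma2_a / sigma2_P
* common environment     c2  = sigma2_c / sigma2_P
* uniformity heritability on the additive scale
      h2_v = sigma2_av / (2 sigma2_P^2 + 3 (sigma2_av + sigma2_cv))
  (and c2_v with sigma2_cv in the numerator)
* genetic coefficient of variation of uniformity
      GCV = sqrt(sigma2_av_exp)

Dispersion components are estimated on the exponential (log-variance) scale;
the additive-scale versions use the first-order linearization
sigma2_av = sigma_E^4 * sigma2_av_exp with sigma2_E the mean fitted residual
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSet",
    "phenotypic_variance",
    "heritability_mean",
    "heritability_uniformity",
    "common_env_uniformity",
    "gcv_uniformity",
    "exp_to_additive",
    "genetic_correlation",
    "derive_parameters",
]


@dataclass
class ParameterSet:
    """One column of a parameter table (one transform x relationship cell)."""

    sigma2_P: float
    h2: float
    c2: float
    sigma2_av: float
    sigma2_cv: float
    h2_v: float
    c2_v: float
    gcv: float
    r_g: float

    def __post_init__(self) -> None:
        for name in ("h2", "c2", "h2_v", "c2_v"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.gcv < 0:
            raise ValueError("gcv must be non-negative")
        if not -1.0 <= self.r_g <= 1.0:
            raise ValueError("genetic correlation outside [-1, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def phenotypic_variance(sigma2_u: float, sigma2_c: float, sigma2_e: float) -> float:
    """sigma2_P = 2 sigma2_u + sigma2_c + sigma2_e (sire-dam components)."""
    _check_nonneg(sigma2_u=sigma2_u, sigma2_c=sigma2_c, sigma2_e=sigma2_e)
    return 2.0 * sigma2_u + sigma2_c + sigma2_e


def _clip_ratio(value: float, name: str) -> float:
    if value > 1.0:
        warnings.warn(f"{name}={value:.4f} clipped to 1", stacklevel=3)
        return 1.0
    if value < 0.0:
        warnings.warn(f"{name}={value:.4f} clipped to 0", stacklevel=3)
        return 0.0
    return value


def heritability_mean(sigma2_a: float, sigma2_P: float) -> float:
    """h2 = sigma2_a / sigma2_P, clipped to [0, 1] with a warning."""
    if sigma2_P <= 0:
        raise ValueError("sigma2_P must be positive")
    _check_nonneg(sigma2_a=sigma2_a)
    return _clip_ratio(sigma2_a / sigma2_P, "h2")


def _uniformity_denominator(sigma2_av: float, sigma2_cv: float, sigma2_P: float) -> float:
    return 2.0 * sigma2_P**2 + 3.0 * (sigma2_av + sigma2_cv)


def heritability_uniformity(
    sigma2_av: float, sigma2_cv: float, sigma2_P: float
) -> float:
    """h2_v on the additive scale.

    The denominator 2 sigma2_P^2 + 3 (sigma2_av + sigma2_cv) is the variance
    of squared phenotypic deviations under normality, which is what a single
    record conveys about an animal's environmental variance.
    """
    if sigma2_P <= 0:
        raise ValueError("sigma2_P must be positive")
    _check_nonneg(sigma2_av=sigma2_av, sigma2_cv=sigma2_cv)
    return sigma2_av / _uniformity_denominator(sigma2_av, sigma2_cv, sigma2_P)


def common_env_uniformity(
    sigma2_cv: float, sigma2_av: float, sigma2_P: float
) -> float:
    """c2_v: same denominator as h2_v with sigma2_cv in the numerator."""
    if sigma2_P <= 0:
        raise ValueError("sigma2_P must be positive")
    _check_nonneg(sigma2_av=sigma2_av, sigma2_cv=sigma2_cv)
    return sigma2_cv / _uniformity_denominator(sigma2_av, sigma2_cv, sigma2_P)


def gcv_uniformity(sigma2_av_exp: float) -> float:
    """Genetic coefficient of variation of uniformity: sqrt of the
    exponential-scale additive variance (scale-free evolvability measure)."""
    _check_nonneg(sigma2_av_exp=sigma2_av_exp)
    return float(np.sqrt(sigma2_av_exp))


def exp_to_additive(
    sigma2_e: float, sigma2_av_exp: float, sigma2_cv_exp: float
) -> tuple[float, float]:
    """First-order conversion of exponential-scale dispersion variances.

    var(sigma2_E * exp(x)) ~ sigma_E^4 * var(x) for small var(x), so
    sigma2_av = sigma2_e^2 * sigma2_av_exp (and likewise for the common
    environment).  ``sigma2_e`` should be the mean fitted residual variance.
    """
    _check_nonneg(
        sigma2_e=sigma2_e, sigma2_av_exp=sigma2_av_exp, sigma2_cv_exp=sigma2_cv_exp
    )
    factor = sigma2_e**2
    return factor * sigma2_av_exp, factor * sigma2_cv_exp


def genetic_correlation(cov: float, var1: float, var2: float) -> float:
    """cov / sqrt(var1 var2), clipped to [-1, 1] with a warning.

    Zero variance makes the correlation undefined; returns NaN with a warning
    rather than failing silently.
    """
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be non-negative")
    if var1 == 0 or var2 == 0:
        warnings.warn("zero variance: genetic correlation undefined", stacklevel=2)
        return float("nan")
    r = cov / np.sqrt(var1 * var2)
    if abs(r) > 1.0:
        warnings.warn(f"genetic correlation {r:.4f} clipped to +/-1", stacklevel=2)
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def derive_parameters(varcomps) -> ParameterSet:
    """Full Table-2-style derivation from a converged sire-dam fit.

    ``varcomps`` is a :class:`uniblup.dhglm.VarianceComponents`; dispersion
    variances are converted from the exponential to the additive scale with
    the baseline residual variance before forming the ratios.
    """
    s2_u = varcomps.sigma2_a / 4.0 if varcomps.genetic_param == "sire_dam" else None
    if s2_u is None:
        # animal parameterization: sigma2_P = sigma2_a/2 * ... does not apply;
        # use the standard decomposition instead
        sigma2_P = varcomps.sigma2_a + varcomps.sigma2_c + varcomps.sigma2_e
    else:
        sigma2_P = phenotypic_variance(s2_u, varcomps.sigma2_c, varcomps.sigma2_e)
    sigma2_av, sigma2_cv = exp_to_additive(
        varcomps.sigma2_e, varcomps.sigma2_av_exp, varcomps.sigma2_cv_exp
    )
    return ParameterSet(
        sigma2_P=sigma2_P,
        h2=heritability_mean(varcomps.sigma2_a, sigma2_P),
        c2=_clip_ratio(varcomps.sigma2_c / sigma2_P, "c2"),
        sigma2_av=sigma2_av,
        sigma2_cv=sigma2_cv,
        h2_v=heritability_uniformity(sigma2_av, sigma2_cv, sigma2_P),
        c2_v=common_env_uniformity(sigma2_cv, sigma2_av, sigma2_P),
        gcv=gcv_uniformity(varcomps.sigma2_av_exp),
        r_g=genetic_correlation(
            varcomps.sigma_a_av_exp, varcomps.sigma2_a, varcomps.sigma2_av_exp
        ),
    )
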