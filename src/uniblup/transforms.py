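"""Phenotype scale handling.

Body-weight variances typically grow with the mean ("scale effect"), so the
analysis runs either on standardized weight (mean 0, variance 1 — mainly an
aid to convergence) or on log weight, which removes a multiplicative scale
effect.  The Box-Cox family (y^lambda - 1)/lambda nests both: the
profile-likelihood estimate of lambda under the fixed-effects-only mean model
indicates which scale the data prefer (lambda near 0 -> log).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "TransformSpec",
    "standardize",
    "boxcox_lambda",
    "boxcox_loglik",
    "apply_transform",
    "invert_transform",
]


@dataclass
class PhenotypeTable:
    """Phenotype records: one row per animal.

    Wraps a DataFrame with columns ``animal`` (unique ids), ``weight`` (g,
    strictly positive), ``age`` (days), ``tank`` and ``year_class``
    (categorical), and optionally ``family`` (full-sib family label, used for
    the common-environment design and fold stratification).
    """

    df: pd.DataFrame

    REQUIRED = ("animal", "weight", "age", "tank", "year_class")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.df.columns:
                raise ValueError(f"phenotype table missing column {c!r}")
        if self.df["animal"].duplicated().any():
            dup = self.df.loc[self.df["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"duplicate animal id {dup!r} in phenotype table")
        if (self.df["weight"] <= 0).any():
            raise ValueError("weights must be strictly positive")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> list[str]:
        return [str(a) for a in self.df["animal"]]

    @property
    def weight(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, dtype={"animal": str}))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class TransformSpec:
    """A fitted, invertible elementwise transform."""

    kind: Literal["standardize", "log", "boxcox"]
    lam: float | None = None  # Box-Cox only
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.kind == "boxcox" and self.lam is None:
            raise ValueError("boxcox spec needs lambda")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "lambda": self.lam,
            "center": self.center,
            "scale": self.scale,
        }


def standardize(values) -> tuple[np.ndarray, TransformSpec]:
    """Shift/scale to sample mean 0 and sample (n-1 divisor) variance 1."""
    y = np.asarray(values, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot standardize a constant vector")
    center = y.mean()
    scale = y.std(ddof=1)
    spec = TransformSpec(kind="standardize", center=center, scale=scale)
    return (y - center) / scale, spec


def _fixed_effects_design(phenotypes: PhenotypeTable) -> np.ndarray:
    """Intercept + age covariate + tank and year-class dummies (drop-first)."""
    df = phenotypes.df
    cols = [np.ones(len(df)), df["age"].to_numpy(dtype=float)]
    for cat in ("tank", "year_class"):
        levels = sorted(map(str, df[cat].astype(str).unique()))
        for lv in levels[1:]:
            cols.append((df[cat].astype(str) == lv).to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design (age, tank, year class) not full rank")
    return X


def boxcox_loglik(lam: float, y: np.ndarray, X: np.ndarray) -> float:
    """Profile log-likelihood of the Box-Cox parameter under y(lam) = Xb + e.

    l(lam) = -n/2 log(RSS(lam)/n) + (lam - 1) sum(log y), the Jacobian term
    making likelihoods comparable across lambda.
    """
    n = len(y)
    z = np.log(y) if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    rss = float(np.sum((z - X @ beta) ** 2))
    return -0.5 * n * np.log(rss / n) + (lam - 1.0) * float(np.sum(np.log(y)))


def boxcox_lambda(
    phenotypes: PhenotypeTable,
    grid: tuple[float, float] = (-2.0, 2.0),
    tol: float = 1e-5,
) -> float:
    """Maximum-likelihood Box-Cox lambda under the fixed-effects mean model.

    A coarse grid scan over ``grid`` locates the mode; golden-section search
    then refines it to ``tol``.  lambda = 0 is the natural-log branch.
    """
    y = phenotypes.weight
    if (y <= 0).any():
        raise ValueError("Box-Cox requires strictly positive weights")
    X = _fixed_effects_design(phenotypes)

    lams = np.arange(grid[0], grid[1] + 1e-9, 0.1)
    lls = np.array([boxcox_loglik(l, y, X) for l in lams])
    k = int(np.argmax(lls))
    lo = lams[max(k - 1, 0)]
    hi = lams[min(k + 1, len(lams) - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = boxcox_loglik(c, y, X), boxcox_loglik(d, y, X)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = boxcox_loglik(c, y, X)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = boxcox_loglik(d, y, X)
    return float(0.5 * (a + b))


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Deterministic elementwise mapping for a fitted spec."""
    y = np.asarray(values, dtype=float)
    if spec.kind == "standardize":
        return (y - spec.center) / spec.scale
    if (y <= 0).any():
        raise ValueError(f"{spec.kind} transform requires positive values")
    if spec.kind == "log":
        z = np.log(y)
    else:  # boxcox
        lam = spec.lam
        z = np.log(y) if abs(lam) < 1e-12 else (np.power(y, lam) - 1.0) / lam
    return (z - spec.center) / spec.scale


def invert_transform(values, spec: TransformSpec) -> np.ndarray:
    """Inverse mapping, for reporting gains back on the gram scale."""
    z = np.asarray(values, dtype=float) * spec.scale + spec.center
    if spec.kind == "standardize":
        return z
    if spec.kind == "log":
        return np.exp(z)
    lam = spec.lam
    if abs(lam) < 1e-12:
        return np.exp(z)
    return np.power(lam * z + 1.0, 1.0 / lam)
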