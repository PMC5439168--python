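"""Masking cross-validation of (G)EBV and residual-comparison diagnostics.

Predictive ability is measured against *adjusted phenotypes*: the phenotype
with the fixed effects removed, i.e. the sum of the estimated genetic,
common-environment and residual parts from the full-data fit (y* for the
mean trait, psi* for uniformity).  Ten family-stratified folds mask about
10% of each family's records; a BLUP-only refit on the unmasked records
predicts breeding values for the masked animals, and the correlations
(Pearson for weight; Pearson, Kendall tau-b and Spearman for uniformity,
whose adjusted phenotype is far from normal) plus the variance-scaled MSEP
summarise each fold over the masked animals that are genotyped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dhglm import DhglmFit, ModelSpec, VarianceComponents, predict_breeding_values
from .pedigree import Pedigree
from .relationships import RelationshipStructure
from .transforms import PhenotypeTable

__all__ = [
    "FoldPlan",
    "CrossvalReport",
    "adjusted_phenotypes",
    "make_folds",
    "run_crossval",
    "msep_scaled",
    "rank_correlations",
    "difference_ci",
    "compare_residual_estimates",
    "residual_scatter",
]


@dataclass
class FoldPlan:
    """Disjoint, exhaustive masks over the phenotyped animals."""

    k: int
    masks: list[set[str]]
    seed: int

    def __post_init__(self) -> None:
        all_ids: set[str] = set()
        for m in self.masks:
            if all_ids & m:
                raise ValueError("fold masks overlap")
            all_ids |= m

    @property
    def animals(self) -> set[str]:
        return set().union(*self.masks) if self.masks else set()


@dataclass
class CrossvalReport:
    """Per-fold metrics plus fold-mean and SE (= SD/sqrt(k)) summaries."""

    per_fold: pd.DataFrame  # columns: fold, trait, metric, value
    k: int
    seed: int
    excluded_folds: list[int] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        df = self.per_fold[~self.per_fold["fold"].isin(self.excluded_folds)]
        g = df.groupby(["trait", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["se"] = out["std"] / np.sqrt(out["count"])
        return out[["trait", "metric", "mean", "se", "count"]]

    def metric(self, trait: str, metric: str) -> float:
        s = self.summary()
        row = s[(s["trait"] == trait) & (s["metric"] == metric)]
        return float(row["mean"].iloc[0])

    def fold_values(self, trait: str, metric: str) -> np.ndarray:
        df = self.per_fold[~self.per_fold["fold"].isin(self.excluded_folds)]
        sel = df[(df["trait"] == trait) & (df["metric"] == metric)]
        return sel.sort_values("fold")["value"].to_numpy()


def adjusted_phenotypes(fit: DhglmFit) -> tuple[pd.Series, pd.Series]:
    """y* = a + c + e and psi* = a_v + c_v + e_v from the full-data solutions.

    Assembled explicitly from the solution vectors; equivalently the observed
    response minus the fitted fixed effects, an identity the tests exploit.
    """
    d = fit._designs
    if not d:
        raise ValueError("fit does not carry its designs; refit with fit_dhglm")
    T, Q, X = d["T"], d["Q"], d["X"]
    genetic_part = T @ fit.ebv_mean
    genetic_disp = T @ fit.ebv_disp
    common_part = Q @ fit.common_mean if Q is not None else 0.0
    common_disp = Q @ fit.common_disp if Q is not None else 0.0
    y_star = genetic_part + common_part + fit.residuals
    psi_star = genetic_disp + common_disp + fit.residuals_disp
    return (
        pd.Series(y_star, index=fit.animals),
        pd.Series(psi_star, index=fit.animals),
    )


def make_folds(
    phenotypes: PhenotypeTable, k: int = 10, seed: int = 0
) -> FoldPlan:
    """Family-stratified partition into k disjoint masks.

    Members of each full-sib family are shuffled and dealt round-robin to the
    folds, so every fold masks ~1/k of each family and an animal masked once
    is never masked again.  Families smaller than k are spread as evenly as
    possible (with a warning).
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    df = phenotypes.df
    if "family" not in df.columns:
        raise ValueError("phenotype table needs a 'family' column for stratified folds")
    rng = np.random.default_rng(seed)
    masks: list[set[str]] = [set() for _ in range(k)]
    offset = 0
    small = 0
    for _, group in df.groupby("family", sort=True):
        members = [str(a) for a in group["animal"]]
        if len(members) < k:
            small += 1
        order = rng.permutation(len(members))
        for pos, j in enumerate(order):
            masks[(offset + pos) % k].add(members[j])
        offset += len(members)  # rotate the deal so folds stay balanced
    if small:
        warnings.warn(
            f"{small} families smaller than k={k}; members spread as evenly as possible",
            stacklevel=2,
        )
    return FoldPlan(k=k, masks=masks, seed=seed)


def msep_scaled(predictions, targets) -> float:
    """Mean squared prediction error divided by the sample (n-1) variance of
    the targets."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("predictions and targets must be equal-length vectors, n >= 2")
    var = float(np.var(t, ddof=1))
    if var == 0:
        raise ValueError("zero target variance: scaled MSEP undefined")
    return float(np.mean((p - t) ** 2)) / var


def rank_correlations(x, y) -> tuple[float, float]:
    """(Kendall tau-b, Spearman rho); NaN with a warning for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for rank correlations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: rank correlations undefined", stacklevel=2)
        return float("nan"), float("nan")
    tau = stats.kendalltau(x, y).statistic  # tau-b (tie-corrected)
    rho = stats.spearmanr(x, y).statistic
    return float(tau), float(rho)


def difference_ci(
    metric_folds_model1, metric_folds_model2
) -> tuple[float, float, float, bool]:
    """Mean difference across folds with its 95% CI.

    d = mean1 - mean2, SE_d = sqrt((SD1^2 + SD2^2)/k), CI = d +/- 1.96 SE_d;
    the difference is called significant when 0 lies outside the CI.
    """
    m1 = np.asarray(metric_folds_model1, dtype=float)
    m2 = np.asarray(metric_folds_model2, dtype=float)
    if len(m1) != len(m2):
        raise ValueError("fold counts differ between models")
    k = len(m1)
    if k < 2:
        raise ValueError("need at least 2 folds for a difference CI")
    d = float(m1.mean() - m2.mean())
    se_d = float(np.sqrt((m1.std(ddof=1) ** 2 + m2.std(ddof=1) ** 2) / k))
    lower, upper = d - 1.96 * se_d, d + 1.96 * se_d
    significant = not (lower <= 0.0 <= upper)
    return d, lower, upper, significant


def run_crossval(
    phenotypes: PhenotypeTable,
    spec: ModelSpec,
    varcomps: VarianceComponents,
    plan: FoldPlan,
    genotyped_ids,
    kinship_inv: RelationshipStructure,
    pedigree: Pedigree,
    full_fit: DhglmFit,
    response: np.ndarray | None = None,
    min_fold_size: int = 3,
) -> CrossvalReport:
    """Masking cross-validation at fixed variance components.

    ``varcomps`` come from the full sire-dam DHGLM fit (converted with
    ``to_animal()`` when ``spec`` asks for animal-model prediction);
    ``full_fit`` supplies the adjusted phenotypes and the working response /
    weights carried into each fold's single BLUP solve.  Metrics are computed
    over the masked animals that are genotyped.  Folds with fewer than
    ``min_fold_size`` such animals are flagged and excluded from summaries.
    """
    y_star, psi_star = adjusted_phenotypes(full_fit)
    genotyped = set(map(str, genotyped_ids))
    rows = []
    excluded = []
    for fold, mask in enumerate(plan.masks):
        blup = predict_breeding_values(
            phenotypes,
            spec,
            varcomps,
            kinship_inv,
            pedigree,
            response=response,
            mask=mask,
            psi=full_fit.psi,
            resid_var=full_fit.fitted_resid_var,
            hat=full_fit.hat_values,
        )
        ebv_mean = blup.animal_ebv(pedigree, "mean")
        ebv_disp = blup.animal_ebv(pedigree, "disp")
        eval_ids = sorted(a for a in mask if a in genotyped and a in y_star.index)
        if len(eval_ids) < min_fold_size:
            excluded.append(fold)
            continue
        ys = y_star.loc[eval_ids].to_numpy()
        ps = psi_star.loc[eval_ids].to_numpy()
        am = np.array([ebv_mean[a] for a in eval_ids])
        ad = np.array([ebv_disp[a] for a in eval_ids])
        tau, rho = rank_correlations(ps, ad)
        rows += [
            (fold, "weight", "pearson", float(stats.pearsonr(ys, am).statistic)),
            (fold, "weight", "msep_scaled", msep_scaled(am, ys)),
            (fold, "uniformity", "pearson", float(stats.pearsonr(ps, ad).statistic)),
            (fold, "uniformity", "kendall", tau),
            (fold, "uniformity", "spearman", rho),
            (fold, "uniformity", "msep_scaled", msep_scaled(ad, ps)),
        ]
    report = CrossvalReport(
        per_fold=pd.DataFrame(rows, columns=["fold", "trait", "metric", "value"]),
        k=plan.k,
        seed=plan.seed,
        excluded_folds=excluded,
    )
    return report


def compare_residual_estimates(
    fit_A: DhglmFit, fit_H: DhglmFit, genotyped_ids
) -> pd.DataFrame:
    """Regression of residuals-under-A on residuals-under-H, per genotype group.

    Returns a two-row frame (groups ``genotyped`` / ``non_genotyped``) with
    the least-squares slope, Pearson correlation and group size, plus the
    paired residuals for a scatter export.
    """
    if fit_A.animals != fit_H.animals:
        raise ValueError("fits cover different phenotype records")
    genotyped = set(map(str, genotyped_ids))
    is_gen = np.array([a in genotyped for a in fit_A.animals])
    rows = []
    for label, sel in (("genotyped", is_gen), ("non_genotyped", ~is_gen)):
        ra = fit_A.residuals[sel]
        rh = fit_H.residuals[sel]
        if len(ra) < 2 or np.ptp(rh) == 0:
            rows.append((label, float("nan"), float("nan"), int(sel.sum())))
            continue
        slope = float(np.polyfit(rh, ra, 1)[0])
        r = float(stats.pearsonr(rh, ra).statistic)
        rows.append((label, slope, r, int(sel.sum())))
    return pd.DataFrame(rows, columns=["group", "slope", "pearson", "n"])


def residual_scatter(
    fit_A: DhglmFit, fit_H: DhglmFit, genotyped_ids
) -> pd.DataFrame:
    """Per-animal residual pairs for a scatter of A-fit against H-fit
    residuals, labelled by genotype group (CSV-ready plot data)."""
    if fit_A.animals != fit_H.animals:
        raise ValueError("fits cover different phenotype records")
    genotyped = set(map(str, genotyped_ids))
    return pd.DataFrame(
        {
            "animal": fit_A.animals,
            "residual_A": fit_A.residuals,
            "residual_H": fit_H.residuals,
            "group": [
                "genotyped" if a in genotyped else "non_genotyped"
                for a in fit_A.animals
            ],
        }
    )
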