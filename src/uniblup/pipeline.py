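"""End-to-end orchestration: QC -> matrices -> DHGLM -> parameters -> CV -> selection.

`run_pipeline` is the programmatic entry point (the package is used from
Python; the example scripts show the same flow step by step).  Given one
:class:`RunConfig` it executes the requested model variants, writes a
parameter table, a cross-validation table, EBV files and a JSON run log, and
is deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import selection as sel
from .dhglm import DhglmFit, ModelSpec, blup_full_fit, fit_dhglm, parent_ids
from .genotypes import qc_snps, scale_genotypes
from .parameters import derive_parameters
from .pedigree import Pedigree
from .relationships import (
    RelationshipStructure,
    build_numerator_relationship,
    invert,
    single_step_pair,
)
from .simulate import SimConfig, SimDataset, read_fixture, simulate_dataset
from .transforms import standardize
from .validation import make_folds, run_crossval

__all__ = [
    "RunConfig",
    "RelationshipSet",
    "build_relationship_set",
    "kinship_inverse_for",
    "run_pipeline",
]


@dataclass
class RelationshipSet:
    """All relationship structures a run needs, built once."""

    A: RelationshipStructure
    A_inv: RelationshipStructure
    H: RelationshipStructure | None = None
    H_inv: RelationshipStructure | None = None
    genotyped_ids: list[str] = field(default_factory=list)


def build_relationship_set(
    pedigree: Pedigree, scaled=None, blend_weight: float = 0.99
) -> RelationshipSet:
    A = build_numerator_relationship(pedigree)
    A_inv = invert(A)
    if scaled is None:
        return RelationshipSet(A=A, A_inv=A_inv)
    H, H_inv = single_step_pair(pedigree, scaled, blend_weight=blend_weight)
    return RelationshipSet(
        A=A, A_inv=A_inv, H=H, H_inv=H_inv, genotyped_ids=list(scaled.animal_ids)
    )


def kinship_inverse_for(
    spec: ModelSpec, rels: RelationshipSet, pedigree: Pedigree
) -> RelationshipStructure:
    """Inverse relationship over the genetic ids a model spec requires.

    Sire-dam models carry genetic effects on the parents only, so the
    relevant kernel is the parent block of A or H (inverted directly: the
    inverse of the submatrix, not the submatrix of the inverse).  Animal
    models use the full matrices, for which the cheap inverses exist.
    """
    if spec.relationship == "H" and rels.H is None:
        raise ValueError("model spec requests H but no genotypes were supplied")
    if spec.genetic_param == "animal":
        return rels.A_inv if spec.relationship == "A" else rels.H_inv
    ids = parent_ids(pedigree)
    base = rels.A if spec.relationship == "A" else rels.H
    block = base.submatrix(ids)
    values = np.linalg.inv(block.values)
    kind = "A_inverse" if spec.relationship == "A" else "H_inverse"
    return RelationshipStructure(ids, 0.5 * (values + values.T), kind)


@dataclass
class RunConfig:
    """One full analysis run.

    Data come either from a fixture directory (written by
    ``simulate.write_fixture``) or from an inline simulation config.
    ``variants`` lists (relationship, transform) pairs; variance components
    are always estimated with the sire-dam DHGLM and cross-validation
    predicts with both the animal and the sire-dam model at those components.
    """

    out_dir: str
    sim: SimConfig | None = None
    fixture_dir: str | None = None
    variants: tuple[tuple[str, str], ...] = (("A", "standardized"), ("H", "standardized"))
    qc_call_rate: float = 0.90
    qc_hwe_p: float = 1e-15
    qc_maf: float = 0.01
    cv_folds: int = 10
    selection_proportion: float = 0.10
    blend_weight: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.fixture_dir is None):
            raise ValueError("provide exactly one of sim= or fixture_dir=")
        for rel, tr in self.variants:
            if rel not in ("A", "H") or tr not in ("standardized", "log"):
                raise ValueError(f"invalid variant ({rel}, {tr})")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a YAML file (lists become tuples;
        a ``sim`` mapping becomes a :class:`uniblup.SimConfig`)."""
        return _run_config_from_yaml(path)


def _run_config_from_yaml(path) -> "RunConfig":
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "sim" in raw and raw["sim"] is not None:
        sim = raw["sim"]
        for key, val in list(sim.items()):
            if isinstance(val, list):
                sim[key] = tuple(val)
        raw["sim"] = SimConfig(**sim)
    if "variants" in raw:
        raw["variants"] = tuple(tuple(v) for v in raw["variants"])
    return RunConfig(**raw)


def _load(config: RunConfig) -> SimDataset:
    if config.fixture_dir is not None:
        return read_fixture(config.fixture_dir)
    return simulate_dataset(config.sim, seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a report bundle (also written to
    ``out_dir``).  Stage failures abort with a stage-named diagnostic; a
    non-converged fit is recorded and its downstream stages are skipped."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        log["stages"].append(name)

    needs_H = any(rel == "H" for rel, _ in config.variants)

    stage("load")
    data = _load(config)
    if needs_H and data.genotypes is None:
        raise ValueError("stage load: variants request H but dataset has no genotypes")

    stage("qc")
    scaled = None
    if data.genotypes is not None:
        geno, qc_report = qc_snps(
            data.genotypes,
            call_rate_min=config.qc_call_rate,
            hwe_p_cutoff=config.qc_hwe_p,
            maf_min=config.qc_maf,
        )
        log["qc"] = {
            "n_input": qc_report.n_input,
            "removed_callrate": qc_report.n_removed_callrate,
            "removed_hwe": qc_report.n_removed_hwe,
            "removed_maf": qc_report.n_removed_maf,
            "n_surviving": qc_report.n_surviving,
        }
        scaled = scale_genotypes(geno)

    stage("relationships")
    rels = build_relationship_set(
        data.pedigree, scaled=scaled, blend_weight=config.blend_weight
    )

    stage("fit")
    responses: dict[str, np.ndarray] = {}
    for _, tr in config.variants:
        if tr not in responses:
            if tr == "standardized":
                responses[tr], tspec = standardize(data.phenotypes.weight)
                log["transform_standardized"] = tspec.to_dict()
            else:
                responses[tr] = np.log(data.phenotypes.weight)
                log["transform_log"] = {"kind": "log"}

    fits: dict[tuple[str, str], DhglmFit] = {}
    param_rows = []
    for rel, tr in config.variants:
        spec = ModelSpec(genetic_param="sire_dam", relationship=rel, transform=tr)
        kin = kinship_inverse_for(spec, rels, data.pedigree)
        fit = fit_dhglm(data.phenotypes, spec, kin, data.pedigree, response=responses[tr])
        fits[(rel, tr)] = fit
        log[f"fit_{rel}_{tr}"] = {
            "converged": fit.converged,
            "iterations": len(fit.loglik_trace),
            "loglik_trace": [float(v) for v in fit.loglik_trace],
        }
        if not fit.converged:
            warnings.warn(
                f"sire-dam DHGLM ({rel}, {tr}) did not converge; downstream "
                "stages for this variant skipped",
                stacklevel=2,
            )
            continue
        ps = derive_parameters(fit.varcomps).to_series()
        ps["relationship"] = rel
        ps["transform"] = tr
        param_rows.append(ps)
        ebv = pd.DataFrame(
            {
                "id": fit.genetic_ids,
                "ebv_mean": fit.ebv_mean,
                "ebv_disp": fit.ebv_disp,
            }
        )
        ebv.to_csv(out / f"ebv_siredam_{rel}_{tr}.csv", index=False)
    if param_rows:
        pd.DataFrame(param_rows).to_csv(out / "parameters.csv", index=False)

    stage("crossval")
    cv_rows = []
    for (rel, tr), fit in fits.items():
        if not fit.converged:
            continue
        plan = make_folds(data.phenotypes, k=config.cv_folds, seed=config.seed)
        for param in ("animal", "sire_dam"):
            pspec = ModelSpec(genetic_param=param, relationship=rel, transform=tr)
            kin = kinship_inverse_for(pspec, rels, data.pedigree)
            vc = fit.varcomps.to_animal() if param == "animal" else fit.varcomps
            # each predicting model refreshes its own working response and
            # adjusted phenotypes on the full data before the fold solves
            full = blup_full_fit(
                data.phenotypes, pspec, vc, kin, data.pedigree,
                response=responses[tr],
            )
            report = run_crossval(
                data.phenotypes,
                pspec,
                vc,
                plan,
                data.genotyped_ids,
                kin,
                data.pedigree,
                full,
                response=responses[tr],
            )
            s = report.summary()
            s["relationship"] = rel
            s["transform"] = tr
            s["model"] = param
            cv_rows.append(s)
    if cv_rows:
        pd.concat(cv_rows).to_csv(out / "crossval.csv", index=False)

    stage("selection")
    sel_rows = []
    for (rel, tr), fit in fits.items():
        if not fit.converged:
            continue
        sires = [g for g in fit.genetic_ids if str(g).startswith("S")]
        if not sires:
            continue
        gebv_mean = pd.Series(
            fit.ebv_mean[[fit.genetic_ids.index(s) for s in sires]], index=sires
        )
        gebv_disp = pd.Series(
            fit.ebv_disp[[fit.genetic_ids.index(s) for s in sires]], index=sires
        )
        spec_idx = sel.PRESET_LOG if tr == "log" else sel.PRESET_OBSERVED
        index = sel.compute_index(gebv_mean, gebv_disp, spec_idx)
        chosen = sel.truncation_select(index, config.selection_proportion)
        gain_mean, _ = sel.genetic_gain(chosen, gebv_mean)
        gain_disp, _ = sel.genetic_gain(chosen, gebv_disp)
        sel_rows.append(
            {
                "relationship": rel,
                "transform": tr,
                "n_selected": len(chosen),
                "gain_mean": gain_mean,
                "gain_disp": gain_disp,
                "selected": ";".join(chosen),
            }
        )
    if sel_rows:
        pd.DataFrame(sel_rows).to_csv(out / "selection.csv", index=False)

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
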