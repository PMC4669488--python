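"""End-to-end orchestration: simulate → mppgl → kinetics → activity → ivive → accuracy.

A :class:`PipelineConfig` fixes the cohort recipe, stage list, prediction
methods and master seed; :func:`run_pipeline` executes the enabled stages in
dependency order, writes one schema-checked CSV per entity plus a JSON
manifest (package version, seed, config hash, per-file row counts and
SHA-256 digests).  Identical config + seed reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from numpy.random import SeedSequence

from . import __version__
from .accuracy import accuracy_summary
from .activity import compute_vl, rank_change_analysis, summarize_activity
from .cohort import (
    CohortSpec,
    cohort_to_frame,
    generate_cohort,
    generate_kinetics,
    generate_por_pairs,
    generate_vm_table,
)
from .datasets import CYP_VM_SPECS, default_cohort_spec, observed_tolbutamide_clearance
from .io import SCHEMAS, write_table
from .ivive import FUB_TOLBUTAMIDE, predict_cohort
from .kinetics import fit_all
from .mppgl import estimate_mppgl

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGE_DEPENDENCIES"]

logger = logging.getLogger(__name__)

STAGE_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "mppgl": ("simulate",),
    "kinetics": ("simulate",),
    "activity": ("simulate", "mppgl"),
    "ivive": ("simulate", "mppgl", "kinetics"),
    "accuracy": ("ivive",),
}

_STAGE_ORDER = tuple(STAGE_DEPENDENCIES)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a full reproducible run needs."""

    n_donors: int = 78
    seed: int = 0
    stages: tuple[str, ...] = _STAGE_ORDER
    methods: str = "all"  # "all" or a single letter A..G
    fub: float = FUB_TOLBUTAMIDE
    microsome_rate_mean: float = 100.0  # nmol/min/mg, POR assay
    por_noise_cv: float = 0.15
    kinetics_noise_cv: float = 0.05
    out_dir: str = "hepscale_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGE_DEPENDENCIES:
                raise PipelineError(f"unknown stage {s!r}")
        enabled = set(self.stages)
        for s in self.stages:
            missing = [d for d in STAGE_DEPENDENCIES[s] if d not in enabled]
            if missing:
                raise PipelineError(
                    f"stage '{s}' requires disabled stage(s) {missing}"
                )
        if self.methods != "all" and self.methods not in "ABCDEFG":
            raise PipelineError(f"methods must be 'all' or one of A..G, got {self.methods!r}")
        if self.n_donors < 1:
            raise PipelineError("n_donors must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"tool": f"hepscale {__version__}", "config_hash": config.config_hash(),
                  "seed": config.seed}
    # one deterministic sub-seed per stochastic stage
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(("cohort", "por", "kinetics", "vm"),
                               SeedSequence(config.seed).spawn(4))
    }

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }
    state: dict = {}
    enabled = [s for s in _STAGE_ORDER if s in config.stages]
    for stage in enabled:
        try:
            files = _RUNNERS[stage](config, state, out, provenance, stage_seeds)
        except Exception as exc:
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = {"rows": files}
        logger.info("stage %s: %s", stage, files)
    for f in sorted(out.glob("*.csv")):
        manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_simulate(config, state, out, provenance, seeds):
    spec = default_cohort_spec(n_donors=config.n_donors, seed=seeds["cohort"])
    cohort = generate_cohort(spec)
    pairs = generate_por_pairs(
        cohort, microsome_rate_mean=config.microsome_rate_mean,
        noise_cv=config.por_noise_cv, seed=seeds["por"],
    )
    series = generate_kinetics(cohort, noise_cv=config.kinetics_noise_cv, seed=seeds["kinetics"])
    vm_table = generate_vm_table(cohort, CYP_VM_SPECS, seed=seeds["vm"])
    state.update(cohort=cohort, pairs=pairs, series=series, vm_table=vm_table)

    donors = cohort_to_frame(cohort)
    write_table(donors, out / "donors.csv", SCHEMAS["donors"], provenance)
    pairs_df = pd.DataFrame(
        {
            "donor_id": [p.donor_id for p in pairs],
            "homogenate_rate_nmol_min_g": [p.homogenate_rate for p in pairs],
            "microsome_rate_nmol_min_mg": [p.microsome_rate for p in pairs],
        }
    )
    write_table(pairs_df, out / "por_pairs.csv", SCHEMAS["por_pairs"], provenance)
    kin_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "donor_id": s.donor_id,
                    "concentration_uM": s.concentrations,
                    "rate_pmol_min_mg": s.rates,
                }
            )
            for s in series
        ],
        ignore_index=True,
    )
    write_table(kin_df, out / "kinetics.csv", SCHEMAS["kinetics"], provenance)
    write_table(vm_table, out / "activities_vm.csv", SCHEMAS["activities_vm"], provenance)
    return {
        "donors.csv": len(donors),
        "por_pairs.csv": len(pairs_df),
        "kinetics.csv": len(kin_df),
        "activities_vm.csv": len(vm_table),
    }


def _run_mppgl(config, state, out, provenance, seeds):
    estimates = [estimate_mppgl(p) for p in state["pairs"]]
    df = pd.DataFrame(
        {"donor_id": [e.donor_id for e in estimates], "mppgl_mg_g": [e.mppgl for e in estimates]}
    )
    state["mppgl"] = df
    write_table(df, out / "mppgl.csv", SCHEMAS["mppgl"], provenance)
    return {"mppgl.csv": len(df)}


def _run_kinetics(config, state, out, provenance, seeds):
    kin_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "donor_id": s.donor_id,
                    "concentration_uM": s.concentrations,
                    "rate_pmol_min_mg": s.rates,
                }
            )
            for s in state["series"]
        ],
        ignore_index=True,
    )
    params = fit_all(kin_df)
    state["kinetic_params"] = params
    write_table(params, out / "kinetic_params.csv", SCHEMAS["kinetic_params"], provenance)
    return {"kinetic_params.csv": len(params)}


def _run_activity(config, state, out, provenance, seeds):
    vl = compute_vl(state["vm_table"], state["mppgl"])
    write_table(vl, out / "activities_vl.csv", SCHEMAS["activities_vl"], provenance)
    rows = []
    for iso, grp in vl.groupby("isoform", sort=True):
        for kind, col in (("vm", "vm_pmol_min_mg"), ("vl", "vl_nmol_min_g")):
            s = summarize_activity(grp[col])
            rows.append(
                {
                    "isoform": iso, "quantity": kind, "n": s.n, "mean": s.mean, "sd": s.sd,
                    "median": s.median, "min": s.min, "max": s.max,
                    "p2_5": s.p2_5, "p97_5": s.p97_5,
                    "fold_minmax": s.fold_minmax, "fold_pi": s.fold_pi,
                }
            )
    summary = pd.DataFrame(rows)
    summary_path = out / "summary_stats.csv"
    with open(summary_path, "w", encoding="utf-8", newline="") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}={value}\n")
        summary.to_csv(fh, index=False)
    report = rank_change_analysis(vl)
    with open(out / "rank_change.csv", "w", encoding="utf-8", newline="") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}={value}\n")
        report.per_donor.to_csv(fh, index=False)
    state["vl"] = vl
    return {
        "activities_vl.csv": len(vl),
        "summary_stats.csv": len(summary),
        "rank_change.csv": len(report.per_donor),
    }


def _run_ivive(config, state, out, provenance, seeds):
    donors = cohort_to_frame(state["cohort"])
    params = state["kinetic_params"]
    cohort_params = pd.DataFrame(
        {
            "donor_id": donors["donor_id"],
            "mppgl": donors["donor_id"].map(
                dict(zip(state["mppgl"]["donor_id"], state["mppgl"]["mppgl_mg_g"]))
            ),
            "clint_vitro": donors["donor_id"].map(
                dict(zip(params["donor_id"], params["clint_vitro_ul_min_mg"]))
            ),
            "bw": donors["bw_kg"],
            "co": donors["co_l_min"],
        }
    )
    preds = predict_cohort(cohort_params, method=config.methods, fub=config.fub)
    state["predictions"] = preds
    write_table(preds, out / "predictions.csv", SCHEMAS["predictions"], provenance)
    return {"predictions.csv": len(preds)}


def _run_accuracy(config, state, out, provenance, seeds):
    observed = observed_tolbutamide_clearance()
    rows = []
    for method, grp in state["predictions"].groupby("method", sort=True):
        rep = accuracy_summary(
            grp["clh_ml_min_kg"].to_numpy(), observed, donor_ids=list(grp["donor_id"])
        )
        rows.append(
            {
                "method": method, "afe_mean": rep.mean, "afe_sd": rep.sd,
                "afe_min": rep.min, "afe_max": rep.max,
                "afe_p2_5": rep.p2_5, "afe_p97_5": rep.p97_5,
                "pct_within_2fold": rep.pct_within_2fold,
            }
        )
    acc = pd.DataFrame(rows)
    write_table(acc, out / "accuracy.csv", SCHEMAS["accuracy"], provenance)
    return {"accuracy.csv": len(acc)}


_RUNNERS = {
    "simulate": _run_simulate,
    "mppgl": _run_mppgl,
    "kinetics": _run_kinetics,
    "activity": _run_activity,
    "ivive": _run_ivive,
    "accuracy": _run_accuracy,
}
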