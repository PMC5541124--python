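"""End-to-end orchestration: simulate (or load) -> filter -> quantify ->
normalize -> merge -> call -> classify, with a machine-readable run report.

The report records counts at every stage and, when ground truth is available
(simulated input), sensitivity and specificity of group-1/group-2 recovery.
Identical config and seed give an identical report.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import filtering, quantify, regulation, synthetic
from .errors import ConfigError
from .psm_io import read_psm_table, write_psm_table

__all__ = ["PipelineConfig", "run_pipeline", "recovery_metrics"]

log = logging.getLogger("isoreg")

VEHICLE_CHANNEL = 115
U0126_CHANNEL = 114


@dataclass(frozen=True)
class PipelineConfig:
    """One structured object driving a full run.

    Exactly one of ``generator`` (simulate) or ``psm_table`` (load a real
    table) must be set; ``truth_table`` optionally accompanies a loaded
    table to enable recovery metrics.
    """

    generator: synthetic.GeneratorConfig | None = field(
        default_factory=synthetic.GeneratorConfig)
    psm_table: str | None = None
    truth_table: str | None = None
    filter: filtering.FilterConfig = field(default_factory=filtering.FilterConfig)
    design: quantify.ExperimentDesign = field(default_factory=quantify.ExperimentDesign)
    threshold: float = 2.0
    robust_sd: bool = False
    merge_strict: bool = False
    pool_fdr: bool = False
    outdir: str | None = None

    def validate(self) -> None:
        if (self.generator is None) == (self.psm_table is None):
            raise ConfigError("exactly one of generator / psm_table must be set")
        if self.generator is not None:
            self.generator.validate()
        elif not Path(self.psm_table).exists():
            raise ConfigError(f"psm_table: file {self.psm_table!r} does not exist")
        if self.truth_table is not None and not Path(self.truth_table).exists():
            raise ConfigError(f"truth_table: file {self.truth_table!r} does not exist")
        if self.threshold <= 0:
            raise ConfigError("threshold must be > 0")
        self.filter.validate()
        self.design.validate()

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Build a config from a TOML file with optional ``[generator]``,
        ``[filter]``, ``[design]`` and top-level scalar keys."""
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "generator" in raw:
            gen = dict(raw["generator"])
            for key in ("peptides_per_protein", "base_abundance", "target_score", "decoy_score"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            kwargs["generator"] = synthetic.GeneratorConfig(**gen)
        if "filter" in raw:
            kwargs["filter"] = filtering.FilterConfig(**raw["filter"])
        if "design" in raw:
            design = dict(raw["design"])
            if "channel_map" in design:
                design["channel_map"] = {int(k): v for k, v in design["channel_map"].items()}
            kwargs["design"] = quantify.ExperimentDesign(**design)
        for key in ("psm_table", "truth_table", "threshold", "robust_sd",
                    "merge_strict", "pool_fdr", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "psm_table" in raw and "generator" not in raw:
            kwargs["generator"] = None
        return cls(**kwargs)


def recovery_metrics(assignments: pd.DataFrame, truth: pd.DataFrame) -> dict[str, Any]:
    """Sensitivity/specificity of group recovery against generator truth.

    Ground-truth group-1 membership is "truly up in vehicle and reversed by
    treatment" (group 2: truly down and reversed); the evaluation universe is
    every target protein in the truth table.
    """
    predicted = {g: set(assignments.loc[assignments["group"] == g, "accession"])
                 for g in ("group1", "group2")}
    metrics: dict[str, Any] = {}
    universe = set(truth["accession"])
    for group, status in (("group1", "up"), ("group2", "down")):
        true_members = set(truth.loc[
            (truth["status_vehicle"] == status) & truth["reversed"], "accession"])
        pred = predicted[group] & universe
        tp = len(pred & true_members)
        fp = len(pred - true_members)
        fn = len(true_members - pred)
        tn = len(universe) - len(true_members) - fp
        metrics[group] = {
            "true_members": len(true_members),
            "predicted": len(pred),
            "sensitivity": tp / max(1, tp + fn) if true_members else None,
            "specificity": tn / max(1, tn + fp),
        }
    return metrics


def _stage(report: dict, name: str, **counts) -> None:
    report["stages"].append({"stage": name, **counts})
    log.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in counts.items()))


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the report dict (also written as JSON when
    ``config.outdir`` is set, alongside the stage output tables)."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {"stages": []}

    # -- acquire PSMs ------------------------------------------------------
    if config.generator is not None:
        psms, truth = synthetic.generate_experiment(config.generator)
        if outdir:
            write_psm_table(psms, outdir / "psms.tsv")
            synthetic.write_truth_table(truth, outdir / "truth.tsv")
    else:
        psms = read_psm_table(config.psm_table)
        truth = synthetic.read_truth_table(config.truth_table) if config.truth_table else None
    n_decoys = sum(p.is_decoy for p in psms)
    _stage(report, "input", psms=len(psms), targets=len(psms) - n_decoys, decoys=n_decoys)

    # -- filter ------------------------------------------------------------
    with_q = filtering.estimate_qvalues(psms, pool=config.pool_fdr)
    retained = filtering.apply_filter(with_q, config.filter)
    _stage(report, "filter", psms_in=len(psms), psms_out=len(retained),
           fdr_threshold=config.filter.fdr_threshold, score_floor=config.filter.score_floor)
    if outdir:
        write_psm_table(retained, outdir / "filtered.tsv")

    # -- quantify + normalize + merge -------------------------------------
    ratios = quantify.aggregate_protein(retained, config.design)
    normalized, offsets = quantify.median_normalize(ratios)
    merged = quantify.merge_experiments(normalized, strict=config.merge_strict)
    _stage(report, "quantify",
           protein_channel_ratios=len(ratios),
           proteins=int(merged["accession"].nunique()) if not merged.empty else 0,
           offsets={f"{e}:{c}": round(o, 6) for e, c, o in offsets.itertuples(index=False)})
    if outdir:
        ratios.to_csv(outdir / "ratios.tsv", sep="\t", index=False)
        normalized.to_csv(outdir / "normalized.tsv", sep="\t", index=False)
        merged.to_csv(outdir / "merged.tsv", sep="\t", index=False)

    # -- regulation calls --------------------------------------------------
    calls = {}
    for contrast, channel in (("vehicle_vs_sham", VEHICLE_CHANNEL),
                              ("u0126_vs_sham", U0126_CHANNEL)):
        dist = regulation.fit_tag_distribution(merged, channel, robust=config.robust_sd)
        contrast_calls = regulation.call_regulation(merged, dist, threshold=config.threshold)
        calls[contrast] = contrast_calls
        counts = contrast_calls["status"].value_counts()
        _stage(report, f"call:{contrast}", channel=channel,
               median=round(dist.median, 6), sd=round(dist.sd, 6),
               up=int(counts.get("up", 0)), down=int(counts.get("down", 0)),
               unchanged=int(counts.get("unchanged", 0)))
        if outdir:
            contrast_calls.to_csv(outdir / f"calls_{contrast}.tsv", sep="\t", index=False)

    # -- contrast classification ------------------------------------------
    assignments, vehicle_only = regulation.classify_contrasts(
        calls["vehicle_vs_sham"], calls["u0126_vs_sham"])
    group_counts = assignments["group"].value_counts()
    _stage(report, "classify",
           **{g: int(group_counts.get(g, 0)) for g in regulation.GROUPS},
           vehicle_only=len(vehicle_only))
    if outdir:
        assignments.to_csv(outdir / "groups.tsv", sep="\t", index=False)

    # -- recovery vs ground truth -----------------------------------------
    if truth is not None:
        report["recovery"] = recovery_metrics(assignments, truth)

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
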