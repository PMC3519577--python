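"""End-to-end orchestration: simulate → QC → global patterns → differential
→ power → validation → enrichment, with per-stage TSV outputs, a JSON
summary of the headline numbers, and full seed-driven determinism.

This module is the importable pipeline surface: construct a
:class:`PipelineConfig` (directly or from YAML) and call
:func:`run_pipeline`.  Every stage writes its tables beside a ``summary.json``
and the resolved configuration, so any stage can be re-run from its
persisted inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, patterns, power, qc, simulate, validation
from .containers import (
    STATUS_CONTROL,
    STATUS_T2D,
    StudyDesign,
    write_beta_matrix,
    write_design,
    write_manifest,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    seed: int = 0
    n_probes: int = 2000
    n_pairs: int = 11
    n_multi: int = 30
    n_snp: int = 15
    n_candidate: int = 136
    detection_threshold: float = 0.05
    significance: float = 0.05
    low_threshold: float = 0.25
    high_threshold: float = 0.75
    permutations: int = 10_000
    permutation_mode: str = "auto"
    effect_sites: dict = field(default_factory=dict)
    simulation: simulate.SimulationConfig | None = None
    stages: tuple = (
        "simulate",
        "qc",
        "global",
        "differential",
        "power",
        "validate",
        "enrich",
    )

    def __post_init__(self) -> None:
        for name, value in (
            ("detection_threshold", self.detection_threshold),
            ("significance", self.significance),
            ("low_threshold", self.low_threshold),
            ("high_threshold", self.high_threshold),
        ):
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.simulation is None:
            self.simulation = dataclasses.replace(
                simulate.MUSCLE_CONFIG,
                n_probes=self.n_probes,
                n_pairs=self.n_pairs,
                effect_sites=dict(self.effect_sites),
                seed=self.seed,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim:
            cfg.simulation = dataclasses.replace(cfg.simulation, **sim)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["simulation"] = dataclasses.asdict(self.simulation)
        data = json.loads(json.dumps(data, default=_json_default))  # tuples -> lists
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the configured stages, writing outputs under ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``.  A stage failure raises an error naming the stage;
    outputs of completed stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    summary: dict = {"seed": config.seed}
    produced: list[str] = ["config_resolved.yaml"]

    state: dict = {}
    for stage in config.stages:
        try:
            _STAGES[stage](config, out, state, summary, produced)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            _flush(out, summary, produced)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _flush(out, summary, produced)
    return summary


def _flush(out: Path, summary: dict, produced: list[str]) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    with open(out / "manifest.txt", "w") as fh:
        fh.write("\n".join(sorted(set(produced + ["summary.json"]))) + "\n")


def _stage_simulate(config, out, state, summary, produced):
    manifest, reference = simulate.generate_probe_manifest(
        config.n_probes, config.n_multi, config.n_snp, config.n_candidate,
        seed=config.seed,
    )
    beta, design, truth = simulate.generate_twin_beta(
        manifest, config.simulation, seed=config.seed
    )
    phenos = simulate.generate_phenotypes(config.n_pairs, seed=config.seed + 1)
    design = StudyDesign(design.samples, phenos)
    panel, _ = simulate.generate_repeat_panel(design, config.simulation,
                                             seed=config.seed + 2)
    state.update(manifest=manifest, reference=reference, beta=beta,
                 design=design, truth=truth, panel=panel)
    write_beta_matrix(beta, out / "beta.tsv")
    write_design(design, out / "design.tsv", out / "phenotypes.tsv")
    write_manifest(manifest, out / "probe_manifest.tsv")
    with open(out / "reference.fasta", "w") as fh:
        fh.write(">synthetic_reference\n")
        for i in range(0, len(reference), 80):
            fh.write(reference[i : i + 80] + "\n")
    produced += ["beta.tsv", "design.tsv", "phenotypes.tsv",
                 "probe_manifest.tsv", "reference.fasta"]
    summary["simulate"] = {
        "n_probes": beta.n_probes,
        "n_samples": beta.n_samples,
        "n_pairs": design.n_pairs,
    }


def _stage_qc(config, out, state, summary, produced):
    manifest = qc.annotate_alignments(state["manifest"], state["reference"])
    retained, report = qc.qc_filter(manifest)
    state["manifest_retained"] = retained
    report.to_frame().to_csv(out / "qc_dispositions.tsv", sep="\t")
    produced.append("qc_dispositions.tsv")
    summary["qc"] = {
        "n_input": report.n_input,
        "n_excluded_multi": report.n_excluded_multi,
        "n_excluded_snp": report.n_excluded_snp,
        "n_retained": report.n_retained,
    }


def _stage_global(config, out, state, summary, produced):
    beta, design, panel = state["beta"], state["design"], state["panel"]
    fr = patterns.methylation_fractions(beta, config.low_threshold,
                                        config.high_threshold)
    rs = []
    for pair, cols in design.pair_columns().iterrows():
        r, _ = patterns.sample_correlation(beta, cols["t2d"], cols["control"])
        rs.append({"pair_id": pair, "r": r})
    corr = pd.DataFrame(rs).set_index("pair_id")
    corr.to_csv(out / "cotwin_correlations.tsv", sep="\t")

    promoter = patterns.intrapair_variation_sd(beta, design, scope="pooled",
                                               label="promoters")
    repeats = patterns.intrapair_variation_sd(panel.pooled(), design,
                                              scope="pooled", label="repeats_all")
    line1_pp = patterns.intrapair_variation_sd(
        panel.elements["LINE1"], design, scope="per_pair", label="LINE1"
    )
    r_bmi, p_bmi = patterns.correlate_variation_phenotype(
        line1_pp, design.phenotype_delta("BMI")
    )
    anova = patterns.overall_anova(beta, design)
    anova.to_csv(out / "anova.tsv", sep="\t")
    produced += ["cotwin_correlations.tsv", "anova.tsv"]
    summary["global"] = {
        "fraction_low": fr.low,
        "fraction_high": fr.high,
        "mean_cotwin_r": float(corr["r"].mean()),
        "promoter_pooled_sd": promoter.sd,
        "repeat_pooled_sd": repeats.sd,
        "line1_sd_vs_bmi_r": r_bmi,
        "line1_sd_vs_bmi_p": p_bmi,
        "anova_pair_p": float(anova.loc["pair", "P"]),
        "anova_status_p": float(anova.loc["status", "P"]),
        "anova_interaction_p": float(anova.loc["pair:status", "P"]),
    }


def _stage_differential(config, out, state, summary, produced):
    beta, design = state["beta"], state["design"]
    manifest = state.get("manifest_retained", state["manifest"])
    plan = differential.PermutationPlan(
        mode=config.permutation_mode, B=config.permutations, seed=config.seed
    )
    cand, cand_counts = differential.run_candidate_analysis(
        beta, design, manifest, plan=plan
    )
    gw, gw_counts = differential.run_genome_wide(beta, design, manifest, plan=plan)
    cand.to_csv(out / "differential_candidate.tsv", sep="\t")
    gw.to_csv(out / "differential_genome_wide.tsv", sep="\t")
    state["genome_wide"] = gw
    produced += ["differential_candidate.tsv", "differential_genome_wide.tsv"]
    summary["differential"] = {"candidate": cand_counts, "genome_wide": gw_counts}


def _stage_power(config, out, state, summary, produced):
    table = power.power_table()
    table.to_csv(out / "power_table.tsv", sep="\t", index=False)
    produced.append("power_table.tsv")
    summary["power"] = {
        f"n{row.n_pairs}_m{row.m_tests}": row.mdd_rounded for row in table.itertuples()
    }


def _stage_validate(config, out, state, summary, produced):
    gw = state.get("genome_wide")
    beta, design = state["beta"], state["design"]
    # validate the top differential probe with simulated clone sequencing at
    # the observed array-level group means
    probe = gw.index[0] if gw is not None and len(gw) else beta.probe_ids[0]
    row = beta.values.loc[probe]
    results = {}
    for status in (STATUS_T2D, STATUS_CONTROL):
        samples = design.samples.index[design.samples["status"] == status]
        pct = float(np.clip(row[samples].mean() * 100.0, 0.0, 100.0))
        table = simulate.generate_clone_table(
            {f"site{k}": pct for k in range(1, 6)},
            n_clones=config.simulation.n_clones,
            seed=config.seed + (3 if status == STATUS_T2D else 4),
            amplicon_id=probe,
            status=status,
        )
        _, amplicon_mean = validation.clone_methylation_summary(table)
        results[status] = amplicon_mean
    summary["validate"] = {
        "probe": probe,
        "amplicon_mean_t2d": results[STATUS_T2D],
        "amplicon_mean_nont2d": results[STATUS_CONTROL],
    }


def _stage_enrich(config, out, state, summary, produced):
    gw = state.get("genome_wide")
    if gw is None or not len(gw):
        summary["enrich"] = {}
        return
    hits = sorted(set(gw.loc[gw["p_raw"] < config.significance, "gene_symbol"]))
    background = sorted(set(gw["gene_symbol"]))
    gene_set = background[: max(10, len(background) // 20)]
    diffs = gw.groupby("gene_symbol")["mean_difference"].mean()
    res = validation.fisher_enrichment(
        hits, gene_set, background, set_name="demo_set", gene_differences=diffs
    )
    summary["enrich"] = {
        "set_name": res.set_name,
        "table": list(res.table),
        "odds_ratio": res.odds_ratio,
        "p_value": res.p_value,
    }


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "global": _stage_global,
    "differential": _stage_differential,
    "power": _stage_power,
    "validate": _stage_validate,
    "enrich": _stage_enrich,
}
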