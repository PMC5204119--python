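"""End-to-end orchestration: simulate -> DE -> validate -> conserve ->
regulatory -> intersect, with one seed and one combined report.

Every stage writes its table under the output directory and contributes a
summary block to the :class:`RunReport` JSON. All randomness flows from the
single seed through named substreams, so a rerun with the same configuration
reproduces byte-identical outputs. Because the study is synthetic, each
stage's summary also scores recovery of the planted truth.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import arrayde, conservation, intersect, io as lio, qpcr, regulatory, simdata
from .config import SimConfig, Species
from .errors import StageError
from .features import GenomicInterval

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_report",
    "read_report",
    "score_de",
    "score_lineage",
    "score_tiers",
    "score_intersection",
]

log = logging.getLogger("lncestro")

#: planted truth label -> class the conservation caller should assign
LABEL_TO_CLASS = {
    "conserved": "conserved_beyond_primates",
    "primate_specific": "primate_specific",
    "primate_plus_treeshrew": "primate_plus_treeshrew",
}


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    fc_thresh: float = 1.4
    q_thresh: float = 0.05
    flank: int = 5000
    polya_window: int = 40
    max_mismatch_per_halfsite: int = 1
    min_qpcr_magnitude: float = qpcr.DEFAULT_MIN_MAGNITUDE
    de_test: str = "anova"  # or "welch"

    def validate(self) -> "PipelineConfig":
        self.sim.validate()
        if self.fc_thresh < 1 or self.q_thresh <= 0 or self.flank < 0:
            raise StageError("config", "thresholds must be positive")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "species_list" in sim_raw:
            sim_raw["species_list"] = tuple(
                Species(**s) for s in sim_raw["species_list"]
            )
        for key in ("effect_size_range", "spike_in_log2_ratios", "tier_counts",
                    "lineage_probs"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        return cls(sim=SimConfig(**sim_raw), **raw).validate()


# ---------------------------------------------------------------------------
# truth-recovery scores
# ---------------------------------------------------------------------------

def score_de(results: pd.DataFrame, truth: simdata.TruthTable) -> dict:
    merged = truth.genes.merge(results, on="gene_id", how="left")
    merged["de_call"] = merged["de_call"].fillna("none")
    planted = merged["de_direction"] != "none"
    called = merged["de_call"] != "none"
    hit = planted & (merged["de_call"] == merged["de_direction"])
    n_called = int(called.sum())
    return {
        "n_genes": int(len(merged)),
        "n_called_up": int((merged["de_call"] == "up").sum()),
        "n_called_down": int((merged["de_call"] == "down").sum()),
        "n_called_none": int((merged["de_call"] == "none").sum()),
        "de_fraction_percent": arrayde.de_fraction_percent(n_called, len(merged)),
        "sensitivity": float(hit.sum() / planted.sum()) if planted.any() else None,
        "false_discovery_proportion": (
            float((called & ~planted).sum() / n_called) if n_called else 0.0
        ),
    }


def score_lineage(lineage: pd.DataFrame, truth: simdata.TruthTable) -> dict:
    t = truth.elements.copy()
    t["expected_class"] = t["lineage_label"].map(LABEL_TO_CLASS)
    merged = t.merge(
        lineage[["kind", "chrom", "strand", "start", "end", "lineage_class"]],
        on=["kind", "chrom", "strand", "start", "end"],
        how="left",
    )
    found = merged["lineage_class"].notna()
    correct = found & (merged["lineage_class"] == merged["expected_class"])
    return {
        "n_elements_planted": int(len(merged)),
        "n_elements_recovered": int(found.sum()),
        "n_elements_correct_class": int(correct.sum()),
        "label_recovery": float(correct.sum() / len(merged)) if len(merged) else None,
    }


def score_tiers(evidence: pd.DataFrame, truth: simdata.TruthTable) -> dict:
    panel = truth.genes[truth.genes["in_panel"]]
    merged = panel.merge(evidence, on="gene_id", how="left")
    counts = merged["tier"].value_counts().to_dict()
    exact = bool((merged["tier"] == merged["true_tier"]).all())
    return {
        "n_chip": int(counts.get("chip", 0)),
        "n_motif_only": int(counts.get("motif_only", 0)),
        "n_none": int(counts.get("none", 0)),
        "partition_matches_truth": exact,
    }


def score_intersection(counts: pd.DataFrame, truth: simdata.TruthTable) -> dict:
    merged = truth.genes.merge(counts, on="gene_id", how="left")
    merged["matched"] = merged["n_matches"].fillna(0) > 0
    exact = bool((merged["matched"] == merged["in_partner"]).all())
    return {
        "n_genes": int(len(merged)),
        "n_matched": int(merged["matched"].sum()),
        "n_planted_shared": int(merged["in_partner"].sum()),
        "matches_truth_exactly": exact,
    }


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def _stage(name):
    def wrap(fn):
        def inner(state, outdir, cfg):
            t0 = time.perf_counter()
            try:
                summary = fn(state, outdir, cfg)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, str(exc)) from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return summary

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(state, outdir, cfg):
    study = simdata.simulate_study(cfg.sim)
    state["study"] = study
    simdata.write_study(study, outdir / "simulated")
    g = study.truth.genes
    return {
        "n_genes": int(len(g)),
        "n_planted_up": int((g["de_direction"] == "up").sum()),
        "n_planted_down": int((g["de_direction"] == "down").sum()),
        "n_elements": int(len(study.truth.elements)),
        "n_panel": int(g["in_panel"].sum()),
    }


@_stage("de")
def _run_de(state, outdir, cfg):
    study = state["study"]
    results, gamma = arrayde.run_de_analysis(
        study.probes,
        study.calibration,
        fc_thresh=cfg.fc_thresh,
        q_thresh=cfg.q_thresh,
        test=cfg.de_test,
    )
    state["de_results"] = results
    lio.write_tsv(results, outdir / "de_results.tsv")
    return {"gamma": gamma, **score_de(results, study.truth)}


@_stage("validate")
def _run_validate(state, outdir, cfg):
    study = state["study"]
    qfc = qpcr.qpcr_log2_fc_table(study.ct)
    panel = study.truth.genes.loc[study.truth.genes["in_panel"], "gene_id"]
    array_fc = state["de_results"][state["de_results"]["gene_id"].isin(panel)]
    report = qpcr.concordance(array_fc, qfc, cfg.min_qpcr_magnitude)
    lio.write_tsv(report.per_gene, outdir / "concordance.tsv")
    return report.summary()


@_stage("conserve")
def _run_conserve(state, outdir, cfg):
    study = state["study"]
    elements = conservation.extract_elements(
        study.transcripts, study.genome, polya_window=cfg.polya_window
    )
    maf = conservation.MafIndex(study.maf_blocks, ref=cfg.sim.human.name)
    lineage = conservation.conservation_table(elements, maf, cfg.sim.species_list)
    state["lineage"] = lineage
    lio.write_tsv(lineage, outdir / "lineage.tsv")
    summary = conservation.summarize_set(lineage)
    lio.write_json(summary, outdir / "conservation_summary.json")
    return {**summary, **score_lineage(lineage, study.truth)}


@_stage("regulatory")
def _run_regulatory(state, outdir, cfg):
    study = state["study"]
    panel = study.loci[study.loci["in_panel"]]
    genes = [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand, r.gene_id)
        for r in panel.itertuples()
    ]
    evidence = regulatory.evidence_table(
        genes,
        study.peaks,
        study.genome,
        flank=cfg.flank,
        max_mismatch_per_halfsite=cfg.max_mismatch_per_halfsite,
    )
    lio.write_tsv(evidence, outdir / "evidence.tsv")
    return score_tiers(evidence, study.truth)


@_stage("intersect")
def _run_intersect(state, outdir, cfg):
    study = state["study"]
    matches, counts = intersect.intersect_catalogues(study.transcripts, study.partner)
    lio.write_tsv(matches, outdir / "matches.tsv")
    lio.write_tsv(counts, outdir / "match_counts.tsv")
    return score_intersection(counts, study.truth)


_STAGES = [
    ("simulate", _run_simulate),
    ("de", _run_de),
    ("validate", _run_validate),
    ("conserve", _run_conserve),
    ("regulatory", _run_regulatory),
    ("intersect", _run_intersect),
]


def run_pipeline(
    config: PipelineConfig, outdir, stages: set[str] | None = None
) -> dict:
    """Run the staged analysis; returns (and writes) the combined report."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    report = {
        "seed": config.sim.seed,
        "config": _jsonable(asdict(config)),
        "stages": {},
    }
    for name, fn in _STAGES:
        if stages is not None and name not in stages:
            report["stages"][name] = "skipped"
            continue
        report["stages"][name] = _jsonable(fn(state, out, config))
    write_report(report, out / "report.json", out / "report.tsv")
    return report


def _jsonable(obj):
    """NaN -> None, numpy scalars -> python, tuples -> lists (deep)."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return _jsonable(obj.item())
    return obj


def write_report(report: dict, json_path, tsv_path=None) -> None:
    lio.write_json(_jsonable(report), json_path)
    if tsv_path is not None:
        rows = []
        for stage, block in report["stages"].items():
            if isinstance(block, dict):
                for key, value in sorted(block.items()):
                    rows.append({"stage": stage, "metric": key, "value": value})
            else:
                rows.append({"stage": stage, "metric": "status", "value": block})
        lio.write_tsv(pd.DataFrame(rows), tsv_path)


def read_report(json_path) -> dict:
    return lio.read_json(json_path)
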