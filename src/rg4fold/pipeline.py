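"""End-to-end orchestration of the RG4 probing analysis.

Each stage reads the previous stage's files and writes its own, so the
CLI subcommands are independently runnable and ``run_demo`` — the
single-command synthetic end-to-end — is exactly the chained stages:

    simulate -> counts (merge) -> rts -> classify -> undetected
             -> bpp -> shalipe -> report

The demo finishes with a truth-vs-called evaluation (RTS sensitivity and
FDR, subclass recovery, folding score by truth label) that only the
synthetic data make possible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counts as cio
from . import motif, rts, shalipe
from .simulate import (
    RG4SEQ_CONDITIONS,
    SHALIPE_STATES,
    SimulationConfig,
    generate_transcriptome,
    read_truth_table,
    simulate_rg4seq,
    simulate_shalipe,
    write_truth_table,
)

logger = logging.getLogger("rg4fold")

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "stage_simulate",
    "stage_merge_counts",
    "stage_rts",
    "stage_classify",
    "stage_undetected",
    "stage_bpp",
    "stage_shalipe",
    "stage_report",
    "run_demo",
]


@dataclass
class MotifParams:
    window: int = 50
    min_tract: int = 2
    max_loop: int = 15
    min_li_coverage: float = 60.0
    flank: int = 50


@dataclass
class ShalipeParams:
    ratio_min: float = 1.1
    min_mean_reads: float = 50.0


@dataclass
class PipelineConfig:
    outdir: str = "rg4fold_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rts: rts.RTSConfig = field(default_factory=rts.RTSConfig)
    motif: MotifParams = field(default_factory=MotifParams)
    shalipe: ShalipeParams = field(default_factory=ShalipeParams)

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        outdir=raw.get("outdir", "rg4fold_run"),
        seed=int(raw.get("seed", 0)),
        simulation=SimulationConfig(**{
            **raw.get("simulation", {}),
            **(
                {"transcript_length_range": tuple(raw["simulation"]["transcript_length_range"])}
                if "transcript_length_range" in raw.get("simulation", {})
                else {}
            ),
        }),
        rts=rts.RTSConfig(**raw.get("rts", {})),
        motif=MotifParams(**raw.get("motif", {})),
        shalipe=ShalipeParams(**raw.get("shalipe", {})),
    )
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    raw = dataclasses.asdict(cfg)
    raw["simulation"]["transcript_length_range"] = list(
        raw["simulation"]["transcript_length_range"]
    )
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def _paths(outdir: str | Path) -> dict[str, Path]:
    out = Path(outdir)
    counts_dir = out / "counts"
    return {
        "out": out,
        "counts": counts_dir,
        "fasta": out / "transcripts.fasta",
        "gff": out / "annotation.gff3",
        "truth": out / "truth.tsv",
        "rts_tsv": out / "rts_sites.tsv",
        "rts_bed": out / "rts_sites.bed",
        "residue": out / "residue_profile.tsv",
        "detected": out / "regions_detected.tsv",
        "detected_bed": out / "regions_detected.bed",
        "predicted": out / "regions_predicted.tsv",
        "undetected": out / "regions_undetected.tsv",
        "bpp": out / "bpp_meta.tsv",
        "scores": out / "folding_scores.tsv",
        "summary": out / "summary.txt",
        "evaluation": out / "evaluation.tsv",
        "config": out / "resolved_config.yaml",
    }


def _count_file(paths: dict[str, Path], assay: str, label: str, rep: str) -> Path:
    return paths["counts"] / f"{assay}_{label}_{rep}.tsv"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> None:
    """Generate the transcriptome, truth table and all per-replicate counts."""
    p = _paths(cfg.outdir)
    p["counts"].mkdir(parents=True, exist_ok=True)
    seqs, annotations, truth = generate_transcriptome(cfg.simulation)
    cio.write_fasta(seqs, p["fasta"])
    cio.write_gff3(annotations.values(), p["gff"])
    write_truth_table(truth, p["truth"])
    logger.info("simulate: %d transcripts, %d planted regions", len(seqs), len(truth))
    for cond in RG4SEQ_CONDITIONS:
        for i, reps in enumerate(simulate_rg4seq(seqs, truth, cond, cfg.simulation)):
            cio.write_stop_counts(reps, _count_file(p, "rg4seq", cond, f"rep{i + 1}"))
    for state in SHALIPE_STATES:
        for i, reps in enumerate(simulate_shalipe(seqs, truth, state, cfg.simulation)):
            cio.write_stop_counts(reps, _count_file(p, "shalipe", state, f"rep{i + 1}"))


def stage_merge_counts(cfg: PipelineConfig) -> None:
    """Sum-merge the replicates of every condition/state."""
    p = _paths(cfg.outdir)
    n = cfg.simulation.n_replicates
    for assay, labels in (("rg4seq", RG4SEQ_CONDITIONS), ("shalipe", SHALIPE_STATES)):
        for label in labels:
            reps = [
                cio.read_stop_counts(_count_file(p, assay, label, f"rep{i + 1}"))
                for i in range(n)
            ]
            merged = cio.merge_replicates(reps)
            for (a, b), r in merged.correlations.items():
                logger.info("merge %s/%s: corr(%s,%s)=%.3f", assay, label, a, b, r)
            cio.write_stop_counts(merged.profiles, _count_file(p, assay, label, "merged"))


def stage_rts(cfg: PipelineConfig) -> list[rts.RTSSite]:
    """Call condition-dependent stall sites (K+ vs Li+) and the residue profile."""
    p = _paths(cfg.outdir)
    n = cfg.simulation.n_replicates
    test = [
        cio.read_stop_counts(_count_file(p, "rg4seq", "K", f"rep{i + 1}")) for i in range(n)
    ]
    control = [
        cio.read_stop_counts(_count_file(p, "rg4seq", "Li", f"rep{i + 1}")) for i in range(n)
    ]
    log: list[str] = []
    sites = rts.detect_rts(test, control, cfg.rts, log=log)
    for line in log:
        logger.info("rts: %s", line)
    logger.info("rts: %d sites", len(sites))
    rts.write_sites_tsv(sites, p["rts_tsv"])
    rts.write_sites_bed(sites, p["rts_bed"])
    seqs = cio.read_fasta(p["fasta"])
    if sites:
        rts.residue_meta_profile(sites, seqs).to_csv(p["residue"], sep="\t", index=False)
    return sites


def stage_classify(cfg: PipelineConfig) -> list[motif.GRichRegion]:
    """Assign the G-rich region upstream of each RTS site to a subclass."""
    p = _paths(cfg.outdir)
    seqs = cio.read_fasta(p["fasta"])
    annotations = cio.read_gff3(p["gff"])
    df = pd.read_csv(p["rts_tsv"], sep="\t")
    regions: list[motif.GRichRegion] = []
    per_subclass: dict[str, int] = {}
    for row in df.itertuples():
        site = rts.RTSSite(
            str(row.transcript_id), int(row.position), str(row.condition_pair),
            float(row.p_value), float(row.drop_statistic),
        )
        region = motif.classify_upstream(site, seqs, cfg.motif.window)
        if region is None:
            continue
        region.genic_region = motif.locate_genic(region, annotations.get(region.transcript_id))
        regions.append(region)
        per_subclass[region.subclass] = per_subclass.get(region.subclass, 0) + 1
    logger.info("classify: %d regions (%s)", len(regions), per_subclass)
    motif.write_regions_tsv(regions, p["detected"])
    motif.write_regions_bed(regions, p["detected_bed"])
    return regions


def stage_undetected(cfg: PipelineConfig) -> list[motif.GRichRegion]:
    """Predict G-rich regions transcriptome-wide and pool the undetected set."""
    p = _paths(cfg.outdir)
    seqs = cio.read_fasta(p["fasta"])
    predicted = motif.predict_transcriptome(seqs, cfg.motif.min_tract, cfg.motif.max_loop)
    motif.write_regions_tsv(predicted, p["predicted"])
    detected = motif.read_regions_tsv(p["detected"])
    li = cio.read_stop_counts(_count_file(_paths(cfg.outdir), "rg4seq", "Li", "merged"))
    log: list[str] = []
    undetected = motif.select_undetected(
        predicted, detected, li, seqs, cfg.motif.min_li_coverage, cfg.motif.flank, log
    )
    for line in log:
        logger.info("undetected: %s", line)
    annotations = cio.read_gff3(p["gff"])
    for region in undetected:
        region.genic_region = motif.locate_genic(region, annotations.get(region.transcript_id))
    logger.info(
        "undetected: %d predicted, %d pass coverage/overlap/flank filters",
        len(predicted), len(undetected),
    )
    motif.write_regions_tsv(undetected, p["undetected"])
    return undetected


def stage_bpp(cfg: PipelineConfig, engine=None) -> None:
    """Base-pairing-probability meta-profile of the detected regions."""
    from . import structure

    p = _paths(cfg.outdir)
    regions = motif.read_regions_tsv(p["detected"])
    if not regions:
        logger.info("bpp: no detected regions; skipping")
        return
    seqs = cio.read_fasta(p["fasta"])
    if engine is None:
        engine = structure.ViennaRNAEngine()
    tracks = [structure.region_track(r, seqs, engine) for r in regions]
    meta = structure.bin_meta(tracks, regions)
    structure.write_meta_tsv(meta, p["bpp"])
    logger.info(
        "bpp: %d regions, paired t p=%s", meta.n_regions,
        f"{meta.p_value:.3g}" if meta.p_value is not None else "NA",
    )


def stage_shalipe(cfg: PipelineConfig) -> list[shalipe.FoldingScoreRecord]:
    """Ginis and folding scores of the detected regions."""
    p = _paths(cfg.outdir)
    regions = motif.read_regions_tsv(p["detected"])
    profiles_by_state = {
        state: cio.read_stop_counts(_count_file(p, "shalipe", state, "merged"))
        for state in SHALIPE_STATES
    }
    log: list[str] = []
    records = shalipe.score_regions(
        regions, profiles_by_state, cfg.shalipe.ratio_min, cfg.shalipe.min_mean_reads, log
    )
    for line in log:
        logger.info("shalipe: %s", line)
    logger.info(
        "shalipe: %d regions, %d scored",
        len(records), sum(r.folding_score is not None for r in records),
    )
    shalipe.write_records_tsv(records, p["scores"])
    return records


def stage_report(cfg: PipelineConfig) -> dict[str, float]:
    """Landscape summary plus the truth-vs-called evaluation."""
    p = _paths(cfg.outdir)
    records = _read_records(p["scores"])
    truth = read_truth_table(p["truth"])
    sites_df = pd.read_csv(p["rts_tsv"], sep="\t") if p["rts_tsv"].exists() else pd.DataFrame()

    lines = []
    scored = [r for r in records if r.folding_score is not None]
    if scored:
        summary = shalipe.summarize_landscape(records)
        lines += [
            f"scored regions: {summary.n_scored}",
            f"median folding score: {summary.median_fs:.3f}",
            f"regions with FS > 0: {summary.n_positive} ({summary.frac_positive:.1%})",
            f"subclass ANOVA p: {_fmt(summary.subclass_anova_p)}",
            f"genic-region ANOVA p: {_fmt(summary.genic_anova_p)}",
        ]
    else:
        lines.append("no regions passed the folding-score filters")

    eval_metrics = _evaluate(truth, sites_df, records, tolerance=2)
    for k, v in eval_metrics.items():
        lines.append(f"{k}: {_fmt(v)}")
    p["summary"].write_text("\n".join(lines) + "\n")
    pd.DataFrame([eval_metrics]).to_csv(p["evaluation"], sep="\t", index=False)
    for line in lines:
        logger.info("report: %s", line)
    return eval_metrics


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "undefined"
    return f"{v:.4g}" if isinstance(v, float) else str(v)


def _read_records(path: Path) -> list[shalipe.FoldingScoreRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        out.append(
            shalipe.FoldingScoreRecord(
                str(r.region_id), str(r.subclass), str(r.genic_region),
                _opt(r.gini_vivo), _opt(r.gini_li), _opt(r.gini_k),
                _opt(r.folding_score),
                str(r.passes_ratio_filter) == "True",
                str(r.passes_coverage_filter) == "True",
            )
        )
    return out


def _opt(v) -> float | None:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(f) else f


def _evaluate(
    truth, sites_df: pd.DataFrame, records, tolerance: int = 2
) -> dict[str, float]:
    """Truth-vs-called metrics, only computable on synthetic data."""
    folded = [t for t in truth if t.folded]
    sites_by_tid: dict[str, list[int]] = {}
    if not sites_df.empty:
        for row in sites_df.itertuples():
            sites_by_tid.setdefault(str(row.transcript_id), []).append(int(row.position))

    hits = 0
    for t in folded:
        stall = t.interval[1] - 1
        if any(abs(pos - stall) <= tolerance for pos in sites_by_tid.get(t.transcript_id, [])):
            hits += 1
    sensitivity = hits / len(folded) if folded else float("nan")

    n_sites = int(sites_df.shape[0]) if not sites_df.empty else 0
    fp = 0
    folded_by_tid = {t.transcript_id: t.interval[1] - 1 for t in folded}
    for tid, positions in sites_by_tid.items():
        for pos in positions:
            stall = folded_by_tid.get(tid)
            if stall is None or abs(pos - stall) > tolerance:
                fp += 1
    fdr = fp / n_sites if n_sites else float("nan")

    truth_by_tid = {t.transcript_id: t for t in truth}
    recovered: set[str] = set()
    fs_folded, fs_unfolded = [], []
    for rec in records:
        tid = rec.region_id.split(":")[0]
        t = truth_by_tid.get(tid)
        if t is None:
            continue
        if t.folded and rec.subclass == t.subclass:
            recovered.add(tid)
        if rec.folding_score is not None:
            (fs_folded if t.folded else fs_unfolded).append(rec.folding_score)
    recovery = len(recovered) / len(folded) if folded else float("nan")

    return {
        "rts_sensitivity": sensitivity,
        "rts_fdr": fdr,
        "n_rts_sites": float(n_sites),
        "subclass_recovery": recovery,
        "median_fs_truth_folded": float(np.median(fs_folded)) if fs_folded else float("nan"),
        "median_fs_truth_unfolded": float(np.median(fs_unfolded)) if fs_unfolded else float("nan"),
    }


def run_demo(cfg: PipelineConfig, engine=None, skip_bpp: bool = False) -> dict[str, float]:
    """The whole synthetic pipeline, stage by stage, from one config.

    Identical to running the subcommands in sequence on each other's files;
    deterministic under ``cfg.seed``.
    """
    p = _paths(cfg.outdir)
    p["out"].mkdir(parents=True, exist_ok=True)
    save_config(cfg, p["config"])
    for name, fn in (
        ("simulate", stage_simulate),
        ("counts", stage_merge_counts),
        ("rts", stage_rts),
        ("classify", stage_classify),
        ("undetected", stage_undetected),
    ):
        _run_stage(name, fn, cfg)
    if not skip_bpp:
        _run_stage("bpp", lambda c: stage_bpp(c, engine), cfg)
    _run_stage("shalipe", stage_shalipe, cfg)
    return _run_stage("report", stage_report, cfg)


def _run_stage(name: str, fn, cfg: PipelineConfig):
    logger.info("stage %s: start", name)
    try:
        return fn(cfg)
    except Exception:
        logger.exception("stage %s failed", name)
        raise
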