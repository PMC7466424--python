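"""Synthetic transcriptomes and probing data with known truth labels.

Every downstream stage of the pipeline is exercised on data generated
here, so the generator plants what the assays are designed to see:

* transcripts carrying one G-rich motif of a known structural subclass,
  surrounded by G-free 50-nt flanks so truth recovery by the motif
  grammar is exact;
* rG4-seq: under a stabilizing cation (K+, with or without the ligand
  PDS) a folded quadruplex stalls reverse transcription at its
  3'-terminal G, so read coverage 5' of that base drops by
  ``stall_efficiency`` and a stop-count spike appears at the base; under
  Li+ nothing stalls;
* SHALiPE: the acylation probe preferentially modifies the 3'-most G of
  each G-tract of a *folded* quadruplex, multiplying that position's
  stop count by ``lastG_enrichment``; unfolded regions give a flat
  profile. The in vivo state follows each region's planted folded flag.

Counts are negative-binomial with dispersion ``noise_dispersion``
(Poisson in the infinite-dispersion limit), matching the overdispersion
of sequencing stop counts.  All outputs are deterministic functions of
``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import ProfileSet, StopCountProfile, TranscriptAnnotation
from .motif import SUBCLASSES, g_tracts, locate_genic, GRichRegion

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "RG4SEQ_CONDITIONS",
    "SHALIPE_STATES",
    "generate_transcriptome",
    "simulate_rg4seq",
    "simulate_shalipe",
    "write_truth_table",
    "read_truth_table",
]

RG4SEQ_CONDITIONS = ("Li", "K", "K_PDS")
SHALIPE_STATES = ("in_vitro_Li", "in_vitro_K", "in_vivo")

_SUBCLASS_LABELS = tuple(s.label for s in SUBCLASSES)
_H = "ACU"
_MARGIN = 60  # nt kept free of the motif at each transcript end
_FLANK = 50  # G-free sanitized flank on each side of a plant


@dataclass
class SimulationConfig:
    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (400, 800)
    n_planted_regions: int = 40
    subclass_mix: dict[str, float] = field(
        default_factory=lambda: {label: 1 / 6 for label in _SUBCLASS_LABELS}
    )
    folded_fraction: float = 0.5
    base_coverage: float = 100.0
    stall_efficiency: float = 0.9
    lastG_enrichment: float = 8.0
    noise_dispersion: float = 20.0  # NB size parameter; inf -> Poisson
    background_stop_rate: float = 0.02  # spontaneous stops per covering read
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0 or self.n_replicates <= 0:
            raise ValueError("counts must be positive")
        if self.n_planted_regions < 0:
            raise ValueError("n_planted_regions must be >= 0")
        if self.n_planted_regions > self.n_transcripts:
            raise ValueError(
                "at most one region is planted per transcript: "
                f"{self.n_planted_regions} regions > {self.n_transcripts} transcripts"
            )
        lo, hi = self.transcript_length_range
        if lo < 2 * _MARGIN + 48:
            raise ValueError(
                f"transcripts of length {lo} are too short to host a motif "
                f"with {_FLANK}-nt flanks"
            )
        if hi < lo:
            raise ValueError("invalid transcript_length_range")
        if abs(sum(self.subclass_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subclass_mix must sum to 1")
        if set(self.subclass_mix) - set(_SUBCLASS_LABELS):
            raise ValueError("unknown subclass in subclass_mix")
        if not 0.0 <= self.folded_fraction <= 1.0:
            raise ValueError("folded_fraction must be in [0, 1]")
        if not 0.0 <= self.stall_efficiency <= 1.0:
            raise ValueError("stall_efficiency must be in [0, 1]")
        if self.lastG_enrichment < 1.0:
            raise ValueError("lastG_enrichment must be >= 1")
        if self.base_coverage <= 0 or self.noise_dispersion <= 0:
            raise ValueError("base_coverage and noise_dispersion must be positive")


@dataclass
class TruthRecord:
    transcript_id: str
    interval: tuple[int, int]  # 0-based half-open
    subclass: str
    folded: bool
    genic_region: str


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def _loops(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[int]:
    return [int(rng.integers(lo, hi + 1)) for _ in range(n)]


def _h_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_H), size=n)) if n else ""


def _plant_motif(rng: np.random.Generator, label: str) -> str:
    """A sequence matching *label* and no higher-priority subclass.

    Loops are drawn from {A, C, U} so the only G-runs are the designed
    tracts; loop-length constraints keep each plant out of the stricter
    grammars above it in the hierarchy (e.g. a G2L1-4 plant always has at
    least one loop of 3-4 nt, so G2L1-2 can never match it).
    """
    if label == "G3L1-15":
        tracts = ["GGG"] * 4
        loops = _loops(rng, 3, 1, 12)  # capped so the plant fits a 50-nt window
    elif label == "G3VL1-9":
        if rng.integers(2) == 0:
            tracts = ["GGG", "GGG", "GGG", "GG"]
        else:
            tracts = ["GG", "GGG", "GGG", "GGG"]
        loops = _loops(rng, 3, 1, 9)
    elif label == "G3bulge":
        bulged = lambda: ("GG" + _h_seq(rng, 1) + "G") if rng.integers(2) == 0 else (
            "G" + _h_seq(rng, 1) + "GG"
        )
        tracts = ["GGG", bulged(), bulged(), "GGG"]
        loops = _loops(rng, 3, 1, 9)
    elif label == "G2L1-2":
        tracts = ["GG"] * 4
        loops = _loops(rng, 3, 1, 2)
    elif label == "G2L1-4":
        tracts = ["GG"] * 4
        while True:
            loops = _loops(rng, 3, 1, 4)
            if max(loops) >= 3:
                break
    elif label == "G2L1-9":
        tracts = ["GG"] * 4
        while True:
            loops = _loops(rng, 3, 1, 9)
            if max(loops) >= 5:
                break
    else:
        raise ValueError(f"unknown subclass {label!r}")
    parts = [tracts[0]]
    for loop, tract in zip(loops, tracts[1:]):
        parts.append(_h_seq(rng, loop))
        parts.append(tract)
    return "".join(parts)


def _annotate(tid: str, length: int) -> TranscriptAnnotation:
    """Coarse 3-way genic layout: first 20% 5'UTR, last 20% 3'UTR."""
    a = int(round(0.2 * length))
    b = int(round(0.8 * length))
    return TranscriptAnnotation(tid, (0, a), (a, b), (b, length))


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, TranscriptAnnotation], list[TruthRecord]]:
    """Random transcripts with planted RG4 motifs and a truth table.

    At most one motif is planted per transcript, at a uniform position at
    least 60 nt from either end; the 50 nt on each side of a plant are
    drawn from {A, C, U} so no unplanned grammar match can arise near it.
    Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = config.transcript_length_range

    labels = list(config.subclass_mix)
    probs = np.array([config.subclass_mix[l] for l in labels], dtype=float)
    n_regions = config.n_planted_regions
    planted_subclasses = list(rng.choice(labels, size=n_regions, p=probs))
    n_folded = int(round(config.folded_fraction * n_regions))
    folded_flags = np.zeros(n_regions, dtype=bool)
    folded_flags[:n_folded] = True
    rng.shuffle(folded_flags)

    host_transcripts = rng.choice(config.n_transcripts, size=n_regions, replace=False)
    plant_for: dict[int, tuple[str, bool]] = {
        int(t): (planted_subclasses[k], bool(folded_flags[k]))
        for k, t in enumerate(host_transcripts)
    }

    seqs: dict[str, str] = {}
    annotations: dict[str, TranscriptAnnotation] = {}
    truth: list[TruthRecord] = []
    width = len(str(config.n_transcripts))
    for t in range(config.n_transcripts):
        tid = f"TX{t + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list("ACGU"), size=length))
        if t in plant_for:
            label, folded = plant_for[t]
            motif = _plant_motif(rng, label)
            start = int(rng.integers(_MARGIN, length - _MARGIN - len(motif) + 1))
            end = start + len(motif)
            seq[max(0, start - _FLANK) : start] = list(
                _h_seq(rng, start - max(0, start - _FLANK))
            )
            seq[start:end] = list(motif)
            seq[end : min(length, end + _FLANK)] = list(
                _h_seq(rng, min(length, end + _FLANK) - end)
            )
            ann = _annotate(tid, length)
            region = GRichRegion(tid, (start, end), motif, label)
            truth.append(
                TruthRecord(tid, (start, end), label, folded, locate_genic(region, ann))
            )
        seqs[tid] = "".join(seq)
        annotations[tid] = _annotate(tid, length)
    return seqs, annotations, truth


# ---------------------------------------------------------------------------
# Count noise
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean *mean* and size *theta* (Poisson as theta->inf)."""
    mean = np.asarray(mean, dtype=float)
    if not np.isfinite(theta):
        return rng.poisson(mean)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _stream_rng(seed: int, stream: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, replicate]))


# ---------------------------------------------------------------------------
# rG4-seq
# ---------------------------------------------------------------------------

def simulate_rg4seq(
    transcriptome: Mapping[str, str],
    truth: list[TruthRecord],
    condition: str,
    config: SimulationConfig,
) -> list[ProfileSet]:
    """Per-replicate rG4-seq stop/coverage profiles for one cation condition.

    Under K+ or K+/PDS a folded region stalls a ``stall_efficiency``
    fraction of RT events at its 3'-terminal base: coverage 5' of the
    region end is scaled by (1 - stall_efficiency) and the stalled events'
    stop counts land on the region's last base.  Li+ is drop-free.
    """
    if condition not in RG4SEQ_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {RG4SEQ_CONDITIONS}")
    config.validate()
    stalls: dict[str, list[tuple[int, int]]] = {}
    if condition != "Li":
        for rec in truth:
            if rec.folded:
                stalls.setdefault(rec.transcript_id, []).append(rec.interval)

    out: list[ProfileSet] = []
    cond_code = RG4SEQ_CONDITIONS.index(condition) + 1
    for rep in range(config.n_replicates):
        rng = _stream_rng(config.seed, cond_code, rep)
        profiles: ProfileSet = {}
        for tid, seq in transcriptome.items():
            n = len(seq)
            cov_mean = np.full(n, config.base_coverage)
            stop_mean = np.zeros(n)
            for (_, end) in stalls.get(tid, ()):
                # RT walks 3'->5'; events crossing the region 3' end terminate
                # at its last base, removing their coverage from everything 5'.
                stop_mean[end - 1] += cov_mean[end - 1] * config.stall_efficiency
                cov_mean[:end] *= 1.0 - config.stall_efficiency
            stop_mean += config.background_stop_rate * cov_mean
            profiles[tid] = StopCountProfile(
                tid,
                _nb_draw(rng, stop_mean, config.noise_dispersion),
                _nb_draw(rng, cov_mean, config.noise_dispersion),
                condition,
                f"rep{rep + 1}",
            )
        out.append(profiles)
    return out


# ---------------------------------------------------------------------------
# SHALiPE-Seq
# ---------------------------------------------------------------------------

def simulate_shalipe(
    transcriptome: Mapping[str, str],
    truth: list[TruthRecord],
    state: str,
    config: SimulationConfig,
) -> list[ProfileSet]:
    """Per-replicate SHALiPE stop-count profiles for one probing state.

    Everywhere the expected stop count is ``base_coverage``; in states
    where a region is folded (in vitro K+ always; in vivo per the truth
    flag) the 3'-most G of each G-tract carries ``lastG_enrichment`` times
    that rate.  The in vitro Li+ state is uniform by construction.
    """
    if state not in SHALIPE_STATES:
        raise ValueError(f"unknown state {state!r}; expected {SHALIPE_STATES}")
    config.validate()

    enriched: dict[str, list[int]] = {}
    for rec in truth:
        folded_here = state == "in_vitro_K" or (state == "in_vivo" and rec.folded)
        if not folded_here:
            continue
        start, end = rec.interval
        seq = transcriptome[rec.transcript_id][start:end]
        for (_, tract_end) in g_tracts(seq):
            enriched.setdefault(rec.transcript_id, []).append(start + tract_end - 1)

    out: list[ProfileSet] = []
    state_code = 10 + SHALIPE_STATES.index(state)
    for rep in range(config.n_replicates):
        rng = _stream_rng(config.seed, state_code, rep)
        profiles: ProfileSet = {}
        for tid, seq in transcriptome.items():
            mean = np.full(len(seq), config.base_coverage)
            for pos in enriched.get(tid, ()):
                mean[pos] *= config.lastG_enrichment
            stops = _nb_draw(rng, mean, config.noise_dispersion)
            profiles[tid] = StopCountProfile(
                tid, stops, stops.copy(), state, f"rep{rep + 1}"
            )
        out.append(profiles)
    return out


# ---------------------------------------------------------------------------
# Truth table IO
# ---------------------------------------------------------------------------

def write_truth_table(truth: list[TruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in truth],
            "start": [r.interval[0] for r in truth],
            "end": [r.interval[1] for r in truth],
            "subclass": [r.subclass for r in truth],
            "folded": [r.folded for r in truth],
            "genic_region": [r.genic_region for r in truth],
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            str(r.transcript_id),
            (int(r.start), int(r.end)),
            str(r.subclass),
            bool(r.folded),
            str(r.genic_region),
        )
        for r in df.itertuples()
    ]
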