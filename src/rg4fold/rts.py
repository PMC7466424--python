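"""Cation-dependent reverse-transcription stalling (RTS) site detection.

A folded RG4 under a stabilizing cation (K+, or K+ plus the ligand PDS)
blocks reverse transcriptase at the quadruplex 3' end, so read coverage
on the 5' side of the stall base collapses relative to the 3' side,
while under Li+ it does not.  For every candidate base the local drop

    d = log2((mean coverage in the 5' window + 1) /
             (mean coverage in the 3' window + 1))

is computed per replicate (the windows are named for transcript
orientation; the enzyme travels 3'->5', so its "downstream" is the 5'
side and a stall makes d negative).  A linear model d ~ condition is
fitted across the replicates of both conditions and the ANOVA F-test
p-value of the condition term is reported; bases with p below alpha
whose drop is more negative in the stabilizing condition are emitted.
Adjacent significant bases within 5 nt collapse to the smallest p-value,
since one quadruplex produces one stall cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import ProfileSet

__all__ = [
    "RTSSite",
    "RTSConfig",
    "detect_rts",
    "residue_meta_profile",
    "write_sites_bed",
    "write_sites_tsv",
]


@dataclass
class RTSSite:
    transcript_id: str
    position: int  # 0-based; the stall base (3'-terminal G of the RG4)
    condition_pair: str  # "K_vs_Li" or "KPDS_vs_Li"
    p_value: float
    drop_statistic: float  # mean d(test) - mean d(control); negative = stall


@dataclass
class RTSConfig:
    alpha: float = 0.05
    window: int = 10  # nt on each side of the candidate base
    min_coverage: float = 20.0  # control-channel floor on the intact (3') side
    collapse_distance: int = 5
    bh_correct: bool = False  # raw p < alpha matches the published procedure

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def _window_drops(coverage: np.ndarray, window: int) -> np.ndarray:
    """d at every interior base: log2 mean-coverage ratio, 5' window over 3' window.

    Candidate base p uses [p-window, p) on the 5' side and (p, p+window] on
    the 3' side; positions without both full windows get NaN.
    """
    n = coverage.size
    d = np.full(n, np.nan)
    if n < 2 * window + 1:
        return d
    csum = np.concatenate([[0], np.cumsum(coverage, dtype=float)])
    pos = np.arange(window, n - window)
    five = (csum[pos] - csum[pos - window]) / window
    three = (csum[pos + 1 + window] - csum[pos + 1]) / window
    d[pos] = np.log2((five + 1.0) / (three + 1.0))
    return d


def _three_prime_mean(coverage: np.ndarray, window: int) -> np.ndarray:
    n = coverage.size
    out = np.full(n, np.nan)
    if n < 2 * window + 1:
        return out
    csum = np.concatenate([[0], np.cumsum(coverage, dtype=float)])
    pos = np.arange(window, n - window)
    out[pos] = (csum[pos + 1 + window] - csum[pos + 1]) / window
    return out


def detect_rts(
    test: Sequence[ProfileSet],
    control: Sequence[ProfileSet],
    config: RTSConfig | None = None,
    condition_pair: str | None = None,
    log: list[str] | None = None,
) -> list[RTSSite]:
    """Detect bases whose coverage drop depends on the cation condition.

    *test* and *control* are per-replicate profile sets of the stabilizing
    (K+ or K+/PDS) and control (Li+) conditions.  Returns sites sorted by
    transcript and position.  Raises if either condition has fewer than
    two replicates (the condition-effect model is unidentifiable).
    """
    config = config or RTSConfig()
    config.validate()
    if len(test) < 2 or len(control) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if condition_pair is None:
        label = next(iter(test[0].values())).condition if test[0] else "test"
        condition_pair = {"K": "K_vs_Li", "K_PDS": "KPDS_vs_Li"}.get(label, f"{label}_vs_Li")

    sites: list[RTSSite] = []
    for tid in sorted(test[0]):
        n = len(test[0][tid])
        if n < 2 * config.window + 1:
            if log is not None:
                log.append(f"{tid}: transcript shorter than 2*window+1, skipped")
            continue
        d_test = np.vstack([_window_drops(reps[tid].coverage, config.window) for reps in test])
        d_ctrl = np.vstack(
            [_window_drops(reps[tid].coverage, config.window) for reps in control]
        )
        # replicates share the NaN edge positions, so plain mean propagates them
        ctrl_three = np.mean(
            np.vstack(
                [_three_prime_mean(reps[tid].coverage, config.window) for reps in control]
            ),
            axis=0,
        )
        with np.errstate(invalid="ignore"):
            valid = (
                ~np.isnan(d_test).any(axis=0)
                & ~np.isnan(d_ctrl).any(axis=0)
                & (ctrl_three >= config.min_coverage)
            )
        pos = np.flatnonzero(valid)
        if pos.size == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # groups with zero variance and zero contrast yield F = 0/0;
            # such bases are non-sites, so the NaN p is mapped to 1 below
            warnings.simplefilter("ignore")
            f_res = stats.f_oneway(d_test[:, pos], d_ctrl[:, pos], axis=0)
        pvals = np.where(np.isfinite(f_res.pvalue), f_res.pvalue, 1.0)
        if config.bh_correct:
            pvals = stats.false_discovery_control(pvals)
        contrast = d_test[:, pos].mean(axis=0) - d_ctrl[:, pos].mean(axis=0)
        hit = (pvals < config.alpha) & (contrast < 0)
        tid_sites = [
            RTSSite(tid, int(p), condition_pair, float(pv), float(c))
            for p, pv, c in zip(pos[hit], pvals[hit], contrast[hit])
        ]
        sites.extend(_collapse(tid_sites, config.collapse_distance))
    return sites


def _collapse(sites: list[RTSSite], distance: int) -> list[RTSSite]:
    """One representative per cluster of calls within *distance* nt.

    A single quadruplex yields a stall cluster whose p-values plateau over
    several bases, so the representative is the base with the strongest
    (most negative) condition contrast — the drop statistic localizes the
    stall sharply where the p-value does not — with the smaller p breaking
    ties.
    """
    if not sites:
        return sites
    sites = sorted(sites, key=lambda s: s.position)
    out: list[RTSSite] = []
    cluster = [sites[0]]
    for s in sites[1:]:
        if s.position - cluster[-1].position <= distance:
            cluster.append(s)
        else:
            out.append(min(cluster, key=lambda s: (s.drop_statistic, s.p_value)))
            cluster = [s]
    out.append(min(cluster, key=lambda s: (s.drop_statistic, s.p_value)))
    return out


# ---------------------------------------------------------------------------
# Residue composition around RTS sites
# ---------------------------------------------------------------------------

def residue_meta_profile(
    sites: Sequence[RTSSite],
    transcriptome: Mapping[str, str],
    upstream: int = 50,
    downstream: int = 25,
) -> pd.DataFrame:
    """Base-composition fractions at each offset relative to the stall base.

    Offsets run from -upstream to +downstream (0 = the RTS base); at each
    offset fractions of A/C/G/U over all in-range sites sum to 1.  Sites
    too close to a transcript end are excluded at out-of-range offsets
    only.  The last row ("background") holds transcriptome-wide base
    frequencies for comparison.
    """
    if not sites:
        raise ValueError("no sites given")
    bases = "ACGU"
    offsets = range(-upstream, downstream + 1)
    counts = {off: {b: 0 for b in bases} for off in offsets}
    for site in sites:
        seq = transcriptome[site.transcript_id]
        for off in offsets:
            p = site.position + off
            if 0 <= p < len(seq) and seq[p] in counts[off]:
                counts[off][seq[p]] += 1
    rows = []
    for off in offsets:
        total = sum(counts[off].values())
        rows.append(
            {"offset": off, **{b: (counts[off][b] / total if total else np.nan) for b in bases}}
        )
    pooled = "".join(transcriptome.values())
    n = len(pooled)
    rows.append({"offset": "background", **{b: pooled.count(b) / n for b in bases}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_sites_bed(sites: Sequence[RTSSite], path: str | Path) -> None:
    """Single-base BED intervals, score = -log10 p."""
    with open(path, "w") as fh:
        for s in sites:
            score = -np.log10(max(s.p_value, 1e-300))
            fh.write(
                f"{s.transcript_id}\t{s.position}\t{s.position + 1}\t"
                f"{s.condition_pair}\t{score:.3f}\t+\n"
            )


def write_sites_tsv(sites: Sequence[RTSSite], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sites],
            "position": [s.position for s in sites],
            "condition_pair": [s.condition_pair for s in sites],
            "p_value": [s.p_value for s in sites],
            "drop_statistic": [s.drop_statistic for s in sites],
        }
    ).to_csv(path, sep="\t", index=False)
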