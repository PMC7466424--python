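"""Competition between RG4 formation and canonical secondary structure.

A quadruplex can only fold where its guanines are not sequestered in
Watson-Crick helices, so G-rich regions capable of folding should show
depressed base-pairing probabilities (BPP) relative to their flanks.
This module obtains per-nucleotide BPP for region + 100-nt flanks from a
pluggable folding engine, bins them for a meta-profile (8 bins over the
region's guanines, 20 five-nt bins per flank, the 15 nearest the region
flagged for display), and tests the G-region vs flank contrast with a
paired t test across regions.

The engine is injected: the ViennaRNA engine (partition function,
dangling-ends model 2, 22 degrees C) is used when the bindings are
available, and tests run on synthetic stub engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif import GRichRegion

__all__ = [
    "BPPTrack",
    "MetaBins",
    "FoldingEngine",
    "ConstantEngine",
    "ArrayEngine",
    "ViennaRNAEngine",
    "compute_bpp",
    "region_track",
    "bin_meta",
    "write_meta_tsv",
]

FLANK = 100
N_G_BINS = 8
N_FLANK_BINS = 20
FLANK_BIN_WIDTH = 5
N_SHOWN_FLANK_BINS = 15


class FoldingEngine(Protocol):
    """Anything that can produce pairing probabilities for an RNA sequence.

    Engines implement ``pair_probabilities`` (list of (i, j, p), 0-based)
    or ``bpp`` (per-nucleotide marginals directly).
    """

    def pair_probabilities(self, sequence: str) -> list[tuple[int, int, float]]: ...


@dataclass
class ConstantEngine:
    """Stub: every nucleotide gets the same marginal pairing probability."""

    value: float = 0.5

    def bpp(self, sequence: str) -> np.ndarray:
        return np.full(len(sequence), self.value)


@dataclass
class ArrayEngine:
    """Stub returning pre-computed per-sequence BPP arrays."""

    tracks: dict[str, np.ndarray]

    def bpp(self, sequence: str) -> np.ndarray:
        return np.asarray(self.tracks[sequence], dtype=float)


class ViennaRNAEngine:
    """Partition-function pairing probabilities from the ViennaRNA bindings.

    Folds at *temperature_C* with dangling-ends model 2 (the ``-p -d2 -T``
    RNAfold options) and returns the upper-triangular pair probabilities.
    """

    def __init__(self, temperature_C: float = 22.0) -> None:
        try:
            import RNA  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA Python bindings not available; inject a stub engine "
                "(ConstantEngine / ArrayEngine) instead"
            ) from exc
        self._RNA = RNA
        self.temperature_C = temperature_C

    def pair_probabilities(self, sequence: str) -> list[tuple[int, int, float]]:
        RNA = self._RNA
        md = RNA.md()
        md.temperature = self.temperature_C
        md.dangles = 2
        fc = RNA.fold_compound(sequence, md)
        fc.pf()
        matrix = fc.bpp()  # 1-based, upper triangular
        out = []
        n = len(sequence)
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                p = matrix[i][j]
                if p > 0:
                    out.append((i - 1, j - 1, float(p)))
        return out


@dataclass
class BPPTrack:
    """Per-nucleotide pairing probability over region + available flanks."""

    region_id: str
    values: np.ndarray  # length = flank5 + region + flank3
    flank5_len: int
    region_len: int
    flank3_len: int
    source: str = ""

    @property
    def region_values(self) -> np.ndarray:
        return self.values[self.flank5_len : self.flank5_len + self.region_len]

    @property
    def flank5_values(self) -> np.ndarray:
        return self.values[: self.flank5_len]

    @property
    def flank3_values(self) -> np.ndarray:
        return self.values[self.flank5_len + self.region_len :]


def compute_bpp(
    sequence: str,
    engine,
    region_id: str = "",
    flank5_len: int = 0,
    flank3_len: int = 0,
) -> BPPTrack:
    """Per-nucleotide BPP of a region-with-flanks sequence.

    The marginal at position i is the sum of pair probabilities over all
    partners, clipped to 1.  *sequence* is flank5 + region + flank3; the
    flank lengths delimit the region inside it.
    """
    seq = sequence.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValueError("sequence contains non-ACGU characters")
    if hasattr(engine, "pair_probabilities"):
        values = np.zeros(len(seq))
        for i, j, p in engine.pair_probabilities(seq):
            values[i] += p
            values[j] += p
        values = np.clip(values, 0.0, 1.0)
        source = type(engine).__name__
    elif hasattr(engine, "bpp"):
        values = np.clip(np.asarray(engine.bpp(seq), dtype=float), 0.0, 1.0)
        source = type(engine).__name__
    else:
        raise TypeError("engine must provide pair_probabilities() or bpp()")
    region_len = len(seq) - flank5_len - flank3_len
    if region_len <= 0:
        raise ValueError("flanks longer than the sequence")
    return BPPTrack(region_id, values, flank5_len, region_len, flank3_len, source)


def region_track(
    region: GRichRegion,
    transcriptome,
    engine,
    flank: int = FLANK,
) -> BPPTrack:
    """Fold a region in its transcript context with up to *flank* nt each side."""
    seq = transcriptome[region.transcript_id]
    lo = max(0, region.start - flank)
    hi = min(len(seq), region.end + flank)
    track = compute_bpp(
        seq[lo:hi],
        engine,
        region_id=f"{region.transcript_id}:{region.start}-{region.end}",
        flank5_len=region.start - lo,
        flank3_len=hi - region.end,
    )
    return track


# ---------------------------------------------------------------------------
# Meta-binning and the paired contrast
# ---------------------------------------------------------------------------

@dataclass
class MetaBins:
    """Occupancy-weighted bin means pooled over regions.

    ``g_bins``: 8 positional bins over each region's guanines.
    ``flank5_bins`` / ``flank3_bins``: 20 consecutive 5-nt bins per flank,
    ordered outward-in for the 5' flank and inward-out for the 3' flank;
    ``shown_flank_bins`` flags the 15 bins nearest the region on each
    side.  Bins with zero occupancy are NaN (missing), never zero.
    """

    g_bins: np.ndarray
    flank5_bins: np.ndarray
    flank3_bins: np.ndarray
    shown_flank5: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    shown_flank3: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    t_statistic: float | None = None
    p_value: float | None = None
    n_regions: int = 0


def _accumulate(sums: np.ndarray, counts: np.ndarray, idx: int, vals: np.ndarray) -> None:
    if vals.size:
        sums[idx] += vals.sum()
        counts[idx] += vals.size


def bin_meta(
    tracks: Sequence[BPPTrack],
    regions: Sequence[GRichRegion],
) -> MetaBins:
    """Pool BPP values into the meta-profile bins and test the G/flank contrast.

    Each region's guanine positions are split positionally into 8 bins of
    near-equal occupancy; each flank into 20 consecutive 5-nt bins counted
    from the region edge outward.  Bin means are occupancy-weighted sums
    over all regions, so pooling half-sets reproduces the joint result.
    The paired two-sided t test compares each region's mean-G BPP with its
    mean-flank BPP; with fewer than two regions the test is undefined and
    only the bins are returned.
    """
    if len(tracks) != len(regions):
        raise ValueError("one track per region required")
    g_sum = np.zeros(N_G_BINS)
    g_cnt = np.zeros(N_G_BINS)
    f5_sum = np.zeros(N_FLANK_BINS)
    f5_cnt = np.zeros(N_FLANK_BINS)
    f3_sum = np.zeros(N_FLANK_BINS)
    f3_cnt = np.zeros(N_FLANK_BINS)
    g_means = []
    flank_means = []
    for track, region in zip(tracks, regions):
        seq = region.sequence
        g_pos = np.array([k for k, b in enumerate(seq) if b == "G"], dtype=int)
        g_vals = track.region_values[g_pos] if g_pos.size else np.zeros(0)
        for b, chunk in enumerate(np.array_split(g_vals, N_G_BINS)):
            _accumulate(g_sum, g_cnt, b, chunk)
        # flank bins are counted from the region edge outward on both sides
        f5 = track.flank5_values[::-1]  # index 0 = nucleotide adjacent to region
        f3 = track.flank3_values
        for b in range(N_FLANK_BINS):
            lo, hi = b * FLANK_BIN_WIDTH, (b + 1) * FLANK_BIN_WIDTH
            _accumulate(f5_sum, f5_cnt, b, f5[lo:hi])
            _accumulate(f3_sum, f3_cnt, b, f3[lo:hi])
        flank_vals = np.concatenate([track.flank5_values, track.flank3_values])
        if g_vals.size and flank_vals.size:
            g_means.append(g_vals.mean())
            flank_means.append(flank_vals.mean())

    with np.errstate(invalid="ignore"):
        g_bins = np.where(g_cnt > 0, g_sum / np.maximum(g_cnt, 1), np.nan)
        f5_bins = np.where(f5_cnt > 0, f5_sum / np.maximum(f5_cnt, 1), np.nan)
        f3_bins = np.where(f3_cnt > 0, f3_sum / np.maximum(f3_cnt, 1), np.nan)
    shown = np.arange(N_FLANK_BINS) < N_SHOWN_FLANK_BINS
    t_stat = p_val = None
    if len(g_means) >= 2:
        diffs = np.asarray(g_means) - np.asarray(flank_means)
        if np.ptp(diffs) == 0:
            # degenerate paired test: zero variance of differences
            t_stat, p_val = (0.0, 1.0) if diffs[0] == 0 else (np.inf, 0.0)
        else:
            res = stats.ttest_rel(g_means, flank_means)
            t_stat, p_val = float(res.statistic), float(res.pvalue)
    return MetaBins(
        g_bins, f5_bins, f3_bins, shown, shown, t_stat, p_val, len(g_means)
    )


def write_meta_tsv(meta: MetaBins, path: str | Path) -> None:
    rows = []
    for b, v in enumerate(meta.flank5_bins):
        rows.append({"part": "flank5", "bin": b, "mean_bpp": v, "shown": bool(meta.shown_flank5[b])})
    for b, v in enumerate(meta.g_bins):
        rows.append({"part": "region_G", "bin": b, "mean_bpp": v, "shown": True})
    for b, v in enumerate(meta.flank3_bins):
        rows.append({"part": "flank3", "bin": b, "mean_bpp": v, "shown": bool(meta.shown_flank3[b])})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if meta.p_value is not None:
            fh.write(
                f"# paired t test (G vs flank): t={meta.t_statistic:.4g} "
                f"p={meta.p_value:.4g} n={meta.n_regions}\n"
            )
        df.to_csv(fh, sep="\t", index=False)
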