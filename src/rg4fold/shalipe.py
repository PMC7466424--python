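"""SHALiPE profile statistics: the Gini index and the in vivo folding score.

The acylation probe NAI preferentially modifies the 3'-most G of each
G-tract when a quadruplex is folded, so the RT-stop profile over the
tract guanines is highly uneven (high Gini) in the folded state and near
uniform (low Gini) when unfolded.  For *n* selected residues with stop
counts r_i and mean r-bar,

    Gini = sum_i sum_j |r_i - r_j| / (2 n^2 r-bar)

which ranges from 0 (uniform) to (n-1)/n (a point mass).  The in vivo
folding score rescales the in vivo Gini between the unfolded (in vitro
Li+) and folded (in vitro K+) benchmarks of the same region:

    FS = (Gini_vivo - Gini_Li) / (Gini_K - Gini_Li)

0 means unfolded in vivo, 1 fully folded; individual regions may exceed
1.  Regions enter the scored set only if Gini_K / Gini_Li >= 1.1 (the
region is quadruplex-capable in vitro) and the tract guanines average
>= 50 reads/nt in every state (the profile is quantifiable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .counts import ProfileSet
from .motif import GRichRegion, g_tracts

__all__ = [
    "ShalipeRegionProfile",
    "GiniResult",
    "FoldingScoreRecord",
    "LandscapeSummary",
    "build_region_profile",
    "gini_value",
    "gini_value_quadratic",
    "gini",
    "control_ginis",
    "folding_score",
    "score_regions",
    "summarize_landscape",
    "write_records_tsv",
]

STATES = ("in_vitro_Li", "in_vitro_K", "in_vivo")
SELECTIONS = ("tract_Gs", "nontract_Gs", "nonG")


@dataclass
class ShalipeRegionProfile:
    """Per-base stop counts of one region in one probing state."""

    region: GRichRegion
    state: str
    counts: np.ndarray
    base: str  # region sequence
    in_tract: np.ndarray  # per-position bool: G inside a G-tract (run >= 2)

    def select(self, selection: str) -> np.ndarray:
        is_g = np.frombuffer(self.base.encode(), dtype="S1") == b"G"
        if selection == "tract_Gs":
            mask = self.in_tract
        elif selection == "nontract_Gs":
            mask = is_g & ~self.in_tract
        elif selection == "nonG":
            mask = ~is_g
        else:
            raise ValueError(f"unknown selection {selection!r}")
        return self.counts[mask]


@dataclass
class GiniResult:
    value: float
    n: int
    mean_reads: float
    selection: str


@dataclass
class FoldingScoreRecord:
    region_id: str
    subclass: str
    genic_region: str
    gini_vivo: float | None
    gini_li: float | None
    gini_k: float | None
    folding_score: float | None
    passes_ratio_filter: bool
    passes_coverage_filter: bool


def build_region_profile(
    region: GRichRegion, profiles: ProfileSet, state: str
) -> ShalipeRegionProfile:
    """Restrict a (merged) transcriptome profile to one region's interval."""
    prof = profiles[region.transcript_id]
    start, end = region.interval
    seq = region.sequence
    in_tract = np.zeros(len(seq), dtype=bool)
    for a, b in g_tracts(seq):
        in_tract[a:b] = True
    return ShalipeRegionProfile(
        region, state, prof.stops[start:end].astype(float), seq, in_tract
    )


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------

def gini_value(r: np.ndarray) -> float:
    """Gini of a count vector via the sorted O(n log n) identity.

    Equivalent to the literal double sum: for sorted r,
    sum_ij |r_i - r_j| = 2 * sum_k (2k + 1 - n) r_(k)  (k 0-based).
    """
    r = np.asarray(r, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("Gini needs at least two residues")
    rbar = r.mean()
    if rbar == 0:
        raise ZeroDivisionError("all counts zero; Gini undefined")
    rs = np.sort(r)
    k = np.arange(n)
    total = 2.0 * np.sum((2 * k + 1 - n) * rs)
    return float(total / (2.0 * n * n * rbar))


def gini_value_quadratic(r: np.ndarray) -> float:
    """Literal O(n^2) double sum; the defining form, kept as the oracle."""
    r = np.asarray(r, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("Gini needs at least two residues")
    rbar = r.mean()
    if rbar == 0:
        raise ZeroDivisionError("all counts zero; Gini undefined")
    total = np.abs(r[:, None] - r[None, :]).sum()
    return float(total / (2.0 * n * n * rbar))


def gini(profile: ShalipeRegionProfile, selection: str = "tract_Gs") -> GiniResult | None:
    """Eq.-style Gini over a residue selection of one region profile.

    ``tract_Gs`` (guanines inside G-tracts) is the headline statistic;
    ``nontract_Gs`` and ``nonG`` are negative controls.  Returns None when
    all selected counts are zero (the mean in the denominator vanishes);
    raises on selections with fewer than two residues.
    """
    r = profile.select(selection)
    if r.size < 2:
        raise ValueError(
            f"selection {selection!r} has {r.size} residues in region "
            f"{profile.region.transcript_id}:{profile.region.interval}"
        )
    if r.sum() == 0:
        return None
    return GiniResult(gini_value(r), int(r.size), float(r.mean()), selection)


def control_ginis(profile: ShalipeRegionProfile) -> dict[str, GiniResult | None]:
    """Gini on tract Gs plus the two control selections, where defined."""
    out: dict[str, GiniResult | None] = {}
    for sel in SELECTIONS:
        try:
            out[sel] = gini(profile, sel)
        except ValueError:
            out[sel] = None
    return out


# ---------------------------------------------------------------------------
# Folding score
# ---------------------------------------------------------------------------

def folding_score(gini_vivo: float, gini_li: float, gini_k: float) -> float:
    """Rescale the in vivo Gini between the in vitro Li+ (0) and K+ (1) anchors."""
    denom = gini_k - gini_li
    if denom == 0:
        raise ZeroDivisionError("Gini(K) equals Gini(Li); folding score undefined")
    return (gini_vivo - gini_li) / denom


def score_regions(
    regions: Iterable[GRichRegion],
    profiles_by_state: Mapping[str, ProfileSet],
    ratio_min: float = 1.1,
    min_mean_reads: float = 50.0,
    log: list[str] | None = None,
) -> list[FoldingScoreRecord]:
    """Tract-G Ginis in all three states, the two inclusion filters, and FS.

    Non-passing regions are retained with their filter flags and no score.
    The coverage filter requires mean tract-G stop counts >= *min_mean_reads*
    in every state (strictest reading; configurable).
    """
    missing = [s for s in STATES if s not in profiles_by_state]
    if missing:
        raise ValueError(f"missing profile states: {missing}")
    records: list[FoldingScoreRecord] = []
    for idx, region in enumerate(regions):
        region_id = f"{region.transcript_id}:{region.start}-{region.end}"
        try:
            results = {
                s: gini(build_region_profile(region, profiles_by_state[s], s))
                for s in STATES
            }
        except (KeyError, ValueError) as exc:
            if log is not None:
                log.append(f"{region_id}: skipped ({exc})")
            continue
        if any(v is None for v in results.values()):
            if log is not None:
                log.append(f"{region_id}: zero tract-G counts in some state; skipped")
            continue
        g_li = results["in_vitro_Li"]
        g_k = results["in_vitro_K"]
        g_vivo = results["in_vivo"]
        passes_cov = all(v.mean_reads >= min_mean_reads for v in results.values())
        # multiplicative form of Gini_K / Gini_Li >= ratio_min; a zero Li+
        # Gini with a positive K+ Gini is an infinite ratio and passes
        passes_ratio = g_k.value > 0 and g_k.value >= ratio_min * g_li.value
        fs = None
        if passes_cov and passes_ratio and g_k.value != g_li.value:
            fs = folding_score(g_vivo.value, g_li.value, g_k.value)
        records.append(
            FoldingScoreRecord(
                region_id,
                region.subclass,
                region.genic_region,
                g_vivo.value,
                g_li.value,
                g_k.value,
                fs,
                passes_ratio,
                passes_cov,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Landscape summaries
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSummary:
    n_scored: int
    median_fs: float
    n_positive: int
    frac_positive: float
    subclass_anova_p: float | None
    subclass_tukey: pd.DataFrame | None
    genic_anova_p: float | None
    genic_tukey: pd.DataFrame | None
    group_sizes: dict[str, dict[str, int]]


def _group_test(
    values: Sequence[float], labels: Sequence[str], log: list[str] | None
) -> tuple[float | None, pd.DataFrame | None, dict[str, int]]:
    df = pd.DataFrame({"fs": values, "group": labels})
    sizes = df["group"].value_counts().to_dict()
    keep = [g for g, n in sizes.items() if n >= 2]
    for g in sizes:
        if g not in keep and log is not None:
            log.append(f"group {g!r} has < 2 members; excluded from ANOVA")
    df = df[df["group"].isin(keep)]
    if df["group"].nunique() < 2:
        return None, None, sizes
    groups = [grp["fs"].to_numpy() for _, grp in df.groupby("group")]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0, None, sizes  # no variance anywhere: nothing to explain
    p = float(stats.f_oneway(*groups).pvalue)
    tukey = pairwise_tukeyhsd(df["fs"].to_numpy(), df["group"].to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return p, tukey_df, sizes


def summarize_landscape(
    records: Sequence[FoldingScoreRecord], log: list[str] | None = None
) -> LandscapeSummary:
    """Median FS, fraction above 0, and per-subclass / per-genic-region tests.

    Only records with a defined folding score enter the summary; groups are
    compared with one-way ANOVA and a Tukey HSD post hoc test.
    """
    scored = [r for r in records if r.folding_score is not None]
    if not scored:
        raise ValueError("no records with a folding score")
    fs = np.array([r.folding_score for r in scored])
    sub_p, sub_tukey, sub_sizes = _group_test(fs, [r.subclass for r in scored], log)
    genic_labels = [r.genic_region or "unknown" for r in scored]
    gen_p, gen_tukey, gen_sizes = _group_test(fs, genic_labels, log)
    return LandscapeSummary(
        n_scored=len(scored),
        median_fs=float(np.median(fs)),
        n_positive=int((fs > 0).sum()),
        frac_positive=float((fs > 0).mean()),
        subclass_anova_p=sub_p,
        subclass_tukey=sub_tukey,
        genic_anova_p=gen_p,
        genic_tukey=gen_tukey,
        group_sizes={"subclass": sub_sizes, "genic_region": gen_sizes},
    )


def write_records_tsv(records: Sequence[FoldingScoreRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
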