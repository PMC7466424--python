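"""The RG4 sequence grammar.

Six structural subclasses of RNA G-quadruplex are defined as regular
expressions over the RNA alphabet, where ``N`` = A/C/G/U and ``H`` =
A/C/U (any base but G):

==========  ==============================================================
G3L1-15     G3 N1-15 G3 N1-15 G3 N1-15 G3      (three-quartet, loops 1-15)
G3VL1-9     G3 N1-9 G3 N1-9 G3 N1-9 G2  or  G2 N1-9 G3 N1-9 G3 N1-9 G3
            (guanine vacancy: one quartet layer is missing a G)
G3bulge     G3 N1-9 B N1-9 B N1-9 G3 with B = GGHG or GHGG
            (one non-G bulge inside a middle tract)
G2L1-2      G2 N1-2 G2 N1-2 G2 N1-2 G2         (two-quartet, loops 1-2)
G2L1-4      loops 1-4
G2L1-9      loops 1-9
==========  ==============================================================

Assignment is hierarchical: the subclasses are tried in the order listed
and the first one matching anywhere in the query window wins, so a
region is labelled with the most structured class its sequence supports.

Transcriptome-wide prediction uses the loose two-quartet grammar
(G>=2, loops 1-15, four tracts) with a non-greedy, non-overlapping scan:
at each start the shortest match is taken and scanning resumes after its
end, so predicted intervals are pairwise disjoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .counts import ProfileSet, TranscriptAnnotation
    from .rts import RTSSite

__all__ = [
    "SUBCLASSES",
    "Subclass",
    "GRichRegion",
    "g_tracts",
    "classify_window",
    "classify_upstream",
    "predict_transcriptome",
    "select_undetected",
    "locate_genic",
    "write_regions_tsv",
    "read_regions_tsv",
    "write_regions_bed",
]

_N = "[ACGU]"
_H = "[ACU]"
_B = f"(?:GG{_H}G|G{_H}GG)"  # one-nucleotide bulge inside a 3-G tract


@dataclass(frozen=True)
class Subclass:
    label: str
    pattern: str
    priority: int  # 1 = most structured, tried first

    @property
    def regex(self) -> re.Pattern[str]:
        return _compiled(self.pattern)


@lru_cache(maxsize=None)
def _compiled(pattern: str) -> re.Pattern[str]:
    return re.compile(pattern)


SUBCLASSES: tuple[Subclass, ...] = (
    Subclass("G3L1-15", f"GGG(?:{_N}{{1,15}}?GGG){{3}}", 1),
    Subclass(
        "G3VL1-9",
        f"(?:GGG(?:{_N}{{1,9}}?GGG){{2}}{_N}{{1,9}}?GG)|(?:GG(?:{_N}{{1,9}}?GGG){{3}})",
        2,
    ),
    Subclass("G3bulge", f"GGG{_N}{{1,9}}?{_B}{_N}{{1,9}}?{_B}{_N}{{1,9}}?GGG", 3),
    Subclass("G2L1-2", f"GG(?:{_N}{{1,2}}?GG){{3}}", 4),
    Subclass("G2L1-4", f"GG(?:{_N}{{1,4}}?GG){{3}}", 5),
    Subclass("G2L1-9", f"GG(?:{_N}{{1,9}}?GG){{3}}", 6),
)


@dataclass
class GRichRegion:
    """A G-rich interval with its structural subclass assignment.

    ``interval`` is 0-based half-open in transcript coordinates;
    ``tract_intervals`` are the maximal G-runs (>=2 G) inside the match,
    relative to the transcript; ``loop_lengths`` the gaps between
    consecutive tracts.
    """

    transcript_id: str
    interval: tuple[int, int]
    sequence: str
    subclass: str  # subclass label, "predicted" or "undetected"
    tract_intervals: list[tuple[int, int]] = field(default_factory=list)
    loop_lengths: list[int] = field(default_factory=list)
    anchor_rts: "RTSSite | None" = None
    genic_region: str = ""
    flank5: str = ""
    flank3: str = ""

    @property
    def start(self) -> int:
        return self.interval[0]

    @property
    def end(self) -> int:
        return self.interval[1]


def g_tracts(sequence: str, min_run: int = 2) -> list[tuple[int, int]]:
    """Maximal runs of >= *min_run* consecutive G, as local intervals."""
    return [
        (m.start(), m.end())
        for m in re.finditer(f"G{{{min_run},}}", sequence)
    ]


def _make_region(
    transcript_id: str,
    seq: str,
    start: int,
    end: int,
    subclass: str,
    anchor: "RTSSite | None" = None,
) -> GRichRegion:
    sub = seq[start:end]
    tracts = [(start + a, start + b) for a, b in g_tracts(sub)]
    loops = [tracts[i + 1][0] - tracts[i][1] for i in range(len(tracts) - 1)]
    return GRichRegion(
        transcript_id, (start, end), sub, subclass, tracts, loops, anchor
    )


# ---------------------------------------------------------------------------
# Hierarchical classification of RTS-upstream windows
# ---------------------------------------------------------------------------

def classify_window(window: str) -> tuple[Subclass, int, int] | None:
    """First-match-wins subclass assignment of a sequence window.

    Subclasses are tried in priority order; within the winning subclass the
    match whose 3' end lies furthest 3' (closest to the RTS anchored at the
    window end) is chosen, taking the shortest match at each start.
    Returns ``(subclass, start, end)`` relative to the window, or None.
    """
    window = window.upper().replace("T", "U")
    for sub in SUBCLASSES:
        best: tuple[int, int] | None = None
        for i in range(len(window)):
            m = sub.regex.match(window, i)
            if m is None:
                continue
            cand = (m.start(), m.end())
            if best is None or cand[1] > best[1] or (cand[1] == best[1] and cand[0] > best[0]):
                best = cand
        if best is not None:
            return sub, best[0], best[1]
    return None


def classify_upstream(
    site: "RTSSite",
    transcriptome: Mapping[str, str],
    window: int = 50,
    slack: int = 3,
) -> GRichRegion | None:
    """Assign the G-rich region upstream of an RTS site to a subclass.

    The query window is the *window* nucleotides ending at (and including)
    the stall base: under the stop-count convention the stall base is the
    3'-terminal G of the quadruplex, so the window contains the motif.
    Because stall localization is only a-couple-of-nucleotides accurate,
    the window is extended *slack* nt past the site so a motif is not
    truncated when the called base sits just inside its final G-tract.
    A window truncated at the transcript start is scanned as-is.
    """
    seq = transcriptome[site.transcript_id]
    lo = max(0, site.position + 1 - window)
    win = seq[lo : min(len(seq), site.position + 1 + slack)]
    hit = classify_window(win)
    if hit is None:
        return None
    sub, s, e = hit
    return _make_region(site.transcript_id, seq, lo + s, lo + e, sub.label, site)


# ---------------------------------------------------------------------------
# Transcriptome-wide prediction (non-greedy, non-overlapping scan)
# ---------------------------------------------------------------------------

def _min_match_end(
    seq: str, start: int, n_tracts: int, min_tract: int, max_loop: int
) -> int | None:
    """Minimal end of a GxL grammar match starting exactly at *start*.

    Dynamic programme over (position, tracts remaining); tracts are taken
    at their minimum width, extra guanines being absorbed by the N loops.
    """
    n = len(seq)
    memo: dict[tuple[int, int], int | None] = {}

    def rec(pos: int, left: int) -> int | None:
        key = (pos, left)
        if key in memo:
            return memo[key]
        out: int | None = None
        if pos + min_tract <= n and seq[pos : pos + min_tract] == "G" * min_tract:
            tract_end = pos + min_tract
            if left == 1:
                out = tract_end
            else:
                for loop in range(1, max_loop + 1):
                    nxt = tract_end + loop
                    if nxt >= n:
                        break
                    sub = rec(nxt, left - 1)
                    if sub is not None and (out is None or sub < out):
                        out = sub
        memo[key] = out
        return out

    return rec(start, n_tracts)


def predict_transcriptome(
    transcriptome: Mapping[str, str],
    min_tract: int = 2,
    max_loop: int = 15,
    n_tracts: int = 4,
) -> list[GRichRegion]:
    """Scan every transcript for putative RG4 motifs (G>=2, loops 1-15, x4).

    Left-to-right, non-greedy (shortest match at each feasible start),
    non-overlapping (scanning resumes after each match), so the returned
    intervals are pairwise disjoint and sorted.
    """
    regions: list[GRichRegion] = []
    for tid in transcriptome:
        seq = transcriptome[tid].upper().replace("T", "U")
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] != "G":
                i += 1
                continue
            end = _min_match_end(seq, i, n_tracts, min_tract, max_loop)
            if end is None:
                i += 1
            else:
                regions.append(_make_region(tid, seq, i, end, "predicted"))
                i = end
    return regions


# ---------------------------------------------------------------------------
# Undetected G-rich regions
# ---------------------------------------------------------------------------

def select_undetected(
    predicted: Iterable[GRichRegion],
    detected: Iterable[GRichRegion],
    li_profiles: "ProfileSet",
    transcriptome: Mapping[str, str],
    min_li_coverage: float = 60.0,
    flank: int = 50,
    log: list[str] | None = None,
) -> list[GRichRegion]:
    """Predicted regions that the stalling assay had power to see but did not.

    Keeps predicted regions with mean Li+ (control) rG4-seq coverage above
    *min_li_coverage*, no overlap with any detected region, and a full
    *flank*-nt sequence available on both sides; the flanks are attached.
    """
    by_tid: dict[str, list[GRichRegion]] = {}
    for d in detected:
        by_tid.setdefault(d.transcript_id, []).append(d)

    out: list[GRichRegion] = []
    for reg in predicted:
        tid = reg.transcript_id
        if tid not in li_profiles:
            if log is not None:
                log.append(f"no Li+ profile for {tid}; region {reg.interval} dropped")
            continue
        cov = li_profiles[tid].coverage[reg.start : reg.end]
        if cov.size == 0 or float(cov.mean()) <= min_li_coverage:
            continue
        if any(d.start < reg.end and reg.start < d.end for d in by_tid.get(tid, [])):
            continue
        seq = transcriptome[tid]
        if reg.start < flank or reg.end + flank > len(seq):
            continue
        kept = GRichRegion(
            tid,
            reg.interval,
            reg.sequence,
            "undetected",
            reg.tract_intervals,
            reg.loop_lengths,
            flank5=seq[reg.start - flank : reg.start],
            flank3=seq[reg.end : reg.end + flank],
        )
        out.append(kept)
    return out


# ---------------------------------------------------------------------------
# Genic localization
# ---------------------------------------------------------------------------

def locate_genic(region: GRichRegion, annotation: "TranscriptAnnotation | None") -> str:
    """Genic label of a region by the midpoint rule.

    The label is the annotated feature (5'UTR / CDS / 3'UTR) containing the
    region midpoint; a midpoint covered by no single feature of an annotated
    transcript yields "spanning"; an unannotated transcript yields "unknown".
    """
    if annotation is None:
        return "unknown"
    mid = (region.start + region.end) // 2
    for name, start, end in annotation.features():
        if start <= mid < end:
            return name
    if annotation.features():
        return "spanning"
    return "unknown"


# ---------------------------------------------------------------------------
# Region file formats
# ---------------------------------------------------------------------------

def write_regions_tsv(regions: Iterable[GRichRegion], path: str | Path) -> None:
    rows = []
    for r in regions:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "start": r.start,
                "end": r.end,
                "subclass": r.subclass,
                "sequence": r.sequence,
                "tracts": ";".join(f"{a}-{b}" for a, b in r.tract_intervals),
                "loop_lengths": ";".join(str(l) for l in r.loop_lengths),
                "genic_region": r.genic_region,
                "anchor_rts": r.anchor_rts.position if r.anchor_rts else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "subclass", "sequence",
            "tracts", "loop_lengths", "genic_region", "anchor_rts",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_regions_tsv(path: str | Path) -> list[GRichRegion]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        tracts = [
            (int(a), int(b))
            for a, b in (t.split("-") for t in str(r.tracts).split(";") if t)
        ]
        loops = [int(x) for x in str(r.loop_lengths).split(";") if x]
        out.append(
            GRichRegion(
                str(r.transcript_id),
                (int(r.start), int(r.end)),
                str(r.sequence),
                str(r.subclass),
                tracts,
                loops,
                genic_region=str(r.genic_region),
            )
        )
    return out


def write_regions_bed(regions: Iterable[GRichRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.subclass}\t0\t+\n")
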