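"""Per-base RT-stop count and coverage profiles, and their file formats.

The substrate of both the rG4-seq and SHALiPE analyses is a pair of
per-transcript integer arrays: ``stops[i]`` (reverse-transcription stop
count assigned to nucleotide *i*) and ``coverage[i]`` (reads overlapping
nucleotide *i*), for one condition and one replicate.

Stop-position convention
------------------------
Reverse transcriptase extends the cDNA toward the template 5' end, so a
read whose 5'-most aligned base sits at transcript position ``i``
(0-based) implies the enzyme terminated at the neighbouring template
nucleotide: the stop is assigned to ``i - 1``.  Reads starting at
position 0 ran off the 5' end and are tallied in a per-transcript
run-off bucket instead of at any position.  The synthetic-data generator
uses the same convention, so simulated and extracted profiles are
directly comparable.

All coordinates are 0-based half-open internally; GFF3's 1-based closed
intervals are converted at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "StopCountProfile",
    "ProfileSet",
    "TranscriptAnnotation",
    "MergeResult",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_stop_counts",
    "write_stop_counts",
    "extract_stop_counts",
    "merge_replicates",
]


@dataclass
class StopCountProfile:
    """Stop counts and coverage for one transcript / condition / replicate."""

    transcript_id: str
    stops: np.ndarray
    coverage: np.ndarray
    condition: str = ""
    replicate: str = ""
    run_off: int = 0  # reads whose 5' end is at position 0

    def __post_init__(self) -> None:
        self.stops = np.asarray(self.stops, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.stops.shape != self.coverage.shape:
            raise ValueError("stops and coverage must have equal length")
        if (self.stops < 0).any() or (self.coverage < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.stops.size


#: One condition+replicate across a transcriptome: transcript_id -> profile.
ProfileSet = dict[str, StopCountProfile]


@dataclass
class TranscriptAnnotation:
    """UTR/CDS layout of one transcript, 0-based half-open."""

    transcript_id: str
    utr5: tuple[int, int] | None
    cds: tuple[int, int] | None
    utr3: tuple[int, int] | None

    def features(self) -> list[tuple[str, int, int]]:
        out = []
        for name, iv in (("5'UTR", self.utr5), ("CDS", self.cds), ("3'UTR", self.utr3)):
            if iv is not None:
                out.append((name, iv[0], iv[1]))
        return out


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read transcript sequences; uppercased, T mapped to U."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_GFF_TYPE = {"5'UTR": "five_prime_UTR", "CDS": "CDS", "3'UTR": "three_prime_UTR"}
_GFF_TYPE_INV = {v: k for k, v in _GFF_TYPE.items()}


def write_gff3(annotations: Iterable[TranscriptAnnotation], path: str | Path) -> None:
    """Write transcript-space UTR/CDS features (GFF3, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            for name, start, end in ann.features():
                fh.write(
                    f"{ann.transcript_id}\trg4fold\t{_GFF_TYPE[name]}\t"
                    f"{start + 1}\t{end}\t.\t+\t.\tID={ann.transcript_id}:{_GFF_TYPE[name]}\n"
                )


def read_gff3(path: str | Path) -> dict[str, TranscriptAnnotation]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    out: dict[str, TranscriptAnnotation] = {}
    for tid, grp in df.groupby("seqid", sort=False):
        ivs: dict[str, tuple[int, int]] = {}
        for _, row in grp.iterrows():
            if row["type"] in _GFF_TYPE_INV:
                ivs[_GFF_TYPE_INV[row["type"]]] = (int(row["start"]) - 1, int(row["end"]))
        out[str(tid)] = TranscriptAnnotation(
            str(tid), ivs.get("5'UTR"), ivs.get("CDS"), ivs.get("3'UTR")
        )
    return out


# ---------------------------------------------------------------------------
# Stop-count TSV dialect
# ---------------------------------------------------------------------------

def write_stop_counts(profiles: ProfileSet, path: str | Path) -> None:
    """One condition+replicate per file; condition/replicate in header comments."""
    profs = list(profiles.values())
    cond = profs[0].condition if profs else ""
    rep = profs[0].replicate if profs else ""
    with open(path, "w") as fh:
        fh.write(f"# condition={cond}\n# replicate={rep}\n")
        fh.write("transcript_id\tposition\tstop_count\tcoverage\n")
        for p in profs:
            for i in range(len(p)):
                fh.write(f"{p.transcript_id}\t{i}\t{p.stops[i]}\t{p.coverage[i]}\n")


def read_stop_counts(path: str | Path) -> ProfileSet:
    cond = rep = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "condition":
                cond = val
            elif key.strip() == "replicate":
                rep = val
    df = pd.read_csv(path, sep="\t", comment="#")
    out: ProfileSet = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        n = int(grp["position"].max()) + 1
        stops = np.zeros(n, dtype=np.int64)
        cov = np.zeros(n, dtype=np.int64)
        stops[grp["position"].to_numpy()] = grp["stop_count"].to_numpy()
        cov[grp["position"].to_numpy()] = grp["coverage"].to_numpy()
        out[str(tid)] = StopCountProfile(str(tid), stops, cov, cond, rep)
    return out


# ---------------------------------------------------------------------------
# Extraction from transcript-space alignments
# ---------------------------------------------------------------------------

def _is_multimapped(read: pysam.AlignedSegment) -> bool:
    if read.is_secondary or read.is_supplementary:
        return True
    try:
        return read.get_tag("NH") > 1
    except KeyError:
        return False


def extract_stop_counts(
    alignments: str | Path | pysam.AlignmentFile,
    transcriptome: Mapping[str, str],
    condition: str = "",
    replicate: str = "",
) -> ProfileSet:
    """Extract per-base stop counts and coverage from a SAM/BAM in transcript space.

    Only uniquely mapped reads are counted (secondary/supplementary records
    and NH>1 are skipped).  A read starting at position ``i`` increments
    ``stops[i-1]``; reads starting at 0 go to the profile's run-off bucket.
    Coverage is incremented at every aligned reference position.

    Raises
    ------
    KeyError
        If an alignment references a transcript absent from *transcriptome*.
    """
    profiles: ProfileSet = {
        tid: StopCountProfile(
            tid,
            np.zeros(len(seq), dtype=np.int64),
            np.zeros(len(seq), dtype=np.int64),
            condition,
            replicate,
        )
        for tid, seq in transcriptome.items()
    }
    owned = not isinstance(alignments, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignments), check_sq=False)
        if owned
        else alignments
    )
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or _is_multimapped(read):
                continue
            tid = read.reference_name
            if tid not in profiles:
                raise KeyError(f"alignment references unknown transcript {tid!r}")
            prof = profiles[tid]
            start = read.reference_start
            if start == 0:
                prof.run_off += 1
            else:
                prof.stops[start - 1] += 1
            for pos in read.get_reference_positions():
                prof.coverage[pos] += 1
    finally:
        if owned:
            af.close()
    return profiles


# ---------------------------------------------------------------------------
# Replicate merging
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    """Sum-merged profiles plus the replicate agreement that justified merging."""

    profiles: ProfileSet
    correlations: dict[tuple[str, str], float] = field(default_factory=dict)


def merge_replicates(replicates: list[ProfileSet], min_correlation: float = 0.9) -> MergeResult:
    """Sum stop counts and coverage across replicates of one condition.

    Pairwise Pearson correlation of log-transformed per-transcript stop
    totals is reported; a correlation below *min_correlation* triggers a
    warning but never a failure (sums preserve count statistics either way).
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to merge")
    conditions = {p.condition for reps in replicates for p in reps.values()}
    if len(conditions) > 1:
        raise ValueError(f"replicates of mixed conditions: {sorted(conditions)}")
    condition = conditions.pop() if conditions else ""
    tids = list(replicates[0])
    for reps in replicates[1:]:
        if set(reps) != set(tids):
            raise ValueError("replicates cover different transcript sets")

    merged: ProfileSet = {}
    for tid in tids:
        stops = sum(reps[tid].stops for reps in replicates)
        cov = sum(reps[tid].coverage for reps in replicates)
        run_off = sum(reps[tid].run_off for reps in replicates)
        merged[tid] = StopCountProfile(tid, stops, cov, condition, "merged", run_off)

    totals = {
        _rep_label(reps, i): np.log1p([reps[tid].stops.sum() for tid in tids])
        for i, reps in enumerate(replicates)
    }
    labels = list(totals)
    correlations = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if len(tids) < 2:
                correlations[(labels[i], labels[j])] = float("nan")
                continue  # correlation over a single transcript is undefined
            r = float(np.corrcoef(totals[labels[i]], totals[labels[j]])[0, 1])
            correlations[(labels[i], labels[j])] = r
            if r < min_correlation:
                warnings.warn(
                    f"replicates {labels[i]}/{labels[j]} correlate at {r:.3f} "
                    f"< {min_correlation}",
                    stacklevel=2,
                )
    return MergeResult(merged, correlations)


def _rep_label(reps: ProfileSet, idx: int) -> str:
    for p in reps.values():
        if p.replicate:
            return p.replicate
    return f"rep{idx + 1}"
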