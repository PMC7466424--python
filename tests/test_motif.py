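"""The RG4 grammar: hierarchical classification, prediction, region selection."""

import re

import numpy as np
import pytest

from rg4fold.counts import StopCountProfile, TranscriptAnnotation
from rg4fold.motif import (
    SUBCLASSES,
    GRichRegion,
    classify_upstream,
    classify_window,
    g_tracts,
    locate_genic,
    predict_transcriptome,
    read_regions_tsv,
    select_undetected,
    write_regions_tsv,
)
from rg4fold.rts import RTSSite
from rg4fold.simulate import _plant_motif

LABELS = [s.label for s in SUBCLASSES]


def brute_force_scan(seq, min_tract=2, max_loop=15, n_tracts=4):
    """Independent oracle: minimal-match enumeration via regex fullmatch.

    For each start, the minimal span whose prefix fullmatches the grammar
    is the non-greedy match; non-overlap advances the scan past it.
    """
    rx = re.compile(
        f"G{{{min_tract}}}(?:[ACGU]{{1,{max_loop}}}G{{{min_tract}}}){{{n_tracts - 1}}}"
    )
    min_span = n_tracts * min_tract + (n_tracts - 1)
    max_span = n_tracts * min_tract + (n_tracts - 1) * max_loop
    intervals = []
    i, n = 0, len(seq)
    while i < n:
        end = None
        for span in range(min_span, min(max_span, n - i) + 1):
            if rx.fullmatch(seq, i, i + span):
                end = i + span
                break
        if end is None:
            i += 1
        else:
            intervals.append((i, end))
            i = end
    return intervals


class TestClassifyWindow:
    def test_canonical_g3_motif(self):
        hit = classify_window("GGGAGGGAGGGAGGG")
        assert hit is not None and hit[0].label == "G3L1-15"

    def test_g2_motif_without_higher_priority_match(self):
        window = "GGAGGAGGAGG"
        hit = classify_window(window)
        assert hit[0].label == "G2L1-2"
        # exhaustive check: no higher-priority pattern matches anywhere
        for sub in SUBCLASSES:
            if sub.priority < 4:
                assert sub.regex.search(window) is None

    def test_guanine_vacancy(self):
        # fourth tract has only two Gs: a G3 quadruplex missing one quartet G
        window = "GGGAGGGAGGGAGG"
        hit = classify_window(window)
        assert hit[0].label == "G3VL1-9"
        assert SUBCLASSES[0].regex.search(window) is None

    def test_bulged_tract(self):
        window = "GGGAGGAGAGGAGAGGG"  # middle tracts GGAG (bulge after GG)
        hit = classify_window(window)
        assert hit[0].label == "G3bulge"

    def test_poly_a_window_matches_nothing(self):
        assert classify_window("A" * 50) is None

    @pytest.mark.parametrize("label", LABELS)
    def test_hierarchy_soundness_on_planted_motifs(self, label):
        """Every planted motif classifies as planted, with no higher-priority
        pattern matching anywhere in a sanitized 50-nt window."""
        rng = np.random.default_rng(77)
        planted_priority = {s.label: s.priority for s in SUBCLASSES}[label]
        for _ in range(50):
            motif = _plant_motif(rng, label)
            pad = "".join(rng.choice(list("ACU"), size=50 - len(motif)))
            window = pad + motif
            sub, start, end = classify_window(window)
            assert sub.label == label
            for other in SUBCLASSES:
                if other.priority < planted_priority:
                    assert other.regex.search(window) is None

    def test_three_prime_most_match_is_chosen(self):
        # two disjoint canonical motifs: the one nearer the window 3' end wins
        window = "GGGAGGGAGGGAGGG" + "ACUACU" + "GGGCGGGCGGGCGGG"
        sub, start, end = classify_window(window)
        assert sub.label == "G3L1-15"
        assert end == len(window)
        assert start == len(window) - 15


class TestClassifyUpstream:
    def test_window_anchored_at_stall_base(self):
        seq = "ACU" * 20 + "GGGAGGGAGGGAGGG" + "ACU" * 20
        # stall base = 3'-terminal G of the motif (position 74)
        site = RTSSite("tx", 74, "K_vs_Li", 0.01, -3.0)
        region = classify_upstream(site, {"tx": seq})
        assert region is not None
        assert region.subclass == "G3L1-15"
        assert region.interval == (60, 75)
        assert region.loop_lengths == [1, 1, 1]
        assert region.tract_intervals[0] == (60, 63)

    def test_window_truncated_at_transcript_start(self):
        seq = "GGGAGGGAGGGAGGG" + "A" * 100
        site = RTSSite("tx", 14, "K_vs_Li", 0.01, -3.0)
        region = classify_upstream(site, {"tx": seq})
        assert region is not None and region.interval == (0, 15)

    def test_no_match_returns_none(self):
        site = RTSSite("tx", 60, "K_vs_Li", 0.01, -3.0)
        assert classify_upstream(site, {"tx": "A" * 100}) is None


class TestPredict:
    def test_poly_a_has_no_regions(self):
        assert predict_transcriptome({"t": "A" * 1000}) == []

    def test_single_motif_spanned(self):
        seq = "A" * 40 + "GGAGGAGGAGG" + "A" * 40
        regions = predict_transcriptome({"t": seq})
        assert [r.interval for r in regions] == [(40, 51)]

    def test_nongreedy_nonoverlapping_on_g_runs(self):
        seq = "GGGGAGGGGAGGGGAGGGG"
        regions = predict_transcriptome({"t": seq})
        assert len(regions) == 1
        assert [r.interval for r in regions] == brute_force_scan(seq)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGU"), size=200, p=[0.2, 0.2, 0.4, 0.2]))
            got = [r.interval for r in predict_transcriptome({"t": seq})]
            assert got == brute_force_scan(seq)
            # disjoint and sorted
            for (a, b), (c, d) in zip(got, got[1:]):
                assert b <= c

    def test_t_mapped_to_u(self):
        regions = predict_transcriptome({"t": "ggtaggtaggtagg".upper() + "A" * 20})
        assert [r.interval for r in regions] == [(0, 14)]


class TestSelectUndetected:
    @staticmethod
    def _setup(mean_cov):
        seq = "A" * 60 + "GGAGGAGGAGG" + "A" * 60
        region = predict_transcriptome({"t": seq})[0]
        cov = np.full(len(seq), int(mean_cov), dtype=np.int64)
        li = {"t": StopCountProfile("t", np.zeros(len(seq), dtype=np.int64), cov, "Li")}
        return seq, region, li

    @pytest.mark.parametrize("cov,kept", [(59, False), (61, True)])
    def test_li_coverage_threshold(self, cov, kept):
        seq, region, li = self._setup(cov)
        out = select_undetected([region], [], li, {"t": seq})
        assert (len(out) == 1) == kept
        if kept:
            assert out[0].subclass == "undetected"
            assert len(out[0].flank5) == 50 and len(out[0].flank3) == 50

    def test_one_nt_overlap_with_detected_excludes(self):
        seq, region, li = self._setup(100)
        detected = GRichRegion("t", (region.end - 1, region.end + 5), "x", "G2L1-2")
        assert select_undetected([region], [detected], li, {"t": seq}) == []

    def test_missing_flank_excludes(self):
        seq = "A" * 30 + "GGAGGAGGAGG" + "A" * 60
        region = predict_transcriptome({"t": seq})[0]
        cov = np.full(len(seq), 100, dtype=np.int64)
        li = {"t": StopCountProfile("t", np.zeros(len(seq), dtype=np.int64), cov, "Li")}
        assert select_undetected([region], [], li, {"t": seq}) == []

    def test_missing_li_profile_drops_with_log(self):
        seq, region, _ = self._setup(100)
        log = []
        assert select_undetected([region], [], {}, {"t": seq}, log=log) == []
        assert any("no Li+ profile" in line for line in log)


class TestLocateGenic:
    ANN = TranscriptAnnotation("t", (0, 100), (100, 400), (400, 500))

    @pytest.mark.parametrize(
        "interval,label",
        [
            ((150, 170), "CDS"),
            ((420, 440), "3'UTR"),
            ((390, 406), "CDS"),  # crosses CDS/3'UTR junction, midpoint 398 in CDS
            ((10, 30), "5'UTR"),
        ],
    )
    def test_midpoint_rule(self, interval, label):
        region = GRichRegion("t", interval, "G" * (interval[1] - interval[0]), "predicted")
        assert locate_genic(region, self.ANN) == label

    def test_unannotated_transcript_is_unknown(self):
        region = GRichRegion("t", (0, 10), "G" * 10, "predicted")
        assert locate_genic(region, None) == "unknown"


def test_region_tsv_round_trip(tmp_path):
    seq = "A" * 40 + "GGGAGGGAGGGAGGG" + "A" * 40
    regions = predict_transcriptome({"t": seq})
    regions[0].genic_region = "CDS"
    path = tmp_path / "regions.tsv"
    write_regions_tsv(regions, path)
    back = read_regions_tsv(path)
    assert len(back) == 1
    assert back[0].interval == regions[0].interval
    assert back[0].sequence == regions[0].sequence
    assert back[0].tract_intervals == regions[0].tract_intervals
    assert back[0].loop_lengths == regions[0].loop_lengths
    assert back[0].genic_region == "CDS"


def test_g_tracts_are_maximal_runs():
    assert g_tracts("GGGAGGAAGAGGGG") == [(0, 3), (4, 6), (10, 14)]
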