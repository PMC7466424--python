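"""Gini index and folding score: exact values, invariants, filters, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rg4fold.counts import StopCountProfile
from rg4fold.motif import GRichRegion, g_tracts
from rg4fold.shalipe import (
    FoldingScoreRecord,
    ShalipeRegionProfile,
    build_region_profile,
    control_ginis,
    folding_score,
    gini,
    gini_value,
    gini_value_quadratic,
    score_regions,
    summarize_landscape,
)

count_vectors = st.lists(
    st.integers(min_value=0, max_value=10_000), min_size=2, max_size=40
).filter(lambda v: sum(v) > 0)


class TestGiniValue:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((10, 10, 10, 10), 0.0),  # uniform: no dispersion
            ((100, 0, 0, 0), 0.75),  # point mass on one of n=4: (n-1)/n
            ((10, 20, 30, 40), 0.25),  # sum |ri-rj| = 200 over 2*16*25
        ],
    )
    def test_exact_values(self, counts, expected):
        assert gini_value(np.array(counts)) == pytest.approx(expected)
        assert gini_value_quadratic(np.array(counts)) == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True)
    @given(count_vectors)
    def test_fast_form_matches_literal_double_sum(self, v):
        r = np.array(v, dtype=float)
        assert gini_value(r) == pytest.approx(gini_value_quadratic(r), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(count_vectors)
    def test_bounds(self, v):
        r = np.array(v, dtype=float)
        n = r.size
        assert -1e-12 <= gini_value(r) <= (n - 1) / n + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(count_vectors, st.floats(min_value=0.01, max_value=1000))
    def test_scale_invariance(self, v, c):
        r = np.array(v, dtype=float)
        assert gini_value(c * r) == pytest.approx(gini_value(r), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(count_vectors, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, v, rnd):
        r = list(v)
        shuffled = list(r)
        rnd.shuffle(shuffled)
        assert gini_value(np.array(shuffled)) == pytest.approx(
            gini_value(np.array(r)), abs=1e-12
        )

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            gini_value(np.array([5.0]))
        with pytest.raises(ZeroDivisionError):
            gini_value(np.zeros(4))


def _region_profile(seq, counts, state="in_vitro_K"):
    region = GRichRegion("t", (0, len(seq)), seq, "G2L1-2", tract_intervals=g_tracts(seq))
    in_tract = np.zeros(len(seq), dtype=bool)
    for a, b in g_tracts(seq):
        in_tract[a:b] = True
    return ShalipeRegionProfile(region, state, np.asarray(counts, dtype=float), seq, in_tract)


class TestGiniSelections:
    SEQ = "GGAGGAGAGGAGG"  # tracts at 0-2,3-5,8-10,11-13; singleton G at 6

    def test_selection_masks(self):
        counts = np.arange(len(self.SEQ), dtype=float)
        prof = _region_profile(self.SEQ, counts)
        assert gini(prof, "tract_Gs").n == 8
        # singleton G (not a tract) is the only non-tract G
        with pytest.raises(ValueError):
            gini(prof, "nontract_Gs")  # just one residue
        assert gini(prof, "nonG").n == 4

    def test_control_ginis_reports_all_selections(self):
        counts = np.arange(len(self.SEQ), dtype=float) + 1
        out = control_ginis(_region_profile(self.SEQ, counts))
        assert set(out) == {"tract_Gs", "nontract_Gs", "nonG"}
        assert out["tract_Gs"] is not None and out["nonG"] is not None
        assert out["nontract_Gs"] is None  # <2 residues in this sequence

    def test_all_zero_counts_reported_missing(self):
        prof = _region_profile(self.SEQ, np.zeros(len(self.SEQ)))
        assert gini(prof, "tract_Gs") is None


class TestFoldingScore:
    def test_vivo_equals_li_gives_zero(self):
        assert folding_score(0.4, 0.4, 0.8) == 0.0

    def test_vivo_equals_k_gives_one(self):
        assert folding_score(0.8, 0.4, 0.8) == 1.0

    def test_direct_substitution(self):
        assert folding_score(0.6, 0.4, 0.8) == pytest.approx(0.5)

    def test_undefined_when_anchors_coincide(self):
        with pytest.raises(ZeroDivisionError):
            folding_score(0.5, 0.4, 0.4)

    def test_monotone_in_vivo_gini(self):
        scores = [folding_score(v, 0.2, 0.6) for v in (0.1, 0.3, 0.5, 0.9)]
        assert scores == sorted(scores)
        assert scores[-1] > 1  # scores above 1 are possible


def _make_state_profiles(seq, tract_counts_by_state, other=60):
    """Transcript-level profiles whose region slice has given tract-G counts."""
    out = {}
    tract_pos = np.concatenate([np.arange(a, b) for a, b in g_tracts(seq)])
    for state, tract_counts in tract_counts_by_state.items():
        counts = np.full(len(seq), other, dtype=np.int64)
        counts[tract_pos] = tract_counts
        out.setdefault(state, {})["t"] = StopCountProfile(
            "t", counts, counts.copy(), state, "merged"
        )
    return out


class TestScoreRegions:
    SEQ = "GGAGGAGGAGG"  # 8 tract Gs

    def _region(self):
        return GRichRegion("t", (0, len(self.SEQ)), self.SEQ, "G2L1-2")

    def test_ratio_filter_excludes_low_contrast(self):
        # Li and K tract ginis nearly equal: ratio ~1.0 < 1.1
        flat = [100, 100, 100, 100, 100, 100, 100, 105]
        profs = _make_state_profiles(
            self.SEQ,
            {"in_vitro_Li": flat, "in_vitro_K": flat, "in_vivo": flat},
        )
        (rec,) = score_regions([self._region()], profs)
        assert not rec.passes_ratio_filter
        assert rec.passes_coverage_filter
        assert rec.folding_score is None

    @pytest.mark.parametrize("mean,passes", [(49.875, False), (50.0, True)])
    def test_coverage_filter_boundary(self, mean, passes):
        li = [30, 30, 30, 30, 30, 30, 30, int(mean * 8) - 210]
        k = [20, 20, 20, 20, 20, 20, 20, int(mean * 8) - 140]
        vivo = k
        profs = _make_state_profiles(
            self.SEQ, {"in_vitro_Li": li, "in_vitro_K": k, "in_vivo": vivo}
        )
        (rec,) = score_regions([self._region()], profs)
        assert rec.passes_coverage_filter == passes

    def test_end_to_end_on_simulated_folded_region(
        self, transcriptome, shalipe_data
    ):
        from rg4fold.counts import merge_replicates
        from rg4fold.motif import classify_window

        seqs, _, truth = transcriptome
        merged = {
            state: merge_replicates(reps).profiles
            for state, reps in shalipe_data.items()
        }
        regions = []
        by_tid = {}
        for rec in truth:
            start, end = rec.interval
            seq = seqs[rec.transcript_id][start:end]
            regions.append(
                GRichRegion(rec.transcript_id, (start, end), seq, rec.subclass)
            )
            by_tid[rec.transcript_id] = rec
        records = score_regions(regions, merged)
        assert len(records) == len(truth)
        folded_fs = [
            r.folding_score
            for r in records
            if r.folding_score is not None
            and by_tid[r.region_id.split(":")[0]].folded
        ]
        assert len(folded_fs) > 0
        assert all(r.passes_coverage_filter for r in records)
        assert np.median(folded_fs) > 0.5

    def test_missing_state_rejected(self):
        with pytest.raises(ValueError, match="missing profile states"):
            score_regions([self._region()], {"in_vivo": {}})


class TestSummarize:
    @staticmethod
    def _rec(fs, subclass="G2L1-2", genic="CDS", i=[0]):
        i[0] += 1
        return FoldingScoreRecord(
            f"t{i[0]}:0-10", subclass, genic, 0.5, 0.2, 0.6, fs, True, True
        )

    def test_median_and_fraction(self):
        records = [self._rec(0.2), self._rec(0.8), self._rec(1.1)]
        s = summarize_landscape(records)
        assert s.median_fs == pytest.approx(0.8)
        assert s.frac_positive == 1.0 and s.n_scored == 3

    def test_equal_fs_across_groups_is_nonsignificant(self):
        records = [
            self._rec(0.5, subclass=sub) for sub in ("G2L1-2", "G3L1-15") for _ in range(4)
        ]
        s = summarize_landscape(records)
        assert s.subclass_anova_p == 1.0

    def test_group_with_one_member_excluded(self):
        records = [self._rec(0.5), self._rec(0.7), self._rec(0.9, subclass="G3bulge")]
        log = []
        s = summarize_landscape(records, log=log)
        assert s.subclass_anova_p is None  # only one group left
        assert any("excluded" in line for line in log)

    def test_distinct_groups_detected(self, rng):
        records = [self._rec(float(v)) for v in rng.normal(1.0, 0.05, size=10)] + [
            self._rec(float(v), subclass="G3L1-15")
            for v in rng.normal(0.0, 0.05, size=10)
        ]
        s = summarize_landscape(records)
        assert s.subclass_anova_p < 0.001
        assert s.subclass_tukey is not None

    def test_no_scored_records_rejected(self):
        rec = FoldingScoreRecord("t:0-1", "G2L1-2", "CDS", None, None, None, None, False, False)
        with pytest.raises(ValueError):
            summarize_landscape([rec])


def test_build_region_profile_slices_and_flags(transcriptome, shalipe_data):
    seqs, _, truth = transcriptome
    rec = truth[0]
    start, end = rec.interval
    seq = seqs[rec.transcript_id][start:end]
    region = GRichRegion(rec.transcript_id, (start, end), seq, rec.subclass)
    prof = build_region_profile(region, shalipe_data["in_vitro_K"][0], "in_vitro_K")
    assert len(prof.counts) == end - start
    assert prof.in_tract.sum() == sum(b - a for a, b in g_tracts(seq))
    # in_tract implies G
    assert all(seq[i] == "G" for i in np.flatnonzero(prof.in_tract))
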