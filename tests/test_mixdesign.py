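"""Overlap scoring, the annealer, and peak-window compilation."""

import itertools

import pytest

import t1screen as t
from t1screen.mixdesign import MixDesign
from t1screen.tables import MetabolitePeakList
from tests.conftest import clashfree_library


def lib(**peaks_by_met):
    return {
        met: MetabolitePeakList(met, tuple(peaks))
        for met, peaks in peaks_by_met.items()
    }


class TestOverlapScore:
    def test_distant_peaks_score_zero(self):
        library = lib(a=[(5.0, 1.0)], b=[(5.5, 1.0)])
        assert t.overlap_score({"a": 0, "b": 0}, library) == 0.0

    def test_single_full_intensity_clash_scores_100(self):
        library = lib(a=[(5.000, 1.0)], b=[(5.010, 1.0)])
        assert t.overlap_score({"a": 0, "b": 0}, library) == 100.0

    def test_separated_clash_scores_zero(self):
        library = lib(a=[(5.000, 1.0)], b=[(5.010, 1.0)])
        assert t.overlap_score({"a": 0, "b": 1}, library) == 0.0

    def test_intensity_scoring_scales_by_product(self):
        library = lib(a=[(5.000, 0.5), (4.0, 1.0)], b=[(5.010, 0.8), (6.0, 1.0)])
        assert t.overlap_score({"a": 0, "b": 0}, library) == pytest.approx(
            100 * 0.5 * 0.8
        )
        assert t.overlap_score(
            {"a": 0, "b": 0}, library, use_intensity=False
        ) == pytest.approx(100)

    def test_same_metabolite_peaks_never_clash(self):
        library = lib(a=[(5.000, 1.0), (5.010, 1.0)])
        assert t.overlap_score({"a": 0}, library) == 0.0

    def test_missing_peak_list_rejected(self):
        with pytest.raises(ValueError, match="without peak lists"):
            t.overlap_score({"ghost": 0}, {})


class TestAnnealer:
    def test_matches_brute_force_on_four_metabolites(self):
        # exactly one clashing pair (a, b): the optimum splits them
        library = lib(
            a=[(5.000, 1.0)], b=[(5.010, 1.0)], c=[(2.0, 1.0)], d=[(8.0, 1.0)]
        )
        best = min(
            t.overlap_score(dict(zip("abcd", combo)), library)
            for combo in itertools.product(range(2), repeat=4)
        )
        sched = t.AnnealSchedule(n_mixes=2, max_mix_size=4, max_steps=2000,
                                 iterations=2, seed=0)
        design = t.anneal_mixes(library, sched)
        assert best == 0.0
        assert design.score == best
        assert design.assignment["a"] != design.assignment["b"]

    def test_must_separate_dominates_score(self):
        library = lib(a=[(2.0, 1.0)], b=[(8.0, 1.0)])  # non-clashing pair
        sched = t.AnnealSchedule(n_mixes=2, max_mix_size=2, max_steps=500,
                                 iterations=1, seed=0)
        design = t.anneal_mixes(library, sched, must_separate=[("a", "b")])
        assert design.assignment["a"] != design.assignment["b"]

    def test_forced_assignments_honoured(self):
        library = lib(a=[(2.0, 1.0)], b=[(8.0, 1.0)], c=[(4.0, 1.0)])
        sched = t.AnnealSchedule(n_mixes=2, max_mix_size=3, max_steps=500,
                                 iterations=1, seed=0)
        design = t.anneal_mixes(library, sched, forced={"a": 1})
        assert design.assignment["a"] == 1

    def test_size_caps_respected_at_library_scale(self):
        library = t.synthetic_library(55, seed=3, mode="scatter", extra_peaks=(1, 2))
        sched = t.AnnealSchedule(n_mixes=4, max_mix_size=15, max_steps=2000,
                                 iterations=1, seed=1)
        design = t.anneal_mixes(library, sched)
        sizes = [len(m) for m in design.mix_members()]
        assert sum(sizes) == 55
        assert all(s <= 15 for s in sizes)

    def test_returned_score_equals_recomputed_score(self):
        library = t.synthetic_library(12, seed=2, mode="scatter", extra_peaks=(1, 2))
        sched = t.AnnealSchedule(n_mixes=3, max_mix_size=5, max_steps=1000,
                                 iterations=1, seed=4)
        design = t.anneal_mixes(library, sched)
        assert design.score == t.overlap_score(design.assignment, library)

    def test_infeasible_constraints_rejected(self):
        library = lib(a=[(2.0, 1.0)], b=[(8.0, 1.0)], c=[(4.0, 1.0)])
        sched = t.AnnealSchedule(n_mixes=2, max_mix_size=2, max_steps=100,
                                 iterations=1, seed=0)
        with pytest.raises(ValueError, match="feasible|infeasible"):
            t.anneal_mixes(
                library, sched,
                must_separate=[("a", "b"), ("b", "c"), ("a", "c")],
            )

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            t.anneal_mixes({}, t.AnnealSchedule(n_mixes=2, max_mix_size=2))

    def test_published_schedule_settings(self):
        sched = t.AnnealSchedule.published()
        assert sched.n_mixes == 4
        assert sched.max_mix_size == 15
        assert sched.start_temp == 10_000
        assert sched.final_temp == 25
        assert sched.max_steps == 500_000
        assert sched.mix_rate == 2
        assert sched.iterations == 10
        assert sched.overlap_range == 0.025


class TestCompilePeakWindows:
    def design_for(self, assignment, n_mixes=1):
        return MixDesign(assignment=assignment, score=0.0, n_mixes=n_mixes)

    def test_lone_peak_gets_full_window(self):
        library = lib(a=[(5.0, 1.0)])
        windows, uncovered = t.compile_peak_windows(
            self.design_for({"a": 0}), library
        )
        (w,) = windows
        assert (w.ppm_lo, w.ppm_hi) == (pytest.approx(4.975), pytest.approx(5.025))
        assert uncovered == []

    def test_clashing_pair_excluded_both_sides(self):
        library = lib(a=[(5.00, 1.0)], b=[(5.01, 1.0)])
        windows, uncovered = t.compile_peak_windows(
            self.design_for({"a": 0, "b": 0}), library
        )
        assert windows == []
        assert uncovered == ["a", "b"]

    def test_metabolite_with_one_clear_peak_stays_quantifiable(self):
        library = lib(a=[(5.00, 1.0), (8.00, 0.5)], b=[(5.01, 1.0)])
        windows, uncovered = t.compile_peak_windows(
            self.design_for({"a": 0, "b": 0}), library
        )
        assert [w.source_peak_ppm for w in windows] == [8.00]
        assert uncovered == ["b"]

    def test_windows_pairwise_disjoint_within_mix(self):
        # survivors at 0.03 < spacing < 0.05 would overlap untruncated
        library = lib(a=[(5.00, 1.0)], b=[(5.04, 1.0)], c=[(5.08, 1.0)])
        windows, _ = t.compile_peak_windows(
            self.design_for({"a": 0, "b": 0, "c": 0}), library
        )
        assert len(windows) == 3
        ordered = sorted(windows, key=lambda w: w.ppm_lo)
        for w1, w2 in zip(ordered, ordered[1:]):
            assert w1.ppm_hi < w2.ppm_lo

    def test_disjointness_on_random_scatter_libraries(self):
        for seed in range(3):
            library = t.synthetic_library(
                15, seed=seed, mode="scatter", extra_peaks=(1, 3)
            )
            design = t.anneal_mixes(
                library,
                t.AnnealSchedule(n_mixes=3, max_mix_size=5, max_steps=1000,
                                 iterations=1, seed=seed),
            )
            windows, _ = t.compile_peak_windows(design, library)
            by_mix = {}
            for w in windows:
                by_mix.setdefault(w.mix_id, []).append(w)
            for ws in by_mix.values():
                ws.sort(key=lambda w: w.ppm_lo)
                for w1, w2 in zip(ws, ws[1:]):
                    assert w1.ppm_hi < w2.ppm_lo


def test_annealer_solves_clashfree_library_quickly():
    library = clashfree_library(n_mets=16, n_mixes=4, n_clusters=6, seed=1)
    sched = t.AnnealSchedule(n_mixes=4, max_mix_size=5, seed=2)
    design = t.anneal_mixes(library, sched)
    assert design.score == 0.0
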