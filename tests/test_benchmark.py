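"""Confusion counts, ROC construction, cutoff selection, and AUC against
brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import t1screen as t
from tests.conftest import matrix_from_scores

# five-pair example: two known interactions, three unknown pairs
FIVE_SCORES = {
    ("P1", "k1"): 0.4,
    ("P1", "k2"): 0.2,
    ("P1", "u1"): 0.3,
    ("P1", "u2"): 0.1,
    ("P1", "u3"): 0.05,
}
FIVE_REF = t.ReferenceSet({("P1", "k1"): "regulatory", ("P1", "k2"): "catalytic"})


def brute_force_roc(scores, reference):
    """Exhaustive threshold enumeration oracle."""
    values = sorted({v for v in scores.values()} | {0.0, 0.5})
    pos = [k for k in scores if k in reference]
    neg = [k for k in scores if k not in reference]
    points = []
    for c in values:
        tp = sum(scores[k] > c for k in pos)
        fp = sum(scores[k] > c for k in neg)
        points.append((c, tp / len(pos), fp / len(neg)))
    return points


def brute_force_auc(scores, reference):
    """Rank-statistic oracle: P(random positive outscores random negative),
    ties counting one half."""
    pos = [scores[k] for k in scores if k in reference]
    neg = [scores[k] for k in scores if k not in reference]
    wins = sum(
        1.0 if a > b else (0.5 if a == b else 0.0)
        for a, b in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestConfusionAtCutoff:
    def test_degenerate_cutoffs(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        high = t.confusion_at_cutoff(matrix, FIVE_REF, 0.9)
        assert (high.tp, high.fp) == (0, 0)
        low = t.confusion_at_cutoff(matrix, FIVE_REF, -1.0)
        assert (low.fn, low.tn) == (0, 0)

    def test_count_conservation(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        for c in (0.0, 0.1, 0.2, 0.3):
            counts = t.confusion_at_cutoff(matrix, FIVE_REF, c)
            assert counts.positives == 2
            assert counts.negatives == 3

    def test_missing_cells_excluded_by_default(self):
        scores = dict(FIVE_SCORES)
        scores[("P1", "u3")] = None
        matrix = matrix_from_scores(scores)
        counts = t.confusion_at_cutoff(matrix, FIVE_REF, 0.0)
        assert counts.negatives == 2
        as_negative = t.confusion_at_cutoff(matrix, FIVE_REF, 0.0, missing="negative")
        assert as_negative.negatives == 3

    def test_reference_outside_rosters_rejected(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        ref = t.ReferenceSet({("ghost", "k1"): "regulatory"})
        with pytest.raises(ValueError, match="roster"):
            t.confusion_at_cutoff(matrix, ref, 0.1)


class TestRocCurve:
    def test_matches_brute_force_enumeration(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        roc = t.roc_curve(matrix, FIVE_REF)
        expected = brute_force_roc(FIVE_SCORES, FIVE_REF)
        got = [(p.cutoff, p.tpr, p.fpr) for p in roc]
        assert got == pytest.approx(expected)

    def test_perfect_separation_passes_through_corner(self):
        scores = {("P", f"k{i}"): 0.5 + 0.01 * i for i in range(3)}
        scores.update({("P", f"u{i}"): 0.1 * i / 10 for i in range(3)})
        ref = t.ReferenceSet({("P", f"k{i}"): "regulatory" for i in range(3)})
        roc = t.roc_curve(matrix_from_scores(scores), ref)
        assert any(p.tpr == 1.0 and p.fpr == 0.0 for p in roc)
        assert t.auc(roc) == 1.0

    def test_degenerate_reference_rejected(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        with pytest.raises(ValueError, match="degenerate"):
            t.roc_curve(matrix, t.ReferenceSet())

    @given(st.integers(min_value=0, max_value=10_000))
    def test_tpr_fpr_non_increasing_in_cutoff(self, seed):
        rng = np.random.default_rng(seed)
        scores = {
            ("P", f"m{i}"): float(rng.normal(0.1, 0.15)) for i in range(12)
        }
        ref = t.ReferenceSet(
            {("P", f"m{i}"): "regulatory" for i in range(12) if rng.random() < 0.4}
        )
        if not 0 < len(ref) < 12:
            return
        roc = t.roc_curve(matrix_from_scores(scores), ref)
        tprs = [p.tpr for p in roc]
        fprs = [p.fpr for p in roc]
        assert tprs == sorted(tprs, reverse=True)
        assert fprs == sorted(fprs, reverse=True)


class TestSelectCutoff:
    def test_five_pair_example_target_034(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        roc = t.roc_curve(matrix, FIVE_REF)
        cutoff, tpr, fpr = t.select_cutoff(roc, 0.34)
        assert cutoff == pytest.approx(0.1)
        assert tpr == 1.0
        assert fpr == pytest.approx(1 / 3)

    def test_target_zero_forces_cutoff_above_unknowns(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        roc = t.roc_curve(matrix, FIVE_REF)
        cutoff, _, fpr = t.select_cutoff(roc, 0.0)
        assert fpr == 0.0
        assert cutoff >= 0.3  # above every unknown-pair score

    def test_target_one_gives_minimal_candidate(self):
        matrix = matrix_from_scores(FIVE_SCORES)
        roc = t.roc_curve(matrix, FIVE_REF)
        cutoff, tpr, _ = t.select_cutoff(roc, 1.0)
        assert cutoff == min(p.cutoff for p in roc)


class TestAUC:
    def test_equals_rank_statistic_on_random_small_sets(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n = int(rng.integers(6, 20))
            scores = {("P", f"m{i}"): round(float(rng.normal(0, 1)), 2) for i in range(n)}
            known = {f"m{i}" for i in range(n) if rng.random() < 0.5}
            if not 0 < len(known) < n:
                continue
            ref = t.ReferenceSet({("P", m): "regulatory" for m in known})
            roc = t.roc_curve(matrix_from_scores(scores), ref)
            assert t.auc(roc) == pytest.approx(
                brute_force_auc(scores, ref), abs=1e-9
            )

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 400
        scores = {("P", f"m{i}"): float(rng.normal()) for i in range(n)}
        ref = t.ReferenceSet(
            {("P", f"m{i}"): "regulatory" for i in range(n) if rng.random() < 0.5}
        )
        roc = t.roc_curve(matrix_from_scores(scores), ref)
        assert t.auc(roc) == pytest.approx(0.5, abs=0.1)


class TestSummaryArithmetic:
    def test_screen_counts_recovered_from_headline_numbers(self):
        counts = t.confusion_from_counts(
            n_proteins=29, n_metabolites=55, n_known=72,
            n_detected=98, n_known_detected=22,
        )
        assert counts.tp + counts.fp + counts.tn + counts.fn == 1595
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (22, 76, 50, 1447)
        assert counts.tpr == pytest.approx(22 / 72)
        assert counts.fpr == pytest.approx(76 / 1523)
        assert counts.fpr <= 0.05

    def test_mean_partners(self):
        assert t.mean_partners(98, 28) == pytest.approx(3.5)
        with pytest.raises(ValueError):
            t.mean_partners(98, 0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            t.confusion_from_counts(2, 2, 1, 2, 3)
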