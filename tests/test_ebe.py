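import math

import numpy as np
import pytest

from somnoval import ebe
from somnoval.ebe import (ConfusionMatrix, EBEMetrics, binary_metrics,
                          cohens_kappa, landis_koch_rating,
                          per_night_summary, stage_accuracy_one_vs_rest)
from somnoval.hypnogram import Hypnogram, PairedNight, STAGES_4
from somnoval.reference import (REFERENCE_CONFUSION, REFERENCE_PREVALENCE,
                                reference_matrix)
from conftest import random_pair


def _pair(ref, test):
    mk = lambda s: Hypnogram(subject_id="s", night_id="n", group="other",
                             epoch_s=30, stages=tuple(s))
    return PairedNight(ref=mk(ref), test=mk(test))


def tally_oracle(pairs):
    counts = np.zeros((4, 4))
    idx = {s: i for i, s in enumerate(STAGES_4)}
    for p in pairs:
        for r, c in zip(p.ref.stages, p.test.stages):
            counts[idx[r], idx[c]] += 1
    return counts


class TestConfusionCounts:
    def test_identical_hypnograms_are_diagonal(self):
        p = _pair(["W", "N12", "N3", "REM"] * 5, ["W", "N12", "N3", "REM"] * 5)
        m = ConfusionMatrix.from_pairs(p)
        assert np.trace(m.counts) == m.total == 20

    def test_hand_tally(self):
        m = ConfusionMatrix.from_pairs(_pair(
            ["W", "W", "N12", "N3", "REM", "REM"],
            ["W", "N12", "N12", "N3", "REM", "W"]))
        expect = np.zeros((4, 4))
        expect[0, 0] = 1; expect[0, 1] = 1; expect[1, 1] = 1
        expect[2, 2] = 1; expect[3, 3] = 1; expect[3, 0] = 1
        assert np.array_equal(m.counts, expect)

    def test_matches_brute_force_tally(self, rng):
        pairs = [random_pair(rng, int(rng.integers(5, 40)))
                 for _ in range(1000)]
        m = ConfusionMatrix.from_pairs(pairs)
        assert np.array_equal(m.counts, tally_oracle(pairs))

    def test_row_normalization_and_prevalence(self, rng):
        m = ConfusionMatrix.from_pairs([random_pair(rng, 200)])
        nonzero = m.counts.sum(axis=1) > 0
        assert np.allclose(m.row_normalized[nonzero].sum(axis=1), 1.0,
                           atol=1e-9)
        assert m.prevalence.sum() == pytest.approx(1.0)

    def test_round_trip_from_row_normalized(self, rng):
        m = ConfusionMatrix.from_pairs([random_pair(rng, 500)])
        back = ConfusionMatrix.from_row_normalized(
            m.row_normalized, m.prevalence, m.total)
        assert np.allclose(back.counts, m.counts, atol=1e-9)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.zeros((4, 4)))


class TestPublishedValuesReproduce:
    """The published group accuracy/kappa values must follow from the
    published row-normalized confusion cells and prevalences alone.
    Cells carry 1-decimal (percent) rounding, hence the 0.1 tolerances."""

    def test_full_sample_two_class_metrics(self):
        sens, spec, acc2 = binary_metrics(reference_matrix("all"))
        assert sens == pytest.approx(93.3, abs=0.1)
        assert spec == pytest.approx(69.5, abs=0.1)
        assert acc2 == pytest.approx(87.8, abs=0.1)
        assert cohens_kappa(reference_matrix("all"), 2) == \
            pytest.approx(0.65, abs=0.01)

    def test_full_sample_four_class_metrics(self):
        m = reference_matrix("all")
        assert ebe.accuracy4(m) == pytest.approx(68.5, abs=0.1)
        assert cohens_kappa(m, 4) == pytest.approx(0.55, abs=0.01)

    @pytest.mark.parametrize("stage,expected", [
        ("W", 87.8), ("N12", 71.5), ("N3", 88.0), ("REM", 89.8)])
    def test_full_sample_stage_accuracies(self, stage, expected):
        assert stage_accuracy_one_vs_rest(reference_matrix("all"), stage) \
            == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize("group,metric,expected", [
        ("healthy", "acc2", 93.0), ("healthy", "acc4", 71.2),
        ("OSA", "acc2", 82.8), ("insomnia", "kappa2", 0.70),
        ("insomnia", "sens", 93.2)])
    def test_group_values(self, group, metric, expected):
        m = reference_matrix(group)
        if metric == "acc2":
            got = binary_metrics(m)[2]
        elif metric == "sens":
            got = binary_metrics(m)[0]
        elif metric == "acc4":
            got = ebe.accuracy4(m)
        else:
            got = cohens_kappa(m, 2)
        tol = 0.01 if metric == "kappa2" else 0.1
        assert got == pytest.approx(expected, abs=tol)


class TestBinaryMetrics:
    def test_perfect_agreement(self):
        p = _pair(["W", "N12", "N3", "REM"], ["W", "N12", "N3", "REM"])
        assert binary_metrics(p) == (100.0, 100.0, 100.0)

    def test_device_scores_everything_sleep(self):
        p = _pair(["W", "W", "N12", "N3"], ["N12", "N3", "N12", "N3"])
        sens, spec, acc = binary_metrics(p)
        assert spec == 0.0 and sens == 100.0 and acc == 50.0

    def test_undefined_when_class_absent(self):
        sens, spec, _ = binary_metrics(_pair(["N12"] * 4, ["N12"] * 4))
        assert math.isnan(spec) and sens == 100.0

    def test_accuracy_is_prevalence_weighted_sens_spec(self, rng):
        for _ in range(50):
            m = ConfusionMatrix.from_pairs([random_pair(rng, 100)])
            sens, spec, acc = binary_metrics(m)
            p_wake = m.prevalence[0]
            assert acc == pytest.approx(p_wake * spec +
                                        (1 - p_wake) * sens, abs=1e-9)

    def test_four_class_accuracy_is_weighted_diagonal(self, rng):
        m = ConfusionMatrix.from_pairs([random_pair(rng, 300)])
        want = 100 * float(m.prevalence @ np.diag(m.row_normalized))
        assert ebe.accuracy4(m) == pytest.approx(want, abs=1e-9)


class TestCohensKappa:
    def test_diagonal_matrix_is_one(self):
        m = ConfusionMatrix(counts=np.diag([5, 10, 3, 2]))
        assert cohens_kappa(m, 4) == pytest.approx(1.0)
        assert cohens_kappa(m, 2) == pytest.approx(1.0)

    def test_outer_product_of_marginals_is_zero(self, rng):
        row = np.array([0.3, 0.4, 0.2, 0.1])
        col = np.array([0.25, 0.35, 0.25, 0.15])
        m = ConfusionMatrix(counts=1000 * np.outer(row, col))
        assert cohens_kappa(m, 4) == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_label_permutation(self, rng):
        m = ConfusionMatrix.from_pairs([random_pair(rng, 400)])
        k = cohens_kappa(m, 4)
        perm = rng.permutation(4)
        m2 = ConfusionMatrix(counts=m.counts[np.ix_(perm, perm)])
        assert cohens_kappa(m2, 4) == pytest.approx(k, abs=1e-12)

    def test_degenerate_single_cell(self):
        counts = np.zeros((4, 4))
        counts[1, 1] = 50
        assert cohens_kappa(ConfusionMatrix(counts=counts), 4) == 1.0
        counts2 = np.zeros((4, 4))
        counts2[1, 2] = 50
        assert cohens_kappa(ConfusionMatrix(counts=counts2), 4) == 0.0


class TestStageAccuracy:
    def test_stage_absent_from_both_is_vacuously_perfect(self):
        p = _pair(["W", "N12"] * 3, ["W", "N12"] * 3)
        m = ConfusionMatrix.from_pairs(p)
        assert stage_accuracy_one_vs_rest(m, "REM") == 100.0


class TestPerNightSummary:
    def test_duplicate_night_mean_equals_single(self, rng):
        p = random_pair(rng, 60)
        table, mean, pooled = per_night_summary([p, p])
        single = EBEMetrics.from_matrix(ConfusionMatrix.from_pairs(p))
        assert mean == single
        assert pooled.total == 120

    def test_mean_of_nights_vs_pooled_brute_force(self, rng):
        a = _pair(["W"] * 5 + ["N12"] * 5, ["W"] * 4 + ["N12"] * 6)
        b = _pair(["W"] * 5 + ["REM"] * 15, ["N3"] * 5 + ["REM"] * 15)
        table, mean, pooled = per_night_summary([a, b])
        acc_a = 100 * 9 / 10
        acc_b = 100 * 15 / 20
        assert mean.accuracy4_pct == pytest.approx((acc_a + acc_b) / 2)
        pooled_acc = 100 * (9 + 15) / 30
        assert ebe.accuracy4(pooled) == pytest.approx(pooled_acc)
        assert mean.accuracy4_pct != pytest.approx(pooled_acc)

    def test_undefined_specificity_excluded_from_mean(self, rng):
        no_wake = _pair(["N12"] * 10, ["N12"] * 10)
        mixed = _pair(["W"] * 5 + ["N12"] * 5, ["W"] * 5 + ["N12"] * 5)
        table, mean, _ = per_night_summary([no_wake, mixed])
        assert mean.specificity_pct == 100.0
        assert table["specificity_pct"].isna().sum() == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_night_summary([])


class TestLandisKoch:
    @pytest.mark.parametrize("kappa,label", [
        (-0.1, "poor"), (0.0, "slight"), (0.20, "slight"), (0.21, "fair"),
        (0.40, "fair"), (0.54, "moderate"), (0.60, "moderate"),
        (0.65, "substantial"), (0.80, "substantial"), (0.81, "almost perfect"),
        (1.0, "almost perfect")])
    def test_bands(self, kappa, label):
        assert landis_koch_rating(kappa) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            landis_koch_rating(1.2)
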