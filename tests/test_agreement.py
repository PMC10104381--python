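import math

import numpy as np
import pytest
from scipy import stats

from somnoval.agreement import (bland_altman_replicates, cicchetti_rating,
                                icc_absolute_agreement_avg, sign_convention,
                                trim_by_difference)


def icc_oracle(ref, dev):
    """Explicit sums-of-squares two-way ANOVA, absolute agreement,
    average measures over k = 2 raters."""
    y = np.column_stack([ref, dev]).astype(float)
    n, k = y.shape
    grand = y.mean()
    msr = k * sum((y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def classic_bland_altman(diffs, z=1.96):
    """Direct one-difference-per-subject Bland-Altman."""
    d = np.asarray(diffs, dtype=float)
    bias = d.mean()
    sd = d.std(ddof=1)
    return bias, bias - z * sd, bias + z * sd


class TestTrimming:
    def test_forty_pairs_drop_one_per_tail(self, rng):
        ref = rng.normal(size=40)
        dev = ref + rng.normal(size=40)
        keep = trim_by_difference(ref, dev, 0.05)
        assert keep.size == 38
        d = dev - ref
        assert d[keep].max() < d.max() and d[keep].min() > d.min()

    def test_small_sample_unchanged(self, rng):
        ref = rng.normal(size=10)
        keep = trim_by_difference(ref, ref + rng.normal(size=10), 0.05)
        assert keep.size == 10

    def test_study_sized_sample_keeps_234(self, rng):
        ref = rng.normal(size=246)
        dev = ref + rng.normal(size=246)
        keep = trim_by_difference(ref, dev, 0.05)
        assert keep.size == 234
        # brute-force sort-and-slice oracle
        d = dev - ref
        inner = np.sort(d)[6:-6]
        assert np.allclose(np.sort(d[keep]), inner)

    def test_never_removes_more_than_fraction(self, rng):
        for n in (7, 19, 40, 101, 246):
            ref = rng.normal(size=n)
            keep = trim_by_difference(ref, ref + rng.normal(size=n), 0.05)
            assert n - keep.size <= math.floor(n * 0.05)

    def test_order_preserved(self, rng):
        ref = rng.normal(size=60)
        keep = trim_by_difference(ref, ref + rng.normal(size=60), 0.05)
        assert np.all(np.diff(keep) > 0)

    def test_full_trim_fraction_rejected(self):
        with pytest.raises(ValueError):
            trim_by_difference([1.0, 2.0], [9.0, -9.0], 1.0)
        with pytest.raises(ValueError):
            trim_by_difference([], [], 0.05)


class TestICC:
    def test_perfect_agreement(self, rng):
        ref = rng.normal(100, 20, 30)
        res = icc_absolute_agreement_avg(ref, ref.copy())
        assert res.estimate == pytest.approx(1.0)
        assert res.rating == "excellent"

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            ref = rng.normal(0, rng.uniform(0.5, 50), n)
            dev = ref * rng.uniform(0.5, 1.5) + rng.normal(0, 5, n)
            res = icc_absolute_agreement_avg(ref, dev)
            want = icc_oracle(ref, dev)
            assert abs(res.estimate - min(want, 1.0)) < 1e-10

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        ref = rng.normal(100, 20, 40)
        dev = ref + rng.normal(3, 8, 40)
        res = icc_absolute_agreement_avg(ref, dev)
        df = pd.DataFrame({"s": list(range(40)) * 2,
                           "r": ["a"] * 40 + ["b"] * 40,
                           "y": np.concatenate([ref, dev])})
        table = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = table[table["Type"].astype(str).str.contains("A,k|2k")].iloc[0]
        assert res.estimate == pytest.approx(float(row["ICC"]), abs=1e-9)
        ci = row[table.columns[-1]]          # pingouin rounds to 2 decimals
        assert res.ci_lower == pytest.approx(float(ci[0]), abs=6e-3)

    def test_systematic_offset_decreases_estimate(self, rng):
        ref = rng.normal(100, 20, 50)
        noise = rng.normal(0, 2, 50)
        estimates = [icc_absolute_agreement_avg(ref, ref + noise + c).estimate
                     for c in (0.0, 10.0, 25.0, 60.0)]
        assert all(a > b for a, b in zip(estimates, estimates[1:]))

    def test_symmetric_in_raters(self, rng):
        ref = rng.normal(50, 10, 25)
        dev = ref + rng.normal(2, 4, 25)
        a = icc_absolute_agreement_avg(ref, dev).estimate
        b = icc_absolute_agreement_avg(dev, ref).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_variance_degenerate(self):
        res = icc_absolute_agreement_avg([5.0] * 5, [5.0] * 5)
        assert res.estimate == 1.0 and res.degenerate

    def test_ci_lower_below_estimate(self, rng):
        ref = rng.normal(0, 10, 20)
        res = icc_absolute_agreement_avg(ref, ref + rng.normal(0, 6, 20))
        assert res.ci_lower <= res.estimate


class TestCicchetti:
    @pytest.mark.parametrize("icc,label", [
        (-0.2, "poor"), (0.39, "poor"), (0.40, "fair"), (0.43, "fair"),
        (0.59, "fair"), (0.60, "good"), (0.74, "good"), (0.75, "excellent"),
        (1.0, "excellent")])
    def test_bands(self, icc, label):
        assert cicchetti_rating(icc) == label


class TestBlandAltman:
    def test_two_subject_closed_form(self):
        res = bland_altman_replicates({"a": [(0.0, 1.0)], "b": [(1.0, 0.0)]})
        assert res.bias == 0.0
        assert res.sd_total == pytest.approx(math.sqrt(2), abs=1e-12)
        assert res.loa_upper == pytest.approx(1.96 * math.sqrt(2), abs=1e-9)
        assert res.loa_lower == pytest.approx(-res.loa_upper)

    def test_all_zero_differences_degenerate(self):
        res = bland_altman_replicates({"a": [(5.0, 5.0), (7.0, 7.0)],
                                       "b": [(3.0, 3.0)]})
        assert res.bias == res.loa_lower == res.loa_upper == 0.0
        assert res.degenerate

    def test_reduces_to_classic_with_single_replicates(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 60))
            d = rng.normal(rng.normal(0, 5), rng.uniform(0.5, 20), n)
            data = {f"s{i}": [(float(d[i]), 0.0)] for i in range(n)}
            res = bland_altman_replicates(data)
            bias, lo, hi = classic_bland_altman(d)
            assert res.bias == pytest.approx(bias, abs=1e-12)
            assert res.loa_lower == pytest.approx(lo, abs=1e-9)
            assert res.loa_upper == pytest.approx(hi, abs=1e-9)
            assert res.s_within == 0.0 and res.m_harmonic == 1.0

    def _simulate(self, rng, n=120, bias=5.0, sb=20.0, sw=10.0):
        data = {}
        for i in range(n):
            m = int(rng.integers(1, 4))
            mu = bias + rng.normal(0, sb)
            data[f"s{i}"] = [(float(mu + rng.normal(0, sw)), 0.0)
                             for _ in range(m)]
        return data

    def test_mover_intervals_contain_point_limits(self, rng):
        res = bland_altman_replicates(self._simulate(rng))
        assert res.loa_lower_ci[0] <= res.loa_lower <= res.loa_lower_ci[1]
        assert res.loa_upper_ci[0] <= res.loa_upper <= res.loa_upper_ci[1]
        assert res.loa_lower <= res.bias <= res.loa_upper

    def test_interval_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 500, 5000):
            res = bland_altman_replicates(self._simulate(rng, n=n))
            widths.append(res.loa_upper_ci[1] - res.loa_upper_ci[0])
        assert widths[0] > widths[1] > widths[2]

    def test_variance_pooling_identity(self, rng):
        res = bland_altman_replicates(self._simulate(rng))
        want = math.sqrt(res.s_between ** 2 +
                         (1 - 1 / res.m_harmonic) * res.s_within ** 2)
        assert res.sd_total == pytest.approx(want, abs=1e-12)

    def test_harmonic_mean_of_replicates(self):
        data = {"a": [(1.0, 0.0)], "b": [(1.0, 0.0), (2.0, 0.0)],
                "c": [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]}
        res = bland_altman_replicates(data)
        assert res.m_harmonic == pytest.approx(3 / (1 + 0.5 + 1 / 3))
        assert res.n_nights == 6

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            bland_altman_replicates({"a": [(1.0, 2.0)]})


class TestSignConvention:
    @pytest.mark.parametrize("bias,label", [
        (7.69, "device underestimates"), (-2.07, "device overestimates"),
        (0.0, "no bias")])
    def test_interpretation(self, bias, label):
        assert sign_convention(bias) == label
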