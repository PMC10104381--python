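"""Subject-level method-agreement statistics.

Three tools used to compare a device against a reference across
subjects, each subject possibly contributing several nights:

* two-sided trimming of the most extreme device-reference differences
  before reliability estimation;
* the absolute-agreement average-measures intraclass correlation
  ICC(A,k) from a two-way layout (subjects random, raters fixed, k = 2),
  with its F-based 95% lower bound and Cicchetti qualitative rating;
* repeated-measures Bland–Altman limits of agreement for unequal
  replicate counts: the bias is the mean of per-subject mean
  differences, the SD of a single difference pools the between-subject
  and within-subject variance components through the harmonic mean of
  the replicate counts, and confidence intervals for the limits use the
  MOVER (method of variance estimates recovery) construction.

Sign convention: differences are reference minus device, so a positive
bias means the device *underestimates* the quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ebe import landis_koch_rating  # noqa: F401  (re-export convenience)


# ---------------------------------------------------------------------------
# Trimming

def trim_by_difference(reference: Sequence[float], device: Sequence[float],
                       total_fraction: float = 0.05) -> np.ndarray:
    """Indices kept after two-sided trimming of extreme differences.

    Computes d = device - reference per pair and removes the
    floor(n * total_fraction / 2) pairs with the largest d and as many
    with the smallest d (2.5% per tail at the default 5%).  Returns the
    kept indices in their original order.
    """
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    if ref.shape != dev.shape or ref.ndim != 1:
        raise ValueError("reference and device must be equal-length 1-D")
    n = ref.size
    if n == 0:
        raise ValueError("no pairs to trim")
    if not (0 <= total_fraction < 1):
        raise ValueError("total_fraction must be in [0, 1)")
    k = int(math.floor(n * total_fraction / 2))
    if 2 * k >= n:
        raise ValueError("trimming would remove every pair")
    if k == 0:
        return np.arange(n)
    order = np.argsort(dev - ref, kind="stable")
    drop = set(order[:k]) | set(order[-k:])
    return np.array([i for i in range(n) if i not in drop])


# ---------------------------------------------------------------------------
# ICC, absolute agreement, average measures (two-way layout, k = 2 raters)

#: Cicchetti qualitative bands for ICC.
_CICCHETTI = [(0.40, "poor"), (0.60, "fair"), (0.75, "good"),
              (1.01, "excellent")]


def cicchetti_rating(icc: float) -> str:
    """Qualitative band: <0.40 poor, 0.40–0.59 fair, 0.60–0.74 good,
    0.75–1 excellent.  Values below 0 rate as poor."""
    for upper, label in _CICCHETTI:
        if icc < upper:
            return label
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    rating: str
    n_subjects_used: int
    n_trimmed: int
    degenerate: bool = False

    def __post_init__(self):
        if self.estimate > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


def icc_absolute_agreement_avg(reference: Sequence[float],
                               device: Sequence[float],
                               alpha: float = 0.05,
                               n_trimmed: int = 0) -> ICCResult:
    """ICC(A,k): absolute-agreement, average-measures, two raters.

    From the two-way subject x rater layout with mean squares MSR
    (subjects), MSC (raters) and MSE (residual):

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    The one-sided lower confidence bound follows the standard F-interval
    for the single-measures form ICC(A,1) with Satterthwaite denominator
    degrees of freedom, stepped up to average measures via the
    Spearman-Brown relation.  With zero total variance (all values
    identical) the estimate is 1 with a degenerate CI, flagged.
    """
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    if ref.shape != dev.shape or ref.ndim != 1:
        raise ValueError("reference and device must be equal-length 1-D")
    n = ref.size
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    k = 2
    y = np.column_stack([ref, dev])          # n x k
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    if ss_tot <= 1e-300:
        return ICCResult(estimate=1.0, ci_lower=1.0, rating="excellent",
                         n_subjects_used=n, n_trimmed=n_trimmed,
                         degenerate=True)

    denom = msr + (msc - mse) / n
    est = (msr - mse) / denom if denom > 0 else 0.0
    est = min(est, 1.0)

    icc_a1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc_a1 >= 1.0 - 1e-12:
        lower_k = est                      # agreement is essentially exact
    else:
        a = k * icc_a1 / (n * (1 - icc_a1))
        b = 1 + k * icc_a1 * (n - 1) / (n * (1 - icc_a1))
        num_df = (a * msc + b * mse) ** 2
        den_df = ((a * msc) ** 2 / (k - 1)
                  + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = num_df / den_df if den_df > 0 else 1.0
        if not math.isfinite(v) or v < 1.0:
            v = 1.0                        # clamp degenerate Satterthwaite df
        f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
        den = f_star * (k * msc + (k * n - k - n) * mse) + n * msr
        lower_1 = n * (msr - f_star * mse) / den if den > 0 else est
        lower_k = lower_1 * k / (1 + (k - 1) * lower_1)
        if not math.isfinite(lower_k):
            lower_k = est
    lower_k = min(max(lower_k, -1.0), est)

    return ICCResult(estimate=est, ci_lower=lower_k,
                     rating=cicchetti_rating(est),
                     n_subjects_used=n, n_trimmed=n_trimmed)


# ---------------------------------------------------------------------------
# Repeated-measures Bland-Altman with MOVER limits

@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 95% limits of agreement under replicated measurements.

    ``bias`` is the mean of per-subject mean differences (reference minus
    device); ``s_between`` the SD of those subject means; ``s_within``
    the pooled within-subject SD of the differences; ``m_harmonic`` the
    harmonic mean of replicate counts.  The SD of a single difference is

        sd_total**2 = s_between**2 + (1 - 1/m_harmonic) * s_within**2

    and the limits of agreement are bias +/- z * sd_total.
    """

    bias: float
    bias_ci: tuple[float, float]
    s_between: float
    s_within: float
    m_harmonic: float
    sd_total: float
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    n_subjects: int
    n_nights: int
    degenerate: bool = False


def sign_convention(bias: float) -> str:
    """Interpretation of the bias under the reference-minus-device sign:
    positive means the device underestimates the quantity."""
    if bias > 0:
        return "device underestimates"
    if bias < 0:
        return "device overestimates"
    return "no bias"


def bland_altman_replicates(
        data: Mapping[str, Sequence[tuple[float, float]]],
        z: float = 1.96, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland-Altman limits of agreement with replicated measurements.

    Parameters
    ----------
    data : mapping subject -> list of (reference, device) night values.
    z : multiplier for the limits (1.96 gives 95% limits).
    alpha : confidence level for the bias and LoA intervals.

    Notes
    -----
    With a single night per subject the estimator reduces exactly to the
    classic Bland-Altman analysis of one difference per subject.  LoA
    confidence intervals use MOVER: each component variance receives a
    chi-square interval, the interval for the composite ``sd_total**2``
    recovers the component intervals in quadrature, and each limit's CI
    combines the bias CI half-width with the half-width of the CI of
    ``z * sd_total``, again in quadrature.
    """
    subjects = list(data)
    n = len(subjects)
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 subjects")
    d_means = np.empty(n)
    m_counts = np.empty(n)
    ss_within = 0.0
    n_nights = 0
    for i, sid in enumerate(subjects):
        pairs = np.asarray(data[sid], dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
            raise ValueError(f"subject {sid!r}: expected nonempty list of "
                             "(reference, device) pairs")
        d = pairs[:, 0] - pairs[:, 1]        # reference minus device
        d_means[i] = d.mean()
        m_counts[i] = d.size
        ss_within += ((d - d.mean()) ** 2).sum()
        n_nights += d.size

    bias = float(d_means.mean())
    s_b = float(d_means.std(ddof=1))
    df_w = int(n_nights - n)                 # sum of (m_i - 1)
    s_w = math.sqrt(ss_within / df_w) if df_w > 0 else 0.0
    m_h = n / float((1.0 / m_counts).sum())
    c = 1.0 - 1.0 / m_h
    var_total = s_b ** 2 + c * s_w ** 2
    sd_total = math.sqrt(var_total)
    loa_lower = bias - z * sd_total
    loa_upper = bias + z * sd_total

    se_bias = s_b / math.sqrt(n)
    t = stats.t.ppf(1 - alpha / 2, n - 1)
    bias_hw = t * se_bias
    bias_ci = (bias - bias_hw, bias + bias_hw)

    degenerate = var_total <= 0
    if degenerate:
        zero = (loa_lower, loa_lower)
        return BlandAltmanResult(
            bias=bias, bias_ci=bias_ci, s_between=s_b, s_within=s_w,
            m_harmonic=m_h, sd_total=sd_total, loa_lower=loa_lower,
            loa_upper=loa_upper, loa_lower_ci=zero,
            loa_upper_ci=(loa_upper, loa_upper), n_subjects=n,
            n_nights=n_nights, degenerate=True)

    # MOVER interval for var_total = s_b^2 + c * s_w^2: chi-square limits
    # per component, discrepancies combined in quadrature.
    vb = s_b ** 2
    vw = c * s_w ** 2
    lb = vb * (n - 1) / stats.chi2.ppf(1 - alpha / 2, n - 1)
    ub = vb * (n - 1) / stats.chi2.ppf(alpha / 2, n - 1)
    if df_w > 0 and vw > 0:
        lw = vw * df_w / stats.chi2.ppf(1 - alpha / 2, df_w)
        uw = vw * df_w / stats.chi2.ppf(alpha / 2, df_w)
    else:
        lw = uw = vw
    var_lo = var_total - math.sqrt((vb - lb) ** 2 + (vw - lw) ** 2)
    var_hi = var_total + math.sqrt((ub - vb) ** 2 + (uw - vw) ** 2)
    var_lo = max(var_lo, 0.0)
    sd_lo_hw = z * (sd_total - math.sqrt(var_lo))
    sd_hi_hw = z * (math.sqrt(var_hi) - sd_total)

    # Each limit: quadrature of the bias CI half-width with the
    # half-width of the CI of z * sd_total, on the matching side.
    inner_hw = math.sqrt(bias_hw ** 2 + sd_lo_hw ** 2)
    outer_hw = math.sqrt(bias_hw ** 2 + sd_hi_hw ** 2)
    loa_lower_ci = (loa_lower - outer_hw, loa_lower + inner_hw)
    loa_upper_ci = (loa_upper - inner_hw, loa_upper + outer_hw)

    return BlandAltmanResult(
        bias=bias, bias_ci=bias_ci, s_between=s_b, s_within=s_w,
        m_harmonic=m_h, sd_total=sd_total, loa_lower=loa_lower,
        loa_upper=loa_upper, loa_lower_ci=loa_lower_ci,
        loa_upper_ci=loa_upper_ci, n_subjects=n, n_nights=n_nights)
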