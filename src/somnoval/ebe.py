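"""Epoch-by-epoch agreement between paired hypnograms.

Implements the confusion matrix (reference stages in rows, device stages
in columns), wake/sleep and four-class accuracy, sensitivity/specificity,
Cohen's kappa, per-stage one-vs-rest accuracy, per-night aggregation, and
the Landis–Koch qualitative kappa bands.

Sensitivity is the ability to correctly classify reference sleep epochs
(positive class = any sleep stage); specificity is the ability to
correctly classify reference wake epochs.

Metric functions accept either integer epoch counts or a joint
probability table scaled to any total: everything is computed on
proportions, so a matrix reconstructed from published row-normalized
percentages and stage prevalences yields the same metrics as the raw
epoch tallies it summarizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hypnogram import PairedNight, STAGES_4

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES_4)}
_W = _STAGE_INDEX["W"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Reference-by-device stage cross-tabulation.

    ``counts[r, c]`` is the number (or probability mass) of epochs scored
    as stage ``labels[r]`` by the reference and ``labels[c]`` by the
    device.  Rows are the reference (PSG), columns the device.
    """

    counts: np.ndarray
    labels: tuple[str, ...] = STAGES_4

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError(f"counts must be {len(self.labels)}x"
                             f"{len(self.labels)}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("negative cell in confusion matrix")
        if c.sum() <= 0:
            raise ValueError("confusion matrix holds zero epochs")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def row_normalized(self) -> np.ndarray:
        """Row-stochastic matrix P(device stage | reference stage)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            out = np.where(rows > 0, self.counts / np.where(rows > 0, rows, 1),
                           0.0)
        return out

    @property
    def prevalence(self) -> np.ndarray:
        """Reference stage shares of the total epochs (sums to 1)."""
        return self.counts.sum(axis=1) / self.total

    @classmethod
    def from_pairs(cls, pairs: "PairedNight | Iterable[PairedNight]"
                   ) -> "ConfusionMatrix":
        """Tally one night or a pooled collection of aligned nights."""
        if isinstance(pairs, PairedNight):
            pairs = [pairs]
        counts = np.zeros((4, 4), dtype=float)
        n_pairs = 0
        for p in pairs:
            n_pairs += 1
            ridx = np.fromiter((_STAGE_INDEX[s] for s in p.ref.stages),
                               dtype=np.intp, count=p.n_epochs)
            cidx = np.fromiter((_STAGE_INDEX[s] for s in p.test.stages),
                               dtype=np.intp, count=p.n_epochs)
            np.add.at(counts, (ridx, cidx), 1)
        if n_pairs == 0:
            raise ValueError("no paired nights supplied")
        return cls(counts=counts)

    @classmethod
    def from_row_normalized(cls, row_probs: Sequence[Sequence[float]],
                            prevalence: Sequence[float],
                            total: float = 1.0) -> "ConfusionMatrix":
        """Rebuild joint counts from row-conditional probabilities.

        ``counts[r, c] = total * prevalence[r] * row_probs[r][c]`` — the
        inverse of (row_normalized, prevalence, total), so published
        row-normalized tables can be fed back into every metric.
        """
        rp = np.asarray(row_probs, dtype=float)
        prev = np.asarray(prevalence, dtype=float)
        return cls(counts=total * prev[:, None] * rp)


def confusion_counts(pairs) -> ConfusionMatrix:
    """Alias for :meth:`ConfusionMatrix.from_pairs`."""
    return ConfusionMatrix.from_pairs(pairs)


def _binarize(counts: np.ndarray) -> np.ndarray:
    """Collapse the 4x4 table to 2x2 [wake, sleep] x [wake, sleep]."""
    sleep = [i for i in range(len(STAGES_4)) if i != _W]
    b = np.empty((2, 2))
    b[0, 0] = counts[_W, _W]
    b[0, 1] = counts[_W, sleep].sum()
    b[1, 0] = counts[sleep, _W].sum()
    b[1, 1] = counts[np.ix_(sleep, sleep)].sum()
    return b


def binary_metrics(matrix: ConfusionMatrix | PairedNight
                   ) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, wake/sleep accuracy %).

    Sensitivity = P(device sleep | reference sleep); specificity =
    P(device wake | reference wake).  Either is NaN when its reference
    class is absent from the night.
    """
    if isinstance(matrix, PairedNight):
        matrix = ConfusionMatrix.from_pairs(matrix)
    b = _binarize(matrix.counts)
    total = b.sum()
    n_wake, n_sleep = b[0].sum(), b[1].sum()
    sens = 100.0 * b[1, 1] / n_sleep if n_sleep > 0 else math.nan
    spec = 100.0 * b[0, 0] / n_wake if n_wake > 0 else math.nan
    acc = 100.0 * (b[0, 0] + b[1, 1]) / total
    return sens, spec, acc


def cohens_kappa(matrix: ConfusionMatrix, classes: int = 4) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    ``classes=2`` binarizes to wake/sleep first.  Expected agreement p_e
    is the product of row and column marginals.  In the degenerate case
    p_e == 1 (all mass in one marginal cell) kappa is 1 if observed
    agreement is perfect, else 0.
    """
    if classes == 2:
        c = _binarize(matrix.counts)
    elif classes == 4:
        c = matrix.counts
    else:
        raise ValueError("classes must be 2 or 4")
    p = c / c.sum()
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe >= 1.0 - 1e-12:
        return 1.0 if po >= 1.0 - 1e-12 else 0.0
    return (po - pe) / (1.0 - pe)


def accuracy4(matrix: ConfusionMatrix) -> float:
    """Four-class overall accuracy, percent."""
    return 100.0 * float(np.trace(matrix.counts)) / matrix.total


def stage_accuracy_one_vs_rest(matrix: ConfusionMatrix, stage: str) -> float:
    """Binary accuracy for one stage against the other three, percent.

    Binarizes both raters to stage/not-stage; accuracy = (TP + TN)/total.
    This is the per-stage accuracy column conventionally printed next to a
    row-normalized confusion matrix.
    """
    i = _STAGE_INDEX[stage]
    c = matrix.counts
    tp = c[i, i]
    fn = c[i, :].sum() - tp
    fp = c[:, i].sum() - tp
    return 100.0 * (matrix.total - fn - fp) / matrix.total


@dataclass(frozen=True)
class EBEMetrics:
    """Agreement metrics for one night or an aggregate."""

    sensitivity_pct: float
    specificity_pct: float
    accuracy2_pct: float
    kappa2: float
    accuracy4_pct: float
    kappa4: float

    @classmethod
    def from_matrix(cls, m: ConfusionMatrix) -> "EBEMetrics":
        sens, spec, acc2 = binary_metrics(m)
        return cls(sensitivity_pct=sens, specificity_pct=spec,
                   accuracy2_pct=acc2, kappa2=cohens_kappa(m, 2),
                   accuracy4_pct=accuracy4(m), kappa4=cohens_kappa(m, 4))


_METRIC_COLS = ["sensitivity_pct", "specificity_pct", "accuracy2_pct",
                "kappa2", "accuracy4_pct", "kappa4"]


def per_night_summary(nights: Iterable[PairedNight]
                      ) -> tuple[pd.DataFrame, EBEMetrics, ConfusionMatrix]:
    """Per-night metrics, their unweighted mean, and the pooled matrix.

    Metrics are computed on each night independently before the
    distribution over nights is summarized; the mean is the unweighted
    arithmetic mean over nights, skipping nights where a metric is
    undefined (e.g. specificity on a night with no wake).  The pooled
    matrix sums epoch counts over all nights.
    """
    nights = list(nights)
    if not nights:
        raise ValueError("no paired nights supplied")
    rows = []
    for p in nights:
        m = ConfusionMatrix.from_pairs(p)
        met = EBEMetrics.from_matrix(m)
        rows.append({"subject_id": p.subject_id, "night_id": p.night_id,
                     "group": p.group, "n_epochs": p.n_epochs,
                     **{k: getattr(met, k) for k in _METRIC_COLS}})
    table = pd.DataFrame(rows)
    mean = EBEMetrics(**{k: float(table[k].mean()) for k in _METRIC_COLS})
    pooled = ConfusionMatrix.from_pairs(nights)
    return table, mean, pooled


#: Landis–Koch qualitative bands for kappa, upper edge inclusive.
_LANDIS_KOCH = [(0.0, "poor"), (0.20, "slight"), (0.40, "fair"),
                (0.60, "moderate"), (0.80, "substantial"),
                (1.0, "almost perfect")]


def landis_koch_rating(kappa: float) -> str:
    """Qualitative agreement band for a kappa value.

    <0 poor; 0–0.20 slight; 0.21–0.40 fair; 0.41–0.60 moderate;
    0.61–0.80 substantial; 0.81–1 almost perfect.
    """
    if kappa > 1:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "poor"
    for upper, label in _LANDIS_KOCH[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"
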