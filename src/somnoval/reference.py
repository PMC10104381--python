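"""Published reference agreement tables for an HR + actimetry sleep stager.

These are the row-normalized confusion matrices (device stage given PSG
stage) and PSG stage prevalences reported by a multi-group validation
study of heart-rate + actimetry sleep staging against polysomnography
(healthy sleepers and patients with obstructive sleep apnea, insomnia or
major depressive disorder; 458 nights in total).  They serve two roles:

* printed inputs for desk-scale checks — the epoch-by-epoch metric
  formulas must reproduce the study's published accuracy/kappa values
  from these cells alone;
* default stage-conditional corruption probabilities for the synthetic
  cohort generator.

Rows/columns follow the canonical stage order (W, N12, N3, REM); values
are proportions.
"""

from __future__ import annotations

import numpy as np

from .ebe import ConfusionMatrix

#: Row-normalized P(device stage | PSG stage), per study group.
REFERENCE_CONFUSION: dict[str, np.ndarray] = {
    "all": np.array([
        [0.695, 0.239, 0.019, 0.047],
        [0.093, 0.690, 0.127, 0.089],
        [0.015, 0.327, 0.641, 0.017],
        [0.046, 0.240, 0.014, 0.701],
    ]),
    "healthy": np.array([
        [0.733, 0.218, 0.012, 0.037],
        [0.071, 0.693, 0.144, 0.092],
        [0.012, 0.296, 0.676, 0.017],
        [0.027, 0.182, 0.005, 0.786],
    ]),
    "OSA": np.array([
        [0.645, 0.280, 0.032, 0.044],
        [0.137, 0.637, 0.124, 0.102],
        [0.049, 0.302, 0.629, 0.019],
        [0.072, 0.281, 0.008, 0.639],
    ]),
    "insomnia": np.array([
        [0.745, 0.199, 0.012, 0.044],
        [0.097, 0.694, 0.120, 0.088],
        [0.008, 0.336, 0.637, 0.020],
        [0.051, 0.259, 0.015, 0.675],
    ]),
    "MDD": np.array([
        [0.658, 0.268, 0.023, 0.052],
        [0.093, 0.696, 0.125, 0.086],
        [0.017, 0.339, 0.630, 0.014],
        [0.048, 0.250, 0.018, 0.683],
    ]),
    "pathologies": np.array([
        [0.692, 0.241, 0.019, 0.048],
        [0.099, 0.689, 0.123, 0.089],
        [0.016, 0.335, 0.632, 0.017],
        [0.051, 0.256, 0.016, 0.677],
    ]),
}

#: PSG stage prevalence (share of scored epochs), per study group.
REFERENCE_PREVALENCE: dict[str, np.ndarray] = {
    "all": np.array([0.232, 0.452, 0.155, 0.161]),
    "healthy": np.array([0.096, 0.514, 0.188, 0.202]),
    "OSA": np.array([0.249, 0.495, 0.117, 0.139]),
    "insomnia": np.array([0.296, 0.405, 0.151, 0.148]),
    "MDD": np.array([0.239, 0.452, 0.152, 0.157]),
    "pathologies": np.array([0.260, 0.439, 0.148, 0.152]),
}

#: Nights analyzed per study group.
REFERENCE_N_NIGHTS = {"all": 458, "healthy": 79, "OSA": 33,
                      "insomnia": 135, "MDD": 211, "pathologies": 379}


def reference_matrix(group: str = "all") -> ConfusionMatrix:
    """The published group matrix as a joint-probability ConfusionMatrix."""
    return ConfusionMatrix.from_row_normalized(
        REFERENCE_CONFUSION[group], REFERENCE_PREVALENCE[group])
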