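"""Sleep architecture and continuity descriptors from a 30-s hypnogram.

All quantities are in minutes except sleep efficiency (percent).  Epoch 0
is lights-off; the final epoch ends at lights-on.  Definitions:

* TIB  — time in bed, lights-off to lights-on.
* SL   — sleep latency: lights-off to the first non-wake epoch.
* TST  — total sleep time: minutes spent in any sleep stage.
* SE   — sleep efficiency, 100 * TST / TIB.
* WASO — wake after sleep onset: all wake minutes from sleep onset to
  lights-on (terminal wake included, so wake = SL + WASO exactly).
* LPS  — latency to persistent sleep: lights-off to the start of the
  first run of at least ``persistent_window_min`` minutes of
  uninterrupted sleep (any mixture of sleep stages by default).
* REML — REM latency: elapsed time from sleep onset to the first REM
  epoch, intervening wake included.

SL, LPS and REML are undefined (NaN) on nights where the defining event
never occurs; WASO is 0 on a night with no sleep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

from .hypnogram import Hypnogram, HypnogramError

_MIN_PER_EPOCH = 0.5


@dataclass(frozen=True)
class SleepParameters:
    """The 12 architecture/continuity descriptors for one night (or mean)."""

    tib_min: float
    tst_min: float
    se_pct: float
    sl_min: float        # NaN if the night contains no sleep
    waso_min: float
    lps_min: float       # NaN if no qualifying persistent-sleep run
    reml_min: float      # NaN if no REM (or no sleep)
    wake_min: float
    n12_min: float
    n3_min: float
    nrem_min: float
    rem_min: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PARAMETER_FIELDS = [f.name for f in fields(SleepParameters)]

#: Short display names used in tidy outputs, one per dataclass field.
PARAMETER_LABELS = {
    "tib_min": "TIB", "tst_min": "TST", "se_pct": "SE", "sl_min": "SL",
    "waso_min": "WASO", "lps_min": "LPS", "reml_min": "REML",
    "wake_min": "Wake", "n12_min": "N1+N2", "n3_min": "N3",
    "nrem_min": "NREM", "rem_min": "REM",
}


def compute_sleep_parameters(hyp: Hypnogram,
                             persistent_window_min: float = 10.0,
                             lps_single_stage: bool = False
                             ) -> SleepParameters:
    """Derive sleep parameters from a collapsed 30-s hypnogram.

    Parameters
    ----------
    hyp : four-class 30-s hypnogram.
    persistent_window_min : minimum uninterrupted-sleep duration defining
        persistent sleep (default 10 min, i.e. 20 consecutive epochs).
    lps_single_stage : if True, the persistent run must stay within one
        single sleep stage rather than any mixture of sleep stages.
    """
    if hyp.epoch_s != 30:
        raise HypnogramError("sleep parameters require a 30-s hypnogram")
    if not hyp.is_collapsed:
        raise HypnogramError("sleep parameters require four-class stages")
    stages = hyp.stages
    n = len(stages)
    tib = n * _MIN_PER_EPOCH

    sleep = [s != "W" for s in stages]
    n_sleep = sum(sleep)
    tst = n_sleep * _MIN_PER_EPOCH
    se = 100.0 * tst / tib

    onset = next((i for i, s in enumerate(sleep) if s), None)
    if onset is None:
        sl = math.nan
        waso = 0.0
    else:
        sl = onset * _MIN_PER_EPOCH
        waso = sum(1 for s in stages[onset:] if s == "W") * _MIN_PER_EPOCH

    window_epochs = int(round(persistent_window_min / _MIN_PER_EPOCH))
    lps = _latency_to_persistent_sleep(stages, window_epochs,
                                       lps_single_stage)

    if onset is None:
        reml = math.nan
    else:
        first_rem = next((i for i in range(onset, n) if stages[i] == "REM"),
                         None)
        reml = math.nan if first_rem is None else \
            (first_rem - onset) * _MIN_PER_EPOCH

    n12 = sum(1 for s in stages if s == "N12") * _MIN_PER_EPOCH
    n3 = sum(1 for s in stages if s == "N3") * _MIN_PER_EPOCH
    rem = sum(1 for s in stages if s == "REM") * _MIN_PER_EPOCH
    wake = tib - tst

    return SleepParameters(
        tib_min=tib, tst_min=tst, se_pct=se, sl_min=sl, waso_min=waso,
        lps_min=lps, reml_min=reml, wake_min=wake, n12_min=n12, n3_min=n3,
        nrem_min=n12 + n3, rem_min=rem)


def _latency_to_persistent_sleep(stages: Sequence[str], window_epochs: int,
                                 single_stage: bool) -> float:
    """Start (minutes from lights-off) of the first qualifying sleep run."""
    run_start = None
    run_len = 0
    for i, s in enumerate(stages):
        if s == "W":
            run_start, run_len = None, 0
            continue
        if run_start is None or (single_stage and s != stages[i - 1]):
            run_start, run_len = i, 0
        run_len += 1
        if run_len >= window_epochs:
            return run_start * _MIN_PER_EPOCH
    return math.nan


def per_subject_average(
        records: Iterable[tuple[str, SleepParameters]]
        ) -> dict[str, SleepParameters]:
    """Average each subject's nights to one SleepParameters per subject.

    Each field is averaged over the nights where it is defined; a field
    missing in every night of a subject stays missing.  This available-case
    mean keeps latency parameters usable when, say, REM never occurred on
    one of three nights.
    """
    by_subject: dict[str, list[SleepParameters]] = {}
    for sid, params in records:
        by_subject.setdefault(sid, []).append(params)
    if not by_subject:
        raise ValueError("no records to average")
    out = {}
    for sid, plist in by_subject.items():
        means = {}
        for name in PARAMETER_FIELDS:
            vals = [getattr(p, name) for p in plist
                    if not math.isnan(getattr(p, name))]
            means[name] = sum(vals) / len(vals) if vals else math.nan
        out[sid] = SleepParameters(**means)
    return out


def parameters_frame(records: Iterable[tuple[str, str, SleepParameters]]
                     ) -> pd.DataFrame:
    """Tidy frame: one row per (subject, night), one column per parameter."""
    rows = []
    for sid, nid, p in records:
        rows.append({"subject_id": sid, "night_id": nid, **p.as_dict()})
    return pd.DataFrame(rows)
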