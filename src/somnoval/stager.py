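"""Transparent rule-based HR + actimetry sleep stager and signal chain.

This module implements the published signal chain around cardio-
actimetric sleep staging — R-R intervals to 1-Hz heart rate, actimetry
vector magnitude, movement and cardiac-arousal detection, 1-s staging
merged to 30-s epochs, recording-eligibility screening, and HR/actimetry
synchronization — with an openly parameterized rule-based classifier.

The staging rules here are deliberately simple and fully documented:
wake when movement or arousal activity is present, N3 when heart rate
sits in its lowest band with low variability, REM when heart-rate
variability is high without movement, N1+N2 otherwise.  They share the
I/O contract of trained commercial classifiers but make no claim to
their accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .hypnogram import merge_epochs


@dataclass(frozen=True)
class RRSeries:
    """Inter-beat (R-R) interval series defined by beat event times."""

    beat_times_s: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times_s, dtype=float)
        if t.size < 2:
            raise ValueError("need at least two beats")
        if (np.diff(t) <= 0).any():
            raise ValueError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times_s", t)

    @property
    def rr_s(self) -> np.ndarray:
        """Successive inter-beat intervals, seconds."""
        return np.diff(self.beat_times_s)


@dataclass(frozen=True)
class SignalSeries:
    """A uniformly sampled 1-Hz series with an optional missing mask."""

    kind: str                       # "heart_rate_bpm" or "activity_counts"
    values: np.ndarray
    start_s: float = 0.0
    missing_mask: np.ndarray = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = self.missing_mask
        m = np.zeros(v.size, dtype=bool) if m is None \
            else np.asarray(m, dtype=bool)
        if m.size != v.size:
            raise ValueError("missing_mask length mismatch")
        if self.kind == "heart_rate_bpm" and (v[~m] <= 0).any():
            raise ValueError("heart rate must be positive where not masked")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "missing_mask", m)

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EventList:
    """Detected (start_s, end_s, kind) intervals, per-kind non-overlapping."""

    events: tuple

    def of_kind(self, kind: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, k in self.events if k == kind]

    def indicator(self, n: int, kind: str | None = None) -> np.ndarray:
        """Binary 1-Hz indicator of event coverage over ``n`` seconds."""
        ind = np.zeros(n, dtype=float)
        for a, b, k in self.events:
            if kind is None or k == kind:
                ind[max(int(a), 0):min(int(math.ceil(b)), n)] = 1.0
        return ind


def rr_to_heart_rate(rr: RRSeries, max_gap_s: float = 5.0) -> SignalSeries:
    """Instantaneous heart rate HR = 60/RR interpolated onto a 1-Hz grid.

    Each inter-beat interval yields one instantaneous HR sample placed at
    the ending beat; linear interpolation fills the 1-Hz grid.  Grid
    seconds falling inside a beat gap longer than ``max_gap_s`` are
    masked rather than interpolated (periods without signal are
    excluded).  Nonpositive intervals are rejected samples.
    """
    times = rr.beat_times_s
    rr_vals = rr.rr_s
    good = rr_vals > 0
    times_hr = times[1:][good]
    hr_vals = 60.0 / rr_vals[good]
    if times_hr.size == 0:
        raise ValueError("no valid R-R intervals")
    n = int(math.floor(times[-1])) + 1
    grid = np.arange(n, dtype=float)
    values = np.interp(grid, times_hr, hr_vals)
    mask = np.zeros(n, dtype=bool)
    gaps = np.flatnonzero(np.diff(times) > max_gap_s)
    for g in gaps:
        mask[(grid > times[g]) & (grid < times[g + 1])] = True
    values[mask] = np.nan
    values = np.where(mask, 1.0, values)    # placeholder under mask
    return SignalSeries(kind="heart_rate_bpm", values=values,
                        missing_mask=mask)


def activity_vector_magnitude(x: Sequence[float], y: Sequence[float],
                              z: Sequence[float]) -> SignalSeries:
    """Per-second Euclidean magnitude of triaxial acceleration counts."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.size == y.size == z.size):
        raise ValueError("axis series lengths differ")
    return SignalSeries(kind="activity_counts",
                        values=np.sqrt(x ** 2 + y ** 2 + z ** 2))


def detect_movements(act: SignalSeries, threshold_counts: float,
                     merge_gap_s: float = 3.0) -> EventList:
    """Movement events: maximal runs of activity above threshold, with
    runs separated by at most ``merge_gap_s`` seconds merged."""
    above = act.values > threshold_counts
    events = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            events.append([float(start), float(i)])
            start = None
    if start is not None:
        events.append([float(start), float(above.size)])
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] <= merge_gap_s:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    return EventList(events=tuple((a, b, "movement") for a, b in merged))


def detect_cardiac_arousals(hr: SignalSeries, baseline_window_s: int = 60,
                            rise_bpm: float = 10.0,
                            return_tol_bpm: float = 3.0,
                            max_event_s: float = 60.0) -> EventList:
    """Cardiac arousals: sudden heart-rate rises that return to baseline.

    An event starts when HR exceeds the trailing-window baseline mean by
    at least ``rise_bpm`` and is kept only if HR returns to within
    ``return_tol_bpm`` of that baseline within ``max_event_s`` seconds;
    the event spans rise to return.  A monotone drift that never returns
    is not an arousal.
    """
    v = hr.values.copy()
    v[hr.missing_mask] = np.nan
    n = v.size
    events = []
    i = baseline_window_s
    while i < n:
        win = v[i - baseline_window_s:i]
        base = np.nanmean(win) if np.isfinite(win).any() else np.nan
        if np.isfinite(base) and np.isfinite(v[i]) and \
                v[i] - base >= rise_bpm:
            limit = min(i + int(max_event_s), n)
            ret = next((j for j in range(i + 1, limit)
                        if np.isfinite(v[j])
                        and abs(v[j] - base) <= return_tol_bpm), None)
            if ret is not None:
                events.append((float(i), float(ret + 1), "cardiac_arousal"))
                i = ret + 1
                continue
            i = limit
            continue
        i += 1
    return EventList(events=tuple(events))


@dataclass(frozen=True)
class StagingRules:
    """Tunable thresholds for the rule-based 1-s stager.

    All defaults were chosen on synthetic data only.
    """

    movement_pad_s: int = 15          # seconds around movement scored wake
    arousal_pad_s: int = 5
    hr_window_s: int = 120            # rolling window for local HR stats
    n3_hr_quantile: float = 0.35      # low-HR band upper quantile
    n3_max_local_sd: float = 3.0      # bpm
    rem_min_local_sd: float = 4.0     # bpm


def _rolling(values: np.ndarray, window: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling mean and SD via cumulative sums."""
    n = values.size
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csq = np.concatenate([[0.0], np.cumsum(values ** 2)])
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    cnt = (hi - lo).astype(float)
    mean = (csum[hi] - csum[lo]) / cnt
    var = np.maximum((csq[hi] - csq[lo]) / cnt - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def stage_epochs(hr: SignalSeries, act: SignalSeries, events: EventList,
                 rules: StagingRules | None = None) -> list[str]:
    """Rule-based 1-s sleep staging from heart rate and actimetry.

    Precedence per second: wake when inside (or within a pad of) a
    movement or cardiac-arousal event; else N3 when heart rate lies in
    its lowest night-level quantile band and local variability is low;
    else REM when local heart-rate variability is high; else N1+N2.
    """
    if rules is None:
        rules = StagingRules()
    if hr.n_samples != act.n_samples:
        raise ValueError("heart-rate and actimetry series lengths differ")
    n = hr.n_samples
    wake = np.zeros(n, dtype=bool)
    for a, b, kind in events.events:
        pad = rules.movement_pad_s if kind == "movement" \
            else rules.arousal_pad_s
        wake[max(int(a) - pad, 0):min(int(math.ceil(b)) + pad, n)] = True
    v = hr.values.copy()
    valid = ~hr.missing_mask
    mean_l, sd_l = _rolling(np.where(valid, v, np.nanmean(v[valid])),
                            rules.hr_window_s)
    hr_low = np.quantile(v[valid], rules.n3_hr_quantile)
    out = []
    for t in range(n):
        if wake[t]:
            out.append("W")
        elif v[t] <= hr_low and sd_l[t] <= rules.n3_max_local_sd:
            out.append("N3")
        elif sd_l[t] >= rules.rem_min_local_sd:
            out.append("REM")
        else:
            out.append("N12")
    return out


def _default_movement_threshold(act: "SignalSeries") -> float:
    """Half the median nonzero activity count (inf when all zero)."""
    nz = act.values[act.values > 0]
    return 0.5 * float(np.median(nz)) if nz.size else float("inf")


def stage_night(hr: SignalSeries, act: SignalSeries,
                rules: StagingRules | None = None,
                movement_threshold: float | None = None) -> list[str]:
    """Full chain: detect events, stage at 1 s, merge to 30-s epochs.

    The movement threshold defaults to half the median of the night's
    nonzero activity counts: most nonzero seconds are genuine movement,
    and a low adaptive threshold keeps short wake bouts detectable.
    Nights with no activity at all detect no movements.
    """
    if movement_threshold is None:
        movement_threshold = _default_movement_threshold(act)
    moves = detect_movements(act, movement_threshold)
    arousals = detect_cardiac_arousals(hr)
    events = EventList(events=moves.events + arousals.events)
    fine = stage_epochs(hr, act, events, rules)
    return merge_epochs(fine, 30, 1)


def eligibility_filter(tib_h: float, hr: SignalSeries | None = None,
                       movements: EventList | None = None,
                       min_tib_h: float = 5.0, max_rr_loss: float = 0.10,
                       periodicity_cv: float = 0.15,
                       min_periodic_events: int = 10
                       ) -> tuple[bool, list[str]]:
    """Screen a recording night for analyzability.

    Rejects, with machine-readable reason codes, nights with a time in
    bed under ``min_tib_h`` hours (``short_tib``), with more than
    ``max_rr_loss`` of the heart-rate samples masked (``rr_loss``), or
    whose movement events recur at a near-constant period — coefficient
    of variation of inter-event intervals below ``periodicity_cv`` over
    at least ``min_periodic_events`` events (``periodic_movement``, a
    documented heuristic).
    """
    reasons = []
    if tib_h < min_tib_h:
        reasons.append("short_tib")
    if hr is not None and hr.n_samples > 0 and \
            hr.missing_mask.mean() > max_rr_loss:
        reasons.append("rr_loss")
    if movements is not None:
        starts = np.array([a for a, b, k in movements.events
                           if k == "movement"])
        if starts.size >= min_periodic_events:
            iv = np.diff(starts)
            if iv.mean() > 0 and iv.std() / iv.mean() < periodicity_cv:
                reasons.append("periodic_movement")
    return (len(reasons) == 0, reasons)


def estimate_sync_offset(hr: SignalSeries, act: SignalSeries,
                         max_lag_s: int = 60,
                         n_permutations: int = 100, seed: int = 0
                         ) -> tuple[float | None, float, bool]:
    """Estimate the device clock offset between HR and actimetry.

    Builds binary 1-Hz indicators of cardiac-arousal and movement events
    and returns the lag (seconds, positive = actimetry lags) maximizing
    their normalized cross-correlation within ``+/-max_lag_s``, the peak
    correlation, and a reliability flag from a circular-shift permutation
    null (peak must exceed the 95th percentile of ``n_permutations``
    random shifts).  Returns (None, 0, False) when either series has no
    events.
    """
    if hr.n_samples < 600 or act.n_samples < 600:
        raise ValueError("need at least 10 minutes of signal")
    n = min(hr.n_samples, act.n_samples)
    a_ind = detect_cardiac_arousals(hr).indicator(n)
    m_ind = detect_movements(act, _default_movement_threshold(act)
                             ).indicator(n)
    if a_ind.sum() == 0 or m_ind.sum() == 0:
        return None, 0.0, False
    a = a_ind - a_ind.mean()
    m = m_ind - m_ind.mean()
    denom = math.sqrt((a ** 2).sum() * (m ** 2).sum())

    def peak_corr(mov: np.ndarray) -> tuple[int, float]:
        # full cross-correlation, restricted to |lag| <= max_lag_s;
        # lag > 0 means the movement series lags the arousal series
        full = signal.correlate(mov, a, mode="full", method="fft")
        center = n - 1
        window = full[center - max_lag_s:center + max_lag_s + 1] / denom
        best = int(np.argmax(window))
        return best - max_lag_s, float(window[best])

    lag, peak = peak_corr(m)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_permutations):
        shift = int(rng.integers(max_lag_s + 1, n - max_lag_s - 1))
        null.append(peak_corr(np.roll(m, shift))[1])
    reliable = peak > np.quantile(null, 0.95)
    return float(lag), peak, reliable
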