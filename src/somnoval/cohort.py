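"""Synthetic study cohorts: PSG hypnograms, device corruption, signals.

The generator emulates the structure of a multi-group device-validation
study so that every downstream analysis is testable without access to
real recordings:

* group-specific sleep architecture (healthy / OSA / insomnia / MDD)
  via a first-order Markov chain over the four collapsed stages at 30-s
  resolution, with a geometric initial wake run controlling sleep
  latency; presets are calibrated to published group means of total
  sleep time, latency and stage minutes;
* a device hypnogram produced by stage-conditional misclassification of
  the PSG hypnogram — the confusion probabilities default to a published
  device-vs-PSG confusion matrix — optionally followed by run-length
  smoothing (device hypnograms of HR-based stagers are typically less
  fragmented than PSG) and a per-subject logit perturbation of the
  confusion diagonal that induces subject-level bias/variance structure;
* stage-dependent 1-Hz heart-rate and wrist-actimetry series with
  movement bursts in wake and transient cardiac arousals at sleep-to-
  wake transitions.

Epoch-independent corruption keeps the generating confusion matrix
analytically known, so recovery tests have an exact target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hypnogram import Hypnogram, PairedNight, STAGES_4, align_pair

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES_4)}


# ---------------------------------------------------------------------------
# Group architecture profiles

@dataclass(frozen=True)
class GroupProfile:
    """Generative description of one study group's sleep architecture."""

    name: str
    transition: np.ndarray               # 4x4 row-stochastic, 30-s epochs
    initial_wake_geometric_p: float      # per-epoch P(leave initial wake)
    tib_epochs: int
    target_means: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (4, 4) or (t < 0).any() or \
                not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"profile {self.name!r}: transition rows must "
                             "be nonnegative and sum to 1")
        if not (0 < self.initial_wake_geometric_p <= 1):
            raise ValueError("initial_wake_geometric_p must be in (0, 1]")
        if self.tib_epochs < 600:
            raise ValueError("tib_epochs must be >= 600 (5 h time in bed)")
        object.__setattr__(self, "transition", t)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary occupancy of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(np.asarray(transition, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_from_targets(occupancy: Sequence[float],
                            dwell_epochs: Sequence[float],
                            n_iter: int = 400) -> np.ndarray:
    """Build a transition matrix with given stationary occupancy and
    mean stage bout lengths.

    Self-transitions are fixed at 1 - 1/dwell; the jump distribution on
    leaving a stage is calibrated by fixed-point iteration until the
    stationary distribution matches ``occupancy``.
    """
    pi_target = np.asarray(occupancy, dtype=float)
    pi_target = pi_target / pi_target.sum()
    dwell = np.asarray(dwell_epochs, dtype=float)
    if (dwell < 1).any():
        raise ValueError("mean dwell must be at least 1 epoch")
    leave = 1.0 / dwell
    w = pi_target * leave                  # initial jump weights
    for _ in range(n_iter):
        p = np.zeros((4, 4))
        for t in range(4):
            others = [u for u in range(4) if u != t]
            wsum = w[others].sum()
            p[t, others] = leave[t] * w[others] / wsum
            p[t, t] = 1.0 - leave[t]
        pi = stationary_distribution(p)
        w = w * pi_target / np.maximum(pi, 1e-12)
        w = w / w.sum()
    return p


def _preset(name: str, tib_min: float, sl_min: float, waso_min: float,
            stage_min: tuple[float, float, float],
            dwell_min: tuple[float, float, float, float],
            targets: dict) -> GroupProfile:
    post_onset = tib_min - sl_min
    n12, n3, rem = stage_min
    occ = np.array([waso_min, n12, n3, rem]) / post_onset
    dwell = np.asarray(dwell_min) * 2.0    # minutes -> 30-s epochs
    return GroupProfile(
        name=name,
        transition=transition_from_targets(occ, dwell),
        initial_wake_geometric_p=1.0 / (sl_min * 2.0),
        tib_epochs=int(round(tib_min * 2)),
        target_means=targets)


def group_presets() -> dict[str, GroupProfile]:
    """Study-group presets calibrated to published PSG group means.

    Time in bed, sleep latency, WASO and stage minutes target the
    published per-group means; bout lengths are plausible choices (wake
    bouts short, NREM/REM bouts around 5-12 min, patients more
    fragmented) since the study reports no bout statistics.
    """
    return {
        "healthy": _preset(
            "healthy", tib_min=480.0, sl_min=11.4, waso_min=33.3,
            stage_min=(235.2, 106.8, 92.9), dwell_min=(2.0, 12.0, 10.0, 10.0),
            targets={"tst_min": 434.9, "se_pct": 90.7, "waso_min": 33.3,
                     "sl_min": 11.4, "n12_min": 235.2, "n3_min": 106.8,
                     "rem_min": 92.9}),
        "OSA": _preset(
            "OSA", tib_min=500.0, sl_min=32.0, waso_min=91.5,
            stage_min=(249.2, 56.8, 71.0), dwell_min=(1.5, 8.0, 5.0, 6.0),
            targets={"tst_min": 377.1, "se_pct": 75.3, "waso_min": 91.5,
                     "sl_min": 32.0, "n12_min": 249.2, "n3_min": 56.8,
                     "rem_min": 71.0}),
        "insomnia": _preset(
            "insomnia", tib_min=478.0, sl_min=46.8, waso_min=83.2,
            stage_min=(198.7, 75.8, 74.0), dwell_min=(2.0, 9.0, 7.0, 7.0),
            targets={"tst_min": 348.4, "se_pct": 72.8, "waso_min": 83.2,
                     "sl_min": 46.8, "n12_min": 198.7, "n3_min": 75.8,
                     "rem_min": 74.0}),
        "MDD": _preset(
            "MDD", tib_min=477.5, sl_min=39.3, waso_min=72.6,
            stage_min=(216.6, 72.1, 74.5), dwell_min=(2.0, 9.0, 7.0, 8.0),
            targets={"tst_min": 363.1, "se_pct": 76.0, "waso_min": 72.6,
                     "sl_min": 39.3, "n12_min": 216.6, "n3_min": 72.1,
                     "rem_min": 74.5}),
    }


#: Nights per subject in the emulated study (inclusive ranges).
STUDY_NIGHT_RANGES = {"healthy": (1, 5), "OSA": (1, 2),
                      "insomnia": (1, 3), "MDD": (1, 2)}

#: Subjects per group in the emulated study.
STUDY_N_SUBJECTS = {"healthy": 26, "OSA": 30, "insomnia": 66, "MDD": 124}


def simulate_psg_hypnogram(profile: GroupProfile, seed,
                           subject_id: str = "s0", night_id: str = "n0"
                           ) -> Hypnogram:
    """Simulate one PSG night from a group profile.

    The night starts with a geometric wake run (sleep latency), enters
    sleep through the wake row's conditional exit distribution, and then
    evolves as a first-order Markov chain to lights-on.
    """
    rng = np.random.default_rng(seed)
    n = profile.tib_epochs
    p = profile.transition
    states = np.empty(n, dtype=np.intp)
    latency = min(int(rng.geometric(profile.initial_wake_geometric_p)), n)
    states[:latency] = _STAGE_INDEX["W"]
    if latency < n:
        w_exit = p[0].copy()
        w_exit[0] = 0.0
        if w_exit.sum() <= 0:              # absorbing wake
            states[latency:] = _STAGE_INDEX["W"]
        else:
            cur = int(rng.choice(4, p=w_exit / w_exit.sum()))
            states[latency] = cur
            cum = np.cumsum(p, axis=1)
            u = rng.random(n - latency - 1)
            for j, i in enumerate(range(latency + 1, n)):
                cur = int(np.searchsorted(cum[cur], u[j], side="right"))
                states[i] = min(cur, 3)
                cur = states[i]
    return Hypnogram(subject_id=subject_id, night_id=night_id,
                     group=profile.name, epoch_s=30,
                     stages=tuple(STAGES_4[i] for i in states))


# ---------------------------------------------------------------------------
# Device corruption

@dataclass(frozen=True)
class CorruptionModel:
    """Stage-conditional device misclassification model.

    ``confusion[r, c]`` is P(device stage c | PSG stage r).  The default
    is the published all-groups device-vs-PSG confusion matrix.
    ``smoothing_run`` > 1 applies post-hoc run-length smoothing so no
    interior device run is shorter than that many epochs.  ``subject_sd``
    is the SD of a per-subject normal perturbation applied to the logit
    of each row's diagonal, creating subject-level accuracy differences.
    """

    confusion: np.ndarray = None
    smoothing_run: int = 1
    subject_sd: float = 0.0

    def __post_init__(self):
        c = self.confusion
        if c is None:
            from .reference import REFERENCE_CONFUSION
            c = REFERENCE_CONFUSION["all"]
        c = np.asarray(c, dtype=float)
        if c.shape != (4, 4) or (c < 0).any() or \
                not np.allclose(c.sum(axis=1), 1.0, atol=0.01):
            raise ValueError("confusion rows must be nonnegative, sum to 1")
        # tables printed to 3 decimals may be off by <=0.01 per row
        c = c / c.sum(axis=1, keepdims=True)
        if self.smoothing_run < 1:
            raise ValueError("smoothing_run must be >= 1")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        object.__setattr__(self, "confusion", c)

    def perturbed(self, shift: float) -> np.ndarray:
        """Confusion with each row's diagonal shifted by ``shift`` on the
        logit scale, off-diagonal mass rescaled proportionally."""
        c = self.confusion.copy()
        for r in range(4):
            d = min(max(c[r, r], 1e-9), 1 - 1e-9)
            d_new = 1.0 / (1.0 + math.exp(-(math.log(d / (1 - d)) + shift)))
            off = c[r].sum() - c[r, r]
            if off > 0:
                c[r] *= (1 - d_new) / off
            c[r, r] = d_new
            c[r] /= c[r].sum()
        return c


def _smooth_runs(states: np.ndarray, min_run: int) -> np.ndarray:
    """Relabel interior runs shorter than ``min_run`` into the longer
    neighbouring run (ties go left) until none remain.  The first and
    last runs of the night are exempt.

    Runs are kept in a doubly linked list so each merge is O(1); the
    whole pass is linear in the number of runs.
    """
    stage, length, prev, nxt = [], [], [], []
    for s in states:
        if stage and stage[-1] == s:
            length[-1] += 1
        else:
            stage.append(int(s))
            length.append(1)
            prev.append(len(stage) - 2)
            nxt.append(len(stage))
    if stage:
        nxt[-1] = -1

    def interior(j: int) -> bool:
        return prev[j] != -1 and nxt[j] != -1

    pending = [j for j in range(len(stage))
               if interior(j) and length[j] < min_run]
    alive = [True] * len(stage)
    while pending:
        j = pending.pop()
        if not alive[j] or not interior(j) or length[j] >= min_run:
            continue
        lft, rgt = prev[j], nxt[j]
        stage[j] = stage[lft] if length[lft] >= length[rgt] else stage[rgt]
        # coalesce with now-equal neighbours
        for nb in (lft, rgt):
            if alive[j] and alive[nb] and stage[nb] == stage[j]:
                keep, drop = (nb, j) if nb == lft else (j, nb)
                length[keep] += length[drop]
                nxt[keep] = nxt[drop]
                if nxt[drop] != -1:
                    prev[nxt[drop]] = keep
                alive[drop] = False
                j = keep
        if interior(j) and length[j] < min_run:
            pending.append(j)
        for nb in (prev[j], nxt[j]):
            if nb != -1 and alive[nb] and interior(nb) \
                    and length[nb] < min_run:
                pending.append(nb)
    out = np.empty(int(np.sum([l for l, a in zip(length, alive) if a])),
                   dtype=np.intp)
    pos = 0
    k = next((i for i in range(len(stage)) if alive[i] and prev[i] == -1),
             -1)
    while k != -1:
        out[pos:pos + length[k]] = stage[k]
        pos += length[k]
        k = nxt[k]
    return out


def corrupt_hypnogram(psg: Hypnogram, model: CorruptionModel, seed,
                      diagonal_shift: float = 0.0) -> Hypnogram:
    """Produce a device hypnogram by stage-conditional relabelling.

    Each epoch is relabelled independently from P(device | PSG), then
    run-length smoothing is applied.  Same length as the input;
    reproducible given the seed.
    """
    if psg.epoch_s != 30 or not psg.is_collapsed:
        raise ValueError("corruption expects a collapsed 30-s hypnogram")
    rng = np.random.default_rng(seed)
    conf = model.perturbed(diagonal_shift) if diagonal_shift else \
        model.confusion
    ridx = np.fromiter((_STAGE_INDEX[s] for s in psg.stages),
                       dtype=np.intp, count=psg.n_epochs)
    cum = np.cumsum(conf, axis=1)
    u = rng.random(psg.n_epochs)
    device = (u[:, None] > cum[ridx]).sum(axis=1)
    if model.smoothing_run > 1:
        device = _smooth_runs(device, model.smoothing_run)
    return Hypnogram(subject_id=psg.subject_id, night_id=psg.night_id,
                     group=psg.group, epoch_s=30,
                     stages=tuple(STAGES_4[i] for i in device))


# ---------------------------------------------------------------------------
# Whole-cohort simulation

def simulate_cohort(profiles: Mapping[str, GroupProfile] | None = None,
                    n_subjects: Mapping[str, int] | None = None,
                    nights_per_subject: Mapping[str, tuple[int, int]]
                    | tuple[int, int] | None = None,
                    corruption: CorruptionModel | None = None,
                    seed: int = 0
                    ) -> tuple[list[PairedNight], dict]:
    """Simulate paired (PSG, device) nights for one or more groups.

    Defaults reproduce the emulated study's shape: four groups, the
    published subject counts and per-group night ranges, and the
    published all-groups confusion as corruption.  Returns the paired
    nights and a truth record (per-subject seeds, night counts, realized
    confusion shift).  Fully reproducible given ``seed``; per-subject
    streams are spawned from one master seed so subsets are independent.
    """
    if profiles is None:
        profiles = group_presets()
    if n_subjects is None:
        n_subjects = {g: STUDY_N_SUBJECTS.get(g, 20) for g in profiles}
    if corruption is None:
        corruption = CorruptionModel()
    master = np.random.SeedSequence(seed)
    pairs: list[PairedNight] = []
    truth = {"seed": seed, "groups": {}}
    for g_i, (gname, profile) in enumerate(sorted(profiles.items())):
        nsub = n_subjects[gname]
        if isinstance(nights_per_subject, Mapping):
            nrange = nights_per_subject[gname]
        elif nights_per_subject is not None:
            nrange = nights_per_subject
        else:
            nrange = STUDY_NIGHT_RANGES.get(gname, (1, 2))
        gtruth = {"n_subjects": nsub, "night_range": list(nrange),
                  "subjects": {}}
        for s_i in range(nsub):
            ss = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(g_i, s_i))
            rng = np.random.default_rng(ss)
            n_nights = int(rng.integers(nrange[0], nrange[1] + 1))
            shift = float(rng.normal(0.0, corruption.subject_sd)) \
                if corruption.subject_sd > 0 else 0.0
            sid = f"{gname}-s{s_i:03d}"
            gtruth["subjects"][sid] = {"n_nights": n_nights,
                                       "diagonal_shift": shift}
            for k in range(n_nights):
                nid = f"n{k}"
                psg = simulate_psg_hypnogram(
                    profile, np.random.default_rng(ss.spawn(1)[0]),
                    subject_id=sid, night_id=nid)
                dev = corrupt_hypnogram(
                    psg, corruption, np.random.default_rng(ss.spawn(1)[0]),
                    diagonal_shift=shift)
                pairs.append(align_pair(psg, dev))
        truth["groups"][gname] = gtruth
    truth["confusion"] = corruption.confusion.tolist()
    truth["smoothing_run"] = corruption.smoothing_run
    truth["subject_sd"] = corruption.subject_sd
    return pairs, truth


# ---------------------------------------------------------------------------
# Stage-dependent physiological signals

@dataclass(frozen=True)
class SignalModel:
    """Stage-dependent 1-Hz heart-rate and actimetry generator settings.

    Heart rate is stage mean plus AR(1) noise; deep sleep is slower and
    steadier than light sleep, REM is variable.  Movement bursts occur
    only during wake; a transient heart-rate pulse marks each
    sleep-to-wake transition (cardiac arousal).
    """

    hr_mean: tuple[float, float, float, float] = (72.0, 62.0, 56.0, 66.0)
    hr_sd: tuple[float, float, float, float] = (5.0, 3.0, 1.5, 6.0)
    ar_coef: float = 0.95
    movement_rate_per_wake_min: float = 2.0
    movement_amplitude: float = 60.0
    movement_duration_s: int = 3
    arousal_rise_bpm: float = 15.0
    arousal_duration_s: int = 20

    def __post_init__(self):
        order = dict(zip(STAGES_4, range(4)))
        if min(self.hr_mean) <= 0:
            raise ValueError("heart-rate means must be positive")
        if self.hr_mean[order["N3"]] >= self.hr_mean[order["N12"]]:
            raise ValueError("N3 heart rate must be below N1+N2")
        if self.hr_sd[order["REM"]] <= self.hr_sd[order["N3"]]:
            raise ValueError("REM heart-rate SD must exceed N3")


def synthesize_signals(psg: Hypnogram, model: SignalModel | None = None,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """1-Hz heart-rate (bpm) and actimetry (counts/s) series for a night.

    Series length is exactly 30 * n_epochs samples.  Reproducible given
    the seed.
    """
    if psg.epoch_s != 30 or not psg.is_collapsed:
        raise ValueError("signal synthesis expects a collapsed 30-s "
                         "hypnogram")
    if model is None:
        model = SignalModel()
    rng = np.random.default_rng(seed)
    sidx = np.repeat(np.fromiter((_STAGE_INDEX[s] for s in psg.stages),
                                 dtype=np.intp, count=psg.n_epochs), 30)
    n = sidx.size
    means = np.asarray(model.hr_mean)[sidx]
    sds = np.asarray(model.hr_sd)[sidx]
    phi = model.ar_coef
    innov = rng.normal(0.0, 1.0, n) * sds * math.sqrt(1 - phi ** 2)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, sds[0])
    for t in range(1, n):
        noise[t] = phi * noise[t - 1] + innov[t]
    hr = means + noise

    # cardiac arousal pulses at sleep -> wake transitions
    trans = np.flatnonzero((sidx[1:] == 0) & (sidx[:-1] != 0)) + 1
    dur = model.arousal_duration_s
    pulse = model.arousal_rise_bpm * np.exp(-np.arange(dur) / (dur / 3.0))
    for t0 in trans:
        end = min(t0 + dur, n)
        hr[t0:end] += pulse[:end - t0]

    act = np.zeros(n)
    wake_sec = np.flatnonzero(sidx == 0)
    if wake_sec.size:
        n_bursts = rng.poisson(model.movement_rate_per_wake_min
                               * wake_sec.size / 60.0)
        starts = rng.choice(wake_sec, size=n_bursts, replace=True) \
            if n_bursts else np.empty(0, dtype=np.intp)
        for t0 in np.sort(starts):
            end = min(int(t0) + model.movement_duration_s, n)
            act[t0:end] += rng.exponential(model.movement_amplitude,
                                           end - int(t0))
    return hr, act
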