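"""Hypnogram containers, stage collapsing, epoch merging, pairing and CSV I/O.

A hypnogram is an ordered sequence of sleep stages at a fixed epoch
duration, anchored so that epoch 0 begins at lights-off and the final
epoch ends at lights-on.  Two stage vocabularies are supported: the raw
five-class AASM set {W, N1, N2, N3, REM} and the collapsed four-class
set {W, N12, N3, REM} in which N1 and N2 form a single "N1+N2" class.
The two vocabularies are never mixed within one sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Raw five-class AASM vocabulary.
STAGES_RAW = ("W", "N1", "N2", "N3", "REM")
#: Collapsed four-class vocabulary, in canonical order (wake first).
STAGES_4 = ("W", "N12", "N3", "REM")
#: Stages counted as sleep in the wake/sleep binarization.
SLEEP_STAGES = ("N12", "N3", "REM")

GROUPS = ("healthy", "OSA", "insomnia", "MDD", "other")

_VALID_EPOCH_S = (1, 30)


class HypnogramError(ValueError):
    """Raised for malformed stage sequences or incompatible hypnograms."""


def collapse_stages(seq: Sequence[str]) -> list[str]:
    """Collapse a five-class stage sequence to the four-class vocabulary.

    N1 and N2 both map to ``N12``; W, N3 and REM are unchanged.  The input
    may already be four-class, in which case the operation is the identity
    (collapsing is idempotent).

    Raises
    ------
    HypnogramError
        If the sequence is empty or contains an unknown label; the error
        message carries the offending position.
    """
    if len(seq) == 0:
        raise HypnogramError("cannot collapse an empty stage sequence")
    out = []
    for i, s in enumerate(seq):
        if s in ("N1", "N2"):
            out.append("N12")
        elif s in STAGES_4:
            out.append(s)
        else:
            raise HypnogramError(f"unknown stage label {s!r} at position {i}")
    return out


def merge_epochs(fine: Sequence[str], target_epoch_s: int = 30,
                 source_epoch_s: int = 1) -> list[str]:
    """Merge a fine-resolution stage sequence into longer epochs.

    Each output epoch takes the most prevalent stage of its window; among
    stages tied for the maximal count, the stage whose first occurrence
    within the window is earliest wins.  A trailing remainder shorter than
    one full window is dropped.

    Parameters
    ----------
    fine : sequence of stage labels at ``source_epoch_s`` resolution.
    target_epoch_s : output epoch duration, must be a multiple of the source.
    """
    if target_epoch_s % source_epoch_s != 0:
        raise HypnogramError(
            f"target epoch {target_epoch_s}s is not a multiple of "
            f"source epoch {source_epoch_s}s")
    w = target_epoch_s // source_epoch_s
    out = []
    for k in range(len(fine) // w):
        window = fine[k * w:(k + 1) * w]
        counts: dict[str, int] = {}
        first: dict[str, int] = {}
        for i, s in enumerate(window):
            counts[s] = counts.get(s, 0) + 1
            first.setdefault(s, i)
        # modal stage; ties resolved by earliest first occurrence
        best = min(counts, key=lambda s: (-counts[s], first[s]))
        out.append(best)
    return out


@dataclass(frozen=True)
class Hypnogram:
    """A scored night: per-epoch stages from lights-off to lights-on."""

    subject_id: str
    night_id: str
    group: str
    epoch_s: int
    stages: tuple[str, ...]

    def __post_init__(self):
        if len(self.stages) == 0:
            raise HypnogramError("hypnogram has no epochs")
        if self.epoch_s not in _VALID_EPOCH_S:
            raise HypnogramError(f"epoch_s must be one of {_VALID_EPOCH_S}, "
                                 f"got {self.epoch_s}")
        labels = set(self.stages)
        if labels <= set(STAGES_4):
            pass
        elif labels <= set(STAGES_RAW):
            pass
        else:
            bad = labels - set(STAGES_RAW) - set(STAGES_4)
            if bad:
                pos = next(i for i, s in enumerate(self.stages) if s in bad)
                raise HypnogramError(
                    f"unknown stage label {self.stages[pos]!r} at epoch {pos}")
            raise HypnogramError(
                "raw (N1/N2) and collapsed (N12) labels mixed in one sequence")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def tib_min(self) -> float:
        """Time in bed (lights-off to lights-on), minutes."""
        return len(self.stages) * self.epoch_s / 60.0

    @property
    def is_collapsed(self) -> bool:
        return "N1" not in self.stages and "N2" not in self.stages

    def collapsed(self) -> "Hypnogram":
        """Return a copy in the four-class vocabulary."""
        return replace(self, stages=tuple(collapse_stages(self.stages)))

    def merged(self, target_epoch_s: int = 30) -> "Hypnogram":
        """Return a copy merged to ``target_epoch_s`` epochs (majority vote)."""
        merged = merge_epochs(self.stages, target_epoch_s, self.epoch_s)
        if not merged:
            raise HypnogramError("hypnogram shorter than one target epoch")
        return replace(self, epoch_s=target_epoch_s, stages=tuple(merged))


@dataclass(frozen=True)
class PairedNight:
    """An aligned (reference, device) pair of 30-s collapsed hypnograms."""

    ref: Hypnogram
    test: Hypnogram

    def __post_init__(self):
        if len(self.ref.stages) != len(self.test.stages):
            raise HypnogramError("paired hypnograms differ in length")
        if self.ref.epoch_s != 30 or self.test.epoch_s != 30:
            raise HypnogramError("paired hypnograms must be at 30-s epochs")

    @property
    def subject_id(self) -> str:
        return self.ref.subject_id

    @property
    def night_id(self) -> str:
        return self.ref.night_id

    @property
    def group(self) -> str:
        return self.ref.group

    @property
    def n_epochs(self) -> int:
        return len(self.ref.stages)


def align_pair(ref: Hypnogram, test: Hypnogram) -> PairedNight:
    """Pair a reference and a device hypnogram for the same night.

    Both sequences are truncated to the shorter length, measured from
    lights-off.  Subject/night identifiers and epoch durations must match.
    """
    if (ref.subject_id, ref.night_id) != (test.subject_id, test.night_id):
        raise HypnogramError(
            f"identifier mismatch: {ref.subject_id}/{ref.night_id} vs "
            f"{test.subject_id}/{test.night_id}")
    if ref.epoch_s != test.epoch_s:
        raise HypnogramError(
            f"epoch duration mismatch: {ref.epoch_s}s vs {test.epoch_s}s")
    if not (ref.is_collapsed and test.is_collapsed):
        raise HypnogramError("align_pair expects collapsed four-class input")
    n = min(len(ref.stages), len(test.stages))
    return PairedNight(ref=replace(ref, stages=ref.stages[:n]),
                       test=replace(test, stages=test.stages[:n]))


# ---------------------------------------------------------------------------
# CSV I/O.  One file may hold many nights; schema:
#   subject_id,night_id,group,epoch_index,stage
# epoch_index is 0-based and contiguous within each night.

CSV_COLUMNS = ["subject_id", "night_id", "group", "epoch_index", "stage"]


def write_hypnograms(hyps: Iterable[Hypnogram], path: str | Path) -> None:
    """Write one or more hypnograms to a single CSV file."""
    frames = []
    for h in hyps:
        frames.append(pd.DataFrame({
            "subject_id": h.subject_id,
            "night_id": h.night_id,
            "group": h.group,
            "epoch_index": range(len(h.stages)),
            "stage": list(h.stages),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                lineterminator="\n")


def read_hypnograms(path: str | Path, epoch_s: int = 30) -> list[Hypnogram]:
    """Read hypnograms from CSV; one Hypnogram per (subject, night).

    Unscored or otherwise unknown labels are rejected with a parse error
    naming the position: the downstream analyses assume fully scored nights.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "night_id": str,
                                  "group": str, "stage": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise HypnogramError(f"{path}: missing columns {missing}")
    out = []
    for (sid, nid), grp in df.groupby(["subject_id", "night_id"], sort=True):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if not (idx == range(len(idx))).all():
            raise HypnogramError(
                f"{path}: night {sid}/{nid} has non-contiguous epoch_index")
        group = grp["group"].iloc[0]
        try:
            out.append(Hypnogram(subject_id=str(sid), night_id=str(nid),
                                 group=str(group), epoch_s=epoch_s,
                                 stages=tuple(grp["stage"])))
        except HypnogramError as e:
            raise HypnogramError(f"{path}: night {sid}/{nid}: {e}") from e
    if not out:
        raise HypnogramError(f"{path}: no nights found")
    return out
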