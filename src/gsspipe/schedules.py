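"""Experiment schedules: blocked localizers and the event-related naming task.

Builders are pure functions of their parameters and an explicit seed, and a
schedule's total duration always equals the exact sum of its parts.  Default
counts and durations reproduce the printed designs of the study the pipeline
emulates: a 264 s auditory language localizer (6 intact + 6 degraded 18 s
blocks + 4 x 12 s fixation), a spatial working-memory ("multiple demand")
localizer with 34 s blocks of 4 trials, a Stroop-style colour-word localizer,
an articulation localizer, a verbal-fluency localizer, and a 295 s rapid
event-related picture-naming run (55 x 2 s trials with jittered ISIs of mean
3.091 s on [0.607, 10.144] s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "DesignSchedule",
    "make_localizer_schedule",
    "make_picture_naming_schedule",
    "events_to_table",
    "write_events_tsv",
    "read_events_tsv",
]

FIXATION = "fixation"


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: str


@dataclass(frozen=True)
class DesignSchedule:
    """An ordered, non-overlapping list of events plus the run duration.

    Fixation/rest periods are represented as events labelled ``fixation``;
    design-matrix construction treats them as baseline (unmodelled).
    """

    events: tuple[Event, ...]
    total_duration_s: float
    design_kind: str  # "blocked" | "event_related"

    def __post_init__(self) -> None:
        if self.design_kind not in ("blocked", "event_related"):
            raise ValueError(f"unknown design_kind {self.design_kind!r}")
        prev_end = 0.0
        for ev in self.events:
            if ev.duration_s < 0:
                raise ValueError("negative event duration")
            if ev.onset_s < prev_end - 1e-9:
                raise ValueError("events overlap or onsets decrease")
            prev_end = ev.onset_s + ev.duration_s
        if self.events and self.total_duration_s < prev_end - 1e-9:
            raise ValueError("total_duration_s shorter than the last event")

    @property
    def conditions(self) -> list[str]:
        """Task condition labels in first-appearance order (fixation excluded)."""
        seen: list[str] = []
        for ev in self.events:
            if ev.condition != FIXATION and ev.condition not in seen:
                seen.append(ev.condition)
        return seen

    def task_events(self, condition: str) -> list[Event]:
        return [ev for ev in self.events if ev.condition == condition]

    def n_volumes(self, tr_s: float) -> int:
        if tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        return int(np.ceil(self.total_duration_s / tr_s))


def _pack(blocks: list[tuple[float, str]], design_kind: str = "blocked",
          lead_s: float = 0.0, tail_s: float = 0.0) -> DesignSchedule:
    """Lay out (duration, condition) segments back to back."""
    events = []
    t = 0.0
    if lead_s > 0:
        events.append(Event(0.0, lead_s, FIXATION))
        t = lead_s
    for dur, cond in blocks:
        events.append(Event(t, dur, cond))
        t += dur
    if tail_s > 0:
        events.append(Event(t, tail_s, FIXATION))
        t += tail_s
    return DesignSchedule(tuple(events), total_duration_s=t, design_kind=design_kind)


def _interleave(task_blocks: list[tuple[float, str]],
                fix_blocks: list[tuple[float, str]],
                rng: np.random.Generator) -> list[tuple[float, str]]:
    """Seeded counterbalancing: shuffle task-block order, spread fixation
    blocks at evenly spaced slots between them."""
    order = list(task_blocks)
    rng.shuffle(order)
    if not fix_blocks:
        return order
    n_slots = len(order) + 1
    replace = len(fix_blocks) > n_slots
    positions = sorted(rng.choice(n_slots, size=len(fix_blocks), replace=replace))
    out: list[tuple[float, str]] = []
    fi = 0
    for slot in range(n_slots):
        while fi < len(fix_blocks) and positions[fi] == slot:
            out.append(fix_blocks[fi])
            fi += 1
        if slot < len(order):
            out.append(order[slot])
    out.extend(fix_blocks[fi:])
    return out


# printed design parameters of the localizer tasks
_MD_TRIAL_S = 0.5 + 4 * 1.0 + 4.0  # fixation + 4 grids + response/feedback window
_LOCALIZER_DEFAULTS = {
    "language": dict(conditions=("intact", "degraded"), n_blocks=6, block_s=18.0,
                     n_fixation=4, fixation_s=12.0, lead_s=0.0),
    "articulation": dict(conditions=("articulation", "motor"), n_blocks=6, block_s=18.0,
                         n_fixation=4, fixation_s=12.0, lead_s=0.0),
    "md": dict(conditions=("hard", "easy"), n_blocks=5, block_s=4 * _MD_TRIAL_S,
               n_fixation=6, fixation_s=16.0, lead_s=0.0),
    "stroop": dict(conditions=("color_words", "neutral_words"), n_blocks=8, block_s=18.0,
                   n_fixation=5, fixation_s=18.0, lead_s=8.0),
    "verbal_fluency": dict(conditions=("fluency", "automated_speech"), n_blocks=6, block_s=10.0,
                           n_fixation=5, fixation_s=10.0, lead_s=0.0),
}


def make_localizer_schedule(design_name: str, seed: int = 0, **overrides) -> DesignSchedule:
    """Build a blocked localizer schedule for one of the named designs.

    Parameters default to the printed block structure of each task; e.g.
    ``language`` yields 6 intact + 6 degraded 18 s blocks and 4 fixation
    blocks of 12 s, totalling exactly 264 s.  ``n_blocks`` is per condition.
    Block order is counterbalanced under the seed.
    """
    if design_name not in _LOCALIZER_DEFAULTS:
        raise ValueError(
            f"unknown design {design_name!r}; choose from {sorted(_LOCALIZER_DEFAULTS)}")
    p = dict(_LOCALIZER_DEFAULTS[design_name])
    p.update(overrides)
    rng = np.random.default_rng(seed)
    task = [(float(p["block_s"]), cond)
            for cond in p["conditions"] for _ in range(int(p["n_blocks"]))]
    fix = [(float(p["fixation_s"]), FIXATION) for _ in range(int(p["n_fixation"]))]
    blocks = _interleave(task, fix, rng)
    return _pack(blocks, "blocked", lead_s=float(p["lead_s"]))


@dataclass(frozen=True)
class ISIParams:
    """Jittered inter-stimulus-interval distribution (seconds)."""
    min_s: float = 0.607
    max_s: float = 10.144
    mean_s: float = 3.091

    def __post_init__(self) -> None:
        if not (self.min_s <= self.mean_s <= self.max_s):
            raise ValueError("ISI mean must lie within [min, max]")


def _sample_isis(n: int, p: ISIParams, rng: np.random.Generator) -> np.ndarray:
    """Truncated-exponential ISIs affinely rescaled to hit the target mean.

    The draw approximates rapid event-related jitter; the affine rescale
    (about the minimum) pins the realised mean to ``p.mean_s`` exactly, then
    any values pushed past ``max_s`` are clipped and the residual mass
    redistributed (iterated until the mean is within 1 ms).
    """
    scale = max(p.mean_s - p.min_s, 1e-6)
    u = rng.uniform(0, 1, size=n)
    span = p.max_s - p.min_s
    # inverse-CDF of an exponential truncated to [0, span]
    raw = -scale * np.log1p(-u * (1 - np.exp(-span / scale)))
    isis = p.min_s + raw
    for _ in range(100):
        err = isis.mean() - p.mean_s
        if abs(err) <= 1e-3:
            break
        free = (isis < p.max_s - 1e-9) if err < 0 else (isis > p.min_s + 1e-9)
        if not free.any():
            break
        isis[free] -= err * n / free.sum()
        np.clip(isis, p.min_s, p.max_s, out=isis)
    return isis


def make_picture_naming_schedule(n_trials: int = 55,
                                 isi_params: ISIParams = ISIParams(),
                                 seed: int = 0,
                                 condition: str = "naming",
                                 trial_duration_s: float = 2.0,
                                 lead_in_s: float = 7.0,
                                 tail_s: float = 8.0) -> DesignSchedule:
    """Rapid event-related picture-naming run.

    7 s lead-in fixation, ``n_trials`` 2 s naming events each followed by a
    jittered ISI, and an 8 s closing fixation; with the default parameters
    the total run length is 295 s to the nearest second.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    isis = _sample_isis(n_trials, isi_params, rng) if n_trials > 1 else np.array([isi_params.mean_s])
    if n_trials > 1 and abs(isis.mean() - isi_params.mean_s) > 1e-3:
        raise RuntimeError("ISI rescaling failed to reach the target mean")
    events = [Event(0.0, lead_in_s, FIXATION)]
    t = lead_in_s
    for i in range(n_trials):
        events.append(Event(t, trial_duration_s, condition))
        t += trial_duration_s
        events.append(Event(t, float(isis[i]), FIXATION))
        t += float(isis[i])
    events.append(Event(t, tail_s, FIXATION))
    t += tail_s
    return DesignSchedule(tuple(events), total_duration_s=t, design_kind="event_related")


# ---------------------------------------------------------------- events I/O

def events_to_table(schedule: DesignSchedule) -> pd.DataFrame:
    return pd.DataFrame(
        {"onset": [e.onset_s for e in schedule.events],
         "duration": [e.duration_s for e in schedule.events],
         "trial_type": [e.condition for e in schedule.events]})


def write_events_tsv(schedule: DesignSchedule, path: str | Path) -> None:
    events_to_table(schedule).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path, design_kind: str = "blocked",
                    total_duration_s: float | None = None) -> DesignSchedule:
    df = pd.read_csv(path, sep="\t")
    events = tuple(Event(float(r.onset), float(r.duration), str(r.trial_type))
                   for r in df.itertuples())
    if total_duration_s is None:
        total_duration_s = max((e.onset_s + e.duration_s for e in events), default=0.0)
    return DesignSchedule(events, total_duration_s=float(total_duration_s),
                          design_kind=design_kind)
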