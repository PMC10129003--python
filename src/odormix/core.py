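"""Shared data model for odor-mixture categorization sessions.

A session is one recording day of a head-fixed categorization task: on each
trial a 3-odorant mixture is presented for ~2 s and the animal reports, by
licking left or right, whether the mixture is the single learned *target*
mixture or anything else.  Trial types are

* ``target`` — the fixed 3-component target mixture,
* ``nontarget`` — 3 distinct odorants drawn from a 13-odorant pool,
* ``nontarget_repeat`` — a session-fixed nontarget mixture presented many
  times, and
* ``probe`` — a mixture sharing exactly one component with the target.

All times are seconds (float).  Trial-relative time is zero at odor onset and
bins are half-open ``[t, t + dt)``.  The per-trial analysis epoch is fixed at
``[-5, +12]`` s around odor onset so that both baseline segments (5–1 s before
odor on and 6–10 s after odor off, for a 2-s odor) fit inside it.

On disk a session is a directory of three plain-text files: ``trials.csv``,
``spikes.csv`` (long format: neuron_id, spike_time) and ``session.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TRIAL_TYPES",
    "TrialRecord",
    "SpikeTrainRecord",
    "SessionRecord",
    "AnalysisConfig",
    "AlignedSpikes",
    "ValidationError",
    "InputError",
    "read_session",
    "write_session",
    "align_spikes",
]

TRIAL_TYPES = ("target", "nontarget", "nontarget_repeat", "probe")

#: fixed analysis epoch around odor onset, seconds
EPOCH_WINDOW = (-5.0, 12.0)


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


class InputError(OSError):
    """A session directory is missing a required file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``first_lick_latency`` is seconds from odor onset to the first lick and is
    ``None`` when the animal never licked; ``correct`` is ``None`` when no
    choice was scored.
    """

    trial_index: int
    trial_type: str
    odor_components: frozenset
    odor_on_time: float
    odor_duration: float = 2.0
    repeat_id: int | None = None
    first_lick_latency: float | None = None
    lick_side: str | None = None
    correct: bool | None = None

    def __post_init__(self):
        object.__setattr__(self, "odor_components", frozenset(self.odor_components))

    @property
    def odor_off_time(self) -> float:
        return self.odor_on_time + self.odor_duration

    def validate(self, target_mixture: frozenset | None = None) -> None:
        if self.trial_index < 0:
            raise ValidationError(f"trial {self.trial_index}: negative index")
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(
                f"trial {self.trial_index}: unknown trial_type {self.trial_type!r}"
            )
        if len(self.odor_components) != 3:
            raise ValidationError(
                f"trial {self.trial_index}: mixture has "
                f"{len(self.odor_components)} components, expected 3"
            )
        if self.first_lick_latency is not None and self.first_lick_latency <= 0:
            raise ValidationError(
                f"trial {self.trial_index}: non-positive first_lick_latency"
            )
        if self.lick_side is not None and self.lick_side not in ("left", "right"):
            raise ValidationError(
                f"trial {self.trial_index}: lick_side {self.lick_side!r}"
            )
        if target_mixture is not None:
            overlap = len(self.odor_components & target_mixture)
            if self.trial_type == "target" and self.odor_components != target_mixture:
                raise ValidationError(
                    f"trial {self.trial_index}: target trial components do not "
                    "equal the session target mixture"
                )
            if self.trial_type == "probe" and overlap != 1:
                raise ValidationError(
                    f"trial {self.trial_index}: probe trial shares {overlap} "
                    "components with the target mixture, expected exactly 1"
                )


@dataclass(frozen=True)
class SpikeTrainRecord:
    """Sorted spike times of one neuron on the session clock."""

    neuron_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )

    def validate(self, session_span: tuple[float, float] | None = None) -> None:
        t = self.spike_times
        if t.ndim != 1:
            raise ValidationError(f"neuron {self.neuron_id}: spike_times not 1-d")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValidationError(f"neuron {self.neuron_id}: spike times decrease")
        if session_span is not None and t.size:
            lo, hi = session_span
            if t[0] < lo or t[-1] > hi:
                raise ValidationError(
                    f"neuron {self.neuron_id}: spike time outside session span "
                    f"[{lo}, {hi}]"
                )

    def __eq__(self, other):
        if not isinstance(other, SpikeTrainRecord):
            return NotImplemented
        return self.neuron_id == other.neuron_id and np.array_equal(
            self.spike_times, other.spike_times
        )


@dataclass
class SessionRecord:
    """Trials, spikes and metadata for one recording day."""

    session_id: str
    mouse_id: str
    day_index: int
    stage: str
    target_mixture: frozenset
    trials: list[TrialRecord]
    spikes: dict[str, SpikeTrainRecord]
    epoch_window: tuple[float, float] = EPOCH_WINDOW

    def __post_init__(self):
        self.target_mixture = frozenset(self.target_mixture)
        self.epoch_window = tuple(float(v) for v in self.epoch_window)

    @property
    def session_span(self) -> tuple[float, float]:
        """Smallest interval containing every trial epoch."""
        if not self.trials:
            return (0.0, 0.0)
        lo, hi = self.epoch_window
        return (self.trials[0].odor_on_time + lo, self.trials[-1].odor_on_time + hi)

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.spikes)

    def trials_of_type(self, *trial_types: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type in trial_types]

    def validate(self) -> None:
        if len(self.target_mixture) != 3:
            raise ValidationError("target_mixture must have exactly 3 components")
        if self.stage not in ("learning", "overtraining", "probe"):
            raise ValidationError(f"unknown stage {self.stage!r}")
        lo, hi = self.epoch_window
        if lo > -5.0 or hi < 12.0:
            raise ValidationError(
                "epoch_window must span at least [-5, +12] s around odor onset"
            )
        onsets = [t.odor_on_time for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("trial odor_on_times must be strictly increasing")
        for tr in self.trials:
            tr.validate(self.target_mixture)
        span = self.session_span
        for st in self.spikes.values():
            st.validate(span)

    def __eq__(self, other):
        if not isinstance(other, SessionRecord):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.mouse_id == other.mouse_id
            and self.day_index == other.day_index
            and self.stage == other.stage
            and self.target_mixture == other.target_mixture
            and self.epoch_window == other.epoch_window
            and self.trials == other.trials
            and self.spikes == other.spikes
        )


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Parameters shared by every analysis stage.

    The onset window (first second after odor on) is tiled by ``n_onset_bins``
    bins of ``bin_width`` seconds, and the per-bin significance threshold is
    Bonferroni-corrected: ``per_bin_alpha = familywise_alpha / n_onset_bins``
    (0.05 / 5 = 0.01 at the defaults).  Baseline is the union of the first and
    last 4 s of the trial epoch: ``baseline_pre`` relative to odor onset and
    ``baseline_post_off`` relative to odor offset.
    """

    bin_width: float = 0.2
    onset_window: tuple[float, float] = (0.0, 1.0)
    n_onset_bins: int = 5
    baseline_pre: tuple[float, float] = (-5.0, -1.0)
    baseline_post_off: tuple[float, float] = (6.0, 10.0)
    familywise_alpha: float = 0.05
    n_shuffles: int = 1000
    min_lick_latency: float = 0.5
    population_window: tuple[float, float] = (0.1, 0.6)
    min_spikes_per_neuron: int = 5
    min_neurons_per_session: int = 4
    lookback_L: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        self.onset_window = tuple(float(v) for v in self.onset_window)
        self.baseline_pre = tuple(float(v) for v in self.baseline_pre)
        self.baseline_post_off = tuple(float(v) for v in self.baseline_post_off)
        self.population_window = tuple(float(v) for v in self.population_window)
        self.validate()

    @property
    def per_bin_alpha(self) -> float:
        return self.familywise_alpha / self.n_onset_bins

    @property
    def onset_bin_edges(self) -> np.ndarray:
        lo, hi = self.onset_window
        return np.linspace(lo, hi, self.n_onset_bins + 1)

    def validate(self) -> None:
        span = self.onset_window[1] - self.onset_window[0]
        if not math.isclose(self.n_onset_bins * self.bin_width, span):
            raise ValidationError(
                f"{self.n_onset_bins} bins of {self.bin_width} s do not tile the "
                f"{span} s onset window"
            )
        if not 0 < self.familywise_alpha < 1:
            raise ValidationError("familywise_alpha must lie in (0, 1)")
        if self.n_shuffles < 1:
            raise ValidationError("n_shuffles must be >= 1")
        if self.lookback_L < 1:
            raise ValidationError("lookback_L must be >= 1")
        lo, hi = EPOCH_WINDOW
        for a, b in (self.onset_window, self.baseline_pre, self.population_window):
            if a < lo or b > hi:
                raise ValidationError(
                    f"window ({a}, {b}) lies outside the trial epoch {EPOCH_WINDOW}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML (or JSON) mapping of field names to values."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# session i/o
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial_index",
    "trial_type",
    "repeat_id",
    "odor_1",
    "odor_2",
    "odor_3",
    "odor_on_time",
    "odor_duration",
    "first_lick_latency",
    "lick_side",
    "correct",
]


def write_session(session: SessionRecord, path: str | Path, force: bool = False) -> None:
    """Write ``trials.csv``, ``spikes.csv`` and ``session.json`` under *path*.

    Refuses to overwrite an existing session directory unless ``force``.
    """
    path = Path(path)
    if not force and (path / "session.json").exists():
        raise FileExistsError(
            f"{path} already holds a session; pass force=True to overwrite"
        )
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for t in session.trials:
        odors = sorted(t.odor_components)
        rows.append(
            {
                "trial_index": t.trial_index,
                "trial_type": t.trial_type,
                "repeat_id": t.repeat_id,
                "odor_1": odors[0],
                "odor_2": odors[1],
                "odor_3": odors[2],
                "odor_on_time": repr(t.odor_on_time),
                "odor_duration": repr(t.odor_duration),
                "first_lick_latency": (
                    "" if t.first_lick_latency is None else repr(t.first_lick_latency)
                ),
                "lick_side": "" if t.lick_side is None else t.lick_side,
                "correct": "" if t.correct is None else int(t.correct),
            }
        )
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path / "trials.csv", index=False)

    spike_rows = {
        "neuron_id": [],
        "spike_time": [],
    }
    for nid, st in session.spikes.items():
        spike_rows["neuron_id"].extend([nid] * st.spike_times.size)
        spike_rows["spike_time"].extend(repr(float(v)) for v in st.spike_times)
    pd.DataFrame(spike_rows).to_csv(path / "spikes.csv", index=False)

    meta = {
        "session_id": session.session_id,
        "mouse_id": session.mouse_id,
        "day_index": session.day_index,
        "stage": session.stage,
        "target_mixture": sorted(session.target_mixture),
        "epoch_window": list(session.epoch_window),
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2))


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_session(path: str | Path) -> SessionRecord:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for name in ("trials.csv", "spikes.csv", "session.json"):
        if not (path / name).exists():
            raise InputError(f"session directory {path} is missing {name}")

    meta = json.loads((path / "session.json").read_text())
    trials_df = pd.read_csv(
        path / "trials.csv", dtype={"lick_side": "string"},
        float_precision="round_trip",
    )
    missing = set(_TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise ValidationError(f"trials.csv is missing columns {sorted(missing)}")

    trials = []
    for i, row in trials_df.iterrows():
        odors = [row["odor_1"], row["odor_2"], row["odor_3"]]
        odors = [o for o in odors if isinstance(o, str) or not pd.isna(o)]
        repeat_id = _opt_float(row["repeat_id"])
        lick_side = row["lick_side"]
        correct = _opt_float(row["correct"])
        try:
            trial = TrialRecord(
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                repeat_id=None if repeat_id is None else int(repeat_id),
                odor_components=frozenset(str(o) for o in odors),
                odor_on_time=float(row["odor_on_time"]),
                odor_duration=float(row["odor_duration"]),
                first_lick_latency=_opt_float(row["first_lick_latency"]),
                lick_side=None if pd.isna(lick_side) else str(lick_side),
                correct=None if correct is None else bool(correct),
            )
            trial.validate()
        except ValidationError as exc:
            raise ValidationError(f"trials.csv row {i}: {exc}") from None
        trials.append(trial)

    spikes_df = pd.read_csv(
        path / "spikes.csv", dtype={"neuron_id": str},
        float_precision="round_trip",
    )
    spikes: dict[str, SpikeTrainRecord] = {}
    for nid, grp in spikes_df.groupby("neuron_id", sort=False):
        spikes[str(nid)] = SpikeTrainRecord(
            neuron_id=str(nid), spike_times=grp["spike_time"].to_numpy(dtype=float)
        )

    session = SessionRecord(
        session_id=meta["session_id"],
        mouse_id=meta["mouse_id"],
        day_index=int(meta["day_index"]),
        stage=meta["stage"],
        target_mixture=frozenset(meta["target_mixture"]),
        trials=trials,
        spikes=spikes,
        epoch_window=tuple(meta["epoch_window"]),
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# spike alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedSpikes:
    """Per-trial spike times relative to an alignment event.

    ``trains`` maps trial_index to an ascending array of relative spike times
    clipped to the trial epoch; ``dropped_trials`` lists trials removed because
    the alignment event was absent (e.g. no first lick).
    """

    reference: str
    trains: dict[int, np.ndarray]
    dropped_trials: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def subset(self, trial_indices: Iterable[int]) -> "AlignedSpikes":
        keep = set(trial_indices)
        return AlignedSpikes(
            reference=self.reference,
            trains={i: t for i, t in self.trains.items() if i in keep},
            dropped_trials=list(self.dropped_trials),
        )


def align_spikes(
    session: SessionRecord, neuron_id: str, reference: str = "odor_on"
) -> AlignedSpikes:
    """Slice one neuron's spike train into trial epochs around *reference*.

    *reference* is one of ``odor_on``, ``odor_off`` or ``first_lick``.  Times
    are returned relative to the reference event and clipped to the session's
    epoch window (which is anchored at odor onset for every reference, so an
    odor-off alignment is the odor-on alignment shifted by the odor duration).
    Trials without the reference event are dropped and reported.
    """
    if neuron_id not in session.spikes:
        raise KeyError(f"unknown neuron {neuron_id!r}")
    if reference not in ("odor_on", "odor_off", "first_lick"):
        raise ValueError(f"unknown reference {reference!r}")

    times = session.spikes[neuron_id].spike_times
    lo, hi = session.epoch_window
    trains: dict[int, np.ndarray] = {}
    dropped: list[int] = []
    for trial in session.trials:
        if reference == "odor_on":
            ref = trial.odor_on_time
        elif reference == "odor_off":
            ref = trial.odor_off_time
        else:
            if trial.first_lick_latency is None:
                dropped.append(trial.trial_index)
                continue
            ref = trial.odor_on_time + trial.first_lick_latency
        # the epoch stays anchored to odor onset regardless of reference
        e_lo = trial.odor_on_time + lo
        e_hi = trial.odor_on_time + hi
        i0, i1 = np.searchsorted(times, [e_lo, e_hi])
        trains[trial.trial_index] = times[i0:i1] - ref
    return AlignedSpikes(reference=reference, trains=trains, dropped_trials=dropped)
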