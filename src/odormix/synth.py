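"""Synthetic session generator.

Emulates the odor-mixture categorization task and the response archetypes seen
in posterior piriform recordings, providing planted ground truth for every
downstream analysis:

* the trial mix — one fixed 3-component target mixture, 3-of-13-component
  nontarget mixtures, session-fixed repeated nontargets, and probe mixtures
  containing exactly one target component;
* the trial timeline — 2 s odor, 500 ms response extension, 10 s intertrial
  interval;
* neuron archetypes — brief or sustained odor-on increases, sustained odor-on
  decreases, lick-locked bursts, odor-off bursts, and unmodulated cells, with
  optional trial-type selectivity;
* behavior — log-normal lick latencies and Bernoulli accuracies per trial
  type, optionally coupled to a slowly drifting "representational separation"
  state that also scales the planted selectivity gains.

Spike trains are inhomogeneous-Poisson realizations (thinning) of
piecewise-constant rate profiles.  All randomness flows from one seed through
``numpy.random.SeedSequence`` spawning, so a session is reproducible from
``(config, day_index, seed)`` alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


import numpy as np

from .core import (
    EPOCH_WINDOW,
    SessionRecord,
    SpikeTrainRecord,
    TrialRecord,
    ValidationError,
)

__all__ = [
    "ARCHETYPES",
    "NeuronSpec",
    "BehaviorModel",
    "GeneratorConfig",
    "GroundTruth",
    "RateProfile",
    "sample_trial_sequence",
    "rate_profile",
    "sample_spikes",
    "generate_session",
]

ARCHETYPES = (
    "odor_on_up_brief",
    "odor_on_up_sustained",
    "odor_on_down",
    "lick_locked",
    "odor_off_up",
    "unmodulated",
)

#: inter-onset interval: 2 s odor + 0.5 s response extension + 10 s ITI
TRIAL_PERIOD = 12.5
#: session clock: first odor onset sits at +5 s so every epoch time is >= 0
CLOCK_ORIGIN = 5.0


@dataclass(frozen=True)
class NeuronSpec:
    """Parameters of one synthetic neuron.

    ``latency`` and ``active_duration`` position the archetype's active window
    relative to its aligning event (odor on, odor off, or the first lick).
    During that window the rate is ``baseline_rate * modulation_gain``, times
    ``selectivity_gain`` on trials matching ``selective_for`` (one of
    ``target``, ``nontarget``, ``repeat_<k>``, ``probe_<k>`` or ``None``).
    """

    archetype: str
    baseline_rate: float = 5.0
    modulation_gain: float = 3.0
    selective_for: str | None = None
    selectivity_gain: float = 1.0
    latency: float = 0.05
    active_duration: float = 0.5

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ValidationError(f"unknown archetype {self.archetype!r}")
        if self.baseline_rate < 0 or self.modulation_gain < 0 or self.selectivity_gain < 0:
            raise ValidationError("rates and gains must be >= 0")
        if self.archetype == "odor_on_down" and self.baseline_rate <= 0:
            raise ValidationError(
                "odor_on_down needs baseline_rate > 0 for the decrease to be observable"
            )


def _matches(selective_for: str | None, trial: TrialRecord) -> bool:
    if selective_for is None:
        return False
    if selective_for == "target":
        return trial.trial_type == "target"
    if selective_for == "nontarget":
        return trial.trial_type == "nontarget"
    kind, _, k = selective_for.partition("_")
    if kind == "repeat":
        return trial.trial_type == "nontarget_repeat" and trial.repeat_id == int(k)
    if kind == "probe":
        return trial.trial_type == "probe" and trial.repeat_id == int(k)
    raise ValidationError(f"unknown selective_for {selective_for!r}")


@dataclass
class BehaviorModel:
    """Lick-latency and accuracy model, per trial type.

    Latencies are log-normal (median ``latency_median[type]`` seconds, shape
    ``latency_sigma``) truncated below at 0.2 s.  ``coupling`` couples probe
    behavior to the separation state ``s``: the probability of a correct probe
    response gains ``coupling * (s - 1)`` and the probe latency median is
    scaled by ``exp(0.5 * coupling * (s - 1))`` — a more separated
    representation makes probes both more often correct and slower, while the
    states themselves make the neural target/nontarget representations more
    distinct.
    """

    latency_median: dict = field(
        default_factory=lambda: {
            "target": 0.8,
            "nontarget": 0.9,
            "nontarget_repeat": 0.9,
            "probe": 1.1,
        }
    )
    latency_sigma: float = 0.35
    accuracy: dict = field(
        default_factory=lambda: {
            "target": 0.95,
            "nontarget": 0.93,
            "nontarget_repeat": 0.93,
            "probe": 0.75,
        }
    )
    p_no_lick: float = 0.02
    coupling: float = 0.0
    #: couples accuracy on *all* non-probe trial types to the separation
    #: state, so that correct trials carry a cleaner population signal
    choice_coupling: float = 0.0
    target_side: str = "left"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session (or a run of sessions)."""

    n_trials: int = 200
    p_target: float = 0.4
    n_repeat_types: int = 2
    repeats_per_session: int = 20
    probe_fraction: float = 0.1
    odor_pool_size: int = 13
    target_mixture: tuple = ("EthylTiglate", "AllylTiglate", "MethylTiglate")
    n_neurons: int = 30
    archetype_weights: dict = field(
        default_factory=lambda: {
            "odor_on_up_brief": 0.25,
            "odor_on_up_sustained": 0.15,
            "odor_on_down": 0.2,
            "lick_locked": 0.1,
            "odor_off_up": 0.05,
            "unmodulated": 0.25,
        }
    )
    selective_fraction: float = 0.3
    selectivity_gain: float = 2.0
    session_drift: float = 0.0
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    # AR(1) separation state: s_t = 1 + ar_rho (s_{t-1} - 1) + ar_sigma eps_t
    ar_rho: float = 0.98
    ar_sigma: float = 0.06
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("p_target", "probe_fraction", "selective_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.odor_pool_size < 3:
            raise ValidationError("odor pool must hold at least 3 odorants")
        if len(set(self.target_mixture)) != 3:
            raise ValidationError("target_mixture must have 3 distinct components")
        w = np.array(list(self.archetype_weights.values()), dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("archetype weights must be non-negative, not all 0")

    @property
    def odor_pool(self) -> list[str]:
        return [f"N{i:02d}" for i in range(1, self.odor_pool_size + 1)]


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream analyses."""

    neuron_specs: dict
    selective_neurons: list
    separation_state: np.ndarray  # one value per trial, in trial order
    day_index: int


# ---------------------------------------------------------------------------
# trial sequence
# ---------------------------------------------------------------------------


def sample_trial_sequence(
    gconf: GeneratorConfig, seed: int | np.random.Generator = 0
) -> list[TrialRecord]:
    """Draw a pseudorandomly interleaved trial sequence (no behavior yet).

    Counts per type are deterministic given the config (rounded fractions;
    probe and repeat counts are capped by what the target fraction leaves
    over); their positions are shuffled.
    """
    gconf.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = gconf.n_trials
    n_target = round(gconf.p_target * n)
    n_probe = min(round(gconf.probe_fraction * n), n - n_target)
    n_repeat = min(gconf.n_repeat_types * gconf.repeats_per_session, n - n_target - n_probe)
    n_plain = n - n_target - n_probe - n_repeat

    kinds = (
        ["target"] * n_target
        + ["probe"] * n_probe
        + ["nontarget_repeat"] * n_repeat
        + ["nontarget"] * n_plain
    )
    rng.shuffle(kinds)

    pool = gconf.odor_pool
    target = frozenset(gconf.target_mixture)
    # session-fixed repeated nontarget mixtures
    repeat_mixtures = {
        k + 1: frozenset(rng.choice(pool, size=3, replace=False))
        for k in range(gconf.n_repeat_types)
    }

    trials: list[TrialRecord] = []
    for i, kind in enumerate(kinds):
        repeat_id = None
        if kind == "target":
            components = target
        elif kind == "nontarget":
            components = frozenset(rng.choice(pool, size=3, replace=False))
        elif kind == "nontarget_repeat":
            repeat_id = int(rng.integers(1, gconf.n_repeat_types + 1))
            components = repeat_mixtures[repeat_id]
        else:  # probe: exactly one target component
            repeat_id = int(rng.integers(1, 4))
            tcomp = sorted(target)[repeat_id - 1]
            others = rng.choice(pool, size=2, replace=False)
            components = frozenset([tcomp, *others])
        trials.append(
            TrialRecord(
                trial_index=i,
                trial_type=kind,
                repeat_id=repeat_id,
                odor_components=components,
                odor_on_time=CLOCK_ORIGIN + i * TRIAL_PERIOD,
                odor_duration=2.0,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# rate profiles and spike sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateProfile:
    """Piecewise-constant firing rate over the trial epoch (odor-on-relative).

    ``edges`` has one more element than ``rates``; the rate on
    ``[edges[i], edges[i+1])`` is ``rates[i]``.
    """

    edges: np.ndarray
    rates: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(self.rates) - 1)
        out = np.asarray(self.rates)[idx]
        out = np.where((t < self.edges[0]) | (t >= self.edges[-1]), 0.0, out)
        return out if out.ndim else float(out)

    @property
    def max_rate(self) -> float:
        return float(np.max(self.rates)) if len(self.rates) else 0.0


def rate_profile(
    spec: NeuronSpec, trial: TrialRecord, separation_state: float = 1.0
) -> RateProfile:
    """Build the trial's rate profile for one neuron.

    The active window sits at ``latency`` after the archetype's aligning event
    (odor onset; odor offset for ``odor_off_up``; the first lick for
    ``lick_locked`` — a lick-locked neuron on a no-lick trial stays at
    baseline).  ``separation_state`` scales the *selective* part of the gain:
    the effective selectivity multiplier is
    ``1 + (selectivity_gain - 1) * state`` on matching trials.
    """
    lo, hi = EPOCH_WINDOW
    base = spec.baseline_rate
    if spec.archetype == "unmodulated":
        return RateProfile(np.array([lo, hi]), np.array([base]))

    if spec.archetype == "odor_off_up":
        anchor = trial.odor_duration
    elif spec.archetype == "lick_locked":
        if trial.first_lick_latency is None:
            return RateProfile(np.array([lo, hi]), np.array([base]))
        anchor = trial.first_lick_latency
    else:
        anchor = 0.0

    start = anchor + spec.latency
    stop = min(start + spec.active_duration, hi)
    start = max(start, lo)
    if stop <= start:
        return RateProfile(np.array([lo, hi]), np.array([base]))

    gain = spec.modulation_gain
    if _matches(spec.selective_for, trial):
        gain = gain * (1.0 + (spec.selectivity_gain - 1.0) * separation_state)
    return RateProfile(
        np.array([lo, start, stop, hi]),
        np.array([base, base * gain, base]),
    )


def sample_spikes(
    rate: RateProfile,
    epoch: tuple[float, float] = EPOCH_WINDOW,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on *epoch* by thinning.

    Candidate spikes are drawn homogeneously at the profile's maximum rate and
    retained with probability ``rate(t) / max_rate``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.asarray(rate.rates, dtype=float)
    if np.any(rates < 0):
        raise ValidationError("rate profile has a negative rate")
    rmax = rate.max_rate
    lo, hi = epoch
    if rmax <= 0 or hi <= lo:
        return np.empty(0)
    n_cand = rng.poisson(rmax * (hi - lo))
    cand = np.sort(rng.uniform(lo, hi, size=n_cand))
    keep = rng.uniform(0.0, rmax, size=n_cand) < rate(cand)
    return cand[keep]


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------


def _draw_neuron_specs(gconf: GeneratorConfig, rng: np.random.Generator) -> list[NeuronSpec]:
    names = list(gconf.archetype_weights)
    w = np.array([gconf.archetype_weights[k] for k in names], dtype=float)
    w = w / w.sum()
    specs = []
    for _ in range(gconf.n_neurons):
        arch = names[rng.choice(len(names), p=w)]
        base = float(rng.uniform(8.0, 14.0)) if arch == "odor_on_down" else float(
            rng.uniform(3.0, 8.0)
        )
        if arch == "odor_on_up_brief":
            lat, dur, gain = 0.05, 0.4, 3.0
        elif arch == "odor_on_up_sustained":
            lat, dur, gain = 0.05, 2.0, 2.5
        elif arch == "odor_on_down":
            lat, dur, gain = 0.05, 2.0, 0.25
        elif arch == "lick_locked":
            lat, dur, gain = -0.1, 0.5, 3.0
        elif arch == "odor_off_up":
            lat, dur, gain = 0.1, 0.5, 3.0
        else:
            lat, dur, gain = 0.0, 0.0, 1.0
        specs.append(
            NeuronSpec(
                archetype=arch,
                baseline_rate=base,
                modulation_gain=gain,
                latency=lat,
                active_duration=dur,
            )
        )
    return specs


def _plant_selectivity(
    specs: list[NeuronSpec],
    gconf: GeneratorConfig,
    day_index: int,
    rng: np.random.Generator,
) -> tuple[list[NeuronSpec], list[int]]:
    """Mark a planted fraction of odor-responsive neurons as selective.

    The fraction grows linearly with ``day_index`` at rate ``session_drift``
    (the overtraining emulation); selectivity splits between target and
    repeat-1 preference.
    """
    frac = min(1.0, max(0.0, gconf.selective_fraction + gconf.session_drift * day_index))
    eligible = [
        i
        for i, s in enumerate(specs)
        if s.archetype in ("odor_on_up_brief", "odor_on_up_sustained", "odor_on_down")
    ]
    n_sel = int(round(frac * len(eligible)))
    chosen = sorted(rng.choice(eligible, size=n_sel, replace=False).tolist())
    out = list(specs)
    for j, i in enumerate(chosen):
        pref = "target" if (j % 3 != 2 or gconf.n_repeat_types == 0) else "repeat_1"
        out[i] = replace(out[i], selective_for=pref, selectivity_gain=gconf.selectivity_gain)
    return out, chosen


def _separation_state(n: int, gconf: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    s = np.empty(n)
    sd_stat = gconf.ar_sigma / math.sqrt(max(1e-12, 1.0 - gconf.ar_rho**2))
    x = rng.normal(0.0, sd_stat)
    for i in range(n):
        s[i] = 1.0 + x
        x = gconf.ar_rho * x + rng.normal(0.0, gconf.ar_sigma)
    return np.clip(s, 0.0, None)


def _simulate_behavior(
    trials: list[TrialRecord],
    state: np.ndarray,
    model: BehaviorModel,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    out = []
    for trial, s in zip(trials, state):
        if rng.uniform() < model.p_no_lick:
            out.append(replace(trial, first_lick_latency=None, lick_side=None, correct=None))
            continue
        p_correct = model.accuracy[trial.trial_type]
        median = model.latency_median[trial.trial_type]
        if trial.trial_type == "probe" and model.coupling != 0.0:
            p_correct = float(np.clip(p_correct + model.coupling * (s - 1.0), 0.02, 0.98))
            median = median * math.exp(0.5 * model.coupling * (s - 1.0))
        elif trial.trial_type != "probe" and model.choice_coupling != 0.0:
            p_correct = float(
                np.clip(p_correct + model.choice_coupling * (s - 1.0), 0.02, 0.98)
            )
        correct = bool(rng.uniform() < p_correct)
        correct_side = (
            model.target_side
            if trial.trial_type == "target"
            else ("right" if model.target_side == "left" else "left")
        )
        side = correct_side if correct else ("right" if correct_side == "left" else "left")
        latency = max(0.2, float(rng.lognormal(math.log(median), model.latency_sigma)))
        out.append(
            replace(trial, first_lick_latency=latency, lick_side=side, correct=correct)
        )
    return out


def generate_session(
    gconf: GeneratorConfig, day_index: int = 0, seed: int | None = None
) -> tuple[SessionRecord, GroundTruth]:
    """Generate one full session plus its ground truth.

    Deterministic given ``(gconf, day_index, seed)``; *seed* defaults to
    ``gconf.rng_seed + day_index``.
    """
    gconf.validate()
    if seed is None:
        seed = gconf.rng_seed + day_index
    ss = np.random.SeedSequence(int(seed))
    rng_trials, rng_neurons, rng_state, rng_beh, rng_spk = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    trials = sample_trial_sequence(gconf, rng_trials)
    state = _separation_state(len(trials), gconf, rng_state)
    specs = _draw_neuron_specs(gconf, rng_neurons)
    specs, selective_idx = _plant_selectivity(specs, gconf, day_index, rng_neurons)
    trials = _simulate_behavior(trials, state, gconf.behavior, rng_beh)

    # Trials are 12.5 s apart but the analysis epoch spans 17 s, so adjacent
    # epochs overlap on the session clock.  To keep the session spike train a
    # single continuous point process, each trial generates spikes only on its
    # own 12.5-s tile [-5, +7.5) (the last trial extends to +12); every
    # archetype's active window lies well inside the tile, so the tails that a
    # trial's epoch borrows from its neighbours are pure baseline, as in the
    # real task's intertrial interval.
    lo, hi = EPOCH_WINDOW
    spikes = {}
    spec_map = {}
    n_tr = len(trials)
    for i, spec in enumerate(specs):
        nid = f"n{i:03d}"
        spec_map[nid] = spec
        all_times = []
        for j, (trial, s) in enumerate(zip(trials, state)):
            prof = rate_profile(spec, trial, separation_state=s)
            tile = (lo, hi if j == n_tr - 1 else lo + TRIAL_PERIOD)
            rel = sample_spikes(prof, tile, rng_spk)
            all_times.append(rel + trial.odor_on_time)
        times = np.sort(np.concatenate(all_times)) if all_times else np.empty(0)
        spikes[nid] = SpikeTrainRecord(neuron_id=nid, spike_times=times)

    stage = "probe" if any(t.trial_type == "probe" for t in trials) else (
        "overtraining" if gconf.session_drift or day_index else "learning"
    )
    session = SessionRecord(
        session_id=f"synth_d{day_index:02d}_s{seed}",
        mouse_id="synth",
        day_index=day_index,
        stage=stage,
        target_mixture=frozenset(gconf.target_mixture),
        trials=trials,
        spikes=spikes,
    )
    session.validate()
    truth = GroundTruth(
        neuron_specs=spec_map,
        selective_neurons=[f"n{i:03d}" for i in selective_idx],
        separation_state=state,
        day_index=day_index,
    )
    return session, truth
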