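"""Per-neuron response classification against a circular-jitter null.

The modulation of a 200-ms bin relative to baseline is
``m = (bin - baseline) / (bin + baseline)``, bounded in [-1, 1]; baseline is
the pooled firing rate over the first and last 4 s of the trial epoch (5-1 s
before odor on and 6-10 s after odor off).  Significance of each bin comes
from a permutation null in which every trial's spike train is independently
circularly shifted by a uniform offset within the trial epoch; the p-value is
the add-one rank of |m| within 1,000 such jittered modulations.

A neuron is *odor-on up* if any of the five 200-ms bins in the first second
after odor on is significant at the Bonferroni-corrected threshold
(0.05 / 5 = 0.01) with positive modulation, *odor-on down* if all its
significant onset bins are negative — unless it is lick-contaminated, in which
case it is left unclassified.  Odor-off responses must pass three criteria
(significant post-offset bin vs baseline; significant late-odor vs post-offset
modulation; consistent direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._stats import add_one_p
from .core import AnalysisConfig, AlignedSpikes, SessionRecord, align_spikes

__all__ = [
    "ModulationResult",
    "OffResponseResult",
    "LickContaminationResult",
    "JitterNull",
    "baseline_rate",
    "modulation_index",
    "circular_jitter_null",
    "classify_odor_onset",
    "detect_lick_contamination",
    "classify_odor_off",
    "population_timecourse",
]

#: trials enter the lick-contamination comparison only if the first lick came
#: at least this long after odor on (seconds)
MIN_LICK_GAP = 0.8
#: lick-adjacent analysis window around the first lick: 400 ms before to
#: 600 ms after, tiled by five 200-ms bins
LICK_WINDOW = (-0.4, 0.6)
#: wrap domain for jittering lick-aligned spike trains (valid for any first
#: lick in the 2.5-s response period given the [-5, 12] odor-anchored epoch)
LICK_SPAN = (-5.0, 9.5)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ModulationResult:
    """Odor-onset modulation statistics and the up/down/none label."""

    neuron_id: str
    m: np.ndarray  # per onset bin, in [-1, 1]
    p: np.ndarray  # per onset bin, add-one permutation p
    label: str  # odor_on_up | odor_on_down | none
    lick_contaminated: bool
    n_shuffles: int
    baseline_hz: float
    bin_rates_hz: np.ndarray

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.m)

    @property
    def significant(self) -> np.ndarray:
        return self.p < 0.05 / len(self.p)


@dataclass
class OffResponseResult:
    """The three odor-off criteria and the resulting label."""

    neuron_id: str
    criterion1: bool
    criterion2: bool
    criterion3: bool
    label: str  # odor_off_up | odor_off_down | none
    p_bins: np.ndarray
    m_bins: np.ndarray
    p_on_off: float
    m_on_off: float


@dataclass
class LickContaminationResult:
    """Outcome of the lick-contamination screen; truthy iff contaminated."""

    neuron_id: str
    contaminated: bool
    no_valid_trials: bool = False
    n_valid_trials: int = 0

    def __bool__(self) -> bool:
        return self.contaminated


@dataclass
class JitterNull:
    """Observed statistic, jitter null distribution, and add-one p-value(s)."""

    observed: np.ndarray
    null: np.ndarray  # (n_shuffles, *observed.shape)
    p: np.ndarray


# ---------------------------------------------------------------------------
# primitive statistics
# ---------------------------------------------------------------------------


def modulation_index(bin_rate, baseline):
    """``(bin - baseline) / (bin + baseline)``, with 0/0 defined as 0."""
    b = np.asarray(bin_rate, dtype=float)
    base = np.asarray(baseline, dtype=float)
    if np.any(b < 0) or np.any(base < 0):
        raise ValueError("rates must be non-negative")
    denom = b + base
    out = np.divide(b - base, denom, out=np.zeros_like(denom), where=denom > 0)
    return float(out) if out.ndim == 0 else out


def _baseline_windows(session: SessionRecord, config: AnalysisConfig):
    """The two baseline segments in odor-on-relative time."""
    durations = {t.odor_duration for t in session.trials}
    if len(durations) > 1:
        raise ValueError("odor_duration varies across trials")
    d = durations.pop() if durations else 2.0
    a, b = config.baseline_post_off
    return [tuple(config.baseline_pre), (d + a, d + b)]


def baseline_rate(
    aligned: AlignedSpikes, session: SessionRecord, config: AnalysisConfig
) -> float:
    """Pooled baseline firing rate in Hz over both baseline segments."""
    if not aligned.trains:
        raise ValueError("no trials to compute a baseline from")
    windows = _baseline_windows(session, config)
    total_dur = sum(b - a for a, b in windows) * len(aligned.trains)
    count = 0
    for t in aligned.trains.values():
        for a, b in windows:
            count += int(np.searchsorted(t, b) - np.searchsorted(t, a))
    return count / total_dur


# ---------------------------------------------------------------------------
# circular-jitter engine
# ---------------------------------------------------------------------------


def circular_jitter_null(
    trains: Sequence[np.ndarray],
    statistic: Callable[[list[np.ndarray]], float | np.ndarray],
    n_shuffles: int,
    seed: int | np.random.Generator = 0,
    span: tuple[float, float] = (-5.0, 12.0),
) -> JitterNull:
    """Generic jitter null: circularly shift each trial independently.

    Each shuffle draws one uniform offset per trial in ``[0, span length)``,
    wraps the trial's spike times modulo the span, and recomputes *statistic*
    (a function of the list of per-trial spike-time arrays, returning a scalar
    or a vector).  p-values follow the add-one rule on absolute magnitude,
    elementwise.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = span
    length = hi - lo
    trains = [np.asarray(t, dtype=float) for t in trains]
    obs = np.atleast_1d(np.asarray(statistic(trains), dtype=float))
    null = np.empty((n_shuffles,) + obs.shape)
    for s in range(n_shuffles):
        offsets = rng.uniform(0.0, length, size=len(trains))
        shifted = [
            np.sort(((t - lo + off) % length) + lo)
            for t, off in zip(trains, offsets)
        ]
        null[s] = np.atleast_1d(np.asarray(statistic(shifted), dtype=float))
    p = np.array([add_one_p(null[:, i], obs[i]) for i in range(obs.size)])
    return JitterNull(observed=obs, null=null, p=p)


def _jitter_window_counts(
    trains: Sequence[np.ndarray],
    windows: Sequence[tuple[float, float]],
    n_shuffles: int,
    rng: np.random.Generator,
    span: tuple[float, float] = (-5.0, 12.0),
    chunk: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per window, observed and under the circular-jitter null.

    Vectorized equivalent of :func:`circular_jitter_null` for count-based
    statistics: returns ``(obs_counts, null_counts)`` with shapes
    ``(n_windows,)`` and ``(n_shuffles, n_windows)``, counts summed over
    trials.  Jitter conserves each trial's spike count exactly.
    """
    lo, hi = span
    length = hi - lo
    times = np.concatenate([np.asarray(t, dtype=float) for t in trains]) if trains else np.empty(0)
    trial_id = np.concatenate(
        [np.full(len(t), i) for i, t in enumerate(trains)]
    ).astype(np.intp) if trains else np.empty(0, dtype=np.intp)
    windows = [(float(a), float(b)) for a, b in windows]

    obs = np.array(
        [np.sum((times >= a) & (times < b)) for a, b in windows], dtype=float
    )
    null = np.empty((n_shuffles, len(windows)))
    base = times - lo
    for start in range(0, n_shuffles, chunk):
        c = min(chunk, n_shuffles - start)
        offsets = rng.uniform(0.0, length, size=(c, len(trains)))
        shifted = (base[None, :] + offsets[:, trial_id]) % length + lo
        for w, (a, b) in enumerate(windows):
            null[start : start + c, w] = ((shifted >= a) & (shifted < b)).sum(axis=1)
    return obs, null


def _binned_modulation(
    trains: list[np.ndarray],
    bin_windows: list[tuple[float, float]],
    baseline_windows: list[tuple[float, float]],
    config: AnalysisConfig,
    rng: np.random.Generator,
    span: tuple[float, float] = (-5.0, 12.0),
    fixed_baseline_hz: float | None = None,
):
    """Per-bin modulation index and jitter p-values for one neuron.

    Baseline is recomputed from the jittered spikes in every shuffle unless a
    ``fixed_baseline_hz`` is supplied (used for lick-aligned bins, whose
    baseline segments are not defined relative to the lick).
    """
    n_trials = len(trains)
    windows = list(bin_windows) + list(baseline_windows)
    obs, null = _jitter_window_counts(trains, windows, config.n_shuffles, rng, span=span)
    nb = len(bin_windows)
    bin_dur = np.array([b - a for a, b in bin_windows]) * n_trials
    obs_rates = obs[:nb] / bin_dur
    null_rates = null[:, :nb] / bin_dur

    if fixed_baseline_hz is None:
        base_dur = sum(b - a for a, b in baseline_windows) * n_trials
        obs_base = obs[nb:].sum() / base_dur
        null_base = null[:, nb:].sum(axis=1) / base_dur
    else:
        obs_base = fixed_baseline_hz
        null_base = np.full(config.n_shuffles, fixed_baseline_hz)

    m_obs = modulation_index(obs_rates, obs_base)
    m_null = modulation_index(null_rates, null_base[:, None])
    p = np.array([add_one_p(m_null[:, i], m_obs[i]) for i in range(nb)])
    return m_obs, p, obs_rates, float(obs_base)


def _bin_edges(lo: float, hi: float, width: float) -> list[tuple[float, float]]:
    n = int(round((hi - lo) / width))
    edges = np.linspace(lo, hi, n + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n)]


# ---------------------------------------------------------------------------
# odor-onset classification
# ---------------------------------------------------------------------------


def classify_odor_onset(
    session: SessionRecord,
    neuron_id: str,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
    lick_contaminated: bool | None = None,
) -> ModulationResult:
    """Classify one neuron as odor-on up, odor-on down, or unmodulated.

    If *lick_contaminated* is not supplied it is computed first (contaminated
    neurons keep their per-bin statistics but get label ``none``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lick_contaminated is None:
        lick_contaminated = bool(
            detect_lick_contamination(session, neuron_id, config, rng)
        )
    aligned = align_spikes(session, neuron_id, "odor_on")
    trains = list(aligned.trains.values())
    bins = _bin_edges(*config.onset_window, config.bin_width)
    m, p, rates, base = _binned_modulation(
        trains, bins, _baseline_windows(session, config), config, rng,
        span=session.epoch_window,
    )
    sig = p < config.per_bin_alpha
    if lick_contaminated or not sig.any():
        label = "none"
    elif np.any(m[sig] > 0):
        label = "odor_on_up"
    else:
        label = "odor_on_down"
    return ModulationResult(
        neuron_id=neuron_id,
        m=m,
        p=p,
        label=label,
        lick_contaminated=bool(lick_contaminated),
        n_shuffles=config.n_shuffles,
        baseline_hz=base,
        bin_rates_hz=rates,
    )


# ---------------------------------------------------------------------------
# lick contamination
# ---------------------------------------------------------------------------


def detect_lick_contamination(
    session: SessionRecord,
    neuron_id: str,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
) -> LickContaminationResult:
    """Screen one neuron for lick-driven modulation.

    Only trials whose first lick came at least 800 ms after odor on enter the
    comparison, and only bins significant at p < 0.05 are considered, on both
    alignments.  A neuron with a significant *positive* odor-period bin is
    contaminated if some significant lick-adjacent bin fires significantly
    faster than the fastest such bin; a neuron without one is contaminated if
    some significant lick-adjacent bin fires significantly slower than its
    reference (the slowest significant odor-period bin, or baseline when no
    odor-period bin is significant).  "Significantly" means the margin must
    exceed twice the lick bin's Poisson standard error, so an odor-locked
    response that merely ties the odor-period extreme is not flagged on
    sampling noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    valid = [
        t.trial_index
        for t in session.trials
        if t.first_lick_latency is not None and t.first_lick_latency >= MIN_LICK_GAP
    ]
    if not valid:
        return LickContaminationResult(neuron_id, False, no_valid_trials=True)

    odor_aligned = align_spikes(session, neuron_id, "odor_on").subset(valid)
    trains = list(odor_aligned.trains.values())
    durations = {t.odor_duration for t in session.trials}
    d = durations.pop()
    odor_bins = _bin_edges(0.0, d, config.bin_width)
    m_odor, p_odor, r_odor, base = _binned_modulation(
        trains, odor_bins, _baseline_windows(session, config), config, rng,
        span=session.epoch_window,
    )

    lick_aligned = align_spikes(session, neuron_id, "first_lick").subset(valid)
    lo, hi = LICK_SPAN
    lick_trains = [t[(t >= lo) & (t < hi)] for t in lick_aligned.trains.values()]
    lick_bins = _bin_edges(*LICK_WINDOW, config.bin_width)
    m_lick, p_lick, r_lick, _ = _binned_modulation(
        lick_trains, lick_bins, [], config, rng, span=LICK_SPAN,
        fixed_baseline_hz=base,
    )

    sig_odor = p_odor < 0.05
    sig_lick = p_lick < 0.05
    pos_sig = sig_odor & (m_odor > 0)
    if not sig_lick.any():
        return LickContaminationResult(neuron_id, False, n_valid_trials=len(valid))
    # rate SE under Poisson counts: sqrt(count) / (n_trials * bin_width)
    denom = len(valid) * config.bin_width
    se = np.sqrt(np.maximum(r_lick * denom, 1.0)) / denom
    if pos_sig.any():
        ref = r_odor[pos_sig].max()
        contaminated = bool(np.any(r_lick[sig_lick] - 2.0 * se[sig_lick] > ref))
    else:
        ref = r_odor[sig_odor].min() if sig_odor.any() else base
        contaminated = bool(np.any(r_lick[sig_lick] + 2.0 * se[sig_lick] < ref))
    return LickContaminationResult(neuron_id, contaminated, n_valid_trials=len(valid))


# ---------------------------------------------------------------------------
# odor-off classification
# ---------------------------------------------------------------------------


def classify_odor_off(
    session: SessionRecord,
    neuron_id: str,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
) -> OffResponseResult:
    """Apply the three odor-off criteria to one neuron.

    (1) at least one 200-ms bin in the second after odor offset significant
    vs baseline at the Bonferroni-corrected threshold; (2) the modulation
    ``(pre - post)/(pre + post)`` between the last 500 ms of the odor period
    and 100-600 ms after offset must exceed the 95th percentile of its jitter
    null in absolute value; (3) both comparisons must point the same way
    (criterion 1's direction is taken at its most significant bin; criterion
    2's is ``sign(post - pre)``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aligned = align_spikes(session, neuron_id, "odor_on")
    trains = list(aligned.trains.values())
    durations = {t.odor_duration for t in session.trials}
    if len(durations) > 1:
        raise ValueError("odor_duration varies across trials")
    d = durations.pop()

    off_bins = _bin_edges(d, d + 1.0, config.bin_width)
    m_bins, p_bins, _, _ = _binned_modulation(
        trains, off_bins, _baseline_windows(session, config), config, rng,
        span=session.epoch_window,
    )
    sig = p_bins < config.per_bin_alpha
    crit1 = bool(sig.any())
    dir1 = int(np.sign(m_bins[np.argmin(p_bins)])) if crit1 else 0

    pre = (d - 0.5, d)
    post = (d + 0.1, d + 0.6)
    n_trials = len(trains)
    obs, null = _jitter_window_counts(
        trains, [pre, post], config.n_shuffles, rng, span=session.epoch_window
    )
    pre_rate, post_rate = obs[0] / (0.5 * n_trials), obs[1] / (0.5 * n_trials)
    m_onoff = modulation_index(pre_rate, post_rate)
    null_m = modulation_index(null[:, 0] / (0.5 * n_trials), null[:, 1] / (0.5 * n_trials))
    p_onoff = add_one_p(null_m, m_onoff)
    crit2 = p_onoff < 0.05
    dir2 = int(np.sign(post_rate - pre_rate))

    crit3 = crit1 and crit2 and dir1 != 0 and dir1 == dir2
    label = "none"
    if crit1 and crit2 and crit3:
        label = "odor_off_up" if dir1 > 0 else "odor_off_down"
    return OffResponseResult(
        neuron_id=neuron_id,
        criterion1=crit1,
        criterion2=crit2,
        criterion3=crit3,
        label=label,
        p_bins=p_bins,
        m_bins=m_bins,
        p_on_off=p_onoff,
        m_on_off=m_onoff,
    )


# ---------------------------------------------------------------------------
# population time course
# ---------------------------------------------------------------------------


def population_timecourse(
    session: SessionRecord,
    neuron_ids: Sequence[str],
    config: AnalysisConfig,
    window: tuple[float, float] = (-1.0, 5.0),
    smooth_sigma_bins: float = 1.0,
) -> dict:
    """Smoothed PSTHs of a set of neurons over -1 to +5 s around odor onset.

    Returns a dict with ``bin_centers`` and two (neurons x bins) matrices:
    ``normalized`` (each row divided by its own maximum; all-zero rows stay
    zero) and ``zscored`` (each row z-scored over the window, then the mean of
    the pre-onset second subtracted).
    """
    if not neuron_ids:
        raise ValueError("need at least one neuron")
    bins = _bin_edges(*window, config.bin_width)
    edges = np.array([a for a, _ in bins] + [bins[-1][1]])
    centers = (edges[:-1] + edges[1:]) / 2
    psth = np.empty((len(neuron_ids), len(bins)))
    for i, nid in enumerate(neuron_ids):
        aligned = align_spikes(session, nid, "odor_on")
        times = np.concatenate(list(aligned.trains.values())) if aligned.trains else np.empty(0)
        counts, _ = np.histogram(times, bins=edges)
        rate = counts / (len(aligned.trains) * config.bin_width)
        psth[i] = gaussian_filter1d(rate, smooth_sigma_bins) if smooth_sigma_bins else rate

    peak = psth.max(axis=1, keepdims=True)
    normalized = np.divide(psth, peak, out=np.zeros_like(psth), where=peak > 0)

    mu = psth.mean(axis=1, keepdims=True)
    sd = psth.std(axis=1, keepdims=True)
    z = np.divide(psth - mu, sd, out=np.zeros_like(psth), where=sd > 0)
    pre = (centers >= -1.0) & (centers < 0.0)
    z = z - z[:, pre].mean(axis=1, keepdims=True)
    return {"bin_centers": centers, "normalized": normalized, "zscored": z}
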