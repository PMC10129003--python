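"""Odor-identity selectivity via label-shuffle tests, plus trend statistics.

A neuron is *selective* for a trial-type contrast (target vs nontarget,
a repeated nontarget vs the other nontargets, or probe vs nontarget) if, in
any of the five 200-ms onset bins, the unsigned difference of mean firing
rates between the two trial groups exceeds what 1,000 group-label shuffles
produce, at the Bonferroni-corrected per-bin threshold (0.05 / 5 = 0.01).

The down-sampled comparison re-runs the test on 50 random subsets of
two-thirds of the rarer trial type (and matched target subsets of the same
size) to compare selective-neuron proportions fairly across trial types; each
neuron is summarized by the mode of its 50 p-values.

Cross-session trends (proportion of selective neurons vs training day) are
Pearson correlations with a day-label-shuffle Monte-Carlo p.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._stats import permutation_corr
from .core import AnalysisConfig, SessionRecord, align_spikes

__all__ = [
    "SelectivityResult",
    "ProportionTrend",
    "DownsampledResult",
    "bin_rate_matrix",
    "selectivity_test",
    "downsampled_selectivity",
    "proportion_trend",
    "modal_p",
]


@dataclass
class SelectivityResult:
    neuron_id: str
    contrast: tuple[str, str]
    diff: np.ndarray  # per-bin unsigned mean rate difference, Hz
    p: np.ndarray  # per-bin add-one shuffle p
    selective: bool
    preferred_group: str | None  # group with the higher mean in the min-p bin


@dataclass
class ProportionTrend:
    values: np.ndarray
    days: np.ndarray
    correlation: float
    p: float
    null: np.ndarray


@dataclass
class DownsampledResult:
    """Per-neuron modal p-values and session proportions for a down-sampled
    focal-type-vs-nontarget contrast alongside its size-matched target
    contrast."""

    trial_type: str
    n_subsampled: int
    focal_modal_p: dict
    target_modal_p: dict
    focal_proportion: float
    target_proportion: float
    skipped: bool = False


def bin_rate_matrix(
    session: SessionRecord,
    neuron_id: str,
    trial_indices,
    config: AnalysisConfig,
) -> np.ndarray:
    """(trials x onset bins) firing-rate matrix in Hz for one neuron."""
    aligned = align_spikes(session, neuron_id, "odor_on")
    edges = config.onset_bin_edges
    out = np.empty((len(trial_indices), config.n_onset_bins))
    for r, ti in enumerate(trial_indices):
        counts, _ = np.histogram(aligned.trains[ti], bins=edges)
        out[r] = counts / config.bin_width
    return out


def _shuffle_p(
    rates: np.ndarray, n_a: int, n_shuffles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed |mean_A - mean_B| per bin and its label-shuffle p-values.

    *rates* stacks group A's trials on top of group B's.  Shuffles permute the
    group labels while preserving group sizes; p is add-one.
    """
    n = rates.shape[0]
    obs = np.abs(rates[:n_a].mean(axis=0) - rates[n_a:].mean(axis=0))
    total = rates.sum(axis=0)
    idx = np.tile(np.arange(n), (n_shuffles, 1))
    idx = rng.permuted(idx, axis=1)[:, :n_a]
    sum_a = rates[idx].sum(axis=1)  # (shuffles, bins)
    null = np.abs(sum_a / n_a - (total - sum_a) / (n - n_a))
    hits = (null >= obs).sum(axis=0)
    return obs, (1 + hits) / (n_shuffles + 1)


def selectivity_test(
    session: SessionRecord,
    neuron_id: str,
    group_a,
    group_b,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
    contrast: tuple[str, str] = ("A", "B"),
) -> SelectivityResult:
    """Label-shuffle test of firing-rate differences between two trial groups.

    *group_a* / *group_b* are iterables of trial indices.  The neuron is
    selective iff any onset bin's p falls below ``per_bin_alpha``; the
    preferred group is the one with the higher mean rate in the most
    significant bin (``None`` on an exact tie).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both trial groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = bin_rate_matrix(session, neuron_id, group_a + group_b, config)
    n_a = len(group_a)
    diff, p = _shuffle_p(rates, n_a, config.n_shuffles, rng)
    selective = bool(p.min() < config.per_bin_alpha)
    preferred = None
    if selective:
        k = int(np.argmin(p))
        mean_a = rates[:n_a, k].mean()
        mean_b = rates[n_a:, k].mean()
        if mean_a != mean_b:
            preferred = contrast[0] if mean_a > mean_b else contrast[1]
    return SelectivityResult(
        neuron_id=neuron_id,
        contrast=tuple(contrast),
        diff=diff,
        p=p,
        selective=selective,
        preferred_group=preferred,
    )


def modal_p(values, decimals: int = 3) -> float:
    """Mode of a set of p-values, resolved by rounding to *decimals* places;
    falls back to the median when every rounded value is unique."""
    rounded = np.round(np.asarray(values, dtype=float), decimals)
    counts = Counter(rounded)
    top, n_top = counts.most_common(1)[0]
    if n_top == 1:
        return float(np.median(rounded))
    return float(top)


def downsampled_selectivity(
    session: SessionRecord,
    trial_type: str,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
    n_resamples: int = 50,
    neuron_ids=None,
    subsample_size: int | None = None,
) -> DownsampledResult:
    """Trial-count-matched selectivity comparison for ``probe`` or ``repeat``.

    Draws ``floor(2/3 * n_focal)`` focal trials (and, independently, equally
    many target trials) without replacement, tests each subset against the
    plain nontarget trials, repeats 50 times, and summarizes each neuron by
    its modal p-value.  Sessions with fewer than 3 focal trials are skipped.
    """
    if trial_type not in ("probe", "repeat"):
        raise ValueError("trial_type must be 'probe' or 'repeat'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    focal_name = "probe" if trial_type == "probe" else "nontarget_repeat"
    focal = [t.trial_index for t in session.trials_of_type(focal_name)]
    targets = [t.trial_index for t in session.trials_of_type("target")]
    nontargets = [t.trial_index for t in session.trials_of_type("nontarget")]
    if len(focal) < 3:
        return DownsampledResult(trial_type, 0, {}, {}, float("nan"), float("nan"), skipped=True)
    if subsample_size is None:
        k = max(2, int(np.floor(2 / 3 * len(focal))))
    else:
        k = min(subsample_size, len(focal))
    k = min(k, len(targets))
    if neuron_ids is None:
        neuron_ids = session.neuron_ids

    focal_modal, target_modal = {}, {}
    for nid in neuron_ids:
        all_idx = focal + targets + nontargets
        rates = bin_rate_matrix(session, nid, all_idx, config)
        pos = {ti: r for r, ti in enumerate(all_idx)}
        nt_rows = [pos[i] for i in nontargets]
        p_focal, p_target = [], []
        for _ in range(n_resamples):
            for pool, sink in ((focal, p_focal), (targets, p_target)):
                sub = rng.choice(pool, size=k, replace=False)
                rows = [pos[i] for i in sub] + nt_rows
                _, p = _shuffle_p(rates[rows], k, config.n_shuffles, rng)
                sink.append(p.min())
        focal_modal[nid] = modal_p(p_focal)
        target_modal[nid] = modal_p(p_target)

    alpha = config.per_bin_alpha
    return DownsampledResult(
        trial_type=trial_type,
        n_subsampled=k,
        focal_modal_p=focal_modal,
        target_modal_p=target_modal,
        focal_proportion=float(np.mean([p < alpha for p in focal_modal.values()])),
        target_proportion=float(np.mean([p < alpha for p in target_modal.values()])),
    )


def proportion_trend(
    proportions,
    day_indices,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> ProportionTrend:
    """Pearson correlation of per-session values against training day, with a
    day-label-shuffle Monte-Carlo p (add-one rule)."""
    values = np.asarray(proportions, dtype=float)
    days = np.asarray(day_indices, dtype=float)
    r, p, null = permutation_corr(values, days, n_shuffles, seed, alternative)
    return ProportionTrend(values=values, days=days, correlation=r, p=p, null=null)
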