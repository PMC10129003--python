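"""Behavioral summaries: choice indices, lick latencies, performance trends.

The *choice index* of a trial type is the fraction of right-lick choices
(1 = always right, 0 = always left).  Two published variants exist: variant A
scores every trial, deeming no-lick trials incorrect, after truncating the
trailing run of no-lick trials (the last licked trial ends the session);
variant B keeps only decided trials (a lick within the 2.5-s response
window).  An accuracy-based formulation (proportion correct for targets, one
minus that for the other types) is reported alongside.

Trials whose first lick precedes 500 ms after odor onset are excluded from
latency (and neural) summaries — never from the choice index — with the
excluded fraction reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnalysisConfig, TrialRecord

__all__ = [
    "BehaviorSummary",
    "choice_index",
    "latency_summary",
    "performance_trend",
    "RESPONSE_WINDOW",
]

#: odor duration plus the 500-ms response extension, seconds
RESPONSE_WINDOW = 2.5


@dataclass
class BehaviorSummary:
    choice: pd.DataFrame
    latency: pd.DataFrame
    n_excluded_short_latency: int
    excluded_fraction: float
    latencies_by_outcome: dict


def _decided(t: TrialRecord, window: float = RESPONSE_WINDOW) -> bool:
    return (
        t.lick_side is not None
        and t.first_lick_latency is not None
        and t.first_lick_latency <= window
    )


def choice_index(
    trials,
    variant: str = "all_trials",
    response_window: float = RESPONSE_WINDOW,
) -> pd.DataFrame:
    """Per-trial-type choice indices.

    Returns one row per trial type with ``n``, the right-lick choice index
    (``choice_index``), and the accuracy-based index (``accuracy_index``:
    proportion correct for targets, 1 - proportion correct otherwise).
    Variant ``all_trials`` truncates trailing no-lick trials and counts
    remaining no-lick trials as incorrect (and as not-right); variant
    ``decided`` keeps only trials with a lick inside the response window.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    if variant == "all_trials":
        last = max(
            (k for k, t in enumerate(trials) if t.lick_side is not None), default=-1
        )
        trials = trials[: last + 1]
    elif variant == "decided":
        trials = [t for t in trials if _decided(t, response_window)]
    else:
        raise ValueError(f"unknown variant {variant!r}")

    if not trials:  # e.g. a session where the animal never licked
        return pd.DataFrame(
            columns=["n", "choice_index", "accuracy_index"],
            index=pd.Index([], name="trial_type"),
        )
    rows = []
    for tt in sorted({t.trial_type for t in trials}):
        grp = [t for t in trials if t.trial_type == tt]
        right = np.mean([t.lick_side == "right" for t in grp])
        correct = np.mean([bool(t.correct) for t in grp])  # None -> incorrect
        acc = correct if tt == "target" else 1.0 - correct
        rows.append(
            {
                "trial_type": tt,
                "n": len(grp),
                "choice_index": float(right),
                "accuracy_index": float(acc),
            }
        )
    return pd.DataFrame(rows).set_index("trial_type")


def latency_summary(trials, config: AnalysisConfig) -> BehaviorSummary:
    """Latency distributions with the short-latency exclusion applied.

    First licks earlier than ``config.min_lick_latency`` (500 ms) are
    excluded and counted; per-type and per-outcome summaries are computed on
    the remainder.  The choice indices in the returned summary are computed
    on the *unexcluded* trials (the exclusion applies only to latency and
    neural analyses).
    """
    trials = list(trials)
    licked = [t for t in trials if t.first_lick_latency is not None]
    short = [t for t in licked if t.first_lick_latency < config.min_lick_latency]
    kept = [t for t in licked if t.first_lick_latency >= config.min_lick_latency]

    rows = []
    for tt in sorted({t.trial_type for t in trials}):
        lats = np.array([t.first_lick_latency for t in kept if t.trial_type == tt])
        rows.append(
            {
                "trial_type": tt,
                "n": lats.size,
                "mean": float(lats.mean()) if lats.size else np.nan,
                "median": float(np.median(lats)) if lats.size else np.nan,
            }
        )
    by_outcome = {
        outcome: np.array(
            [t.first_lick_latency for t in kept if t.correct is bool(outcome)]
        )
        for outcome in (True, False)
    }
    return BehaviorSummary(
        choice=choice_index(trials) if trials else pd.DataFrame(),
        latency=pd.DataFrame(rows).set_index("trial_type"),
        n_excluded_short_latency=len(short),
        excluded_fraction=len(short) / len(licked) if licked else 0.0,
        latencies_by_outcome=by_outcome,
    )


def performance_trend(
    values,
    day_indices,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
):
    """Trend of a per-session behavioral value (e.g. choice index) across
    days: Pearson correlation with a day-label-shuffle Monte-Carlo p."""
    from .selectivity import proportion_trend

    return proportion_trend(values, day_indices, n_shuffles, seed, alternative)
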