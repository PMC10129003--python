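"""Population decoding of the task category (target vs everything else).

Each trial is summarized by every simultaneously recorded neuron's spike
count in the 100-600 ms post-odor-onset window; neurons with fewer than 5
spikes summed over all trials in that window (or with zero count variance)
are excluded and sessions retaining fewer than 4 neurons are rejected.  The
trials-x-neurons matrix is z-scored per neuron so each contributes equally.

Decoding uses linear discriminant analysis over 10 independent random 90/10
train/test splits; chance level is calibrated by re-running the whole
procedure on category-shuffled labels (add-one Monte-Carlo p).  The per-trial
posterior probability assigned to the trial's true category (averaged over
the splits in which the trial was held out) serves as a finer-grained
accuracy measure for cross-day trend tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._stats import permutation_corr
from .core import AnalysisConfig, SessionRecord, align_spikes

__all__ = [
    "PopulationMatrix",
    "DecodeResult",
    "SessionRejectedError",
    "build_population_matrix",
    "decode_category",
    "decode_null",
    "accuracy_day_trend",
]


class SessionRejectedError(ValueError):
    """Too few neurons survive the exclusion rules to analyze the session."""

    def __init__(self, n_retained: int, minimum: int):
        self.n_retained = n_retained
        super().__init__(
            f"session retains {n_retained} neurons, fewer than the required {minimum}"
        )


@dataclass
class PopulationMatrix:
    """z-scored trials x neurons response matrix with exclusion bookkeeping."""

    X: np.ndarray
    raw_counts: np.ndarray
    neuron_ids: list
    excluded: dict  # neuron_id -> reason
    labels: pd.DataFrame  # trial_index, trial_type, is_target, correct, day, latency

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Category labels: True for target trials."""
        return self.labels["is_target"].to_numpy()


@dataclass
class DecodeResult:
    fold_accuracies: np.ndarray
    accuracy: float
    posterior: np.ndarray  # per trial, P(true category), NaN if never held out
    by_trial_type: dict
    n_splits: int


def build_population_matrix(
    session: SessionRecord,
    config: AnalysisConfig,
    exclude_neurons=(),
    exclude_early_lick: bool = False,
    trial_indices=None,
) -> PopulationMatrix:
    """Window spike counts, exclusions, and per-neuron z-scoring.

    *exclude_neurons* removes neurons up front (e.g. lick-contaminated ones);
    *exclude_early_lick* drops trials whose first lick precedes the end of the
    counting window (600 ms) — the robustness variant.
    """
    lo, hi = config.population_window
    trials = session.trials
    if trial_indices is not None:
        keep = set(trial_indices)
        trials = [t for t in trials if t.trial_index in keep]
    if exclude_early_lick:
        trials = [
            t
            for t in trials
            if t.first_lick_latency is None or t.first_lick_latency >= hi
        ]
    idx = [t.trial_index for t in trials]

    counts = {}
    excluded = dict.fromkeys(exclude_neurons, "manual")
    for nid in session.neuron_ids:
        if nid in excluded:
            continue
        aligned = align_spikes(session, nid, "odor_on")
        c = np.array(
            [
                np.searchsorted(aligned.trains[i], hi)
                - np.searchsorted(aligned.trains[i], lo)
                for i in idx
            ],
            dtype=float,
        )
        if c.sum() < config.min_spikes_per_neuron:
            excluded[nid] = "min_spikes"
        elif c.std() == 0:
            excluded[nid] = "zero_variance"
        else:
            counts[nid] = c

    if len(counts) < config.min_neurons_per_session:
        raise SessionRejectedError(len(counts), config.min_neurons_per_session)

    raw = np.column_stack(list(counts.values()))
    X = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    labels = pd.DataFrame(
        {
            "trial_index": idx,
            "trial_type": [t.trial_type for t in trials],
            "is_target": [t.trial_type == "target" for t in trials],
            "correct": [t.correct for t in trials],
            "day": session.day_index,
            "first_lick_latency": [t.first_lick_latency for t in trials],
        }
    )
    return PopulationMatrix(
        X=X,
        raw_counts=raw,
        neuron_ids=list(counts),
        excluded=excluded,
        labels=labels,
    )


def _lda() -> LinearDiscriminantAnalysis:
    # Ledoit-Wolf shrinkage keeps the within-class covariance invertible at
    # desk scale (few trials relative to neurons)
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def decode_category(
    matrix: PopulationMatrix,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
    y: np.ndarray | None = None,
    n_splits: int = 10,
    test_fraction: float = 0.1,
    partitioned: bool = False,
) -> DecodeResult:
    """LDA decoding of target-vs-everything over independent 90/10 splits.

    By default the splits are drawn at random (not a partition) and a split
    whose training set misses a class is redrawn; with ``partitioned`` the
    trials are shuffled once and cut into ``n_splits`` disjoint folds so each
    trial is held out exactly once.  Accuracy is the mean over splits; each
    trial's posterior is the mean probability assigned to its true category
    over the splits where it was held out.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = matrix.X
    y = matrix.y if y is None else np.asarray(y)
    n = len(y)
    if min(np.sum(y), np.sum(~y)) < 2:
        raise ValueError("each category needs at least 2 trials")
    n_test = max(1, int(round(test_fraction * n)))

    folds = None
    if partitioned:
        for _ in range(1000):
            order = rng.permutation(n)
            folds = np.array_split(order, n_splits)
            if all(len(np.unique(y[np.setdiff1d(order, f)])) == 2 for f in folds):
                break
        else:
            raise ValueError("could not partition with both classes in every fold")

    accs = np.empty(n_splits)
    post_sum = np.zeros(n)
    post_n = np.zeros(n)
    hit = np.zeros(n)
    tested = np.zeros(n)
    for s in range(n_splits):
        if partitioned:
            test = folds[s]
            train = np.setdiff1d(np.arange(n), test)
        else:
            for _ in range(1000):
                perm = rng.permutation(n)
                test, train = perm[:n_test], perm[n_test:]
                if len(np.unique(y[train])) == 2:
                    break
            else:
                raise ValueError(
                    "could not draw a training split containing both classes"
                )
        clf = _lda().fit(X[train], y[train])
        pred = clf.predict(X[test])
        accs[s] = np.mean(pred == y[test])
        proba = clf.predict_proba(X[test])
        true_col = np.searchsorted(clf.classes_, y[test])
        post_sum[test] += proba[np.arange(len(test)), true_col]
        post_n[test] += 1
        hit[test] += pred == y[test]
        tested[test] += 1

    posterior = np.divide(post_sum, post_n, out=np.full(n, np.nan), where=post_n > 0)
    by_type = {}
    for tt in matrix.labels["trial_type"].unique():
        rows = (matrix.labels["trial_type"] == tt).to_numpy() & (tested > 0)
        if rows.any():
            by_type[tt] = float(hit[rows].sum() / tested[rows].sum())
    return DecodeResult(
        fold_accuracies=accs,
        accuracy=float(accs.mean()),
        posterior=posterior,
        by_trial_type=by_type,
        n_splits=n_splits,
    )


def decode_null(
    matrix: PopulationMatrix,
    config: AnalysisConfig,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    observed: DecodeResult | None = None,
) -> tuple[np.ndarray, float, DecodeResult]:
    """Category-label-shuffle null for decoding accuracy.

    Re-runs the full 10-split procedure on shuffled labels *n_shuffles* times;
    p is the add-one Monte-Carlo rank of the observed mean accuracy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if observed is None:
        observed = decode_category(matrix, config, rng)
    null = np.empty(n_shuffles)
    y = matrix.y
    for s in range(n_shuffles):
        null[s] = decode_category(matrix, config, rng, y=rng.permutation(y)).accuracy
    p = float((1 + np.sum(null >= observed.accuracy)) / (n_shuffles + 1))
    return null, p, observed


def accuracy_day_trend(
    session_results,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    trial_type: str | None = None,
    correct_only: bool = True,
    alternative: str = "two-sided",
):
    """Trend of decoder accuracy across training days.

    *session_results* is a sequence of ``(day_index, DecodeResult,
    PopulationMatrix)`` triples.  Each session is summarized by the mean
    posterior probability of the true category (restricted to correct trials
    and, optionally, one trial type); the summary is correlated with day via
    the day-label-shuffle Monte-Carlo engine.
    """
    days, scores = [], []
    for day, res, matrix in session_results:
        mask = ~np.isnan(res.posterior)
        if correct_only:
            corr = matrix.labels["correct"].to_numpy()
            mask &= np.array([bool(c) for c in np.where(pd.isna(corr), False, corr)])
        if trial_type is not None:
            mask &= (matrix.labels["trial_type"] == trial_type).to_numpy()
        if mask.any():
            days.append(day)
            scores.append(float(np.nanmean(res.posterior[mask])))
    if len(days) < 3:
        raise ValueError("need at least 3 sessions for a day trend")
    r, p, null = permutation_corr(scores, days, n_shuffles, seed, alternative)
    return {
        "days": np.asarray(days),
        "scores": np.asarray(scores),
        "correlation": r,
        "p": p,
        "null": null,
    }
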