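"""Population-vector correlations, TNT similarity and probe-trial look-back.

Each trial's population vector (per-neuron z-scored window counts) is
correlated with every other trial's; correlation coefficients are optionally
z-scored over the session's off-diagonal pairs so sessions with different
neuron counts are comparable.  A trial's *target/nontarget similarity* is

``TNT(x) = mean_i corr(x, NT_i)`` for a target trial x (and vice versa for a
nontarget trial) — the average correlation with all trials of the opposite
category; negative values mean a more differentiated representation.  Probe
trials inherit ``ProbeTNT(x_i)``: the mean TNT of the L nearest preceding
TNT-bearing trials (L = 10 in the main analysis), a proxy for the separation
state of the cortex when the probe arrives.  ProbeTNT is then associated with
probe lick latency (Pearson r, index-shuffle Monte-Carlo) and with probe
outcome (one-sided rank test and median-difference outcome shuffle), and the
outcome association is swept over look-back windows of 3-50 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import mc_p_less, _pearson
from .core import SessionRecord
from .decoding import PopulationMatrix

__all__ = [
    "SimilarityResult",
    "ProbeAssociation",
    "pv_correlation_matrix",
    "category_block_means",
    "trial_category_labels",
    "tnt_series",
    "probe_tnt",
    "probe_association",
    "lookback_sweep",
]


@dataclass
class SimilarityResult:
    """Trial-pair correlation matrices (raw and z-scored) for one session."""

    corr_raw: np.ndarray
    corr_z: np.ndarray | None
    trial_index: np.ndarray
    trial_type: np.ndarray
    valid: np.ndarray  # False for zero-variance trial vectors

    @property
    def matrix(self) -> np.ndarray:
        return self.corr_z if self.corr_z is not None else self.corr_raw


@dataclass
class ProbeAssociation:
    latency_r: float
    latency_p: float
    rank_p: float
    median_diff: float
    median_diff_p: float
    n: int
    undefined: bool = False


def pv_correlation_matrix(
    matrix: PopulationMatrix, normalize: bool = True
) -> SimilarityResult:
    """Pairwise Pearson correlation of trial population vectors.

    With *normalize*, coefficients are z-scored using the mean and SD of the
    off-diagonal upper triangle (one normalization per session).  Trials whose
    vector has zero variance get NaN pairs and are excluded from the
    normalization.
    """
    X = matrix.X
    n = X.shape[0]
    if n < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 trials and 2 neurons")
    sd = X.std(axis=1)
    valid = sd > 0
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr[~valid, :] = np.nan
    corr[:, ~valid] = np.nan

    corr_z = None
    if normalize:
        iu = np.triu_indices(n, k=1)
        pairs = corr[iu]
        pairs = pairs[~np.isnan(pairs)]
        mu, s = pairs.mean(), pairs.std()
        corr_z = (corr - mu) / s if s > 0 else np.zeros_like(corr)
        corr_z[np.isnan(corr)] = np.nan
    return SimilarityResult(
        corr_raw=corr,
        corr_z=corr_z,
        trial_index=matrix.labels["trial_index"].to_numpy(),
        trial_type=matrix.labels["trial_type"].to_numpy(),
        valid=valid,
    )


def trial_category_labels(session: SessionRecord, trial_indices) -> np.ndarray:
    """Display categories: T, NT, NT<k> (repeats), P<k> (probes)."""
    by_index = {t.trial_index: t for t in session.trials}
    out = []
    for i in trial_indices:
        t = by_index[i]
        if t.trial_type == "target":
            out.append("T")
        elif t.trial_type == "nontarget":
            out.append("NT")
        elif t.trial_type == "nontarget_repeat":
            out.append(f"NT{t.repeat_id}")
        else:
            out.append(f"P{t.repeat_id}")
    return np.array(out)


def category_block_means(sim: SimilarityResult, categories) -> pd.DataFrame:
    """Mean pair correlation within and between categories.

    Self-pairs (the diagonal) never enter any average; a category with a
    single trial has a missing within-block mean.
    """
    categories = np.asarray(categories)
    mat = sim.matrix
    cats = sorted(set(categories))
    out = pd.DataFrame(index=cats, columns=cats, dtype=float)
    for a in cats:
        ia = np.flatnonzero(categories == a)
        for b in cats:
            ib = np.flatnonzero(categories == b)
            block = mat[np.ix_(ia, ib)].astype(float).copy()
            if a == b:
                np.fill_diagonal(block, np.nan)
            vals = block[~np.isnan(block)]
            out.loc[a, b] = vals.mean() if vals.size else np.nan
    return out


def tnt_series(sim: SimilarityResult) -> np.ndarray:
    """Per-trial target/nontarget similarity, in trial order.

    Target trials average their correlation with every nontarget trial
    (plain and repeated nontargets alike) and vice versa; probe trials (and
    invalid trials) get NaN.
    """
    types = sim.trial_type
    is_t = types == "target"
    is_nt = np.isin(types, ("nontarget", "nontarget_repeat"))
    if not is_t.any() or not is_nt.any():
        raise ValueError("session needs at least one target and one nontarget trial")
    mat = sim.matrix
    out = np.full(len(types), np.nan)
    for i in range(len(types)):
        if is_t[i]:
            opp = is_nt
        elif is_nt[i]:
            opp = is_t
        else:
            continue
        vals = mat[i, opp]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = vals.mean()
    return out


def probe_tnt(
    tnt: np.ndarray,
    probe_positions,
    L: int = 10,
    strict_index: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Look-back interpolation of TNT onto probe trials.

    For a probe at sequence position i, averages the TNT of the nearest L
    preceding TNT-bearing trials (skipping probes and other NaN trials); with
    *strict_index*, averages over exactly the L preceding positions instead,
    NaNs ignored.  Returns ``(values, defined)``; probes with fewer than L
    usable predecessors are flagged undefined.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    tnt = np.asarray(tnt, dtype=float)
    values = np.full(len(probe_positions), np.nan)
    defined = np.zeros(len(probe_positions), dtype=bool)
    for j, pos in enumerate(probe_positions):
        if strict_index:
            window = tnt[max(0, pos - L) : pos]
            usable = window[~np.isnan(window)]
            if pos >= L and usable.size:
                values[j] = usable.mean()
                defined[j] = True
        else:
            prior = tnt[:pos]
            usable = prior[~np.isnan(prior)]
            if usable.size >= L:
                values[j] = usable[-L:].mean()
                defined[j] = True
    return values, defined


def probe_association(
    probe_tnt_values,
    outcomes,
    latencies,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    session_ids=None,
) -> ProbeAssociation:
    """Associate ProbeTNT with probe latency and outcome.

    Latency: Pearson correlation plus a one-sided ('less than expected')
    index-shuffle Monte-Carlo p.  Outcome: one-sided test that correct probes
    have *lower* ProbeTNT than incorrect ones — a rank test (signed-rank over
    per-session medians when *session_ids* provides pairs, pooled
    Mann-Whitney otherwise) and a median-difference Monte-Carlo with shuffled
    outcome labels.  All undefined (NaN) entries are dropped first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(probe_tnt_values, dtype=float)
    out = np.asarray(outcomes, dtype=float)
    lat = np.asarray(latencies, dtype=float)
    keep = ~np.isnan(v) & ~np.isnan(out) & ~np.isnan(lat)
    v, out, lat = v[keep], out[keep].astype(bool), lat[keep]
    sid = None if session_ids is None else np.asarray(session_ids)[keep]
    if v.size < 10:
        raise ValueError("need at least 10 defined ProbeTNT values")

    latency_r = _pearson(v, lat)
    null_r = np.array(
        [_pearson(v, rng.permutation(lat)) for _ in range(n_shuffles)]
    )
    latency_p = mc_p_less(null_r, latency_r)

    if out.all() or not out.any():
        return ProbeAssociation(
            latency_r, latency_p, float("nan"), float("nan"), float("nan"),
            n=int(v.size), undefined=True,
        )

    rank_p = _outcome_rank_p(v, out, sid)
    obs_diff = float(np.median(v[out]) - np.median(v[~out]))
    null_diff = np.empty(n_shuffles)
    for s in range(n_shuffles):
        sh = rng.permutation(out)
        null_diff[s] = np.median(v[sh]) - np.median(v[~sh])
    diff_p = mc_p_less(null_diff, obs_diff)
    return ProbeAssociation(
        latency_r=latency_r,
        latency_p=latency_p,
        rank_p=rank_p,
        median_diff=obs_diff,
        median_diff_p=diff_p,
        n=int(v.size),
    )


def _outcome_rank_p(v: np.ndarray, out: np.ndarray, sid) -> float:
    """One-sided rank test that correct-probe TNT is lower than incorrect."""
    if sid is not None:
        pairs = []
        for s in np.unique(sid):
            m = sid == s
            if out[m].any() and (~out[m]).any():
                pairs.append(np.median(v[m & out]) - np.median(v[m & ~out]))
        if len(pairs) >= 5:
            return float(sps.wilcoxon(pairs, alternative="less").pvalue)
    return float(sps.mannwhitneyu(v[out], v[~out], alternative="less").pvalue)


def lookback_sweep(
    tnt,
    probe_positions,
    outcomes,
    latencies,
    L_range=range(3, 51),
    n_shuffles: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Correct-vs-incorrect ProbeTNT p-values across look-back window sizes.

    Returns one row per L with the rank-test p, the median-difference
    Monte-Carlo p, and the number of defined probes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outcomes = np.asarray(outcomes, dtype=float)
    latencies = np.asarray(latencies, dtype=float)
    rows = []
    for L in L_range:
        values, defined = probe_tnt(tnt, probe_positions, L=L)
        try:
            assoc = probe_association(
                values, outcomes, latencies, n_shuffles=n_shuffles, seed=rng
            )
            rows.append(
                {
                    "L": L,
                    "rank_p": assoc.rank_p,
                    "median_diff_p": assoc.median_diff_p,
                    "n_defined": int(defined.sum()),
                }
            )
        except ValueError:
            rows.append(
                {"L": L, "rank_p": np.nan, "median_diff_p": np.nan,
                 "n_defined": int(defined.sum())}
            )
    return pd.DataFrame(rows)
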