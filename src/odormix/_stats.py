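"""Small shared statistics helpers (add-one Monte-Carlo rules, trend engine)."""

from __future__ import annotations

import numpy as np

__all__ = ["add_one_p", "mc_p_less", "permutation_corr"]


def add_one_p(null: np.ndarray, observed: float) -> float:
    """Two-sided add-one permutation p-value on absolute magnitude.

    ``p = (1 + #{|null| >= |observed|}) / (n + 1)`` — never exactly zero, at
    most 1.  NaN null entries (degenerate shuffles) count as non-exceeding.
    """
    null = np.asarray(null, dtype=float)
    n = null.size
    if n < 1:
        raise ValueError("empty null distribution")
    hits = np.sum(np.abs(null[~np.isnan(null)]) >= abs(observed))
    return float((1 + hits) / (n + 1))


def mc_p_less(null: np.ndarray, observed: float) -> float:
    """One-sided add-one Monte-Carlo p for 'observed is smaller than the null'."""
    null = np.asarray(null, dtype=float)
    n = null.size
    if n < 1:
        raise ValueError("empty null distribution")
    hits = np.sum(null[~np.isnan(null)] <= observed)
    return float((1 + hits) / (n + 1))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r with a 0 guard for zero-variance inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def permutation_corr(
    values,
    positions,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> tuple[float, float, np.ndarray]:
    """Pearson correlation of *values* against *positions* with a
    position-label shuffle null.

    Returns ``(r, p, null_r)`` where ``p`` follows the add-one Monte-Carlo
    rule for the requested *alternative* (``two-sided`` compares magnitudes,
    ``greater``/``less`` are one-sided on the signed correlation).  A constant
    input yields ``r = 0, p = 1``.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.size != positions.size:
        raise ValueError("values and positions differ in length")
    if values.size < 3:
        raise ValueError("need at least 3 observations for a trend")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    r = _pearson(values, positions)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = _pearson(values, rng.permutation(positions))
    if values.std() == 0 or positions.std() == 0:
        return 0.0, 1.0, null
    if alternative == "two-sided":
        p = add_one_p(null, r)
    elif alternative == "greater":
        p = float((1 + np.sum(null >= r)) / (n_shuffles + 1))
    elif alternative == "less":
        p = mc_p_less(null, r)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, p, null
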