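"""Per-generation and per-treatment summary statistics.

The headline quantities are the realized population sex ratio (fraction of
sons among all juveniles) and the realized dispersal attempt rate (fraction
of mated daughters attempting dispersal, counted before mortality).  The
under-dense patch diagnostic quantifies how many patches are too sparse to
reach the "constant non-disperser" threshold implied by the population-mean
dispersal reaction norm — the regime in which density-dependent dispersal
cannot alleviate local resource competition.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "population_sex_ratio",
    "dispersal_attempt_rate",
    "estimate_threshold",
    "undersized_patch_fraction",
    "final_window_mean",
]


def population_sex_ratio(is_son: np.ndarray) -> float:
    """Fraction of sons among this generation's juveniles (pooled patches)."""
    is_son = np.asarray(is_son)
    if is_son.size == 0:
        raise ValueError("sex ratio undefined for an empty generation")
    return float(np.mean(is_son))


def dispersal_attempt_rate(attempted: np.ndarray) -> float:
    """Fraction of mated daughters that attempted dispersal (pre-mortality)."""
    attempted = np.asarray(attempted)
    if attempted.size == 0:
        raise ValueError("attempt rate undefined with no mated daughters")
    return float(np.mean(attempted))


def estimate_threshold(mean_p0: float, mean_p1: float, d_max: int) -> int:
    """Non-disperser threshold K of the population-mean reaction norm.

    K is the smallest daughter count D in [0, d_max] at which the mean norm
    ``mean_p0 + (mean_p1 - mean_p0) * D / d_max`` becomes positive — i.e. the
    patch size below which even full retention leaves the patch short of
    exportable daughters.  The endpoint means are genotypic (unclipped), so a
    negative ``mean_p0`` defers the crossing.  If the norm is positive already
    at D = 0 the threshold is 0; if it never turns positive it is ``d_max``.
    """
    if d_max < 0:
        raise ValueError("d_max must be non-negative")
    if mean_p0 > 0.0:
        return 0
    if mean_p1 <= 0.0:  # value at d_max; norm never positive on [0, d_max]
        return d_max
    # mean_p0 <= 0 < mean_p1: single upward crossing at x = -p0 * d_max / (p1 - p0)
    x = -mean_p0 * d_max / (mean_p1 - mean_p0)
    return min(int(math.floor(x)) + 1, d_max)


def undersized_patch_fraction(daughter_counts: np.ndarray, K: int) -> float:
    """Fraction of occupied patches whose daughter count falls below K.

    ``daughter_counts`` holds the post-mating daughter count of every patch;
    empty patches are excluded from the denominator.  NaN if no patch is
    occupied.
    """
    counts = np.asarray(daughter_counts)
    occupied = counts > 0
    n_occ = int(occupied.sum())
    if n_occ == 0:
        return float("nan")
    return float((counts[occupied] < K).sum() / n_occ)


def final_window_mean(series: np.ndarray, window: int) -> float:
    """Mean of the final ``window`` entries, ignoring NaNs."""
    series = np.asarray(series, dtype=float)
    if not 1 <= window <= series.shape[0]:
        raise ValueError(f"window must be in [1, {series.shape[0]}], got {window}")
    tail = series[-window:]
    if np.isnan(tail).all():
        return float("nan")
    return float(np.nanmean(tail))
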