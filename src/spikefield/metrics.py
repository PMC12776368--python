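"""Event-related summaries and effect sizes.

* PSTH: sliding-window firing rate (50 ms window, 10 ms steps by default).
* Repetition effect: d' between responses to novel and repeated images,
  ``d' = (mu_nov - mu_rep) / ((sigma_nov + sigma_rep) / 2)``, positive for
  repetition suppression.
* Pearson correlations between event-related time courses and between
  response magnitude and image memorability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TimeCourse",
    "RepetitionEffect",
    "psth",
    "repetition_dprime",
    "timecourse_correlation",
    "memorability_correlation",
]


@dataclass
class TimeCourse:
    """A sliding-window time course labeled by bin centers (ms)."""

    values: np.ndarray
    times: np.ndarray
    window_ms: float = 50.0
    step_ms: float = 10.0
    baseline_subtracted: bool = False
    measure: str = "rate_hz"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.times):
            raise ValueError("values and times must have equal length")


@dataclass
class RepetitionEffect:
    """d' between novel and repeated responses; > 0 iff mu_nov > mu_rep."""

    d_prime: float
    mu_nov: float
    mu_rep: float
    sigma_nov: float
    sigma_rep: float
    n_images: int


def psth(
    spike_times_ms: Sequence[np.ndarray],
    range_ms: tuple[float, float] = (-200.0, 500.0),
    window_ms: float = 50.0,
    step_ms: float = 10.0,
    baseline_window: tuple[float, float] | None = None,
) -> TimeCourse:
    """Trial-averaged firing rate in sliding half-open bins [t, t + window).

    ``spike_times_ms`` holds one array of spike times (ms relative to
    stimulus onset) per trial.  Bin count is
    ``floor((span - window) / step) + 1``; bins are labeled by center.
    With ``baseline_window``, the mean rate in that window is subtracted.
    """
    lo, hi = float(range_ms[0]), float(range_ms[1])
    span = hi - lo
    if window_ms > span:
        raise ValueError("window exceeds the requested range span")
    if baseline_window is not None and (
        baseline_window[0] < lo or baseline_window[1] > hi
    ):
        raise ValueError("range must cover the baseline window")
    n_bins = int(np.floor((span - window_ms) / step_ms)) + 1
    starts = lo + step_ms * np.arange(n_bins)
    centers = starts + window_ms / 2.0

    counts = np.zeros(n_bins)
    n_trials = len(spike_times_ms)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    for trial in spike_times_ms:
        t = np.asarray(trial, dtype=float)
        for b, s in enumerate(starts):
            counts[b] += np.count_nonzero((t >= s) & (t < s + window_ms))
    rate = counts / n_trials / (window_ms / 1000.0)

    subtracted = False
    if baseline_window is not None:
        mask = (centers >= baseline_window[0]) & (centers < baseline_window[1])
        if not mask.any():
            raise ValueError("baseline window contains no bins")
        rate = rate - rate[mask].mean()
        subtracted = True
    return TimeCourse(
        values=rate,
        times=centers,
        window_ms=window_ms,
        step_ms=step_ms,
        baseline_subtracted=subtracted,
    )


def repetition_dprime(nov: np.ndarray, rep: np.ndarray) -> RepetitionEffect:
    """Repetition-suppression effect size across images.

    Uses sample standard deviations (n - 1 denominator).  Raises when both
    SDs are zero (the statistic is undefined).
    """
    nov = np.asarray(nov, dtype=float)
    rep = np.asarray(rep, dtype=float)
    if nov.size < 2 or rep.size < 2:
        raise ValueError("need at least two images per condition")
    mu_n, mu_r = nov.mean(), rep.mean()
    sd_n, sd_r = nov.std(ddof=1), rep.std(ddof=1)
    denom = (sd_n + sd_r) / 2.0
    if denom == 0:
        raise ValueError("both conditions have zero variance; d' undefined")
    return RepetitionEffect(
        d_prime=float((mu_n - mu_r) / denom),
        mu_nov=float(mu_n),
        mu_rep=float(mu_r),
        sigma_nov=float(sd_n),
        sigma_rep=float(sd_r),
        n_images=int(min(nov.size, rep.size)),
    )


def timecourse_correlation(
    a: TimeCourse, b: TimeCourse, window_ms: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between two time courses on one grid."""
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
        raise ValueError("time courses must share the same time grid")
    mask = np.ones(len(a.times), dtype=bool)
    if window_ms is not None:
        mask = (a.times >= window_ms[0]) & (a.times < window_ms[1])
    x, y = a.values[mask], b.values[mask]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance time course; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def memorability_correlation(
    response_magnitude: np.ndarray, memorability: np.ndarray
) -> dict:
    """Pearson correlation and least-squares line of response on memorability.

    Returns ``{'r', 'p', 'slope', 'intercept'}``.
    """
    x = np.asarray(memorability, dtype=float)
    y = np.asarray(response_magnitude, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three matched pseudoimages")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }
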