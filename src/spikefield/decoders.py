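"""Population decoding: novelty classifiers, neuron-dropping curves,
power-law efficiency fits, behavioral rescaling, RSA, category decoding.

Two linear readouts distinguish novel from repeated images by the rule
``w . x > b -> novel`` (ties -> repeated):

* the *spike-count classifier*, with every weight 1/N and bias at the
  projected midpoint of the class means — equivalent to thresholding the
  population mean count;
* the *diagonal-covariance Fisher linear discriminant* (FLD),
  ``w = (mu_nov - mu_rep) / sigma^2`` with the variance averaged across
  the two classes and off-diagonal covariance terms set to zero, which in
  effect weights each observation by its discriminability.

Cross-validation always splits by image (never by observation), shuffles
each observation's image assignment within matched-n-back sets to remove
spurious across-session correlations, and stratifies the 80/20 split by
n-back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .pseudopop import Pseudopopulation

__all__ = [
    "LinearReadout",
    "DecodingResult",
    "PowerLawFit",
    "BehaviorPrediction",
    "spike_count_classifier",
    "fld_fit",
    "classify",
    "cross_validated_decoding",
    "neuron_dropping_curve",
    "fit_power_law",
    "efficiency_ratio",
    "gaussian_performance",
    "rescale_to_behavior",
    "prediction_quality",
    "rsa_matrix",
    "prototype_decoder",
    "nearest_centroid_decoder",
]

log = logging.getLogger(__name__)


@dataclass
class LinearReadout:
    """Linear decision rule: classify novel iff ``w . x > b``."""

    weights: np.ndarray
    bias: float
    kind: str = "spike_count"

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """``w . x - b`` for observation x item matrix ``x``; > 0 -> novel."""
        return self.weights @ np.asarray(x, dtype=float) - self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Labels for each column of ``x``; the boundary goes to 'repeated'."""
        return np.where(self.decision_values(x) > 0, "novel", "repeated")


def spike_count_classifier(
    train_nov: np.ndarray, train_rep: np.ndarray
) -> LinearReadout:
    """Uniform-weight readout: w_i = 1/N, b = w . (mu_nov + mu_rep) / 2."""
    train_nov = np.asarray(train_nov, dtype=float)
    train_rep = np.asarray(train_rep, dtype=float)
    if train_nov.shape[1] == 0 or train_rep.shape[1] == 0:
        raise ValueError("both training classes must be non-empty")
    n = train_nov.shape[0]
    w = np.full(n, 1.0 / n)
    b = float(w @ (train_nov.mean(axis=1) + train_rep.mean(axis=1)) / 2.0)
    return LinearReadout(weights=w, bias=b, kind="spike_count")


def fld_fit(train_nov: np.ndarray, train_rep: np.ndarray) -> LinearReadout:
    """Diagonal-covariance Fisher linear discriminant.

    ``w_i = (mu_nov_i - mu_rep_i) / var_i`` with ``var_i`` the sample
    variance averaged across the two classes; an observation with zero
    variance gets weight 0 (with a logged notice) since it carries no
    usable variance model.  Bias at the projected class-mean midpoint.
    """
    train_nov = np.asarray(train_nov, dtype=float)
    train_rep = np.asarray(train_rep, dtype=float)
    if train_nov.shape[1] < 2 or train_rep.shape[1] < 2:
        raise ValueError("need at least two training images per class")
    mu_n = train_nov.mean(axis=1)
    mu_r = train_rep.mean(axis=1)
    var = (train_nov.var(axis=1, ddof=1) + train_rep.var(axis=1, ddof=1)) / 2.0
    if np.all(var == 0):
        raise ValueError("all observations have zero variance; FLD undefined")
    w = np.zeros_like(mu_n)
    nonzero = var > 0
    w[nonzero] = (mu_n - mu_r)[nonzero] / var[nonzero]
    if not nonzero.all():
        log.info("FLD: %d zero-variance observations got weight 0",
                 int((~nonzero).sum()))
    b = float(w @ (mu_n + mu_r) / 2.0)
    return LinearReadout(weights=w, bias=b, kind="fld")


_FITTERS = {"spike_count": spike_count_classifier, "fld": fld_fit}


def classify(
    readout: LinearReadout, test_nov: np.ndarray, test_rep: np.ndarray
) -> float:
    """Fraction of test items assigned their true label."""
    pred_n = readout.predict(test_nov)
    pred_r = readout.predict(test_rep)
    correct = np.count_nonzero(pred_n == "novel") + np.count_nonzero(
        pred_r == "repeated"
    )
    return correct / (len(pred_n) + len(pred_r))


@dataclass
class DecodingResult:
    """Cross-validated accuracy with per-iteration spread."""

    accuracy: float
    per_iteration: np.ndarray
    population_size: int
    n_cv: int
    n_subsample: int
    measure: str
    classifier: str

    @property
    def sd(self) -> float:
        return float(np.std(self.per_iteration))


def _strata(images, stratify_by: str | None) -> list[np.ndarray]:
    if stratify_by is None:
        return [np.arange(len(images))]
    values = images[stratify_by].to_numpy()
    return [np.flatnonzero(values == v) for v in np.unique(values)]


def _stratified_split(
    strata: list[np.ndarray], train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cols in strata:
        perm = rng.permutation(cols)
        n_test = max(1, int(round(len(cols) * (1 - train_fraction))))
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return np.concatenate(train), np.concatenate(test)


def cross_validated_decoding(
    pseudo: Pseudopopulation,
    classifier: str = "spike_count",
    measure: str = "spikes",
    population_size: int | None = None,
    n_cv: int = 1000,
    n_subsample: int = 50,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_by: str | None = "n_back",
) -> DecodingResult:
    """Cross-validated novel-vs-repeated decoding accuracy.

    Runs ``n_subsample`` resamplings of ``population_size`` observations;
    within each, every observation's image assignment is shuffled within
    matched-n-back sets (decorrelating sessions) and ``n_cv /
    n_subsample`` stratified 80/20 train/test splits are evaluated.
    ``per_iteration`` holds all ``n_cv`` accuracies; ``accuracy`` is their
    mean.
    """
    nov, rep = pseudo.responses(measure)
    n_obs, n_img = nov.shape
    if population_size is None:
        population_size = n_obs
    if population_size > n_obs:
        raise ValueError(
            f"population_size {population_size} exceeds {n_obs} observations"
        )
    if n_subsample < 1 or n_cv < n_subsample:
        raise ValueError("need n_cv >= n_subsample >= 1")
    strata = _strata(pseudo.images, stratify_by)
    for cols in strata:
        if len(cols) < 5:
            value = (
                pseudo.images[stratify_by].to_numpy()[cols[0]]
                if stratify_by
                else "all"
            )
            raise ValueError(
                f"stratum {stratify_by}={value} has only {len(cols)} images; "
                "cannot stratify an 80/20 split"
            )
    fitter = _FITTERS[classifier]
    rng = np.random.default_rng(seed)
    splits_per_group = n_cv // n_subsample
    extra = n_cv - splits_per_group * n_subsample

    per_iteration = np.empty(n_cv)
    it = 0
    for g in range(n_subsample):
        rows = rng.choice(n_obs, size=population_size, replace=False)
        sub_nov = nov[rows].copy()
        sub_rep = rep[rows].copy()
        # shuffle image assignment within n-back sets, per observation,
        # keeping each image's novel/repeated pair together
        for r in range(population_size):
            for cols in strata:
                perm = rng.permutation(cols)
                sub_nov[r, cols] = sub_nov[r, perm]
                sub_rep[r, cols] = sub_rep[r, perm]
        n_splits = splits_per_group + (1 if g < extra else 0)
        for _ in range(n_splits):
            train_img, test_img = _stratified_split(strata, train_fraction, rng)
            assert not set(train_img) & set(test_img)
            readout = fitter(sub_nov[:, train_img], sub_rep[:, train_img])
            per_iteration[it] = classify(
                readout, sub_nov[:, test_img], sub_rep[:, test_img]
            )
            it += 1
    return DecodingResult(
        accuracy=float(per_iteration.mean()),
        per_iteration=per_iteration,
        population_size=int(population_size),
        n_cv=n_cv,
        n_subsample=n_subsample,
        measure=measure,
        classifier=classifier,
    )


def neuron_dropping_curve(
    pseudo: Pseudopopulation,
    classifier: str = "spike_count",
    measure: str = "spikes",
    sizes: Sequence[int] = (1, 2, 4, 8, 16, 32),
    n_cv: int = 1000,
    n_subsample: int = 50,
    seed: int = 0,
    stratify_by: str | None = "n_back",
) -> list[DecodingResult]:
    """Decoding accuracy as a function of population size.

    The per-size seeds are derived from ``seed`` and the size index only,
    so spike- and channel-based curves run under a shared seed schedule
    for paired comparison.
    """
    results = []
    for i, size in enumerate(sizes):
        results.append(
            cross_validated_decoding(
                pseudo,
                classifier=classifier,
                measure=measure,
                population_size=int(size),
                n_cv=n_cv,
                n_subsample=n_subsample,
                seed=seed + 7919 * i,
                stratify_by=stratify_by,
            )
        )
    return results


def cross_validated_projections(
    pseudo: Pseudopopulation,
    measure: str = "spikes",
    population_size: int | None = None,
    n_cv: int = 200,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> dict:
    """Signed FLD decision values of held-out items, keyed by condition.

    Conditions are 'novel' (all held-out novel presentations pooled) and
    one integer key per n-back (held-out repeated presentations).  Uses
    the same image-stratified splitting and within-n-back shuffling as
    :func:`cross_validated_decoding`; feeds :func:`rescale_to_behavior`.
    """
    nov, rep = pseudo.responses(measure)
    n_obs = nov.shape[0]
    if population_size is None:
        population_size = n_obs
    if population_size > n_obs:
        raise ValueError("population_size exceeds available observations")
    strata = _strata(pseudo.images, "n_back")
    n_backs = pseudo.images["n_back"].to_numpy()
    rng = np.random.default_rng(seed)
    out: dict = {"novel": []}
    for nb in np.unique(n_backs):
        out[int(nb)] = []
    for _ in range(n_cv):
        rows = rng.choice(n_obs, size=population_size, replace=False)
        sub_nov = nov[rows].copy()
        sub_rep = rep[rows].copy()
        for r in range(population_size):
            for cols in strata:
                perm = rng.permutation(cols)
                sub_nov[r, cols] = sub_nov[r, perm]
                sub_rep[r, cols] = sub_rep[r, perm]
        train_img, test_img = _stratified_split(strata, train_fraction, rng)
        readout = fld_fit(sub_nov[:, train_img], sub_rep[:, train_img])
        out["novel"].extend(readout.decision_values(sub_nov[:, test_img]))
        vals = readout.decision_values(sub_rep[:, test_img])
        for v, nb in zip(vals, n_backs[test_img]):
            out[int(nb)].append(v)
    return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class PowerLawFit:
    """Least-squares fit of accuracy vs. population size, y = a x^b + c."""

    a: float
    b: float
    c: float
    sizes: np.ndarray
    accuracies: np.ndarray
    sse: float

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=float) ** self.b + self.c

    def n_at(self, target: float = 0.75) -> float | None:
        """Population size at which the fitted curve reaches ``target``.

        ``None`` when the target is unattainable on x > 0 (asymptote below
        target, a decreasing curve already below it, or a flat fit with
        negligible growth term).
        """
        if abs(self.a) < 1e-9:  # flat curve: y == c everywhere
            return 0.0 if target <= self.c else None
        if self.a > 0:
            if target <= self.c:
                return 0.0
            return float(((target - self.c) / self.a) ** (1.0 / self.b))
        if self.a < 0 and target < self.c:
            return float(((target - self.c) / self.a) ** (1.0 / self.b))
        return None


def fit_power_law(
    sizes: Sequence[int | float],
    accuracies: Sequence[float],
    b_bounds: tuple[float, float] = (1e-6, 2.0),
) -> PowerLawFit:
    """Fit ``y = a x^b + c`` by profiled least squares.

    For fixed exponent b the model is linear in (a, c), so a and c are
    solved in closed form and only b is searched (grid + bounded local
    refinement) — deterministic and exact on noiseless model data.
    """
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(accuracies, dtype=float)
    if x.size < 4:
        raise ValueError("need at least four points to fit a three-parameter law")
    if np.any(x <= 0):
        raise ValueError("sizes must be positive")

    def profile_sse(b: float) -> tuple[float, float, float]:
        design = np.column_stack([x**b, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return float(resid @ resid), float(coef[0]), float(coef[1])

    best = None
    grid = np.linspace(b_bounds[0], b_bounds[1], 41)
    for b0 in grid:
        sse, a, c = profile_sse(b0)
        if best is None or sse < best[0]:
            best = (sse, a, b0, c)
    res = optimize.minimize_scalar(
        lambda b: profile_sse(b)[0],
        bounds=b_bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    sse, a, c = profile_sse(float(res.x))
    if sse < best[0]:
        best = (sse, a, float(res.x), c)
    sse, a, b, c = best[0], best[1], best[2], best[3]
    return PowerLawFit(a=a, b=b, c=c, sizes=x, accuracies=y, sse=sse)


def efficiency_ratio(
    spike_fit: PowerLawFit, hga_fit: PowerLawFit, target: float = 0.75
) -> float:
    """How many-fold more units than channels are needed to reach ``target``
    accuracy; > 1 means the channel measure is more data-efficient."""
    n_spike = spike_fit.n_at(target)
    n_hga = hga_fit.n_at(target)
    if n_spike is None or n_hga is None:
        raise ValueError(f"target accuracy {target} not attained by both fits")
    if n_hga == 0:
        raise ValueError("channel fit attains the target at size 0; ratio undefined")
    return float(n_spike / n_hga)


def gaussian_performance(mean: float, sd: float, condition: str) -> float:
    """Correct-response probability of a Gaussian decision variable.

    The decision variable f = w.x - b is positive for 'novel' responses;
    a repeated-condition response is correct when f < 0.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if condition == "novel":
        return float(stats.norm.sf(0.0, loc=mean, scale=sd))
    return float(stats.norm.cdf(0.0, loc=mean, scale=sd))


@dataclass
class BehaviorPrediction:
    """Rescaled neural prediction of behavior and its quality."""

    predicted_performance: dict
    chosen_population_size: float
    mse_neural: float
    mse_benchmark: float
    pq: float
    sd_plateau: float
    mean_slopes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pq > 1 + 1e-12:
            raise ValueError("PQ cannot exceed 1")


def prediction_quality(mse_neural: float, behavior: dict | Sequence[float]) -> float:
    """PQ = 1 - MSE_neural / MSE_benchmark, the benchmark being constant
    50% performance across conditions.  1 = perfect, 0 = chance-level."""
    vals = np.asarray(
        list(behavior.values()) if isinstance(behavior, dict) else behavior,
        dtype=float,
    )
    mse_benchmark = float(np.mean((vals - 0.5) ** 2))
    if mse_benchmark == 0:
        raise ValueError(
            "behavior is exactly 50% everywhere; the benchmark MSE is zero "
            "and PQ is undefined"
        )
    return 1.0 - mse_neural / mse_benchmark


def rescale_to_behavior(
    projections: dict[int, dict],
    behavior: dict,
    size_grid: Sequence[float],
) -> BehaviorPrediction:
    """Match FLD readout performance to behavior by extrapolating size.

    ``projections[size][condition]`` holds the signed FLD decision values
    of cross-validated test items at each measured population size, per
    condition ('novel' and one key per n-back).  Projection means grow
    proportionally with population size while spreads plateau, so the
    per-condition mean is fit through the origin against size, the SD is
    fixed at its plateau (the mean per-condition SD at the largest
    measured size), and performance at a candidate size is the Gaussian
    probability of the correct response side.  The candidate minimizing
    MSE to behavior is chosen; because all condition means share the same
    linear growth, the rank order of predicted performance across
    conditions is preserved by rescaling.
    """
    sizes = sorted(projections)
    if len(sizes) < 2:
        raise ValueError("need projections at >= 2 population sizes")
    size_grid = list(size_grid)
    if not size_grid:
        raise ValueError("size_grid is empty")
    conditions = list(behavior)
    for s in sizes:
        missing = [c for c in conditions if c not in projections[s]]
        if missing:
            raise ValueError(f"size {s} lacks projections for {missing}")

    s_arr = np.asarray(sizes, dtype=float)
    slopes = {}
    for c in conditions:
        means = np.array([np.mean(projections[s][c]) for s in sizes])
        slopes[c] = float((s_arr @ means) / (s_arr @ s_arr))  # through origin
    s_max = sizes[-1]
    sd_plateau = float(
        np.mean([np.std(projections[s_max][c], ddof=1) for c in conditions])
    )
    if sd_plateau <= 0:
        raise ValueError("projection spread at the largest size is zero")

    best = None
    for cand in size_grid:
        perf = {
            c: gaussian_performance(slopes[c] * cand, sd_plateau, _side(c))
            for c in conditions
        }
        mse = float(
            np.mean([(perf[c] - float(behavior[c])) ** 2 for c in conditions])
        )
        if best is None or mse < best[0] - 1e-15:
            best = (mse, cand, perf)
    mse_neural, chosen, perf = best
    vals = np.array([float(behavior[c]) for c in conditions])
    mse_benchmark = float(np.mean((vals - 0.5) ** 2))
    pq = prediction_quality(mse_neural, behavior)
    return BehaviorPrediction(
        predicted_performance=perf,
        chosen_population_size=float(chosen),
        mse_neural=mse_neural,
        mse_benchmark=mse_benchmark,
        pq=pq,
        sd_plateau=sd_plateau,
        mean_slopes=slopes,
    )


def _side(condition) -> str:
    return "novel" if condition == "novel" else "repeated"


def rsa_matrix(responses: np.ndarray) -> np.ndarray:
    """Image x image representational similarity.

    Each observation's activity is z-scored across images; the matrix
    entry (i, j) is the Pearson correlation of the two images' z-scored
    population vectors.  Zero-variance observations are dropped with a
    notice.
    """
    x = np.asarray(responses, dtype=float)
    sd = x.std(axis=1)
    usable = sd > 0
    if usable.sum() < 2:
        raise ValueError("need at least two observations with nonzero variance")
    if not usable.all():
        log.info("RSA: dropping %d zero-variance observations",
                 int((~usable).sum()))
    z = (x[usable] - x[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    mat = np.corrcoef(z, rowvar=False)
    np.fill_diagonal(mat, 1.0)
    return mat


def _prototype_accuracy(
    responses: np.ndarray,
    labels: np.ndarray,
    n_cv: int,
    rng: np.random.Generator,
    metric: str,
) -> float:
    classes = np.unique(labels)
    members = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in members.items():
        if len(idx) < 2:
            raise ValueError(f"category {c!r} has fewer than 2 images")
    correct = 0
    total = 0
    for _ in range(n_cv):
        test_idx = {c: rng.choice(members[c]) for c in classes}
        prototypes = np.column_stack(
            [
                responses[:, np.setdiff1d(members[c], [test_idx[c]])].mean(axis=1)
                for c in classes
            ]
        )
        for true_c in classes:
            v = responses[:, test_idx[true_c]]
            if metric == "correlation":
                scores = _corr_scores(v, prototypes)
                pick = int(np.argmax(scores))
            else:
                dists = np.linalg.norm(prototypes - v[:, None], axis=0)
                pick = int(np.argmin(dists))
            correct += classes[pick] == true_c
            total += 1
    return correct / total


def _corr_scores(v: np.ndarray, prototypes: np.ndarray) -> np.ndarray:
    """Pearson r of ``v`` with each prototype column; degenerate
    (zero-variance) pairs score -inf so they are never selected; argmax
    ties resolve to the lowest category index."""
    vc = v - v.mean()
    pc = prototypes - prototypes.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(vc) * np.linalg.norm(pc, axis=0)
    scores = np.full(prototypes.shape[1], -np.inf)
    ok = denom > 0
    scores[ok] = (vc @ pc[:, ok]) / denom[ok]
    return scores


def prototype_decoder(
    responses: np.ndarray,
    categories: Sequence,
    n_cv: int = 1000,
    seed: int = 0,
) -> float:
    """Five-way (generally k-way) prototype classification accuracy.

    Each iteration holds out one random image per category, averages the
    remaining images into a prototype vector per category, and assigns
    each held-out image to the category whose prototype it correlates
    with most strongly (Pearson; ties to the lowest category index).
    """
    labels = np.asarray(categories)
    return _prototype_accuracy(
        np.asarray(responses, dtype=float),
        labels,
        n_cv,
        np.random.default_rng(seed),
        metric="correlation",
    )


def nearest_centroid_decoder(
    responses: np.ndarray,
    categories: Sequence,
    n_cv: int = 1000,
    seed: int = 0,
) -> float:
    """Euclidean nearest-centroid variant of :func:`prototype_decoder`,
    provided as a robustness check on the choice of classifier."""
    labels = np.asarray(categories)
    return _prototype_accuracy(
        np.asarray(responses, dtype=float),
        labels,
        n_cv,
        np.random.default_rng(seed),
        metric="euclidean",
    )
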