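"""ABC model choice, Bayes factors, parameter posteriors and cross-validation.

Distances are Euclidean on statistics standardized by their per-column median
absolute deviation over the reference table.  The two regression-based model
choice methods weight accepted rows with an Epanechnikov kernel in distance
(bandwidth = the largest accepted distance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent_sim import ReferenceTable
from .popgen_stats import SummaryStatisticVector

__all__ = [
    "ABCConfig",
    "ModelPosterior",
    "PosteriorSummary",
    "CVResult",
    "standardize",
    "rejection_sample",
    "model_posterior_rejection",
    "model_posterior_mnlogistic",
    "model_posterior_neuralnet",
    "bayes_factors",
    "estimate_parameters",
    "hpd",
    "cross_validate",
]


@dataclass
class ABCConfig:
    tolerance: float = 0.01
    method: str = "rejection"  # rejection | mnlogistic | neuralnet
    nnet_count: int = 100
    nnet_maxit: int = 1000
    nnet_hidden: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance <= 1.0:
            raise ValueError("tolerance must be in (0, 1]")
        if self.nnet_count < 1:
            raise ValueError("nnet_count must be >= 1")
        if self.method not in ("rejection", "mnlogistic", "neuralnet"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ModelPosterior:
    models: list[str]
    pp: np.ndarray  # posterior probability per model, sums to 1
    method: str
    tolerance: float
    n_accepted: int
    bf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        self.bf = bayes_factors(self.pp)

    def to_series(self) -> pd.Series:
        return pd.Series(self.pp, index=self.models, name="PP")


@dataclass
class PosteriorSummary:
    parameter: str
    draws: np.ndarray
    mean: float
    ci95: tuple[float, float]  # 1.96 * SE(mean) around the mean
    hpd95: tuple[float, float]  # shortest interval holding >= 95% of draws
    tolerance: float


@dataclass
class CVResult:
    """Prediction error Epred = sum((est-true)^2) / (n * Var(true)) per
    parameter and tolerance."""

    epred: pd.DataFrame  # index: parameter, columns: tolerance
    n_cv: int


# ---------------------------------------------------------------------------
# Standardization & rejection
# ---------------------------------------------------------------------------


def _mad(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=0)
    return np.median(np.abs(x - med), axis=0)


def standardize(
    ref_stats: np.ndarray,
    obs: np.ndarray,
    stat_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each statistic by its MAD over the reference table.

    Zero-MAD (constant) columns are dropped with a warning.  Returns
    (scaled reference, scaled observation, kept-column indices).
    """
    ref_stats = np.asarray(ref_stats, dtype=float)
    obs = np.asarray(obs, dtype=float).ravel()
    if ref_stats.shape[1] != obs.shape[0]:
        raise ValueError("reference and observed statistic dimensions differ")
    scale = _mad(ref_stats)
    keep = np.flatnonzero(scale > 0)
    if keep.size == 0:
        raise ValueError("no statistic column with positive spread")
    if keep.size < ref_stats.shape[1]:
        dropped = sorted(set(range(ref_stats.shape[1])) - set(keep))
        names = (
            [stat_names[i] for i in dropped] if stat_names is not None else dropped
        )
        warnings.warn(f"dropping constant statistic column(s): {names}")
    return ref_stats[:, keep] / scale[keep], obs[keep] / scale[keep], keep


def _distances(ref_scaled: np.ndarray, obs_scaled: np.ndarray) -> np.ndarray:
    diff = ref_scaled - obs_scaled
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def rejection_sample(
    ref: ReferenceTable | np.ndarray,
    obs: SummaryStatisticVector | np.ndarray,
    tolerance: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the floor(tolerance*n) rows nearest to obs.

    Ties at the acceptance boundary are broken by stable row order.
    """
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    if isinstance(ref, ReferenceTable):
        stats = ref.stats_matrix()
        names = ref.stat_names
    else:
        stats = np.asarray(ref, dtype=float)
        names = None
    obs_v = obs.values if isinstance(obs, SummaryStatisticVector) else np.asarray(obs)
    ref_s, obs_s, _ = standardize(stats, obs_v, names)
    d = _distances(ref_s, obs_s)
    n_keep = int(math.floor(tolerance * len(d)))
    if n_keep == 0:
        raise ValueError(
            f"tolerance {tolerance} too small: floor({tolerance}*{len(d)}) = 0 rows"
        )
    order = np.argsort(d, kind="stable")
    acc = order[:n_keep]
    return acc, d[acc]


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------


def _epanechnikov(dist: np.ndarray) -> np.ndarray:
    h = dist.max()
    if h == 0:
        return np.ones_like(dist)
    w = 1.0 - (dist / h) ** 2
    # the boundary row would get weight 0; keep it marginally in the fit
    return np.maximum(w, 1e-6)


def model_posterior_rejection(
    ref: ReferenceTable,
    obs: SummaryStatisticVector | np.ndarray,
    tolerance: float,
) -> ModelPosterior:
    """PP per model = its fraction among accepted rows."""
    acc, _ = rejection_sample(ref, obs, tolerance)
    labels = ref.df["model"].to_numpy()[acc]
    models = _model_order(ref)
    pp = np.array([np.mean(labels == m) for m in models])
    return ModelPosterior(models, pp, "rejection", tolerance, len(acc))


def _model_order(ref: ReferenceTable) -> list[str]:
    return list(pd.unique(ref.df["model"]))


def model_posterior_mnlogistic(
    ref: ReferenceTable,
    obs: SummaryStatisticVector | np.ndarray,
    tolerance: float,
) -> ModelPosterior:
    """Multinomial logistic regression of model label on standardized
    statistics over the accepted rows, kernel-weighted in distance; class
    probabilities evaluated at the observation, clipped and renormalized."""
    from sklearn.linear_model import LogisticRegression

    stats = ref.stats_matrix()
    obs_v = obs.values if isinstance(obs, SummaryStatisticVector) else np.asarray(obs)
    ref_s, obs_s, _ = standardize(stats, obs_v, ref.stat_names)
    d = _distances(ref_s, obs_s)
    n_keep = int(math.floor(tolerance * len(d)))
    if n_keep == 0:
        raise ValueError("tolerance too small")
    acc = np.argsort(d, kind="stable")[:n_keep]
    labels = ref.df["model"].to_numpy()[acc]
    models = _model_order(ref)
    present = [m for m in models if m in set(labels)]
    missing = [m for m in models if m not in set(labels)]
    if missing:
        warnings.warn(f"model(s) absent from accepted set, PP=0: {missing}")
    if len(present) < 2:
        pp = np.array([1.0 if m in present else 0.0 for m in models])
        return ModelPosterior(models, pp, "mnlogistic", tolerance, n_keep)
    w = _epanechnikov(d[acc])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(max_iter=2000, C=1e4)
        clf.fit(ref_s[acc], labels, sample_weight=w)
        proba = clf.predict_proba(obs_s.reshape(1, -1))[0]
    by_class = dict(zip(clf.classes_, proba))
    pp = np.array([by_class.get(m, 0.0) for m in models])
    pp = np.clip(pp, 0.0, 1.0)
    pp = pp / pp.sum()
    return ModelPosterior(models, pp, "mnlogistic", tolerance, n_keep)


def model_posterior_neuralnet(
    ref: ReferenceTable,
    obs: SummaryStatisticVector | np.ndarray,
    tolerance: float,
    rng: np.random.Generator,
    nnet_count: int = 100,
    nnet_maxit: int = 1000,
    hidden: int = 5,
) -> ModelPosterior:
    """Ensemble of single-hidden-layer classifiers on the accepted rows.

    Kernel weighting enters through a weighted bootstrap of the training rows
    for each ensemble member; PP is the ensemble-mean class probability at
    the observation.  Members whose fit fails are dropped (warning if >20%)."""
    from sklearn.neural_network import MLPClassifier

    stats = ref.stats_matrix()
    obs_v = obs.values if isinstance(obs, SummaryStatisticVector) else np.asarray(obs)
    ref_s, obs_s, _ = standardize(stats, obs_v, ref.stat_names)
    d = _distances(ref_s, obs_s)
    n_keep = int(math.floor(tolerance * len(d)))
    if n_keep == 0:
        raise ValueError("tolerance too small")
    acc = np.argsort(d, kind="stable")[:n_keep]
    labels = ref.df["model"].to_numpy()[acc]
    models = _model_order(ref)
    present = sorted(set(labels))
    missing = [m for m in models if m not in present]
    if missing:
        warnings.warn(f"model(s) absent from accepted set, PP=0: {missing}")
    if len(present) < 2:
        pp = np.array([1.0 if m in present else 0.0 for m in models])
        return ModelPosterior(models, pp, "neuralnet", tolerance, n_keep)

    x, y = ref_s[acc], labels
    w = _epanechnikov(d[acc])
    w = w / w.sum()
    probs: list[np.ndarray] = []
    dropped = 0
    for _ in range(nnet_count):
        take = rng.choice(len(x), size=len(x), replace=True, p=w)
        xt, yt = x[take], y[take]
        if len(set(yt)) < 2:
            dropped += 1
            continue
        seed = int(rng.integers(2**31 - 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = MLPClassifier(
                    hidden_layer_sizes=(hidden,),
                    max_iter=nnet_maxit,
                    random_state=seed,
                )
                net.fit(xt, yt)
                p = net.predict_proba(obs_s.reshape(1, -1))[0]
        except Exception:
            dropped += 1
            continue
        by_class = dict(zip(net.classes_, p))
        probs.append(np.array([by_class.get(m, 0.0) for m in models]))
    if dropped > 0.2 * nnet_count:
        warnings.warn(f"{dropped}/{nnet_count} ensemble members dropped")
    if not probs:
        raise RuntimeError("every neural-network ensemble member failed")
    pp = np.mean(probs, axis=0)
    pp = np.clip(pp, 0.0, 1.0)
    pp = pp / pp.sum()
    return ModelPosterior(models, pp, "neuralnet", tolerance, n_keep)


def bayes_factors(pp: np.ndarray) -> np.ndarray:
    """BF[i, j] = PP_i / PP_j under equal model priors; +inf where PP_j = 0
    and PP_i > 0, 1 on the diagonal and for 0/0."""
    pp = np.asarray(pp, dtype=float)
    k = len(pp)
    bf = np.empty((k, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        bf = pp[:, None] / pp[None, :]
    bf[np.isnan(bf)] = 1.0  # 0/0
    np.fill_diagonal(bf, 1.0)
    return bf


# ---------------------------------------------------------------------------
# Parameter posteriors
# ---------------------------------------------------------------------------


def hpd(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval of consecutive order statistics holding >= level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("hpd needs at least 2 draws")
    m = int(math.ceil(level * n))
    m = min(max(m, 2), n)
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def estimate_parameters(
    ref: ReferenceTable,
    obs: SummaryStatisticVector | np.ndarray,
    tolerance: float,
    params: list[str] | None = None,
) -> dict[str, PosteriorSummary]:
    """Rejection-posterior summaries (mean, 95% CI of the mean, 95% HPD) for
    each parameter of a single-model reference table."""
    if len(ref) == 0:
        raise ValueError("empty reference table")
    if len(ref.models()) > 1:
        raise ValueError("restrict the table to a single model first")
    acc, _ = rejection_sample(ref, obs, tolerance)
    if len(acc) < 30:
        warnings.warn(f"only {len(acc)} accepted draws: unstable summaries")
    params = params or ref.param_names
    out: dict[str, PosteriorSummary] = {}
    for p in params:
        draws = ref.df[p].to_numpy(dtype=float)[acc]
        mean = float(draws.mean())
        if len(draws) > 1 and draws.std(ddof=1) > 0:
            se = float(draws.std(ddof=1) / math.sqrt(len(draws)))
            ci = (mean - 1.96 * se, mean + 1.96 * se)
            hp = hpd(draws, 0.95)
        else:
            ci = (mean, mean)
            hp = (mean, mean)
        out[p] = PosteriorSummary(
            parameter=p, draws=draws, mean=mean, ci95=ci, hpd95=hp, tolerance=tolerance
        )
    return out


def posterior_report(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    rows = []
    for p, s in summaries.items():
        rows.append(
            {
                "parameter": p,
                "mean": s.mean,
                "ci95_low": s.ci95[0],
                "ci95_high": s.ci95[1],
                "hpd95_low": s.hpd95[0],
                "hpd95_high": s.hpd95[1],
                "n_accepted": len(s.draws),
                "tolerance": s.tolerance,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    ref: ReferenceTable,
    rng: np.random.Generator,
    n_cv: int = 1000,
    tolerances: tuple[float, ...] = (0.005, 0.01, 0.05),
    params: list[str] | None = None,
) -> CVResult:
    """Leave-one-out prediction error of the rejection estimator.

    For each of ``n_cv`` randomly held-out rows, its statistics play the
    observation against all remaining rows; the point estimate is the
    posterior mean.  Epred_p = sum((est - true)^2) / (n_cv * Var(true)).
    """
    n = len(ref)
    if n < 10 * n_cv:
        raise ValueError(f"reference table ({n} rows) smaller than 10 x n_cv")
    params = params or [p for p in ref.param_names if ref.df[p].nunique() > 1]
    stats = ref.stats_matrix()
    scale = _mad(stats)
    keep = scale > 0
    stats_s = stats[:, keep] / scale[keep]
    theta = ref.df[params].to_numpy(dtype=float)
    held = rng.choice(n, size=n_cv, replace=False)
    est = {tol: np.empty((n_cv, len(params))) for tol in tolerances}
    mask = np.ones(n, dtype=bool)
    for r, i in enumerate(held):
        mask[i] = False
        d = _distances(stats_s[mask], stats_s[i])
        order = np.argsort(d, kind="stable")
        rest_theta = theta[mask]
        for tol in tolerances:
            m = int(math.floor(tol * (n - 1)))
            if m == 0:
                raise ValueError(f"tolerance {tol} accepts zero rows")
            assert i not in np.flatnonzero(mask)[order[:m]]
            est[tol][r] = rest_theta[order[:m]].mean(axis=0)
        mask[i] = True
    truth = theta[held]
    var = truth.var(axis=0, ddof=0)
    rows = {}
    for tol in tolerances:
        rows[tol] = ((est[tol] - truth) ** 2).sum(axis=0) / (n_cv * var)
    df = pd.DataFrame(rows, index=params)
    df.columns.name = "tolerance"
    return CVResult(epred=df, n_cv=n_cv)
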