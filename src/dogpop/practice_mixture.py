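"""Distribution of dogs registered per veterinary practice.

A K-component univariate normal mixture is fitted to per-practice
registered-dog counts by maximum likelihood (EM), checked with a
Kolmogorov-Smirnov test whose p-value comes from a parametric bootstrap
(refitting each replicate), and turned into a veterinary-subpopulation size
distribution by scaling mean practice size by the effective number of
practices.  A Pearson chi-square test probes response bias of the practice
survey against the sampling frame.

The mixture EM is written here rather than delegated because the pipeline
needs its per-iteration log-likelihood trace, quantile-partition restarts
and a standard-deviation floor with restart-on-collapse; an off-the-shelf
fit is used only as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureParams",
    "MixtureFit",
    "Chi2Result",
    "KSResult",
    "fit_mixture_em",
    "ks_gof",
    "response_bias_test",
    "vet_subpop_sampler",
]


@dataclass
class MixtureParams:
    """Weights, means and standard deviations of a 1-D normal mixture,
    components ordered by ascending mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        order = np.argsort(self.means)
        self.weights = self.weights[order]
        self.means = self.means[order]
        self.sds = self.sds[order]

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def validate(self) -> None:
        if not (
            len(self.weights) == len(self.means) == len(self.sds) >= 1
        ):
            raise ValueError("weights, means, sds must have equal length >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise ValueError("weights must be nonnegative and sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("component sds must be positive")

    def mean(self) -> float:
        return float(self.weights @ self.means)

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        dens = stats.norm.pdf(x[:, None], self.means, self.sds)
        return dens @ self.weights

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return stats.norm.cdf(x[:, None], self.means, self.sds) @ self.weights

    def ppf(self, q: float, lo: float | None = None, hi: float | None = None) -> float:
        """Quantile by bisection on the mixture CDF."""
        lo = float(self.means.min() - 10 * self.sds.max()) if lo is None else lo
        hi = float(self.means.max() + 10 * self.sds.max()) if hi is None else hi
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if self.cdf(mid)[0] < q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])

    def loglik(self, x: np.ndarray) -> float:
        return float(np.log(np.maximum(self.pdf(x), 1e-300)).sum())


@dataclass
class MixtureFit:
    params: MixtureParams
    loglik: float
    trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    restart: int = 0


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float


@dataclass
class KSResult:
    d: float
    p_value: float | None
    n_boot: int = 0


def _em_single(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[MixtureParams, list[float]] | None:
    """One EM run; None signals component collapse (caller restarts)."""
    n = len(x)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # E step: responsibilities via log densities for stability
        logdens = stats.norm.logpdf(x[:, None], means, sds) + np.log(weights)
        m = logdens.max(axis=1, keepdims=True)
        dens = np.exp(logdens - m)
        total = dens.sum(axis=1, keepdims=True)
        ll = float((np.log(total) + m).sum())
        trace.append(ll)
        resp = dens / total
        # M step
        nk = resp.sum(axis=0)
        if (nk < 1e-10).any():
            return None
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if (sds < sd_floor).any():
            return None
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return MixtureParams(weights, means, sds), trace


def _partition_init(x_sorted: np.ndarray, cuts: np.ndarray) -> tuple:
    """Initial (weights, means, sds) from a partition of the sorted data."""
    groups = np.split(x_sorted, cuts)
    weights = np.asarray([len(g) for g in groups], dtype=float)
    weights /= weights.sum()
    means = np.asarray([g.mean() for g in groups])
    sds = np.asarray([max(g.std(), 1e-12) for g in groups])
    return weights, means, sds


def fit_mixture_em(
    sizes,
    k: int = 3,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> MixtureFit:
    """Maximum-likelihood normal mixture via EM with restarts.

    Restart 0 partitions the sorted data into K equal quantile blocks; later
    restarts use random cut points.  Components whose standard deviation
    falls below 1e-3 times the data SD are treated as collapsed and the
    restart is abandoned.  The best-log-likelihood fit is returned, with its
    (non-decreasing) per-iteration log-likelihood trace.
    """
    x = np.sort(np.asarray(sizes, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(np.unique(x)) < k:
        raise ValueError(f"k={k} exceeds the number of distinct values")
    if len(x) < 2 * k:
        raise ValueError("need at least 2*k observations")
    data_sd = float(x.std())
    sd_floor = max(1e-3 * data_sd, 1e-12)
    rng = np.random.default_rng(seed)
    n = len(x)

    if k == 1:
        # Closed-form MLE; a single EM iteration lands here exactly.
        params = MixtureParams(np.ones(1), np.asarray([x.mean()]), np.asarray([max(x.std(), sd_floor)]))
        return MixtureFit(params, params.loglik(x), [params.loglik(x)], 1, 0)

    best: MixtureFit | None = None
    attempt = 0
    restart = 0
    while restart < n_restarts and attempt < 4 * n_restarts:
        attempt += 1
        if restart == 0:
            cuts = np.asarray([round(n * j / k) for j in range(1, k)])
        else:
            cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
        init = _partition_init(x, cuts)
        result = _em_single(x, *init, tol=tol, max_iter=max_iter, sd_floor=sd_floor)
        if result is None:
            logger.debug("EM restart %d collapsed; retrying", restart)
            if restart == 0:
                restart += 1  # do not loop forever on the deterministic init
            continue
        params, trace = result
        fit = MixtureFit(params, trace[-1], trace, len(trace), restart)
        if best is None or fit.loglik > best.loglik:
            best = fit
        restart += 1
    if best is None:
        raise RuntimeError("every EM restart collapsed; is the data degenerate?")
    best.params.validate()
    return best


def ks_statistic(sizes, mixture: MixtureParams) -> float:
    """sup |ECDF - mixture CDF| over the sample points."""
    x = np.sort(np.asarray(sizes, dtype=float))
    n = len(x)
    cdf = mixture.cdf(x)
    upper = np.abs(np.arange(1, n + 1) / n - cdf)
    lower = np.abs(cdf - np.arange(0, n) / n)
    return float(np.maximum(upper, lower).max())


def ks_gof(
    sizes,
    mixture: MixtureParams,
    n_boot: int = 500,
    seed: int | None = None,
    refit_restarts: int = 3,
) -> KSResult:
    """KS goodness of fit with a parametric-bootstrap p-value.

    Because the mixture was fitted to the same data, the classical KS null
    distribution does not apply; each bootstrap replicate is drawn from the
    fitted mixture and *refitted* before computing its statistic.
    """
    mixture.validate()
    d = ks_statistic(sizes, mixture)
    if n_boot <= 0:
        return KSResult(d, None, 0)
    if n_boot < 100:
        logger.warning("n_boot=%d is small; the KS p-value will be coarse", n_boot)
    rng = np.random.default_rng(seed)
    n = len(sizes)
    k = mixture.n_components
    exceed = 0
    done = 0
    for _ in range(n_boot):
        sample = mixture.rvs(n, rng)
        try:
            refit = fit_mixture_em(
                sample, k=k, n_restarts=refit_restarts,
                seed=int(rng.integers(2**31)),
            )
        except (ValueError, RuntimeError):
            continue
        done += 1
        if ks_statistic(sample, refit.params) >= d:
            exceed += 1
    p = (1 + exceed) / (1 + done) if done else None
    return KSResult(d, p, done)


def response_bias_test(frame_counts, respondent_counts) -> Chi2Result:
    """Pearson chi-square for response bias across frame strata.

    Contingency table: respondents vs non-respondents by level, so
    df = levels - 1.  Expected cell counts below 5 trigger a warning.
    """
    levels = list(frame_counts)
    if set(levels) != set(respondent_counts):
        raise ValueError("frame and respondent tables must share the same levels")
    frame = np.asarray([frame_counts[lv] for lv in levels], dtype=float)
    resp = np.asarray([respondent_counts[lv] for lv in levels], dtype=float)
    if frame.sum() <= 0:
        raise ValueError("frame total must be positive")
    if (resp > frame).any():
        raise ValueError("respondents cannot exceed the frame in any level")
    table = np.vstack([resp, frame - resp])
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning("chi-square expected counts below 5; p-value approximate")
    return Chi2Result(float(chi2), int(df), float(p))


def vet_subpop_sampler(
    sizes=None,
    mixture: MixtureParams | None = None,
    n_responses: int = constants.N_PRACTICE_RESPONSES,
    n_effective_practices: float = constants.EFFECTIVE_PRACTICES,
    n_draws: int = 3600,
    seed: int | None = None,
):
    """Monte-Carlo distribution of the veterinary-subpopulation size.

    Each draw is the mean of a size-``n_responses`` resample of practice
    sizes (parametric from the mixture when given, otherwise nonparametric
    from the observed sizes) multiplied by the effective number of
    practices: the sampling distribution of the *mean* practice size scaled
    to the national practice count.
    """
    from .registry_survival import SubpopulationEstimate

    if n_effective_practices <= 0:
        raise ValueError("n_effective_practices must be positive")
    if mixture is None and (sizes is None or len(sizes) == 0):
        raise ValueError("need observed sizes or a fitted mixture")
    rng = np.random.default_rng(seed)
    if mixture is not None:
        mixture.validate()
        draws = mixture.rvs((n_draws, n_responses), rng).mean(axis=1)
    else:
        x = np.asarray(sizes, dtype=float)
        draws = x[rng.integers(0, len(x), size=(n_draws, n_responses))].mean(axis=1)
    draws = draws * n_effective_practices
    return SubpopulationEstimate.from_draws("vet", draws)
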