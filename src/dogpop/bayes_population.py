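"""Bayesian combination of survey proportions and subpopulation sizes.

Two models drive the population estimates:

* **Membership-proportion model.**  Whether a surveyed dog belongs to a
  subpopulation (vet-registered, insured, kennel-club registered) is
  Bernoulli(p) with a single logit-scale intercept, ``logit(p) = alpha``.
  The posterior of alpha is sampled by adaptive random-walk Metropolis.  In
  ``dog`` mode the likelihood uses the pooled dog-level counts (this case
  has an analytic check: a flat prior on alpha induces a Beta(y, n-y)
  posterior on p).  In the default ``area`` mode the set of survey areas is
  resampled with replacement once per thinning block (a cluster bootstrap
  inside the chain), so the retained samples mix posterior uncertainty with
  between-area heterogeneity — matching the survey's clustered design.

* **Multiplier estimates.**  Total population draws are a subpopulation
  size divided by a membership-proportion draw, N_i = S_i / p_i.  The
  survey-only estimate instead scales a normal intercept-only model of
  per-area dogs-per-household rates by the national household count, with
  an informative normal prior applied on the population scale.

Summaries are posterior medians with equal-tailed 95% credibility
intervals; convergence is checked with the Gelman-Rubin statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from . import constants
from .synthetic_data import SurveyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "McmcSettings",
    "PriorSpec",
    "ProportionPosterior",
    "PopulationEstimate",
    "proportion_posterior",
    "beta_oracle",
    "population_from_subpop",
    "population_from_household_rate",
    "gelman_rubin",
    "credibility_interval",
]


@dataclass
class McmcSettings:
    n_iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 50
    n_chains: int = 2
    seed: int | None = None
    proposal_sd: float = 0.1  # adaptive start

    def validate(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PriorSpec:
    """``flat`` or ``normal(mean, sd)``; used on the alpha scale for the
    proportion model and on the population scale for the household-rate
    model."""

    kind: str = "normal"
    mean: float = 0.0
    sd: float = 10.0

    def validate(self) -> None:
        if self.kind not in ("flat", "normal"):
            raise ValueError("prior kind must be 'flat' or 'normal'")
        if self.kind == "normal" and self.sd <= 0:
            raise ValueError("normal prior needs sd > 0")


@dataclass
class ProportionPosterior:
    subpopulation: str
    alpha_chains: np.ndarray  # (n_chains, n_retained)
    mode: str
    settings: McmcSettings
    acceptance: float = float("nan")

    @property
    def alpha(self) -> np.ndarray:
        return self.alpha_chains.reshape(-1)

    @property
    def p(self) -> np.ndarray:
        return expit(self.alpha)

    @property
    def p_chains(self) -> np.ndarray:
        return expit(self.alpha_chains)

    def median(self) -> float:
        return float(np.median(self.p))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        return credibility_interval(self.p, level)

    def rhat(self) -> float:
        return gelman_rubin(self.alpha_chains)


@dataclass
class PopulationEstimate:
    combination: str
    median: float
    ci_low: float
    ci_high: float
    draws: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_draws(cls, combination: str, draws) -> "PopulationEstimate":
        draws = np.asarray(draws, dtype=float)
        if draws.size == 1:  # degenerate inputs give a degenerate interval
            value = float(draws[0])
            return cls(combination, value, value, value, draws)
        lo, hi = credibility_interval(draws)
        return cls(combination, float(np.median(draws)), lo, hi, draws)


def _cluster_counts(
    dataset: SurveyDataset, subpopulation: str, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster (dogs, flagged dogs) for the requested sampling unit."""
    if mode == "area":
        by_area = dataset.dogs_by_area()
        groups = [by_area[a] for a in dataset.areas]
    elif mode == "household":
        households: dict[str, list] = {}
        for dog in dataset.dogs:
            households.setdefault(dog.household_id, []).append(dog)
        groups = list(households.values())
    elif mode == "dog":
        groups = [[d] for d in dataset.dogs]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    n = np.asarray([len(g) for g in groups], dtype=float)
    y = np.asarray(
        [sum(d.flag(subpopulation) for d in g) for g in groups], dtype=float
    )
    return y, n


def _run_metropolis_chain(
    y_blocks: np.ndarray,
    n_blocks: np.ndarray,
    settings: McmcSettings,
    prior: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One adaptive RW-Metropolis chain on alpha.

    ``y_blocks`` / ``n_blocks`` give the (possibly resampled) pooled counts
    in force during each thinning block; a sample is retained at the end of
    every post-burn-in block.  Proposal-sd adaptation (toward 30%
    acceptance) runs during burn-in only.
    """
    n_iter, burn, thin = settings.n_iterations, settings.burn_in, settings.thin
    flat_prior = prior.kind == "flat"
    pm, psd = prior.mean, prior.sd

    def logpost(a: float, yt: float, nt: float) -> float:
        ll = yt * a - nt * math.log1p(math.exp(a)) if a < 500 else yt * a - nt * a
        if not flat_prior:
            ll -= 0.5 * ((a - pm) / psd) ** 2
        return ll

    eps = rng.standard_normal(n_iter)
    logu = np.log(rng.random(n_iter))
    sd = settings.proposal_sd
    y0, n0 = float(y_blocks[0]), float(n_blocks[0])
    p0 = min(max(y0 / n0 if n0 else 0.5, 1e-3), 1 - 1e-3)
    alpha = math.log(p0 / (1 - p0))
    lp = logpost(alpha, y0, n0)
    kept = np.empty(settings.n_retained_per_chain)
    k = 0
    accepted = 0
    accepted_window = 0
    for i in range(n_iter):
        if i % thin == 0:
            block = i // thin
            yt, nt = float(y_blocks[block]), float(n_blocks[block])
            lp = logpost(alpha, yt, nt)
        prop = alpha + sd * eps[i]
        lp_prop = logpost(prop, yt, nt)
        if lp_prop - lp > logu[i]:
            alpha, lp = prop, lp_prop
            accepted += 1
            accepted_window += 1
        if i < burn and (i + 1) % 100 == 0:
            rate = accepted_window / 100
            sd = min(max(sd * math.exp(rate - 0.3), 1e-4), 25.0)
            accepted_window = 0
        if i >= burn and (i - burn) % thin == thin - 1:
            if k < kept.size:
                kept[k] = alpha
                k += 1
    return kept, accepted / n_iter


def proportion_posterior(
    dataset: SurveyDataset,
    subpopulation: str,
    mode: str = "area",
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> ProportionPosterior:
    """Posterior of the membership probability p for one subpopulation."""
    prior = prior or PriorSpec("normal", 0.0, 10.0)
    settings = settings or McmcSettings()
    prior.validate()
    settings.validate()
    y, n = _cluster_counts(dataset, subpopulation, mode)
    if n.sum() < 1:
        raise ValueError("need at least one dog with a defined flag")
    total_y, total_n = y.sum(), n.sum()
    if total_y in (0.0, total_n):
        logger.warning(
            "%s flags are all %s: posterior rests on the prior tail",
            subpopulation,
            "set" if total_y else "unset",
        )
    seed_seq = np.random.SeedSequence(settings.seed)
    chain_seqs = seed_seq.spawn(settings.n_chains)
    n_blocks = settings.n_iterations // settings.thin + 1
    chains = []
    acc = []
    for seq in chain_seqs:
        rng = np.random.default_rng(seq)
        if mode == "dog":
            yb = np.full(n_blocks, total_y)
            nb = np.full(n_blocks, total_n)
        else:
            idx = rng.integers(0, len(n), size=(n_blocks, len(n)))
            yb = y[idx].sum(axis=1)
            nb = n[idx].sum(axis=1)
            empty = nb == 0
            yb[empty], nb[empty] = total_y, total_n  # degenerate resample guard
        kept, rate = _run_metropolis_chain(yb, nb, settings, prior, rng)
        chains.append(kept)
        acc.append(rate)
    return ProportionPosterior(
        subpopulation, np.vstack(chains), mode, settings, float(np.mean(acc))
    )


def beta_oracle(y: int, n: int, q) -> float | np.ndarray:
    """Quantile of Beta(y, n-y): the p-posterior a flat prior on alpha
    induces from y successes in n dog-level Bernoulli trials."""
    if not 0 < y < n:
        raise ValueError("beta_oracle needs 0 < y < n")
    out = stats.beta(y, n - y).ppf(q)
    return float(out) if np.isscalar(q) else out


def population_from_subpop(
    subpop,
    proportion: ProportionPosterior | np.ndarray,
    combination: str | None = None,
) -> PopulationEstimate:
    """Multiplier estimate: population draws N_i = S_i / p_i.

    ``subpop`` may be a scalar, an array of draws, or a
    ``SubpopulationEstimate`` with draws.  Sample sets are recycled to a
    common length; non-positive proportion draws are excluded (logged).
    """
    p = proportion.p if isinstance(proportion, ProportionPosterior) else np.asarray(proportion, dtype=float)
    if hasattr(subpop, "draws"):
        s = subpop.draws if subpop.draws is not None else np.asarray([subpop.median])
        combination = combination or subpop.source
    else:
        s = np.atleast_1d(np.asarray(subpop, dtype=float))
    m = max(len(s), len(p))
    s = np.resize(s, m)
    p = np.resize(p, m)
    ok = p > 0
    if not ok.all():
        logger.warning("excluded %d draws with non-positive proportion", (~ok).sum())
    if not ok.any():
        raise ValueError("all proportion draws are non-positive")
    tag = combination if combination is not None else (
        proportion.subpopulation if isinstance(proportion, ProportionPosterior) else "subpop"
    )
    return PopulationEstimate.from_draws(tag, s[ok] / p[ok])


def population_from_household_rate(
    area_rates,
    n_households: float = constants.N_HOUSEHOLDS,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> PopulationEstimate:
    """Survey-only estimate from per-area dogs-per-household rates.

    Normal intercept-only model r_a ~ N(mu, sigma^2) with unknown variance,
    Gibbs-sampled (Jeffreys prior on sigma^2); each retained mu draw is
    scaled by the national household count.  The informative prior (by
    default the earlier national estimate, mean 10.5M, sd 459k) constrains
    the *population* mu * n_households, i.e. it induces a normal prior on mu
    with mean and sd divided by n_households.
    """
    prior = prior or PriorSpec(
        "normal", constants.MURRAY_PRIOR_MEAN, constants.MURRAY_PRIOR_SD
    )
    settings = settings or McmcSettings()
    prior.validate()
    settings.validate()
    if n_households <= 0:
        raise ValueError("n_households must be positive")
    r = np.asarray(area_rates, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 area rates")
    n = len(r)
    rbar = float(r.mean())
    if r.var() == 0.0 and prior.kind == "flat":
        # No between-area variance and no prior: the intercept is the common
        # rate exactly.
        draws = np.full(settings.n_chains * settings.n_retained_per_chain, rbar * n_households)
        return PopulationEstimate.from_draws("survey", draws)
    if prior.kind == "normal":
        m0 = prior.mean / n_households
        tau0_prec = (n_households / prior.sd) ** 2
    else:
        m0, tau0_prec = 0.0, 0.0

    seed_seq = np.random.SeedSequence(settings.seed)
    chains = []
    for seq in seed_seq.spawn(settings.n_chains):
        rng = np.random.default_rng(seq)
        kept = np.empty(settings.n_retained_per_chain)
        k = 0
        mu = rbar
        for i in range(settings.n_iterations):
            ss = float(((r - mu) ** 2).sum())
            sigma2 = max(ss, 1e-300) / rng.chisquare(n)
            prec = n / sigma2 + tau0_prec
            mean = (rbar * n / sigma2 + m0 * tau0_prec) / prec
            mu = rng.normal(mean, 1.0 / math.sqrt(prec))
            if i >= settings.burn_in and (i - settings.burn_in) % settings.thin == settings.thin - 1:
                if k < kept.size:
                    kept[k] = mu
                    k += 1
        chains.append(kept)
    draws = np.concatenate(chains) * n_households
    est = PopulationEstimate.from_draws("survey", draws)
    est.chains = np.vstack(chains) * n_households
    return est


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor over equal-length chains.

    R-hat = sqrt(var_plus / W) with var_plus = (n-1)/n W + B/n.  With zero
    between-chain variance the textbook formula returns sqrt((n-1)/n) < 1;
    that degenerate case (identical chains) is reported as exactly 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("chains too short")
    means = chains.mean(axis=1)
    b = n * means.var(ddof=1)
    w = chains.var(axis=1, ddof=1).mean()
    if b == 0.0:
        return 1.0
    if w == 0.0:
        return float("inf")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def credibility_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed interval by linear-interpolation quantiles."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return float(lo), float(hi)
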