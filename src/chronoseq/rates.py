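"""Among-site rate heterogeneity and molecular-clock models.

Site rates follow the discrete-gamma mixture (equal-probability
categories whose rates are the within-bin means of a Gamma(alpha, alpha)
distribution — Yang's mean method) optionally combined with a
proportion of invariant sites.  The mixture always has mean rate 1, so
the clock alone sets the time scale.

Branch rates (clocks) are either strict (one rate for every branch) or
uncorrelated relaxed clocks with i.i.d. per-branch multipliers from a
lognormal or inverse-Gaussian distribution, both parameterized by their
real-space mean M and standard deviation proxy S so that the expected
multiplier is M regardless of dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.stats

from .trees import Phylogeny

__all__ = [
    "SiteRateModel",
    "BranchRateModel",
    "discrete_gamma_rates",
    "sample_site_rates",
    "sample_branch_rates",
]


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete-gamma + invariant-sites mixture.

    ``alpha`` is the gamma shape (None disables gamma variation),
    ``n_categories`` the number of equal-probability gamma bins, and
    ``p_inv`` the proportion of invariant (rate-0) sites.
    """

    alpha: Optional[float] = None
    n_categories: int = 1
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")

    def categories(self) -> Tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the full mixture, invariant class
        included; mean rate is 1."""
        return discrete_gamma_rates(
            self.alpha, self.n_categories if self.alpha is not None else 1, self.p_inv
        )


@dataclass(frozen=True)
class BranchRateModel:
    """Clock model mapping time units to substitution units.

    strict: every branch gets ``rate`` (default 1, i.e. branch lengths
    already in substitution units).  lognormal / inverse_gaussian:
    i.i.d. multipliers with real-space mean ``mean`` and spread
    ``stdev``; ``stdev = 0`` degenerates to a strict clock at ``mean``.
    """

    kind: str = "strict"
    rate: float = 1.0
    mean: float = 1.0
    stdev: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "lognormal", "inverse_gaussian"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.kind == "strict" and not self.rate > 0:
            raise ValueError("clock rate must be > 0")
        if self.kind != "strict" and not self.mean > 0:
            raise ValueError("clock mean must be > 0")
        if self.stdev < 0:
            raise ValueError("clock stdev must be >= 0")


def discrete_gamma_rates(
    alpha: Optional[float], k: int, p_inv: float = 0.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Category rates and probabilities of the discrete-gamma(+p_inv) mixture.

    The k gamma categories have equal probability (1 - p_inv)/k; each
    rate is the mean of Gamma(alpha, rate=alpha) within its quantile bin,
    divided by (1 - p_inv) so the whole mixture (with the invariant
    category at rate 0) has mean exactly 1.  Returns rates in increasing
    category order, invariant category (if any) first.
    """
    if k < 1:
        raise ValueError("need at least one category")
    if not (0.0 <= p_inv < 1.0):
        raise ValueError("p_inv must lie in [0, 1)")
    if alpha is None or k == 1:
        gamma_rates = np.array([1.0])
        k = 1
    else:
        if not alpha > 0:
            raise ValueError("alpha must be > 0")
        dist = scipy.stats.gamma(a=alpha, scale=1.0 / alpha)
        # mean within quantile bin [q_i, q_{i+1}]: k * (F_{a+1}(x_{i+1}) - F_{a+1}(x_i))
        # using the identity  integral x f_a(x) dx = mean * F_{a+1}(x)
        edges = dist.ppf(np.arange(1, k) / k)
        upper = scipy.stats.gamma(a=alpha + 1, scale=1.0 / alpha)
        cdf_vals = np.concatenate([[0.0], upper.cdf(edges), [1.0]])
        gamma_rates = k * np.diff(cdf_vals)
        gamma_rates /= float(np.mean(gamma_rates))  # exact mean-1 cleanup
    gamma_rates = gamma_rates / (1.0 - p_inv)
    probs = np.full(k, (1.0 - p_inv) / k)
    if p_inv > 0.0:
        return (
            np.concatenate([[0.0], gamma_rates]),
            np.concatenate([[p_inv], probs]),
        )
    return gamma_rates, probs


def sample_site_rates(
    model: SiteRateModel, n_sites: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site (rate, category index) realizations of the mixture.

    Each site is independently invariant (rate 0) with probability
    p_inv, else assigned a uniformly chosen gamma category.
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    rates, probs = model.categories()
    idx = rng.choice(len(rates), size=n_sites, p=probs)
    return rates[idx], idx


def sample_branch_rates(
    tree: Phylogeny, clock: BranchRateModel, rng: np.random.Generator
) -> Dict[int, float]:
    """Per-branch rate multipliers keyed by ``id(child_node)``.

    Strict clocks assign ``rate`` everywhere; relaxed clocks draw one
    i.i.d. multiplier per branch.  Branches are visited in pre-order, so
    a fixed seed gives a reproducible assignment.
    """
    branches = [n for n in tree.preorder() if n.parent is not None]
    if clock.kind == "strict":
        draws = np.full(len(branches), clock.rate)
    elif clock.stdev == 0.0:
        draws = np.full(len(branches), clock.mean)
    elif clock.kind == "lognormal":
        # log-rate ~ Normal(log M - S^2/2, S)  =>  E[rate] = M
        mu = np.log(clock.mean) - 0.5 * clock.stdev**2
        draws = rng.lognormal(mean=mu, sigma=clock.stdev, size=len(branches))
    else:  # inverse_gaussian: mean M, shape lambda = M^3 / S^2
        lam = clock.mean**3 / clock.stdev**2
        draws = rng.wald(clock.mean, lam, size=len(branches))
    return {id(b): float(r) for b, r in zip(branches, draws)}
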