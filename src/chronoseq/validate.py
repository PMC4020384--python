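"""Exact site-pattern probabilities and goodness-of-fit validation.

The simulator is a Monte Carlo sampler; the pruning recursion here
computes, for small trees, the exact probability of every site pattern
(the tuple of tip states in one alignment column) under the same model.
Comparing exact probabilities with long-run simulated pattern
frequencies by a Pearson chi-square test validates the sampler end to
end; the same routines double as the oracle for the test suite.

Also provides the mean pairwise amino-acid p-distance used to summarize
sequence saturation.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.stats

from .engine import GAP, Alignment
from .epochs import EpochModel
from .rates import BranchRateModel, SiteRateModel
from .substitution import (
    RateMatrix,
    StateSpace,
    SubstitutionSpec,
    build_rate_matrix,
    stationary_distribution,
    transition_probabilities,
)
from .trees import Phylogeny

__all__ = [
    "enumerate_site_patterns",
    "pattern_probability",
    "pattern_probabilities",
    "chisq_goodness_of_fit",
    "mean_pairwise_aa_distance",
]

#: refuse to enumerate more than this many patterns
DEFAULT_PATTERN_CAP = 10**6


def enumerate_site_patterns(
    n_tips: int, space: StateSpace, cap: int = DEFAULT_PATTERN_CAP
) -> List[Tuple[str, ...]]:
    """All ``size**n_tips`` tip-state tuples, lexicographic in state order."""
    total = space.size**n_tips
    if total > cap:
        raise ValueError(
            f"{total} patterns exceed the cap of {cap}; sample patterns instead"
        )
    return list(itertools.product(space.states, repeat=n_tips))


def _clock_rate(clock: Optional[BranchRateModel]) -> float:
    if clock is None:
        return 1.0
    if clock.kind == "strict":
        return clock.rate
    if clock.stdev == 0.0:
        return clock.mean
    raise ValueError(
        "exact pattern probabilities require a deterministic clock "
        "(strict, or relaxed with stdev 0)"
    )


def pattern_probabilities(
    tree: Phylogeny,
    subst: Union[SubstitutionSpec, RateMatrix, EpochModel],
    site_model: Optional[SiteRateModel] = None,
    clock: Optional[BranchRateModel] = None,
    patterns: Optional[Sequence[Tuple[str, ...]]] = None,
) -> Dict[Tuple[str, ...], float]:
    """Exact probabilities of site patterns by the pruning recursion.

    Tip partial likelihoods are state indicators; internal partials
    combine the children through the branch transition matrices; the
    root partial is dotted with the root (equilibrium) frequencies.
    Rate mixtures are averaged over categories — the invariant category
    contributes only to constant patterns.  Patterns follow the tree's
    taxon order.
    """
    site_model = site_model or SiteRateModel()
    rate0 = _clock_rate(clock)
    if isinstance(subst, (RateMatrix, EpochModel)):
        model = subst
    else:
        model = build_rate_matrix(subst)
    space = model.space
    if isinstance(model, EpochModel):
        root_freqs = model.oldest_stationary_distribution()
    else:
        root_freqs = (
            model.frequencies if model.reversible else stationary_distribution(model)
        )

    tips = tree.tips
    if patterns is None:
        patterns = enumerate_site_patterns(len(tips), space)
    for pat in patterns:
        if len(pat) != len(tips):
            raise ValueError(
                f"pattern length {len(pat)} does not match {len(tips)} tips"
            )
    n_pat = len(patterns)
    state_idx = {s: i for i, s in enumerate(space.states)}

    cat_rates, cat_probs = site_model.categories()
    total = np.zeros(n_pat)
    for rate_c, prob_c in zip(cat_rates, cat_probs):
        partials: Dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip:
                tip_pos = tips.index(node)
                L = np.zeros((n_pat, space.size))
                for p, pat in enumerate(patterns):
                    L[p, state_idx[pat[tip_pos]]] = 1.0
            else:
                L = np.ones((n_pat, space.size))
                for child in node.children:
                    rate = rate0 * rate_c
                    if isinstance(model, EpochModel):
                        P = model.branch_transition_matrix(
                            node.height, child.height, rate
                        )
                    else:
                        P = transition_probabilities(model, child.length * rate)
                    L *= partials[id(child)] @ P.T
                for child in node.children:
                    partials.pop(id(child), None)
            partials[id(node)] = L
        total += prob_c * (partials[id(tree.root)] @ root_freqs)
    return {pat: float(p) for pat, p in zip(patterns, np.clip(total, 0.0, 1.0))}


def pattern_probability(
    tree: Phylogeny,
    subst: Union[SubstitutionSpec, RateMatrix, EpochModel],
    site_model: Optional[SiteRateModel],
    clock: Optional[BranchRateModel],
    pattern: Sequence[str],
) -> float:
    """Probability of a single site pattern (see `pattern_probabilities`)."""
    return pattern_probabilities(
        tree, subst, site_model, clock, patterns=[tuple(pattern)]
    )[tuple(pattern)]


def chisq_goodness_of_fit(
    observed: Sequence[float],
    expected_probs: Sequence[float],
    min_expected: float = 5.0,
) -> Tuple[float, int, float]:
    """Pearson chi-square test of observed counts against probabilities.

    Categories with expected count below ``min_expected`` are pooled
    into a single class (classical guidance).  Returns (statistic,
    degrees of freedom, upper-tail p-value).
    """
    obs = np.asarray(observed, dtype=float)
    probs = np.asarray(expected_probs, dtype=float)
    if obs.shape != probs.shape:
        raise ValueError("observed and expected must have matching shapes")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts sum to zero")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"expected probabilities sum to {probs.sum()}, not 1")
    exp = probs * n
    big = exp >= min_expected
    o_classes = list(obs[big])
    e_classes = list(exp[big])
    if np.any(~big):
        o_classes.append(obs[~big].sum())
        e_classes.append(exp[~big].sum())
    if len(o_classes) < 2:
        raise ValueError("fewer than 2 classes after pooling")
    o = np.array(o_classes)
    e = np.array(e_classes)
    stat = float(((o - e) ** 2 / e).sum())
    df = len(o) - 1
    p = float(scipy.stats.chi2.sf(stat, df))
    return stat, df, p


def mean_pairwise_aa_distance(
    alignment: Union[Alignment, Sequence[str]],
) -> float:
    """Mean pairwise p-distance over all unordered row pairs.

    Columns with a gap in either row are excluded from that pair's
    comparison; pairs with no comparable columns are dropped.  Returns a
    proportion in [0, 1].
    """
    if isinstance(alignment, Alignment):
        rows = [alignment.rows[name] for name in alignment.taxa]
    else:
        rows = list(alignment)
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences must have equal lengths")
    mats = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    gap = GAP.encode()
    dists = []
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            ok = (mats[i] != gap) & (mats[j] != gap)
            n_ok = int(ok.sum())
            if n_ok == 0:
                continue
            dists.append(float((mats[i][ok] != mats[j][ok]).sum()) / n_ok)
    if not dists:
        raise ValueError("no pair has comparable columns")
    return float(np.mean(dists))
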