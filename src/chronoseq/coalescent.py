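"""Coalescent simulation of genealogies for (possibly heterochronous) taxa.

The demographic models are the standard constant-size and exponential
growth coalescents.  Time is measured in tree units (heights), and the
population-size parameter ``theta`` is the product of effective
population size and generation time on that same scale, so no separate
generation-time parameter exists.  Under exponential growth the
population size looking back in time is ``N(h) = theta * exp(-g * h)``
at height ``h``; ``g = 0`` reduces to the constant model.

Heterochronous sampling follows the standard algorithm: lineages become
active at their sampling heights; candidate coalescence times proposed
before the next sampling event are discarded and the waiting process is
restarted once the new lineage is activated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Node, Phylogeny, TaxonSet

__all__ = ["DemographicModel", "draw_coalescent_time", "simulate_genealogy"]


@dataclass(frozen=True)
class DemographicModel:
    """Coalescent population-size history.

    Parameters
    ----------
    kind:
        ``"constant"`` or ``"exponential"``.
    theta:
        Population-size parameter (N_e x tau) in tree time units; > 0.
        For the exponential model this is the size at height 0.
    growth_rate:
        Growth rate g per time unit (exponential model only).  Positive g
        means the population grew towards the present, i.e. shrinks
        looking back in time.  g may be negative; the resulting coalescent
        can then be improper (some pairs never coalesce), which
        `draw_coalescent_time` reports as an infinite waiting time.
    """

    kind: str = "constant"
    theta: float = 1.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential"):
            raise ValueError(f"unknown demographic model kind {self.kind!r}")
        if not self.theta > 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not math.isfinite(self.growth_rate):
            raise ValueError("growth_rate must be finite")


def draw_coalescent_time(
    k: int,
    start_height: float,
    demo: DemographicModel,
    rng: np.random.Generator,
) -> float:
    """Draw the height of the next coalescence among ``k`` active lineages.

    The waiting time W from ``start_height`` satisfies
    ``P(W > w) = exp(-Integral_0^w k(k-1) / (2 N(start_height + s)) ds)``.
    Constant model: W ~ Exponential with rate k(k-1)/(2 theta).
    Exponential model: closed-form inversion of the integrated intensity;
    returns ``inf`` when the total integrated intensity is bounded below
    the exponential deviate (possible only for negative growth rates).
    """
    if k < 2:
        raise ValueError(f"need at least 2 active lineages, got {k}")
    pair_rate = k * (k - 1) / 2.0
    e = rng.exponential(1.0)
    g = demo.growth_rate
    if demo.kind == "constant" or g == 0.0:
        return start_height + e * demo.theta / pair_rate
    # integrated intensity over w: pair_rate/theta * e^{g h} (e^{g w} - 1)/g
    arg = 1.0 + g * e * demo.theta * math.exp(-g * start_height) / pair_rate
    if arg <= 0.0:
        return math.inf
    return start_height + math.log(arg) / g


def simulate_genealogy(
    taxa: TaxonSet,
    demo: DemographicModel,
    rng: np.random.Generator,
) -> Phylogeny:
    """Simulate a binary rooted genealogy for ``taxa`` under ``demo``.

    Tips sit at their taxon heights.  Moving rootwards, lineages activate
    at their sampling heights; each coalescence merges two uniformly
    chosen active lineages.  A proposed coalescence older than the next
    sampling height is discarded: the new lineage is activated and the
    waiting process restarts from that height (the memoryless property
    does not hold across the activation for the exponential model, and
    restarting is exact in both cases).
    """
    if len(taxa) < 2:
        raise ValueError(f"need at least 2 taxa, got {len(taxa)}")

    pending = sorted(
        (Node(taxon=t, height=float(t.height)) for t in taxa),
        key=lambda n: n.height,
    )
    active: list[Node] = []
    height = 0.0

    while len(active) + len(pending) > 1:
        # activate everything sampled at or below the current height
        while pending and pending[0].height <= height:
            active.append(pending.pop(0))
        if len(active) < 2:
            height = pending[0].height
            continue
        proposal = draw_coalescent_time(len(active), height, demo, rng)
        if pending and proposal > pending[0].height:
            height = pending[0].height  # activation interrupts the wait
            continue
        if math.isinf(proposal):
            raise RuntimeError(
                "improper coalescent: lineages fail to coalesce under "
                f"growth rate {demo.growth_rate}"
            )
        height = proposal
        i, j = rng.choice(len(active), size=2, replace=False)
        left, right = active[i], active[j]
        parent = Node(children=[left, right], height=height)
        left.parent = right.parent = parent
        left.length = height - left.height
        right.length = height - right.height
        active = [n for idx, n in enumerate(active) if idx not in (i, j)]
        active.append(parent)

    tree = Phylogeny(active[0], time_calibrated=True)
    tree.validate()
    return tree
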