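"""Time-heterogeneous (epoch) substitution processes.

An epoch model partitions the evolutionary history into height
intervals, each owning its own substitution specification over one
shared state space: spec 0 applies on [0, h1), spec i on [h_i, h_{i+1})
and the last spec beyond the oldest boundary.  A branch crossing
boundaries evolves under the piecewise process; its transition matrix is
the product of the per-segment matrix exponentials, ordered
chronologically (oldest segment leftmost), so ``P[i, j]`` is the
probability that a parent in state i yields a child in state j.

Normalization across epochs ("each", the default): every epoch's
generator is normalized to mean rate 1 at its own equilibrium, so the
clock rate sets the total substitution rate in every epoch and the
epoch parameters redistribute that rate among substitution types (for
a codon model with omega shrinking back in time, non-synonymous change
freezes while synonymous change continues and saturates).  This is the
convention of Bayesian phylogenetic inference engines, where each
component substitution model is normalized independently.  The
alternative "first" normalizes only the youngest epoch's generator and
divides every older epoch by that same constant, so the *total* rate
also declines back in time.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .substitution import (
    RateMatrix,
    StateSpace,
    SubstitutionSpec,
    _raw_generator,
    default_state_space,
    stationary_distribution,
    transition_probabilities,
)

__all__ = ["EpochModel", "branch_transition_matrix"]


class EpochModel:
    """Ordered height intervals, each with its own substitution spec.

    Parameters
    ----------
    boundaries:
        Strictly increasing positive heights h1 < ... < hm.
    specs:
        m + 1 substitution specifications over one shared state space;
        specs[0] is the youngest (heights in [0, h1)).
    normalize:
        "each" (default) — every epoch normalized to mean rate 1
        separately — or "first" — one scale anchored to the youngest
        epoch, older epochs keeping their relative raw rates.
    """

    def __init__(
        self,
        boundaries: Sequence[float],
        specs: Sequence[SubstitutionSpec],
        space: Optional[StateSpace] = None,
        normalize: str = "each",
    ):
        boundaries = [float(b) for b in boundaries]
        if any(b <= 0 for b in boundaries):
            raise ValueError("epoch boundaries must be > 0")
        if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
            raise ValueError("epoch boundaries must be strictly increasing")
        if len(specs) != len(boundaries) + 1:
            raise ValueError(
                f"{len(boundaries)} boundaries require {len(boundaries) + 1} "
                f"specs, got {len(specs)}"
            )
        if normalize not in ("first", "each"):
            raise ValueError("normalize must be 'first' or 'each'")
        self.boundaries = boundaries
        self.specs = list(specs)
        self.space = space or default_state_space(specs[0])
        self.normalize = normalize
        self._matrices = self._build()

    def _build(self) -> List[RateMatrix]:
        raw = [_raw_generator(spec, self.space) for spec in self.specs]
        matrices: List[RateMatrix] = []
        beta0 = None
        for Q, pi in raw:
            Q = Q.copy()
            np.fill_diagonal(Q, 0.0)
            diag = -Q.sum(axis=1)
            beta = float(-(pi * diag).sum())
            if beta <= 0:
                raise ValueError("degenerate epoch generator: zero substitution rate")
            if beta0 is None:
                beta0 = beta  # youngest epoch anchors the scale
            divisor = beta if self.normalize == "each" else beta0
            Qn = Q / divisor
            np.fill_diagonal(Qn, diag / divisor)
            flux = pi[:, None] * Qn
            reversible = bool(np.allclose(flux, flux.T, atol=1e-10))
            matrices.append(RateMatrix(self.space, Qn, pi, divisor, reversible))
        return matrices

    @property
    def matrices(self) -> List[RateMatrix]:
        """Per-epoch generators, youngest first, on the shared scale."""
        return self._matrices

    @property
    def n_epochs(self) -> int:
        return len(self.specs)

    def epoch_index(self, height: float) -> int:
        """The epoch containing ``height`` (boundaries belong to the older side)."""
        if height < 0:
            raise ValueError("height must be >= 0")
        i = 0
        for b in self.boundaries:
            if height >= b:
                i += 1
            else:
                break
        return i

    def segments(
        self, parent_height: float, child_height: float
    ) -> List[Tuple[int, float]]:
        """Split [child_height, parent_height] at boundaries.

        Returns (epoch index, duration) pairs ordered chronologically,
        i.e. oldest segment first.
        """
        if child_height < 0 or parent_height < 0:
            raise ValueError("heights must be >= 0")
        if parent_height < child_height:
            raise ValueError("parent height must be >= child height")
        cuts = [child_height]
        cuts += [b for b in self.boundaries if child_height < b < parent_height]
        cuts.append(parent_height)
        out = []
        for lo, hi in zip(cuts, cuts[1:]):
            if hi > lo:
                out.append((self.epoch_index(0.5 * (lo + hi)), hi - lo))
        out.reverse()  # oldest first
        if not out:  # zero-length branch
            out.append((self.epoch_index(child_height), 0.0))
        return out

    def branch_transition_matrix(
        self,
        parent_height: float,
        child_height: float,
        rate_multiplier: float = 1.0,
    ) -> np.ndarray:
        """Transition matrix of a branch under the piecewise process.

        Each segment contributes ``expm(Q_epoch * rate * duration)``;
        factors multiply in chronological order (oldest leftmost).
        """
        if rate_multiplier < 0:
            raise ValueError("rate multiplier must be >= 0")
        P = np.eye(self.space.size)
        for epoch_idx, duration in self.segments(parent_height, child_height):
            P = P @ transition_probabilities(
                self._matrices[epoch_idx], rate_multiplier * duration
            )
        return P

    def oldest_stationary_distribution(self) -> np.ndarray:
        """Equilibrium of the oldest epoch's process (root sequences are
        drawn from it, since the root pre-dates every boundary)."""
        return stationary_distribution(self._matrices[-1])


def branch_transition_matrix(
    epochs: EpochModel,
    parent_height: float,
    child_height: float,
    branch_rate_multiplier: float = 1.0,
) -> np.ndarray:
    """Functional alias for :meth:`EpochModel.branch_transition_matrix`."""
    return epochs.branch_transition_matrix(
        parent_height, child_height, branch_rate_multiplier
    )
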