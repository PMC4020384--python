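"""Pre-order Monte Carlo simulation of sequences along phylogenies.

The simulator visits nodes parent-before-child.  The root sequence is
drawn site-wise from the substitution model's equilibrium frequencies
(or supplied explicitly); each child's state at site s is then sampled
from the row of the branch transition matrix indexed by the parent's
state, with branch distance

    clock_multiplier(branch) * site_rate(s) * (parent_height - child_height).

Site-rate categories share transition matrices, so each branch costs one
matrix exponential per category rather than one per site.  Epoch
(time-heterogeneous) branches use the chronologically ordered product of
per-segment exponentials and require a time-calibrated tree.

Multiple partitions are simulated independently (per-partition seeds are
spawned from the global seed, so adding partitions never perturbs
earlier ones) and concatenated; taxa missing from a partition are padded
with gaps across that partition's columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .epochs import EpochModel
from .rates import BranchRateModel, SiteRateModel, sample_branch_rates, sample_site_rates
from .substitution import (
    RateMatrix,
    SubstitutionSpec,
    build_rate_matrix,
    stationary_distribution,
    transition_probabilities,
)
from .trees import Node, Phylogeny

__all__ = ["Partition", "Alignment", "sample_root_sequence", "simulate_partition", "simulate"]

GAP = "-"


@dataclass
class Partition:
    """One simulation unit: sites x tree x models.

    ``n_sites`` counts model states (codon partitions count codon
    columns).  ``root_sequence`` optionally fixes the root states
    (a list of state labels, e.g. codons for codon partitions).
    ``emit_amino_acids`` makes a codon partition output translated
    amino acids instead of nucleotide triplets.
    """

    n_sites: int
    tree: Phylogeny
    subst: Union[SubstitutionSpec, EpochModel]
    site_model: SiteRateModel = field(default_factory=SiteRateModel)
    clock: BranchRateModel = field(default_factory=BranchRateModel)
    root_sequence: Optional[Sequence[str]] = None
    emit_amino_acids: bool = False
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("a partition needs at least one site")

    @property
    def taxa(self):
        return self.tree.taxa


@dataclass
class Alignment:
    """Concatenated simulation output.

    ``taxa`` is the ordered union over partitions; ``rows`` maps taxon
    name to its full-width character string (gap-padded where a taxon is
    absent from a partition); ``partition_ranges`` gives each
    partition's [start, end) column range in characters.
    """

    taxa: List[str]
    rows: Dict[str, str]
    partition_ranges: List[Tuple[int, int]]
    datatype: str = "dna"

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        width = self.n_columns
        for name in self.taxa:
            if len(self.rows[name]) != width:
                raise ValueError(f"ragged alignment row {name!r}")


def _resolve_model(subst: Union[SubstitutionSpec, EpochModel]):
    if isinstance(subst, EpochModel):
        return subst
    return build_rate_matrix(subst)


def _equilibrium(model: Union[RateMatrix, EpochModel]) -> np.ndarray:
    if isinstance(model, EpochModel):
        return model.oldest_stationary_distribution()
    if model.reversible:
        return model.frequencies
    return stationary_distribution(model)


def sample_root_sequence(
    subst: Union[SubstitutionSpec, RateMatrix, EpochModel],
    n_sites: int,
    rng: np.random.Generator,
    root_sequence: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Root state indices: i.i.d. equilibrium draws, or the supplied
    explicit sequence verbatim.

    Epoch models draw from the *oldest* epoch's stationary distribution
    (the root pre-dates all epoch boundaries).
    """
    if isinstance(subst, (RateMatrix, EpochModel)):
        model = subst
        space = model.space
    else:
        try:
            model = build_rate_matrix(subst)
        except ValueError:
            # degenerate frequency vectors (e.g. a point mass) break the
            # generator normalization but still define a root distribution
            from .substitution import _raw_generator, default_state_space

            space = default_state_space(subst)
            _, pi = _raw_generator(subst, space)
            if root_sequence is None:
                return rng.choice(space.size, size=n_sites, p=pi / pi.sum())
            model = None  # explicit-sequence path below needs only the space
        else:
            space = model.space
    if root_sequence is not None:
        if len(root_sequence) != n_sites:
            raise ValueError(
                f"explicit root sequence has {len(root_sequence)} states, expected {n_sites}"
            )
        try:
            return np.array([space.index(s) for s in root_sequence], dtype=np.int64)
        except ValueError as exc:
            raise ValueError(f"root sequence state not in alphabet: {exc}") from exc
    pi = _equilibrium(model)
    return rng.choice(space.size, size=n_sites, p=pi / pi.sum())


def _sample_children(
    P: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized categorical draw of child states given parent states."""
    rows = P[parent_states]
    rows = rows / rows.sum(axis=1, keepdims=True)
    u = rng.random((len(parent_states), 1))
    return (rows.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)


def simulate_partition(
    p: Partition, rng: np.random.Generator
) -> Dict[Node, np.ndarray]:
    """Simulate one partition; returns state-index vectors for every node.

    Deterministic under a fixed generator state.  Transition matrices
    are cached per (branch geometry, site category).
    """
    tree = p.tree
    if tree.root.height is None:
        raise ValueError("tree heights not computed")
    model = _resolve_model(p.subst)
    if isinstance(model, EpochModel) and not tree.time_calibrated:
        raise ValueError(
            "epoch models require a time-calibrated tree; this tree is in "
            "substitution units"
        )

    site_rates, site_cat = sample_site_rates(p.site_model, p.n_sites, rng)
    cat_rates, _ = p.site_model.categories()
    branch_mult = sample_branch_rates(tree, p.clock, rng)

    states: Dict[Node, np.ndarray] = {}
    states[tree.root] = sample_root_sequence(model, p.n_sites, rng, p.root_sequence)

    cache: Dict[Tuple, np.ndarray] = {}
    sites_by_cat = {c: np.flatnonzero(site_cat == c) for c in np.unique(site_cat)}

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[node.parent]
        child = np.empty(p.n_sites, dtype=np.int64)
        mult = branch_mult[id(node)]
        for c, sites in sites_by_cat.items():
            rate = mult * cat_rates[c]
            if rate == 0.0 or node.length == 0.0:
                child[sites] = parent_states[sites]
                continue
            if isinstance(model, EpochModel):
                key = (node.parent.height, node.height, rate)
                if key not in cache:
                    cache[key] = model.branch_transition_matrix(
                        node.parent.height, node.height, rate
                    )
            else:
                key = (node.length * rate,)
                if key not in cache:
                    cache[key] = transition_probabilities(model, node.length * rate)
            child[sites] = _sample_children(cache[key], parent_states[sites], rng)
        states[node] = child
    return states


def _emit(p: Partition, states: np.ndarray) -> str:
    model = _resolve_model(p.subst)
    space = model.space
    labels = [space.states[s] for s in states]
    if space.kind == "codon" and p.emit_amino_acids:
        return "".join(space.amino_acids[s] for s in states)
    return "".join(labels)


def _partition_datatype(p: Partition) -> str:
    model = _resolve_model(p.subst)
    kind = model.space.kind
    if kind == "nucleotide" or (kind == "codon" and not p.emit_amino_acids):
        return "dna"
    if kind == "amino_acid" or (kind == "codon" and p.emit_amino_acids):
        return "protein"
    return "standard"


def _internal_labels(tree: Phylogeny) -> Dict[Node, str]:
    labels: Dict[Node, str] = {}
    for i, node in enumerate(tree.preorder()):
        if not node.is_tip:
            labels[node] = f"node{i}"
    return labels


def simulate(
    partitions: Sequence[Partition],
    global_seed: int,
    keep_ancestral: bool = False,
) -> Union[Alignment, Tuple[Alignment, Alignment]]:
    """Simulate all partitions and concatenate into one `Alignment`.

    Partitions are independent: seeds are spawned per partition from
    ``global_seed``, so earlier partitions are unaffected by later ones.
    With ``keep_ancestral`` a second alignment of internal-node
    sequences (labelled by pre-order index) is returned as well.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    seeds = np.random.SeedSequence(global_seed).spawn(len(partitions))

    taxa_order: List[str] = []
    seen = set()
    for p in partitions:
        for name in p.taxa.names:
            if name not in seen:
                seen.add(name)
                taxa_order.append(name)

    tip_chunks: List[Dict[str, str]] = []
    anc_chunks: List[Dict[str, str]] = []
    widths: List[int] = []
    for p, seed in zip(partitions, seeds):
        rng = np.random.default_rng(seed)
        states = simulate_partition(p, rng)
        chunk: Dict[str, str] = {}
        for tip in p.tree.tips:
            chunk[tip.taxon.name] = _emit(p, states[tip])
        width = len(next(iter(chunk.values())))
        if any(len(s) != width for s in chunk.values()):
            raise AssertionError("unequal partition row widths")
        widths.append(width)
        tip_chunks.append(chunk)
        if keep_ancestral:
            labels = _internal_labels(p.tree)
            anc_chunks.append(
                {lab: _emit(p, states[node]) for node, lab in labels.items()}
            )

    ranges: List[Tuple[int, int]] = []
    offset = 0
    for w in widths:
        ranges.append((offset, offset + w))
        offset += w

    rows = {
        name: "".join(
            chunk.get(name, GAP * w) for chunk, w in zip(tip_chunks, widths)
        )
        for name in taxa_order
    }
    datatypes = {_partition_datatype(p) for p in partitions}
    datatype = datatypes.pop() if len(datatypes) == 1 else "standard"
    aln = Alignment(taxa_order, rows, ranges, datatype)
    aln.validate()
    if not keep_ancestral:
        return aln

    anc_order: List[str] = []
    anc_seen = set()
    for chunk in anc_chunks:
        for lab in chunk:
            if lab not in anc_seen:
                anc_seen.add(lab)
                anc_order.append(lab)
    anc_rows = {
        lab: "".join(chunk.get(lab, GAP * w) for chunk, w in zip(anc_chunks, widths))
        for lab in anc_order
    }
    anc = Alignment(anc_order, anc_rows, ranges, datatype)
    anc.validate()
    return aln, anc
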