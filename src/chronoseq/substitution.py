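"""Normalized CTMC rate matrices and finite-time transition probabilities.

A substitution process is a continuous-time Markov chain on a discrete
state space (4 nucleotides, 20 amino acids, 61 sense codons, or an
arbitrary trait alphabet) with generator Q.  Generators built here are
normalized so that ``-sum_i pi_i Q_ii = 1`` with pi the build
frequencies, which makes evolutionary *distance* mean expected
substitutions per site.

Supported parameterizations:

* nucleotides — HKY (transition/transversion bias kappa), TN93 (separate
  purine and pyrimidine transition factors), GTR (six exchangeabilities);
* codons — GY94 (omega = dN/dS, kappa; single-nucleotide moves only) and
  MG94 (separate synonymous/non-synonymous rates alpha, beta targeting
  nucleotide frequencies);
* amino acids — empirical exchangeability models (Dayhoff, JTT,
  BLOSUM62, WAG, LG) loaded from plain-text data files;
* general — an arbitrary, possibly sparse and non-reversible,
  off-diagonal rate table (e.g. discrete phylogeographic traits).

Finite-time probabilities ``P(d) = expm(Q d)`` use a symmetrized
eigen-decomposition when the chain is reversible (real spectrum,
numerically robust) and scipy's scaling-and-squaring otherwise.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg
from Bio.Data import CodonTable
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StateSpace",
    "nucleotide_space",
    "amino_acid_space",
    "codon_space",
    "general_space",
    "HKY",
    "TN93",
    "GTR",
    "GY94",
    "MG94",
    "EmpiricalAA",
    "General",
    "RateMatrix",
    "build_rate_matrix",
    "transition_probabilities",
    "stationary_distribution",
    "f1x4_frequencies",
    "f3x4_frequencies",
    "EMPIRICAL_AA_MODELS",
]

NUCLEOTIDES = ("A", "C", "G", "T")
AMINO_ACIDS = tuple("ARNDCQEGHILKMFPSTWYV")
_PURINES = {"A", "G"}

EMPIRICAL_AA_MODELS = ("Dayhoff", "JTT", "BLOSUM62", "WAG", "LG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


# ---------------------------------------------------------------------------
# state spaces


@dataclass(frozen=True)
class StateSpace:
    """An ordered discrete alphabet for a CTMC.

    For codon spaces each state is a nucleotide triplet and carries its
    encoded amino acid; stop codons of the chosen genetic code are
    excluded.
    """

    kind: str
    states: Tuple[str, ...]
    amino_acids: Optional[Tuple[str, ...]] = None  # codon spaces only
    code_table: Optional[int] = None

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("state labels must be unique")
        if len(self.states) < 2:
            raise ValueError("state space needs at least 2 states")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)


def nucleotide_space() -> StateSpace:
    return StateSpace("nucleotide", NUCLEOTIDES)


def amino_acid_space() -> StateSpace:
    return StateSpace("amino_acid", AMINO_ACIDS)


def codon_space(code_table: int = 1) -> StateSpace:
    """Sense codons of an NCBI genetic code, lexicographic in A<C<G<T.

    The universal code (table 1) yields 61 codons.
    """
    table = CodonTable.unambiguous_dna_by_id[code_table]
    stops = set(table.stop_codons)
    codons, aas = [], []
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            for c in NUCLEOTIDES:
                codon = a + b + c
                if codon in stops:
                    continue
                codons.append(codon)
                aas.append(table.forward_table[codon])
    return StateSpace("codon", tuple(codons), tuple(aas), code_table)


def general_space(labels: Sequence[str]) -> StateSpace:
    return StateSpace("general", tuple(labels))


# ---------------------------------------------------------------------------
# substitution specifications


def _check_freqs(freqs: np.ndarray, size: int) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (size,):
        raise ValueError(f"frequency vector has length {freqs.shape}, expected {size}")
    if np.any(freqs < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1, got {freqs.sum()}")
    return freqs


@dataclass(frozen=True)
class HKY:
    """Hasegawa-Kishino-Yano nucleotide model: q_ij proportional to
    kappa*pi_j for transitions and pi_j for transversions."""

    kappa: float = 1.0
    frequencies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")


@dataclass(frozen=True)
class TN93:
    """Tamura-Nei model with separate purine (kappa1: A<->G) and
    pyrimidine (kappa2: C<->T) transition factors."""

    kappa1: float = 1.0
    kappa2: float = 1.0
    frequencies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if not (self.kappa1 > 0 and self.kappa2 > 0):
            raise ValueError("kappa1, kappa2 must be > 0")


@dataclass(frozen=True)
class GTR:
    """General time-reversible model: q_ij proportional to r_ij pi_j with
    exchangeabilities ordered (AC, AG, AT, CG, CT, GT)."""

    rates: Tuple[float, float, float, float, float, float] = (1.0,) * 6
    frequencies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or any(r < 0 for r in self.rates):
            raise ValueError("GTR needs six non-negative exchangeabilities")


@dataclass(frozen=True)
class GY94:
    """Goldman-Yang codon model parameterized by omega (dN/dS) and kappa.

    Codons differing at more than one position never interchange
    directly; single-position moves get pi_j times 1 / kappa / omega /
    omega*kappa for synonymous-transversion / synonymous-transition /
    non-synonymous-transversion / non-synonymous-transition.
    """

    omega: float = 1.0
    kappa: float = 1.0
    frequencies: Optional[Sequence[float]] = None
    code_table: int = 1

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")


@dataclass(frozen=True)
class MG94:
    """Muse-Gaut codon model: single-position moves at the frequency of
    the incoming nucleotide, times alpha (synonymous) or beta
    (non-synonymous), optionally times kappa for transitions."""

    alpha: float = 1.0
    beta: float = 1.0
    kappa: Optional[float] = None
    nucleotide_frequencies: Optional[Sequence[float]] = None
    code_table: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha, beta must be >= 0")
        if self.kappa is not None and not self.kappa > 0:
            raise ValueError("kappa must be > 0 when supplied")


@dataclass(frozen=True)
class EmpiricalAA:
    """Published empirical amino-acid replacement model
    (Dayhoff, JTT, BLOSUM62, WAG or LG); q_ij proportional to s_ij pi_j
    with the model's frequencies unless overridden."""

    name: str = "LG"
    frequencies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.name not in EMPIRICAL_AA_MODELS:
            raise ValueError(
                f"unknown empirical model {self.name!r}; choose from {EMPIRICAL_AA_MODELS}"
            )


@dataclass(frozen=True)
class General:
    """Arbitrary off-diagonal rate table over a general state space;
    may be sparse and non-reversible."""

    rates: Sequence[Sequence[float]] = field(default=())
    frequencies: Optional[Sequence[float]] = None
    labels: Optional[Sequence[str]] = None


SubstitutionSpec = Union[HKY, TN93, GTR, GY94, MG94, EmpiricalAA, General]


def default_state_space(spec: SubstitutionSpec) -> StateSpace:
    """The natural state space of a specification."""
    if isinstance(spec, (HKY, TN93, GTR)):
        return nucleotide_space()
    if isinstance(spec, (GY94, MG94)):
        return codon_space(spec.code_table)
    if isinstance(spec, EmpiricalAA):
        return amino_acid_space()
    if isinstance(spec, General):
        if spec.labels is not None:
            return general_space(spec.labels)
        n = len(spec.rates)
        return general_space([f"S{i}" for i in range(n)])
    raise TypeError(f"not a substitution spec: {spec!r}")


# ---------------------------------------------------------------------------
# codon frequency helpers


def f1x4_frequencies(
    nucleotide_freqs: Sequence[float], space: Optional[StateSpace] = None
) -> np.ndarray:
    """Codon frequencies as the product of one nucleotide composition,
    renormalized over the sense codons."""
    space = space or codon_space()
    pi_nt = _check_freqs(np.asarray(nucleotide_freqs, float), 4)
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    freqs = np.array(
        [pi_nt[idx[c[0]]] * pi_nt[idx[c[1]]] * pi_nt[idx[c[2]]] for c in space.states]
    )
    return freqs / freqs.sum()


def f3x4_frequencies(
    position_freqs: Sequence[Sequence[float]], space: Optional[StateSpace] = None
) -> np.ndarray:
    """Codon frequencies from three position-specific nucleotide
    compositions, renormalized over the sense codons."""
    space = space or codon_space()
    pis = [_check_freqs(np.asarray(p, float), 4) for p in position_freqs]
    if len(pis) != 3:
        raise ValueError("need three position-specific frequency vectors")
    idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    freqs = np.array(
        [pis[0][idx[c[0]]] * pis[1][idx[c[1]]] * pis[2][idx[c[2]]] for c in space.states]
    )
    return freqs / freqs.sum()


# ---------------------------------------------------------------------------
# empirical amino-acid data files

_empirical_cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}


def load_empirical_aa(name: str) -> Tuple[np.ndarray, np.ndarray]:
    """Load (exchangeability matrix S, frequencies) for an empirical model.

    Files are whitespace-delimited lower-triangle exchangeabilities
    followed by a frequency line (PAML dat-file dialect), in the standard
    order A R N D C Q E G H I L K M F P S T W Y V.
    """
    if name in _empirical_cache:
        return _empirical_cache[name]
    fname = name.lower() + ".dat"
    text = (
        importlib.resources.files("chronoseq.data").joinpath(fname).read_text()
    )
    rows: List[List[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    tri, freq_line = rows[:-1], rows[-1]
    if len(tri) != 19 or any(len(r) != i + 1 for i, r in enumerate(tri)):
        raise ValueError(f"malformed exchangeability triangle in {fname}")
    S = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        S[i, : len(row)] = row
    S = S + S.T
    freqs = _check_freqs(np.array(freq_line) / np.sum(freq_line), 20)
    _empirical_cache[name] = (S, freqs)
    return S, freqs


# ---------------------------------------------------------------------------
# rate-matrix construction


@dataclass(frozen=True)
class RateMatrix:
    """A normalized CTMC generator with its build frequencies.

    ``matrix`` has non-negative off-diagonals, zero row sums, and is
    scaled so ``-sum_i freqs_i matrix_ii = 1``.  ``normalization`` is the
    divisor applied to reach that scale (the raw generator's mean rate),
    kept so that epoch models can undo per-matrix scaling and share one
    reference scale instead.
    """

    space: StateSpace
    matrix: np.ndarray
    frequencies: np.ndarray
    normalization: float
    reversible: bool

    @property
    def size(self) -> int:
        return self.space.size


def _raw_generator(
    spec: SubstitutionSpec, space: StateSpace
) -> Tuple[np.ndarray, np.ndarray]:
    """Unnormalized generator and build frequencies for a spec."""
    n = space.size

    if isinstance(spec, (HKY, TN93, GTR)):
        if space.kind != "nucleotide":
            raise ValueError(f"{type(spec).__name__} requires a nucleotide space")
        pi = (
            _check_freqs(np.asarray(spec.frequencies, float), 4)
            if spec.frequencies is not None
            else np.full(4, 0.25)
        )
        Q = np.zeros((4, 4))
        if isinstance(spec, GTR):
            r = {("A", "C"): spec.rates[0], ("A", "G"): spec.rates[1],
                 ("A", "T"): spec.rates[2], ("C", "G"): spec.rates[3],
                 ("C", "T"): spec.rates[4], ("G", "T"): spec.rates[5]}
            for i, a in enumerate(NUCLEOTIDES):
                for j, b in enumerate(NUCLEOTIDES):
                    if i != j:
                        Q[i, j] = r[tuple(sorted((a, b)))] * pi[j]
        else:
            if isinstance(spec, HKY):
                k_pur = k_pyr = spec.kappa
            else:
                k_pur, k_pyr = spec.kappa1, spec.kappa2
            for i, a in enumerate(NUCLEOTIDES):
                for j, b in enumerate(NUCLEOTIDES):
                    if i == j:
                        continue
                    if _is_transition(a, b):
                        Q[i, j] = (k_pur if a in _PURINES else k_pyr) * pi[j]
                    else:
                        Q[i, j] = pi[j]
        return Q, pi

    if isinstance(spec, GY94):
        if space.kind != "codon":
            raise ValueError("GY94 requires a codon space")
        pi = (
            _check_freqs(np.asarray(spec.frequencies, float), n)
            if spec.frequencies is not None
            else np.full(n, 1.0 / n)
        )
        Q = np.zeros((n, n))
        for i, j, pos, transition in _single_nt_moves(space):
            syn = space.amino_acids[i] == space.amino_acids[j]
            mult = (spec.kappa if transition else 1.0) * (1.0 if syn else spec.omega)
            Q[i, j] = mult * pi[j]
        return Q, pi

    if isinstance(spec, MG94):
        if space.kind != "codon":
            raise ValueError("MG94 requires a codon space")
        pi_nt = (
            _check_freqs(np.asarray(spec.nucleotide_frequencies, float), 4)
            if spec.nucleotide_frequencies is not None
            else np.full(4, 0.25)
        )
        nt_idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
        Q = np.zeros((n, n))
        for i, j, pos, transition in _single_nt_moves(space):
            syn = space.amino_acids[i] == space.amino_acids[j]
            rate = spec.alpha if syn else spec.beta
            if spec.kappa is not None and transition:
                rate *= spec.kappa
            Q[i, j] = rate * pi_nt[nt_idx[space.states[j][pos]]]
        # MG94 is reversible w.r.t. the product (F1x4) codon composition
        pi = f1x4_frequencies(pi_nt, space)
        return Q, pi

    if isinstance(spec, EmpiricalAA):
        if space.kind != "amino_acid":
            raise ValueError("empirical amino-acid models require the amino-acid space")
        S, model_freqs = load_empirical_aa(spec.name)
        pi = (
            _check_freqs(np.asarray(spec.frequencies, float), 20)
            if spec.frequencies is not None
            else model_freqs
        )
        Q = S * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        return Q, pi

    if isinstance(spec, General):
        R = np.asarray(spec.rates, dtype=float)
        if R.shape != (n, n):
            raise ValueError(f"rate table shape {R.shape} does not match space size {n}")
        if np.any(R[~np.eye(n, dtype=bool)] < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        Q = R.copy()
        np.fill_diagonal(Q, 0.0)
        if np.any(Q.sum(axis=1) == 0.0):
            dead = [space.states[i] for i in np.flatnonzero(Q.sum(axis=1) == 0.0)]
            raise ValueError(f"all-zero rate row(s) for state(s) {dead}")
        pi = (
            _check_freqs(np.asarray(spec.frequencies, float), n)
            if spec.frequencies is not None
            else np.full(n, 1.0 / n)
        )
        return Q, pi

    raise TypeError(f"not a substitution spec: {spec!r}")


def _single_nt_moves(space: StateSpace):
    """Yield (i, j, position, is_transition) for codon pairs one
    nucleotide apart."""
    states = space.states
    n = len(states)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = [p for p in range(3) if states[i][p] != states[j][p]]
            if len(diff) != 1:
                continue
            pos = diff[0]
            yield i, j, pos, _is_transition(states[i][pos], states[j][pos])


def build_rate_matrix(
    spec: SubstitutionSpec, space: Optional[StateSpace] = None
) -> RateMatrix:
    """Build the normalized generator for ``spec`` on ``space``.

    The generator is scaled so the expected substitution rate at the
    build frequencies is one per unit distance.
    """
    space = space or default_state_space(spec)
    Q, pi = _raw_generator(spec, space)
    np.fill_diagonal(Q, 0.0)
    diag = -Q.sum(axis=1)
    beta = float(-(pi * diag).sum())
    if beta <= 0:
        raise ValueError("degenerate generator: zero total substitution rate")
    Qn = Q / beta
    np.fill_diagonal(Qn, diag / beta)
    flux = pi[:, None] * Qn
    reversible = bool(np.allclose(flux, flux.T, atol=1e-10))
    return RateMatrix(space, Qn, pi, beta, reversible)


# ---------------------------------------------------------------------------
# transition probabilities


def transition_probabilities(Q: RateMatrix, distance: float) -> np.ndarray:
    """Finite-time transition matrix ``P = expm(matrix * distance)``.

    ``distance`` is in expected substitutions per site (the generator is
    normalized).  Reversible generators use the symmetrized
    eigen-decomposition; others fall back to scaling-and-squaring.
    Entries are clipped to [0, 1] after numerical cleanup.
    """
    if not math.isfinite(distance) or distance < 0:
        raise ValueError(f"distance must be finite and >= 0, got {distance}")
    M = np.asarray(Q.matrix, dtype=float)
    if np.any(np.isnan(M)):
        raise ValueError("NaN in generator")
    if distance == 0.0:
        return np.eye(Q.size)
    if Q.reversible and np.all(Q.frequencies > 0):
        P = _expm_reversible(Q, distance)
    else:
        P = scipy.linalg.expm(M * distance)
    np.clip(P, 0.0, 1.0, out=P)
    return P


def _expm_reversible(Q: "RateMatrix", d: float) -> np.ndarray:
    # the eigen-decomposition is distance-independent; memoize it on the
    # (frozen) RateMatrix so repeated branch evaluations pay only the
    # reconstruction cost
    cached = getattr(Q, "_eig", None)
    if cached is None:
        sq = np.sqrt(Q.frequencies)
        S = (sq[:, None] * Q.matrix) / sq[None, :]
        S = 0.5 * (S + S.T)  # enforce exact symmetry
        w, V = np.linalg.eigh(S)
        cached = (sq, w, V)
        object.__setattr__(Q, "_eig", cached)
    sq, w, V = cached
    E = (V * np.exp(w * d)) @ V.T
    return (E / sq[:, None]) * sq[None, :]


def stationary_distribution(Q: RateMatrix) -> np.ndarray:
    """Equilibrium frequencies pi with pi Q = 0, sum(pi) = 1.

    Raises for reducible generators, naming the unreachable states.
    """
    M = Q.matrix
    n = Q.size
    adj = (M > 0) & ~np.eye(n, dtype=bool)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        # states outside the largest strongly connected component
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        stranded = [Q.space.states[i] for i in np.flatnonzero(labels != main)]
        raise ValueError(f"reducible generator; states not mutually reachable: {stranded}")
    A = np.vstack([M.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
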