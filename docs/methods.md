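# Methods

## Time scale and trees

All temporal quantities are *heights*: time before the most recently
sampled tip, which sits at height 0. Taxa carry sampling heights
(`name<TAB>height` tables; all-zero heights mean contemporaneous
sampling), and a tree is either time-calibrated (branch lengths are
durations) or in substitution units (implicit clock rate 1, so lengths
are expected substitutions per site). Node heights and branch lengths
are kept consistent to 1e−9: after parsing, heights are propagated from
root-to-tip path lengths with the youngest tip pinned at 0, or anchored
to user-supplied tip heights, which must agree with the branch lengths
to 1e−6 (we refuse to rescale inconsistent input rather than guess
which source is right). NEWICK stores only branch lengths, so absolute
heights of a heterochronous tree survive a round trip only when
re-anchored from its taxa. Multifurcating input trees are accepted —
the pre-order recursion never requires binarity — but simulated
coalescent genealogies are always binary.

## Coalescent simulation

The genealogy simulator implements the standard heterochronous
coalescent. Lineages activate at their sampling heights; with k active
lineages the waiting time to the next merger has survival function
exp(−∫ k(k−1)/(2N(s)) ds). Constant size: N(s) = θ, so the wait is
exponential with rate k(k−1)/(2θ). Exponential growth: N(s) =
θ·e^(−g·s) looking back, inverted in closed form; negative g can make
the total intensity finite, in which case the draw is +∞ and simulation
reports the improper model. A proposed merger older than the next
sampling event is discarded and the clock restarted at that event —
exact for both models (for the exponential model the process is not
memoryless across the activation, and restarting from the activation
height is the correct conditional draw). θ is N_e×τ directly in tree
time units (years in the shipped study); no separate generation-time
parameter exists. Verified against E[tMRCA] = 2θ(1−1/n), the
exponentiality of per-k interval lengths (KS), and exchangeability of
the first-coalescing pair (χ²).

## Substitution models

Generators are built over fixed state orders (nucleotides A,C,G,T;
amino acids ARNDCQEGHILKMFPSTWYV; sense codons lexicographic with stop
codons of the chosen NCBI genetic code removed — 61 states for the
universal code) and normalized so −∑π_i q_ii = 1 at the build
frequencies. GY94 forbids multi-nucleotide codon moves and multiplies
π_j by κ for transitions and ω for amino-acid-changing moves; MG94 uses
the frequency of the incoming nucleotide with separate synonymous (α)
and non-synonymous (β) rates and an optional κ (off by default — the
plain parameterization has none). MG94's stationary distribution is the
F1x4 product composition restricted to sense codons, which is also what
the builder uses as its frequency vector. Codon equilibrium frequencies
default to uniform 1/61; F1x4/F3x4 helpers are provided. Empirical
amino-acid models (Dayhoff, JTT, BLOSUM62 — the usual phylogenetic
reading of "BLOSUM" — WAG, LG) ship as plain-text lower-triangle
exchangeability files with the published frequencies, overridable.

Finite-time probabilities P(d) = exp(Qd): reversible generators (all of
the above) are exponentiated through the symmetrized eigen-decomposition
D^(1/2) Q D^(−1/2) (real spectrum, numerically robust; the decomposition
is memoized per generator since it is distance-independent). General
trait matrices — possibly sparse and non-reversible — use scipy's
scaling-and-squaring. Entries are clipped to [0,1] after cleanup; rows
sum to 1 within 1e−9. Stationary distributions come from a least-squares
solve of πQ = 0 with a strong-connectivity check that names unreachable
states.

## Site and branch rates

Among-site variation uses the discrete-gamma approximation with k
equal-probability categories whose rates are within-bin means of
Gamma(α, α) (the mean method, matching mainstream Bayesian tooling,
rather than the median method), combined with a proportion p_inv of
invariant sites; gamma rates are divided by (1−p_inv) so the full
mixture has mean exactly 1 and the clock alone carries the time scale.
Clocks: strict (default rate 1), or uncorrelated relaxed with i.i.d.
per-branch multipliers from a lognormal or inverse-Gaussian
distribution. Both relaxed kinds are parameterized by the real-space
mean M (so M multiplies branch lengths interpretably) and a spread S:
lognormal log-rate ~ Normal(log M − S²/2, S); inverse-Gaussian mean M,
shape λ = M³/S². S = 0 degenerates to a strict clock at M.

## Epoch models

An epoch model owns m strictly increasing boundary heights and m+1
substitution specifications on one shared state space; spec 0 governs
[0, h₁) and the last spec everything beyond h_m. A branch is cut at
every boundary it crosses and its transition matrix is the product of
per-segment exponentials ordered chronologically (oldest factor
leftmost), so P[i,j] is the probability a parent in state i leaves a
child in state j; site-rate and clock multipliers scale each segment's
duration. Root sequences are drawn from the *oldest* epoch's stationary
distribution, since the root pre-dates every boundary.

Normalization across epochs was a genuinely open design choice and the
default was revised during validation. With per-epoch normalization
("each", the default) every epoch's generator has mean rate 1, which is
what inference engines that compose independently normalized
substitution models produce; the clock then fixes the *total*
substitution rate everywhere, and parameters such as ω only
redistribute it between substitution types. The alternative ("first")
normalizes the youngest epoch and scales older epochs by the same
constant, so the total rate itself declines back in time. For the
shipped ω schedule the two differ sharply: per-epoch normalization
keeps synonymous change running (and saturating) at depth while
non-synonymous change freezes — amino-acid distance ≈ 0.42 for a tip
pair coalescing 10,000 years ago — whereas shared scaling suppresses
the deep total rate too, giving ≈ 0.19. Only the first behaviour
reproduces the saturation regime the study targets, and it is the
faithful reading of how epoch models are composed in practice; the
"first" convention remains available via `EpochModel(..., normalize="first")`.

## Simulation engine

Pre-order traversal; per-branch, per-site-category transition matrices
are computed once and cached, so cost scales with branches × categories
rather than sites. Child states are drawn vectorized from the parent's
matrix row. Partitions are independent simulation units (own tree,
models, sites); per-partition RNG streams are spawned from the global
seed, so adding a partition never perturbs earlier ones, and one seed
reproduces output byte for byte. Concatenated alignments gap-pad taxa
missing from a partition. Codon partitions emit nucleotide triplets by
default or translated amino acids on request; ancestral sequences can
be emitted as a parallel alignment with pre-order node labels. Site-rate
categories are resampled on every simulation call. Epoch models demand a
time-calibrated tree (boundaries are in time units); combining them with
a substitution-unit tree is an error.

## Validation harness

For trees small enough to enumerate patterns (size^tips ≤ 10⁶), the
pruning recursion computes exact pattern probabilities: indicator tip
partials, children folded through branch transition matrices, root
partial dotted with the equilibrium frequencies, mixture categories
averaged (the invariant category only reaches constant patterns). The
Pearson χ² harness pools cells with expected count below 5 (classical
guidance; the choice matters little at n = 100,000 with 64 patterns)
and the simulator must pass at the 1% level — a stochastic check run at
three fixed seeds with a 2-of-3 policy so a single 1%-tail draw cannot
fail the suite. The 3-taxon fixture ((A:0.3,B:0.3):0.2,C:0.5) with
κ = 4, α = 0.5 and four categories is a fixture choice, not an
externally fixed configuration. The amino-acid summary statistic is the
mean pairwise p-distance: mismatches over compared columns, columns with
a gap in either row excluded, averaged over unordered pairs.

## The deep-time saturation study

The shipped pipeline emulates increasingly strong purifying selection
back in time for a rapidly evolving virus: GY94 with ω stepping through
1.0, 0.2, 0.1, 0.02, 0.01, 0.002, 0.001 at boundaries 10, 50, 100, 500,
1000, 5000 years; strict clock 3×10⁻³ codon substitutions/codon
site/year; 50 taxa sampled evenly over 25 years; constant-size
genealogies swept over θ ∈ {1, 5, 10, 50, 100, 500, 1000} with ~100
replicates distributed across levels. κ = 2 and uniform codon
frequencies are defaults (the scenario fixes neither); 500 codons per
replicate by default, 300 in the acceptance run — the mean distance is
insensitive to length, only its variance is not.

Conditioning on a target tMRCA stretches each genealogy's *internal*
node heights so the root reaches the target while tip sampling heights
stay fixed. Scaling the whole tree instead would multiply the sampling
window (0–25 years becomes 0–190 at a typical stretch factor), pushing
tips past the young, nearly neutral epochs and visibly biasing
amino-acid divergence low; internal-only stretching agrees with genuine
reject-sampling of deep genealogies (checked directly) at a small
fraction of the cost. Only deepening (factor ≥ 1) is allowed.

At a conditioned tMRCA of 10,000 years this pipeline yields a mean
pairwise amino-acid p-distance of ≈ 0.33 (exact value per seed reported
by `scripts/acceptance.py`): root-crossing tip pairs reach ≈ 0.42 and
the average over all pairs — most of which coalesce well below the root
— is lower. A homogeneous ω = 0.5 process at the same depth drives
distances past 0.8 (essentially randomized proteins), while the epoch
schedule preserves clear homology; distance rises monotonically with
realized tMRCA across the θ sweep.

## What the generator does and does not emulate

Synthetic data here have known trees, i.i.d. sites given the rate
mixture, no indels, no recombination within a partition (recombination
can be approximated by giving partitions different trees), no selection
beyond what the codon model's ω encodes, and exact model match between
simulator and oracle. Passing validation therefore demonstrates
correctness of the sampling machinery, not realism of any particular
model for real alignments.

## Numerical choices and limitations

Generator normalization to 1e−10; row sums of transition matrices to
1e−9; height/length duality to 1e−9; frequency vectors must sum to 1
within 1e−9. Degenerate inputs: zero-length branches copy states
(P(0) = I); a frequency point mass is accepted for root sampling but
rejected as a generator (zero total rate); all-zero rows in trait
matrices are an error, as are reducible generators when a stationary
distribution is requested. Known limitations: no indel process, no
autocorrelated or local clocks, no birth–death tree simulation, no
likelihood-based inference; pattern enumeration is capped at 10⁶
combinations, so exact validation of codon models is limited to very
few tips (two 61-state tips are fine; the stochastic engine itself has
no such limit).
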