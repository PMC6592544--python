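# Methods

## The problem

A single RepSeq snapshot of a T-cell repertoire contains on the order of
10^5–10^6 unique CDR3 nucleotide rearrangements. Antigen exposure drives the
expansion of many clonotypes with *similar* CDR3 amino-acid sequences
(convergent recognition of a few immunodominant epitopes), so responding
clonotypes sit in locally crowded regions of sequence space. The difficulty
is that V(D)J recombination itself produces crowded regions: high-generation-
probability sequences have many neighbors for purely statistical reasons.
`alicetcr` separates the two by testing each sequence's observed neighbor
count against a null model derived from a generative recombination model.

## The statistical model

Within a VJ class containing `n` unique nucleotide clonotypes, the number of
neighbors `d(σ)` of an amino-acid CDR3 `σ` — nucleotide clonotypes whose
amino-acid sequence has the same length and Hamming distance ≤ 1 from `σ`,
including nucleotide variants of `σ` itself — is modeled under the null as

    d | σ  ~  Poisson(λ),    λ = n · Q · Σ_{σ' ~ σ} P_gen(σ'),

where `P_gen(σ')` is the probability that recombination produces the
amino-acid sequence `σ'`, and `Q` rescales for thymic selection, which
removes a fraction `1 − 1/Q` of generated sequences. The default
`Q = 9.41` is the published average over VJ combinations. The p-value is the
upper tail `P(d' ≥ d(σ))`; p-values are Benjamini–Hochberg adjusted (pooled
over all tested sequences in all VJ classes by default; per-class scope is
available) and adjusted p < 0.001 marks a hit.

Pipeline filters, applied in this order:

1. Clonotypes with identical (CDR3nt, V, J) are collapsed (germline
   sequencing errors), read counts summed.
2. Only clonotypes with more than 1 read count as neighbors (singletons are
   enriched in sequencing errors). The focal `σ` is tested regardless of its
   own read count; the filter scopes what counts as a *neighbor*.
3. Only sequences with `d(σ) > 2` are tested.
4. Sequences whose Monte-Carlo neighborhood probability is 0 are discarded
   before adjustment: they carry no usable null, and a sequence whose entire
   one-mismatch neighborhood is never generated in 10^6+ draws is more
   likely an artifact than a clone. Discarding before BH makes the
   multiple-testing family exactly the set of testable sequences; the
   alternative reading (discard after adjustment) would only shrink the
   family further and is not provided.

### Length-dependent selection factors

Optionally `Q` is refined per CDR3 length `L` within each VJ class:
`Q_L = Q · R_L / Σ_{L'} R_{L'} P_data(L')` with
`R_L = P_data(L)/P_gen(L)`, comparing the data's length distribution with
that of the model's simulated productive sequences. `Q_L` is computed with
exact rational arithmetic on the integer length counts, so when the two
distributions coincide the factors reduce to `Q` bit-exactly and the two
modes produce identical hit tables. Lengths observed in data but never
simulated receive a pseudocount of 1 in the simulated histogram (logged).

### The d/n baseline

`d_hits_baseline` implements the model-free alternative: select sequences
with `d(σ)/n` above a threshold, or calibrate the threshold to yield a
target hit count (ties at the threshold are all included, so the realized
count can exceed the target). It exists to quantify what the recombination
null adds; it shares the neighbor filter but uses no P_gen.

## Monte-Carlo generation probabilities

`P_gen` per VJ class is estimated by simulation: draw `n_sim` rearrangements
with the V and J fixed (segment trims, insertion length, and insertion
letters from their model distributions), translate the in-frame products,
and count distinct amino-acid sequences. Estimates are normalized by the
*total* number of draws, not the productive subset, so they are
probabilities of the full recombination process; the `productive_only` flag
changes only which draws enter the numerator. The default `n_sim` is 10^6
per VJ class — on the toy model this resolves P_gen down to 10^-6, and the
zero-neighborhood discard handles sequences below that resolution. Larger
values (the published analyses used 10^8) are a configuration change, not a
code change.

Tables are deterministic given the seed, and a `PgenCache` memoizes them per
(model, n_sim, seed): the tables are a property of the model, not of any
repertoire, so repeated runs over different samples reuse them. Per-class
seeds are derived from the master seed and the class name (CRC32 mix), so
classes are independent but reproducible.

An exact dynamic-programming P_gen evaluator is deliberately out of scope;
`register_pgen_backend` defines the contract (nonnegative, agrees with
Monte-Carlo within sampling error) for plugging one in.

## The generative model and the toy default

`GenModel` describes segment choice (joint V–J usage, or V–D–J with an
explicit D), per-segment deletion-length distributions, insertion-length
distributions, and an insertion nucleotide model (independent letters, or a
first-order Markov chain as dinucleotide statistics suggest). Model files
use a small sectioned text format (`modelio`); parameters are inputs — no
model inference from data is attempted.

The bundled `toy_beta_model` has two V suffixes (starting at the conserved
Cys), two J prefixes (ending at the conserved Phe), trims of 0–4 nt per
side, and 0–6 slightly GC-biased insertions. It yields ≈33% productive
draws and a few thousand distinct amino-acid CDR3s per VJ class
(lengths 8–12), so a 5 000-clonotype sample populates neighborhoods densely
enough for realistic `d` statistics while 10^6 draws resolve individual
P_gen values. It makes no attempt to match human V/J usage.

## Abundance-aware statistic

The basic method uses only presence/absence of neighbors. The advanced
variant replaces `d` with `s = Σ_i f(c_i)` over the neighbors' read counts
`c_i`. Under the null each neighbor's abundance is an independent draw from
the empirical distribution `P_f` of transformed abundances (computed once
per run over all neighbor-eligible clonotypes, pooled across VJ classes),
so `P(s|d)` is the d-fold convolution of `P_f` and
`P(s|σ) = Σ_d P(s|d) P(d|σ)` with the same Poisson `P(d|σ)`.

Because clone sizes are power-law distributed, the default transform is
`f(c) = log c`, discretized on a fixed grid of 0.1 natural-log units
(configurable); observed `s` is accumulated on the same grid, making the
comparison exact on the grid. `f(c) = c` uses a unit grid (counts are
integers). The mixture over `d` is truncated at the smallest `d_max` whose
Poisson tail is below 10^-12, and the truncated tail mass is added to the
p-value in full (conservative). The indicator transform `f(c) = 1` gives
`s = d` identically, and the pipeline routes it through the basic Poisson
path so the reduction is bit-exact rather than merely numerically close.

## Selection logos

For a cluster of same-length hits, a factorized selection model
`P_sel(σ) = (1/Z) P_gen(σ) exp(Σ_i s_i(σ_i))` is fit against positional
background frequencies (taken from model-generated sequences of the
cluster's VJ class and length). Coefficients start at 0 and follow the
L2-regularized ascent update
`s_i(a) ← s_i(a) + ε [P_data,i(a) − P_sel,i(a) − 2λ s_i(a)]` with defaults
`ε = 0.5`, `λ = 0.02`; after every update each position is shifted by a
common constant so `Σ_a P_gen,i(a) e^{s_i(a)} = 1` (which makes the
constraint hold at every accepted iterate and projects out the additive
gauge freedom — any constant-shifted initialization converges to the same
solution). Iteration stops when the summed squared update falls below 10^-6
(cap 10^5 iterations, then an error with diagnostics). Background cells at
exactly 0 get a pseudo-probability of 10^-6 (renormalized and flagged) so
the constraint stays defined. Under the per-position constraint the global
`Z` equals 1 only if positions are independent under the background; the
residual product is reported as `z`, not forced to 1. Cluster sequences are
unweighted by clone size.

Letter heights: classical logos use per-position information content
`log2(20) − H(p)` times frequency; selection logos use
`P_data,i(a) · s_i(a)`, so depleted residues plot below the axis.

## Synthetic data

The generator produces the three ingredients the tests need:

- **Null repertoires**: distinct nucleotide rearrangements sampled from the
  model, zipf read counts (default exponent 2.5, rejection-truncated at
  10^4 — a typical RepSeq clone-size tail where roughly 75% of clonotypes
  are singletons).
- **Planted clusters**: `k` clonotypes (default 15) within one substitution
  of a seed sequence, sharing its VJ class, read counts ≥ 2 (default) times
  an inflation factor. The seed is the generated sequence with the lowest
  Monte-Carlo *neighborhood* probability above a floor of 10^-5 — low enough
  that recombination cannot explain the cluster, high enough that an
  independent Monte-Carlo table will not hit the zero-neighborhood discard.
  (The neighborhood sum, not the seed's own P_gen, is what enters λ: a rare
  variant of a common core sequence has low P_gen but a crowded,
  Poisson-expected neighborhood.) A stealth
  mode (singleton counts) exercises the neighbor filter: such clusters must
  never be detected. Clusters can be pinned to a VJ class; scenarios with
  both a genuine and a stealth cluster pin them to disjoint classes so their
  neighbor statistics cannot interact.
- **Sequencing errors**: singleton one-nucleotide variants of existing
  clonotypes at a per-base rate (Poisson in count × length × rate), the
  artifact the singleton filter and germline collapse are designed for.

Every clonotype carries exactly one label (null / planted / error), so
sensitivity and specificity are computable against ground truth.

What passing these tests shows — and does not. Null repertoires are drawn
from the generative model *without* thymic-selection subsampling while the
test applies `Q = 9.41`, so the null calibration is deliberately
conservative (raw p-values strongly sub-uniform); the tests verify the
method does not overcall under its own stated null, not that `Q` is correct
for any real repertoire. The toy model's diversity is ~10^3 smaller than a
human beta-chain repertoire, read counts carry no PCR-amplification
structure, and planted clusters are geometrically idealized (exact
Hamming-1 balls). Results on real data additionally depend on the fidelity
of the recombination model parameters, which are inputs here.

## Numerical choices

- Poisson tails via the survival function; for means below the underflow
  range the leading term is evaluated in log space and the p-value floored
  at the smallest positive double instead of returning 0.
- BH adjustment delegates to `statsmodels` (`fdr_bh`); the test suite checks
  it against a textbook step-up implementation.
- Neighbor counting is hash-based (one dictionary lookup per one-mismatch
  variant, 1 + 19L per sequence); the suite verifies it against O(n²)
  brute-force pairwise Hamming on random classes.
- `Q_L` in exact rational arithmetic (see above).
- Default problem sizes in the validation suite and acceptance script: 20
  repertoires of 5 000 clonotypes, 10^6 Monte-Carlo draws per VJ class, 20
  selection-recovery simulations of 500 sequences each — sizes at which
  every stochastic check has comfortable margins on a single CPU.

## Known limitations

- Substitution-only neighborhoods (no indels), matching the one-mismatch
  definition; indel-tolerant variants would need a different variant
  enumeration and null.
- The VDJ (explicit-D) sampler is a straightforward per-draw implementation,
  orders of magnitude slower than the vectorized VJ path; fine for small
  models, not for 10^8-draw tables.
- No cohort-level statistics beyond exact public-hit intersection; no
  paired αβ-chain analysis.
- The abundance null assumes neighbor abundances are exchangeable draws from
  the pooled empirical distribution, ignoring any abundance–P_gen coupling.
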