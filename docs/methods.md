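# Methods

## The motif model

`admotif` models a transcription-factor binding motif of length `L` as an
inhomogeneous first-order Markov chain over the DNA alphabet — an
*adjacent dinucleotide matrix* (ADM).  The parameters are an initial
distribution over A,C,G,T at position 1 and, for every later position
`h`, a 4x4 matrix of conditionals `P(X_h = b | X_{h-1} = a)`.  The
probability of a site `a_1..a_L` is the chain product
`initial(a_1) * prod_h P(a_h | a_{h-1})`.  A classic PPM (order-zero
position probability matrix) is the degenerate ADM whose conditionals do
not depend on the predecessor; the package supports both orders.
Matrices are serialized in a 16 x L layout (rows AA..TT), with the first
column holding the initial distribution replicated across predecessor
rows so the file shape is uniform.

A *dimeric* motif is composed of two monomer chains with

* an orientation `o` in {HT, HH, TT, TH}, realized by
  reverse-complementing the first monomer (TT, TH), the second (HH, TH)
  or neither (HT); homodimers skip TH, which duplicates HT by strand
  symmetry, and
* a signed spacing `d`: the distance from the right end of the first
  oriented monomer to the left end of the second; negative `d` means an
  overlap of `|d|` bases (the overlap must be shorter than either
  monomer).

The reverse complement of an ADM is again an ADM (the time reversal of a
Markov chain is Markov); it is built exactly from the position-wise
joint dinucleotide distributions, so `P_rc(s) = P(revcomp(s))` holds for
every sequence.

For spacings `d >= delta` (independence threshold, default 4) the dimer
is the *expected* model: first monomer, `d` background columns, second
monomer entered through its initial distribution.  Within overlaps
(`d < 0`) two order-one chains disagree about conditioning, so the
overlapped columns take the renormalized elementwise product of the two
monomers' position marginals — order zero inside the overlap — and the
first post-overlap column of the trailing monomer re-enters with its own
conditionals.  For `d < delta` the `|d| + 2` middle columns (gap or
overlap plus one flanking column each side) are replaced by a learned
*bridging* component `psi`; the derived *deviation*
`kappa = psi - expected middle` makes binding co-operativity explicit
(its conditional rows sum to zero).  A mixture over one or more
monomers, all their dimers on a per-pair spacing grid (default
`[-floor(min(l1,l2)/2), 10]`), and a background chain is the full model;
per monomer pair the dimer weights form the co-operative binding (COB)
table, displayed in integer multiples of 0.001.

The background is a homogeneous chain, order zero by default (an
order-one option exists); matrices being compared or reported always
include it.

## Learning

Training uses ZOOPS (zero-or-one occurrence per sequence) EM.  Per read
the E-step computes a posterior over (component, start, strand) —
proportional to `lambda_k / N_ik` times the likelihood ratio of the
window against the background, with `N_ik` the number of admissible
placements — plus a background-only mass.  Placements covering an
ambiguous base (N) are inadmissible; fully ambiguous reads are
background-only.  Reads of unequal length are handled per read through
`N_ik`.  The M-step re-estimates:

* mixing weights (component posterior means),
* monomer chains from monomeric placements and half-sites of dimers
  with `d >= delta` only — half-sites of closer dimers are distorted by
  the partner site and are excluded; with an empty pair set (monomeric
  mode) all placements are used,
* bridging components from the bridging windows of close-dimer
  placements,
* the background from posterior-weighted non-motif positions.

Minus-strand counts are reverse-complemented into motif coordinates
before accumulation.  With an infinite Hamming radius and pruning
disabled this is exact EM (the log-likelihood trace is non-decreasing);
the test suite asserts this property.

Two heuristics temper the pure EM search:

* **Hamming restriction** (radius `rho`, default 3 for ADMs, 2 for
  PPMs): placements whose window lies more than `rho` mismatches from
  the current consensus of the component (per half-site, for dimers)
  are excluded from the *matrix* updates.  The restriction limits what
  the chains are learned from; mixing weights and the background keep
  the full posterior.  This scope matters: if filtered placements also
  lose their weight, their mass re-routes through whichever other
  component still has an admissible window, and with a diffuse motif at
  high signal fractions the monomer weight absorbs 0.3–0.4 of the
  mixture that belongs to dimers.  A `filter_scope="all"` option applies
  the stricter full-mass removal for comparison.
* **Weak-dimer pruning**: from iteration 3 on, dimer cells whose weight
  falls below `1e-4` are removed permanently (their weight joins the
  background) and appear as empty COB cells.  Monomers are never pruned.

The search is seeded: each monomer starts from an IUPAC seed with the
allowed bases sharing `match_weight = 0.8` per position (order zero;
order-one structure appears after the first M-step), bridging components
start at the expected slices (zero deviation), and the weight starts as
0.5 background with the rest uniform over live components.  Convergence
is declared when the weighted maximum norm between consecutive models
falls below `epsilon = 1e-3` (default; `maxiter = 150`).

**Weighted maximum norm.**  The distance between two structurally equal
mixtures is the maximum over components of
`max(|lam_1 - lam_2|, min(lam_1, lam_2) * max |M_1 - M_2|)` where `M`
is the component's free matrix (the 16 x L monomer matrix; the bridging
blocks for close dimers; far dimers contribute only their weight, being
determined by their monomers).  The mixing parameters range over
monomers and dimers; the background weight is the derived quantity
`1 - sum(lambda)` and carries no term of its own (otherwise every
dimer-weight error would be re-counted, summed, as a background term
that dominates the maximum), while the background chain's matrix
difference is weighted by `min(lam_bg)` like any other matrix.  A dimer
cell alive in only one model enters with the other weight as zero.

**Post-processing.**  The "85% rule" keeps components in decreasing
weight order until the selected fraction of the non-background signal
reaches the threshold; removed weight is reassigned to the background so
the submodel remains a proper mixture, and selected weights are
unchanged.

**Numerical notes.**  Scoring uses likelihood *ratios* against the
background, so the per-read flank terms cancel and no log-space
bookkeeping is needed at read lengths in the tens to hundreds of bases.
Consensus extraction is max-product dynamic programming with ties broken
toward the alphabetically smaller base at each backtracking step (a
determinism guarantee, not a modeling claim).  Estimation adds a
pseudocount of 0.01 per matrix cell.  Zero-mass conditional rows
(unreachable predecessor states, e.g. after reverse-complementing a
deterministic chain) are filled with the uniform distribution and
flagged with a warning.  Given identical inputs and seeds, learning and
simulation are bit-reproducible.

## The simulator

`generate_reads` draws, per read, a component by weight (background-only
with probability `lam_0`), samples a site from the component chain
(including bridging columns for close dimers), reverse-complements it
with probability 1/2, places it at a uniform admissible start and fills
the rest with background.  Ground truth (component, start, strand) is
logged per read.  This emulates one round of an enriched fixed-length
read set (HT-SELEX-like windows of 40 bp); it does *not* model
enrichment cycles, PCR amplification bias, sequencing error, positional
bias, or flanking-primer composition.  Tests passing on simulated data
therefore demonstrate correctness of the estimator under its own
generative assumptions, not robustness to those real-data artifacts.

Two reference fixtures drive the sanity experiments:

* a homodimer mixture around a HOXB13-like monomer (seed `CYMRTAAAA`)
  with cells HT 4 (weight 0.061), HH 4 (0.055), HH 2 (0.068), TT 2
  (0.034), HH 5 (0.082) over a uniform background (0.70), rescalable to
  total signal fractions 0.03 / 0.30 / 0.90, optionally with a
  hand-specified deviation added to a bridging window;
* a two-monomer mixture with consensus sequences two mismatches apart,
  each at a configurable fraction (0.005 … 0.45), for probing the
  Hamming restriction at low signal.

The HOXB13-like monomer shipped in code (`hoxb13_standin`) is a
**synthetic stand-in**, not an estimate from experimental data: the
IUPAC seed distribution (match weight 0.85) augmented with deterministic
adjacent dependence coupling the degenerate positions (Y->M, M->R), the
kind of structure first-order models exist to capture.
`load_supplementary_monomer` substitutes any published 16 x L matrix.

## Evaluation

Model fit is summarized by the squared Pearson correlation between
k-mer occurrence counts and model scores (8-mers by default; 10-mers
for larger read sets).  Counts slide over both strands and collapse a
k-mer with its reverse complement into one canonical class.  The score
of a word sums, over mixture components, strands and all offsets
overlapping the word by at least one position, the component probability
of the covered letters (overhanging component positions marginalized
through the chain marginals, uncovered word positions scored by
background), each placement weighted by `lambda / #placements`, plus the
pure-background term; canonical class scores double non-palindromic
words, whose class pools two words' occurrences.  Raw-scale correlation
is the default; log–log and minimum-count filtering are options.  R^2 is
invariant to positive rescaling of scores, so only relative scores
matter.

## Problem sizes in the shipped tests

The packaged experiments run at reduced but statistically comfortable
sizes chosen for a single-CPU workstation: relearning experiments use
6 000–20 000 reads of length 40 (the reference experiment design uses
100 000; recovery error shrinks with read count, so the bounds asserted
at the smaller sizes are conservative in the direction that matters),
the co-operativity recovery uses 50 000 reads, and the fit-correlation
checks use 100 000.  The acceptance script accepts `--seed` and drives
every random draw from it.

## Known limitations

* The Hamming restriction uses plain string distance to the current
  consensus.  For strongly multi-modal ADMs (two high-probability paths
  several mismatches apart) a small radius can exclude one mode from the
  matrix updates; a probability-based neighborhood would be the natural
  refinement.
* The expected model inside overlaps is order zero; the exact
  conditional structure of overlapping order-one chains is not
  identifiable from the product construction alone.
* Mixing-weight estimates absorb a small background leak (windows that
  look motif-like by chance), visible as a ~0.02–0.04 underestimate of
  the background weight at signal fraction 0.30 without the Hamming
  restriction; the restriction suppresses most of it.
* OOPS/TCM alignment models, Markov orders above one, arbitrary-pair
  dependencies, multimers beyond dimers, and graphical logo rendering
  are out of scope (logo geometry is exported as JSON instead).
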