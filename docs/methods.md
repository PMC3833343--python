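# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `olfdiverge`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Codon-counting divergence statistics

All pairwise statistics operate on a `CodonAlignedPair`: the codon
columns of a nucleotide alignment back-translated from a protein
alignment, with gap-containing columns and columns holding a stop codon
in either sequence removed pairwise. Gaps must span whole codons;
partial-codon gaps are rejected as malformed input. Each retained column
carries its ungapped codon index in both sequences so that per-residue
annotations can be anchored later.

**Protein distance** is the proportion of differing residues (p-distance)
with an optional (default) Poisson correction d = −ln(1 − p). Saturation
(p ≥ 1) yields an explicit undefined flag rather than an infinity.

**dN/dS** uses Nei–Gojobori (1986) style counting rather than a
maximum-likelihood codon model. Counting is deterministic, cheap, and
checkable against an exhaustive enumeration oracle, which is what the
test suite relies on; numerical agreement with ML estimates on the same
data is not claimed. Conventions:

* *Site counting.* For each codon, each of the three positions
  contributes one site, shared equally among its single-nucleotide
  changes that do not create a stop codon (nonsense mutations are
  disregarded and the remaining changes renormalised). A codon therefore
  always contributes exactly 3 sites, and the radical + conservative
  split of nonsynonymous sites sums exactly to the nonsynonymous total —
  the invariant N_R + N_C = N_sites holds to machine precision. Site
  totals are averaged over the two sequences.
* *Difference counting.* Codons differing at k positions are resolved by
  averaging over all k! minimal mutational pathways with equal weight;
  pathways passing through a stop codon are excluded. In the degenerate
  case where every pathway is blocked, all pathways are used and
  stop-touching steps are scored as radical nonsynonymous changes (the
  most change-like interpretation); this arises only for a handful of
  codon pairs and is covered by the oracle.
* *Correction.* Proportions p = diffs/sites are Jukes–Cantor corrected,
  d = −3/4·ln(1 − 4p/3). p ≥ 3/4 flags the affected rate undefined.
* *Ratios.* ω = dN/dS is an explicit undefined flag (never an infinity)
  when dS = 0 or a rate is saturated — with one deliberate exception: a
  numerator rate of exactly 0 over a saturated denominator is reported as
  0, since the ratio's value is 0 regardless of the denominator's
  magnitude. The same rule governs dR/dC.

**dR/dC** partitions nonsynonymous sites and differences into *radical*
(across Dayhoff classes) and *conservative* (within a class) fractions,
using the class partition {AGPST, DENQ, HKR, ILMV, FWY, C}. Sites are
split fractionally by the class of each possible single-nucleotide
change; observed differences use the same pathway averaging as dN/dS;
each proportion is Jukes–Cantor corrected separately. Codon-level
counting was chosen over protein-level counting so that sites and
differences share one bookkeeping.

**Region and charge profiling** assigns every amino-acid-differing column
to a topology region (TM / inside / outside) through the *first*
sequence's ungapped residue position — the first sequence is the
annotated reference, so profiling is intentionally not symmetric under
swapping the pair (all rate statistics are). Because gap columns are
dropped pairwise before profiling, every retained column maps to a
reference position; the output still carries an `unassigned` bucket for
completeness. A substitution counts as touching a charged residue when
either residue of the column is in the configurable set, default
{E, N, Y}. Note that N and Y are not negatively charged; the default
follows the source convention for these receptors verbatim and is a
config knob, not a chemical claim.

## Orthologous groups

An orthologous group (OG) is a clade of the two-species gene tree whose
bootstrap support strictly exceeds the threshold (default 90) and whose
gene content is consistent with a single ancestral gene: at most one gene
from one of the species (1:1; k:1 with k−1 gains; k:0 with k−1 gains and
one loss). Inconsistent or unsupported clades are descended through,
polytomies child by child; a leaf with no supported cross-species partner
becomes a singleton OG scored as ancestral-present plus a loss in the
absent species — a species-specific *gain* would be expected to cluster
with a within-species paralog instead. Losses are therefore at most 1 per
species per OG and per-species counts always reconstruct as
1 + gains − losses, an invariant enforced at summary time.

Conventions: trees are used as rooted as written (optional midpoint
rooting for unrooted ML output); internal nodes without a support label —
typically the root — are treated as fully supported. Raising the support
threshold can only split OGs, never merge them (tested).

## Single-replicate reliable fold change

With no biological replicates, significance calling rests on counting
uncertainty alone. Gene counts are modelled as Poisson; with an
uninformative Gamma prior the expression rate of a gene with count k in a
library of L mapped reads has posterior Gamma(k + 1)/L. For the log2
rate ratio z = log2(rate_b/rate_a), let q_lo and q_hi be the (1 − c) and
c quantiles at credibility c (default 0.99). The reliable fold change is
q_lo if q_lo > 0, q_hi if q_hi < 0, and 0 otherwise; a non-zero value is
a significant call and is always shrunk relative to the raw log2 ratio.
This is a same-spirit reimplementation of the published single-replicate
approach, not a bit-compatible clone of that tool; its exact prior and
normalisation constants are replaced by the documented Poisson–Gamma
posterior with library-size normalisation.

Quantiles are Monte-Carlo (default 100 000 draws) for transparency, with
one independent seed substream per gene so results do not depend on table
order. The test oracle is the closed-form identity
X/(X + Y) ~ Beta(k_b + 1, k_a + 1) for independent Gammas, which gives
exact quantiles of the monotone-transformed ratio. Under the null the
construction yields ≈ 2(1 − c) significant calls (≈ 2% at c = 0.99),
which the calibration test bounds at 2.5%.

Raw log2 fold changes are flagged undefined when either count is zero;
the reliable value remains defined. RPKM is 10⁹·count/(library·length);
"detectable" defaults to count > 0 with an optional RPKM floor (the
source never defines detectability). The dN/dS-quartile contrast splits
genes at ω quartiles (rank-based, so ties cannot collapse bins) and
compares |gfold| between the most-conserved quartile and the rest with a
Wilcoxon rank-sum test, plus all pairwise contrasts; an all-identical ω
vector is flagged degenerate rather than tested.

## Pseudo-reference

Fixed interspecific differences are substituted into the reference to
remove read-mapping bias toward the reference species. Only
single-nucleotide variants pass; filters are read depth ≥ 5 (INFO DP by
default, configurable) and variant quality ≥ 60 (QUAL) — both read as
minima. Each passing site receives its most frequent alternative allele
(first sample's AD; ties broken lexicographically A<C<G<T and logged);
indels and multi-nucleotide records are skipped with a warning. Sequence
lengths are preserved and untouched positions are bit-identical. A
reference-allele mismatch is a hard error, which doubles as a guard
against accidentally applying the same variant set twice. Coordinates are
1-based inclusive (VCF convention) at the module boundary.

## Antennal receptivity

The deorphanisation matrix (receptor × odorant, Δspikes/s over baseline)
is first filtered: receptors whose maximum response is below 100 spikes/s
are dropped, then odorant columns re-evaluated over the survivors — the
order is fixed (receptors first) and logged. Missing cells are ignored by
the filter and contribute 0 afterwards (count logged); responses below
baseline are treated as indeterminate and clamped to 0.

Receptivity is A_s(o) = Σ_r RPKM_s(r)·max(response(r,o), 0) — linear in
the RPKM vector, so scaling a species' abundances by k scales its whole
profile by k. Cross-species use of a single species' response matrix
assumes functional conservation between OR orthologs; the sibling
species' abundances are re-keyed onto the reference receptor identifiers
through an explicit ortholog map. The interspecific change
ρ(o) = A_g(o)/A_q(o) is reported both raw and as a symmetric signed
percent (100·(ρ−1) for ρ ≥ 1, else −100·(1/ρ−1)) so that enrichment in
either species reads on the same scale; |signed percent| ≤ 10 is banded
as unchanged. Odorants with zero receptivity in exactly one species are
reported as one-sided (infinite change, flagged); zero in both species is
undefined and excluded from sorting.

Class enrichment builds, per chemical class (or per the human-associated
flag), the 2×2 table of in/out-of-class × enriched-in-g/enriched-in-q
over banded odorants only, optionally restricted to |signed percent|
above a floor, and applies a two-sided Fisher exact test implemented by
integer hypergeometric enumeration (tables with point probability ≤ the
observed one, compared exactly, so knife-edge ties carry no
floating-point ambiguity). Strata with an empty in- or out-group are
flagged untestable rather than assigned a p-value.

## Synthetic data: what it shows and what it does not

The generators are deliberately simple: uniform sense-codon ancestors
with accept/reject substitution (synonymous proposals always fix,
nonsynonymous with probability ω, accepted replacements steered radical
with the planted probability), Poisson counts with lognormal gene rates,
one newick tree per OG with all supports at 100, uniform depths and
qualities spanning the variant-filter boundaries, and block-structured
receptor tuning with one planted species-biased chemical class. They
validate the pipeline's logic — estimator consistency, exact
reconciliation, calibration, filter boundaries, enrichment power — under
known truth. They do not emulate codon usage bias,
transition/transversion asymmetry, alignment error, RNAseq
overdispersion beyond Poisson, bootstrap noise, or receptor pleiotropy,
so passing tests demonstrate correctness of the methods, not performance
guarantees on real libraries.

Default conditions (all in `SimulationConfig`, all overridable): 3000
codons and 0.15 substitution events per codon per lineage (divergence low
enough that Jukes–Cantor is comfortably below saturation, as for very
recently diverged siblings); 2000 genes at mean depth 200 with a planted
DE fraction of 0.5 at |log2fc| = 2 — the source comparison found DE in
the large majority of detectable chemosensory genes, and this fraction
also gives the fold-change caller's ≈ 2% null rate a wide margin against
the 5% FDR bound it is tested at; 250 (tests: 500) orthogroups with
single gain/loss probabilities of a few percent, matching the observed
rarity of turnover events (12 of 253 OGs); a 20 × 24 response panel at
25% tuning sparsity with a 3× abundance bias planted on the
specialist receptors of one class.

## Problem sizes and numerics

The validation suite uses sizes that make its statistical bounds sharp on
one CPU: the exhaustive counting-oracle sweep covers all pairs of up to 3
codons over a 6-codon alphabet chosen to exercise synonymous,
conservative, radical and stop-adjacent changes (~48 000 pairs) plus 200
random 10-codon pairs over all sense codons; ω recovery uses 50
replicates of 3000 codons per ω; calibration and power use 2000 genes;
Fisher exactness sweeps every 2×2 table with N ≤ 40 (135 750 tables)
against an independent enumeration. All comparisons against exact oracles
use 1e-12 absolute tolerance; Monte-Carlo quantities are compared to
closed forms at tolerances set by their simulation error. All randomness
flows from explicit integer seeds through numpy `SeedSequence`
substreams; reruns are bit-reproducible.

## Known limitations

* Counting estimators share the known small-divergence assumptions of
  the Nei–Gojobori family; with transition/transversion bias or codon
  usage bias they are biased relative to ML codon models.
* Gain/loss reconciliation is defined for exactly two species and does
  not model duplication-transfer-loss or bootstrap uncertainty beyond
  the hard support threshold.
* The fold-change caller models counting noise only; with biological
  replication a dispersion-aware model should be preferred.
* The receptivity model inherits the functional-conservation assumption
  for orthologous receptors and ignores receptor–co-receptor
  stoichiometry; it is a transcript-weighted summary, not a biophysical
  prediction.
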