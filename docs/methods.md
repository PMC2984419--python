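# Methods

## The problem

Several ulvophycean green algae (Dasycladales, Cladophorales,
Trentepohliales, the genus *Blastophysa*) read the stop codons TAG and
TAA ("TAR") as glutamine in their nuclear genomes; under this
non-canonical code only TGA terminates translation.  Their sister and
related lineages (Bryopsidales, *Ignatius*, Ulvales–Ulotrichales, and
the rest of the green plants) use the standard code, so the reassigned
taxa form a *paraphyletic* group on the reference phylogeny.  The
package implements the full analysis chain needed to establish and
interpret such a distribution: code inference from coding alignments,
glutamine codon-usage profiling, ancestral reconstruction under
competing scenarios, and likelihood-based topology testing.

## Code inference

A taxon's code is inferred from two independent signals.

1. **TAR at conserved glutamine columns.**  Reference taxa asserted to
   use the standard code define conserved Gln columns: codon columns
   where at least `min_ref` references carry a fully resolved codon and
   a fraction `support_threshold` or more of them translate to Q under
   the standard table.  A query taxon's TAG/TAA codons at those columns
   would be internal stops under the standard code, so their repeated
   occurrence is evidence of reassignment.  Codons containing gaps or
   ambiguity characters never enter either the numerator or denominator
   — the conservative choice that cannot fabricate evidence.
2. **Terminal stop usage.**  Observed 3' terminal codons corroborate:
   exclusive TGA usage is consistent with reassignment, use of all three
   stops with the standard code.  Terminal stops are optional evidence
   (EST fragments often lack the 3' end); when present and
   `require_terminal_consistency` is set, a TAR terminal stop blocks a
   `TAR_GLN` verdict and TAR evidence at Gln columns *plus* a TAR
   terminal stop yields `AMBIGUOUS` with an explicit conflict warning.

Defaults: `support_threshold = 0.9`, `min_ref = 3`,
`min_tar_evidence = 2`.  "Highly conserved" is not a quantity with an
agreed value; 0.9 balances the small reference panels of single-gene
alignments, and requiring two independent TAR observations guards
against isolated sequencing or alignment errors.  Evidence pools
additively across genes (the verdict is per organism, not per gene);
per-gene screens are retained for audit.

## Glutamine codon usage

CAA and CAG encode glutamine under both codes and are counted across the
whole coding region for every taxon.  TAR codons are counted anywhere in
the region, but only for taxa with a `TAR_GLN` verdict — under that code
an internal TAR cannot terminate, while under the standard code it is
never glutamine.  Frequencies are the four counts normalised to sum to
one; a taxon with zero observed glutamine codons is flagged `missing`
and excluded from ancestral estimation.  Counts are pooled across genes
(a per-gene table is also emitted); GC3 (the G+C share of resolved third
codon positions) is available as a descriptive covariate for the CAG>CAA
and TAG>TAA bias.

## Ancestral reconstruction

**Discrete scenarios.**  The code state (0 = standard, 1 = TAR→Gln) is
reconstructed on the rooted reference tree under two parsimony regimes.
Equal-cost (Fitch) parsimony permits both gains and reversals; on the
shipped topology its minimum of 2 changes decomposes uniquely into one
gain on the stem of the five-lineage clade and one reversal on the
Bryopsidales stem — the "single origin + reversal" scenario.
Camin–Sokal parsimony forbids 1→0 changes; its minimum equals the number
of maximal all-reassigned subtrees (three on the shipped topology:
Trentepohliales, Dasycladales, Cladophorales+*Blastophysa*) — the
"independent gains" scenario.  The stepwise-acquisition scenario is the
biological reading that reconciles the two counts; it adds no new
combinatorial quantity.  Optimal labelings are enumerated *exactly* by
dynamic programming over node states with full backtracking of ties
(a cap of 10^6 labelings guards pathological inputs), so gain/loss
partitions and event edges are never sampled.  Event edges are
identified by the tip set of the clade they subtend, which is stable
under any node reordering.

**Continuous usage frequencies.**  Each of the four codon frequencies is
treated as an independent univariate trait under Brownian motion
(correlated multi-trait BM is out of scope; the non-independence of code
and usage evolution is a known limitation of the BM description).
Ancestral values are the joint-ML solution: the minimiser of
Σ_edges (x_child − x_parent)²/t, computed by one sparse-Laplacian solve
per trait, which coincides with the GLS/empirical-Bayes conditional mean
given the tips.  On a star tree the root is the 1/v-weighted tip mean.
The rate σ² (trait units² per unit branch length) is estimated from the
tip marginal x ~ N(μ1, σ²C): the quadratic form divided by n (`ML`,
default) or n − 1 (`REML`, unbiased).  Note that R's `ape::ace` reports
a joint-likelihood σ² equal to the same quadratic form divided by the
number of edges (2n − 2); ancestral *states* agree between the two
parameterisations and are cross-checked against `ace` in the test suite.
Standard errors come from the conditional covariance σ²·(L_II)⁻¹ of
internal nodes given tips.  Zero-length branches are replaced by
1e-8 × tree height so the covariance stays invertible; tips with missing
profiles are pruned before fitting.  Per-node 4-vectors can be clipped
to [0, 1] and renormalised onto the simplex for reporting, with raw
values retained.

Branch lengths are used as given (ML estimates in expected
substitutions/site); no ultrametricisation is performed, on the view
that substitutional divergence approximates the opportunity for
codon-usage evolution better than absolute time.

## Likelihood engine

Per-site log-likelihoods on a fixed topology are computed by
Felsenstein's pruning algorithm under GTR+Γ.  The GTR generator is built
from six exchangeabilities and stationary frequencies, scaled to one
expected substitution per unit branch length, and exponentiated through
the symmetric eigendecomposition (Π^{1/2} Q Π^{-1/2}).  Rate variation
uses the discrete-Γ approximation with equal-probability categories
(default 8) whose rates are the category means of a mean-1 Γ(α); the
site likelihood averages categories with equal weights.  Gaps and N are
missing data (all-ones conditionals).  Per-node rescaling keeps partial
likelihoods in range.  Partitioned data (e.g. per-gene × codon-position)
may use a model per partition with shared branch lengths.

Branch lengths on a fixed topology are optimised by per-edge bounded
Brent search swept to a total-lnL improvement below 1e-6; the total is
non-decreasing by construction.  With a degree-2 root, only the *sum* of
the two root-adjacent edges is identifiable under a reversible model —
tests check exactly that.  `fit_gtr_gamma` optimises exchangeabilities
(GT ≡ 1) and α on the log scale with L-BFGS-B over empirical base
frequencies, alternating with branch-length sweeps.

Site rates for noise reduction come either from per-site Fitch steps
over the four nucleotide states (default; normalised by the maximum
observed count) or from the posterior-mean Γ-category rate.  Stripping
retains exactly ⌈keep_fraction × n⌉ slowest sites (default 0.75), ties
broken by original column order, with a column-provenance map.

## Topology tests

Candidate topologies are compared from their site-lnL vectors by RELL
resampling (no re-optimisation).  At each scale r in the canonical grid
0.5, 0.6, …, 1.4, B = 10,000 replicates draw ⌊r·n⌋ sites with
replacement; the topology with the highest resampled total wins, exact
ties splitting the win.  The AU p-value fits
bp(r) = 1 − Φ(d√r + c/√r) by weighted least squares on the probit scale
(binomial weights), reporting p = 1 − Φ(d − c); scales with bp ∈ {0, 1}
carry no probit information and are excluded, and if fewer than three
scales remain the result is clamped to 0 or 1 and flagged saturated.
KH p-values use the centred RELL null for the deficit against the best
topology; SH corrects with the max statistic over all candidates.
Resampling is iid across sites (partition-stratified resampling is not
the standard RELL and is not default).  All draws come from one seeded
generator, so results are bit-reproducible per seed.

The type-I behaviour of the AU implementation is checked by simulation
under the least-favourable null: two topologies with equal expected
lnL (iid normal per-site differences, mean 0), 1000 datasets of 100
sites, B = 10,000 — the rejection rate at α = 0.05 must fall in
[0.03, 0.07].

## Synthetic data

The generator produces exactly the structures the analyses assume, with
full provenance:

* **Coding alignments.**  Default 8 genes × 60 codon columns on the
  11-lineage fixture tree, 8 designated glutamine columns per gene
  (≈ 64 pooled Gln observations per taxon, matching the pooled-evidence
  regime of a multi-gene screen).  Glutamine columns are filled per
  taxon from its codon distribution — defaults (CAG, CAA, TAG, TAA) =
  (0.6, 0.4, 0, 0) for standard-code taxa and (0.45, 0.2, 0.25, 0.1)
  under reassignment, encoding the CAG>CAA, TAG>TAA GC3 bias.
  Background columns are invariant with probability 0.4, otherwise
  evolve along the tree with a Jukes–Cantor kernel at
  Γ(0.5)-distributed column rates.  Two hard guarantees are enforced by
  deterministic remapping: no taxon ever carries an internal stop codon
  (third position → C), and no background codon is ever glutamine
  (CAR → AAR, i.e. lysine), so the designated Gln columns are exactly
  the conserved-Q columns and standard taxa never contain internal TAR.
  The remapping breaks exact reversibility of the background process;
  the classifier consumes amino-acid conservation only, so this is
  immaterial to what the tests demonstrate.  Terminal stops: uniform
  over {TAA, TAG, TGA} for standard taxa, always TGA under reassignment.
* **Trees** by a Yule process with exponential waiting times.
* **Brownian motion** walks with logged node values.
* **Site-lnL matrices** with a shared per-site baseline plus independent
  normal per-topology offsets — iid normal differences with configured
  means, the calibration bed for the AU test.
* **Nucleotide alignments** under arbitrary GTR+Γ for the likelihood and
  site-rate tests.

What the generator does *not* emulate: alignment error, compositional
heterogeneity across lineages, codon-level selection, within-gene rate
autocorrelation, and any mechanistic tRNA/eRF1 competition dynamics.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Simulation-based checks use deliberately modest sizes chosen as adequate
for their purpose: 200 random ≤12-tip trees against the exhaustive
parsimony oracle, 4-taxon trees for exhaustive likelihood summation
(agreement to 1e-10), 500 replicates for BM parameter recovery (GLS
agreement to 1e-8; the ML σ̂² is compared against its finite-sample
expectation σ²(n−1)/n), 200 end-to-end replicates for verdict accuracy,
and 1000 null datasets for AU calibration.  Ties in stripping and RELL
are resolved deterministically as documented.  ΔlnL values are reported
to one decimal in summaries.

## The shipped fixture

`data/fig1_prose.nwk` + `data/code_states.tsv` encode the reference
topology *as described in prose* — the five-lineage clade
(Trentepohliales, ((Dasycladales, Bryopsidales), (Cladophorales,
*Blastophysa*))) nested within standard-code relatives — with invented,
plausible branch lengths.  The parsimony scenario counts are invariant
to the branch lengths and robust to the exact arrangement of
Trentepohliales relative to the other reassigned lineages; the fixture
is a reconstruction from text, not published data, and is labelled as
such wherever it appears.

## Known limitations

* The discrete reconstruction argues by parsimony counts, not rates; no
  Mk-model ML or stochastic mapping is provided.
* σ² per trait is univariate; the four frequencies are not jointly
  constrained to the simplex during estimation (renormalisation is a
  post-processing step).
* The likelihood engine evaluates given topologies only — no tree
  search, no model selection.
* Only the TAR→Gln reassignment is detected; other code variants
  (TGA→Trp/Cys etc.) are out of scope.
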