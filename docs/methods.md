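# Methods

`edsnet` re-implements, as a tested pipeline exercised on synthetic data
with known truth, the computational chain used to identify a conserved
herbivory-elicited early-defense-signaling (EDS) co-expression module
across six closely related *Nicotiana* species and to ask whether
duplicates derived from the Solanaceae whole-genome triplication (WGT)
are preferentially retained in it.  This note records the models, the
parameters that matter, and the design choices made where the published
description leaves the design open.

## The synthetic study system

The generator is the definition of the study conditions; everything the
pipeline consumes can be produced by it.

**Species tree.**  The fixed preset is a rooted six-leaf tree
(`N_obtusifolia`, `N_miersii`, `N_linearis`, `N_acuminata`,
`N_pauciflora`, `N_attenuata`) whose stem branch (the edge above the
root) carries the WGT label `SOL_WGT_STEM`; every branch below the root
is a focal-lineage (lineage-specific duplication) branch.  Node labels
name the branch above the node, so the labelling round-trips through
newick.

**Gene families.**  Families evolve top-down along species-tree
branches: per incoming lineage each branch draws a Poisson
(`dup_rate_per_branch`, default 0.1) number of binary duplications; a
lineage entering a branch is lost with `loss_prob` (default 0.02); on
the WGT branch every incoming lineage triplicates, each of the two extra
copies kept independently with `wgt_retention_prob` (default 0.25).
This branch-wise event-count scheme (rather than a continuous-time
birth–death process) is deliberately simple: recovery tests only need a
known mapping from events to gene-tree topology.  The emitted truth
gives, per gene, the branch of its most recent duplication *surviving in
the pruned gene tree*; with losses a few per cent of genes become
undatable from topology alone, which is exactly the slack the recovery
criterion (≥ 95 %) allows.  Branch supports are 1.0 by default (oracle
mode) or Beta-distributed via a noise knob.

**Expression.**  The design is 6 species × {control `WW`, elicitor
`FAC`} × 3 replicates (36 samples).  Counts are negative binomial with
variance μ + φμ², φ = 0.1.  Baseline log2 abundance is N(7, 1.2²) per
gene; per-(gene, species) batch offsets are N(0, 0.5²) on the log2
scale; per-sample depth varies lognormally (sd 0.15 log2).  One planted
100-gene module receives a log2 induction effect of 2 (±10 % per gene)
*only* in induced cells — elicited samples of the four responsive
species (the two earliest-branching species do not respond, mirroring
the two non-responders in the real design).  A per-sample latent
activity (1 ± 0.05 in induced cells, 0 elsewhere) scales the induction
and drives the trait — the stand-in for the maximum induced jasmonate
level shortly after elicitation — as `trait = 100·activity + N(0, 10)`.
Four decoy modules of 75 genes driven by latent factors unrelated to
treatment (loadings 0.4–0.7) emulate the background co-expression
structure of a real transcriptome; they are what makes "the planted
module ranks first for trait coupling" a non-trivial claim.

What the generator does **not** emulate: read-level artifacts (mapping
bias, gene-length effects on dispersion), cross-species orthology
uncertainty in the count table (the same gene ids exist in every
species), tagwise dispersion, and correlated traits.  Passing tests
therefore show the chain is correct and calibrated under its stated
model, not that it is robust to those real-data complications.

**Codon pairs.**  Two sequences diverge from a random stop-free
ancestor; each nucleotide position draws Poisson(`target_ks`/2) mutation
events per branch; synonymous changes are always accepted, nonsynonymous
ones with probability ω, changes creating stops are rejected.  Under
degeneracy-weighted site counting this gives expected synonymous
divergence ≈ `target_ks` and rate ratio ≈ ω.  Stop rejection removes a
small fraction of nonsynonymous opportunity, biasing estimated ω
slightly downward at ω near 1 (≈ 0.91 recovered at ω = 1, Ks = 0.2);
the neutral-calibration tolerance (±0.1) covers this.

## Expression chain

**TMM.**  Factors follow the standard trimmed-mean-of-M-values recipe:
reference sample chosen by the 75th count percentile closest to the
mean, M and A values over doubly expressed genes, rank-based double
trimming (30 % per M tail, 5 % per A tail), precision-weighted mean,
factors rescaled to geometric mean 1.  The implementation reproduces
edgeR's `calcNormFactors` to ~1e-6 on test fixtures (edgeR serves as an
independent oracle in one test, never as the implementation).

**FPKM and the expression filter.**  FPKM uses effective library sizes
(library × TMM factor).  A gene is "expressed" when FPKM is *strictly*
greater than 5 in at least three samples; thresholds written as
"greater than" are read as strict everywhere in the package.

**Exact NB test.**  Counts are rescaled to the geometric-mean library
size, summed within the two groups, and the first group's sum is tested
against its conditional distribution given the total (group sums of n
NB(μ, φ) replicates are NB(nμ, φ/n); at φ = 0 the conditional law is
binomial).  Two-sided p doubles the smaller tail, capped at 1.  This
matches the exact-test family used by edgeR to machine precision on
fixed-dispersion fixtures.  The common dispersion, when estimated, is
the pooled method-of-moments ratio Σ(var−mean)/Σ mean² over within-group
moments — far less biased at 3 replicates than averaging per-gene
estimates, but inflated when a minority of genes carries real biological
variance; per-gene (tagwise) shrinkage is deliberately out of scope.
Fold changes use normalized group means with pseudocount 0.5; a gene is
DE when linear |FC| > 1.5 (strict) and BH-adjusted p < 0.05.

**Batch adjustment.**  The standard parametric empirical-Bayes
location/scale adjustment for log-scale expression (normal prior on
per-gene batch locations, inverse-gamma on scales, the usual iterative
posterior solution), with covariates (treatment) preserved via the
design matrix.  It matches `sva::ComBat` to ~1e-5 (iteration tolerance)
on test fixtures.  Because the location estimates are shrunk toward
their across-gene prior, per-gene batch means are equalized only up to
a shrinkage residual; the tests assert strong reduction, not exact
equality.

## Co-expression chain

Unsigned networks with Pearson correlation: adjacency |cor|^β, unsigned
topological overlap `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij)`, diagonal fixed at 1.  The scale-free fit index is the signed R²
of the log-binned log p(k) ~ log k regression; `pick_soft_power` takes
the smallest candidate in 1–20 reaching R² ≥ 0.8.  The pipeline default
is β = 6 (the customary unsigned default): with only 36 samples the fit
index is noisy, and a fixed default keeps the end-to-end run stable
while the selection operation remains available and tested.

Modules come from average-linkage clustering of 1 − TOM with a static
height cut (default 0.98) and minimum size 30; the dynamic-hybrid
refinement of the reference R implementation is out of scope, so a
detected module includes a halo of weakly attached genes from the random
correlation tail.  The chain's own membership filter handles this: core
genes have signed kME (correlation with the sign-oriented module
eigengene) above 0.75, and recovery of the planted module is scored on
the core set, mirroring the published chain which also restricted the
module to kME > 0.75 before downstream analysis.  Hubs are the top
⌈5 %⌉ genes by connectivity on the designated (e.g. elicited-samples)
network.  Module–trait coupling is computed per gene (Pearson with the
trait), averaged per module, with a Wilcoxon–Mann–Whitney test of the
top module's member correlations against all other modules' members;
whether the original analysis averaged per-gene correlations or used
eigengenes is not stated — per-gene averaging is implemented.

**Preservation.**  For a module taken from the reference data, observed
statistics in the test data are: mean within-module adjacency (density),
and the correlations of (kIM_ref, kIM_test) and of ref/test adjacency
entries (connectivity).  Each is standardized against `n_perm` (default
200) equally sized random gene sets; Z-connectivity is the median of its
two statistics, Z-summary the mean of Z-density and Z-connectivity.
This is a deliberately simplified variant of the published composite
(which medians over ~7 statistics); the interpretation thresholds are
kept — above 10 preserved, below 2 not preserved — and both calibrations
are tested (structured module vs an independent replicate dataset scores
≫ 10; random gene sets average |Z| < 2).  When ref and test data are
identical the connectivity permutation distribution is degenerate
(every correlation is 1); a degenerate statistic contributes Z = 0.  The
permutation p uses the add-one upper tail and is floored at
1/(n_perm+1).

## Phylogenomic chain

Similarity hits survive with E < 1e-20, aligned length > 60 aa,
coverage > 60 % and identity > 50 % (all strict); self-hits are removed
and reciprocal hits merged at the best E-value.  MCL runs on
−log10(E) capped at 200, with self-loops set to each node's maximum
incident weight (standard MCL practice; needed for convergence of the
expansion/inflation iteration), inflation 2.0, and clusters read off as
connected components of the limit support.

Reconciliation is the standard LCA mapping (a node is a duplication iff
it maps to the same species-tree node as one of its children), checked
against a naive quadratic oracle.  A gene's most recent duplication is
the first duplication node on its leaf-to-root path; the call is
*accepted* only when that node's support and both children's supports
(leaves count 1.0) strictly exceed 0.9 — "the three closest branches"
read as the node plus its two children, the threshold parameterizable.
Low-support branches are filtered after reconciliation, not collapsed
before it.  Genes with uncertain calls are excluded from retention
totals.  WGT pairs are disjoint pairs of focal-species, leaf-expressed
genes from the same homolog group dated to the WGT branch, paired
greedily by gene-tree proximity; when three triplication copies survive,
the two topologically closest pair and the third stays unpaired.
Ancient segmental duplications on the stem are indistinguishable from
the WGT here (the published synteny confirmation is out of scope); the
branch label alone defines "WGT-retained".

## Ka/Ks

Counting method with per-codon degeneracy-averaged sites (changes to
stop codons count as nonsynonymous opportunity), multi-step codon
differences averaged over stop-free minimal pathways, and the
Jukes–Cantor correction d = −¾ ln(1 − 4p/3); p ≥ ¾ is reported as
saturated.  This replaces the YN-style estimator used in the original
analysis (transition/transversion and codon-frequency corrections are
out of scope); the Ks < 0.02 exclusion rule is preserved, and the
implementation agrees with an independent NG86 implementation
(Biopython's) to ~1e-3.  The ω < 1 test is a one-sided Fisher exact test
on the 2×2 table (nonsynonymous, synonymous) × (substituted,
unsubstituted sites), counts rounded half-up for the table only — the
published analysis does not specify its table construction, so this is a
documented choice.

## Retention enrichment

Category enrichment uses `odds = (p1/(1−p1))/(p2/(1−p2))` with p1 the
category fraction in the gene set and p2 genome-wide, plus an exact
upper-tail binomial p for the set count at rate p2.  In the
human-readable report odds are truncated (not rounded) to two decimals,
matching the printing convention of the worked example, and p-values
below 2.2e-16 print as "< 2.2E-16".  The preferential-retention test
compares observed 0/1/2-members-in-module pair counts with the
independent-recruitment null (per-gene module probability q = m/2n,
expected counts n·Binomial(2, q)) by a 2-df Pearson χ²; an exact
multinomial tail replaces the χ² when an expected category drops below
1.  TE-insertion enrichment flags genes with ≥ 1 family insertion within
the upstream window (1 kb, boundary inclusive, strand-aware distances
from the transcription start; BED inputs 0-based half-open).

## Problem sizes and numerics

The end-to-end synthetic run uses 2,000 genes × 36 samples, one planted
100-gene module plus four decoys, 200 gene families, 100 codon pairs ×
300 codons, and 200 preservation permutations; the null calibration of
the exact NB test uses 5,000 genes.  These sizes give stable recovery
statistics (planted-module core Jaccard 1.0, reconciliation recovery
> 99 %, type-I error within 0.05 ± 0.02) while a full pipeline run
completes in well under a minute on one CPU.  All randomness flows from
a single integer seed through `numpy.random.default_rng`; identical
seeds give bit-identical outputs.  Ties in connectivity rankings break
lexicographically by gene id; module labels order by decreasing size.

## Known limitations

Static-cut module detection needs the core-membership filter to reach
clean recovery; the common-dispersion estimate is inflated when many
genes carry biological variance, costing DE power at 3 replicates (a
per-seed recovery spread of roughly 0.8–1.0 at the default effect
size); the preservation composite is a two-statistic variant of the
published seven-statistic score, so its Z values are comparable in
interpretation but not numerically to the reference implementation; and
the ω estimator's stop-rejection bias makes it mildly conservative near
neutrality.
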