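# Methods

`mmclonal` reconstructs the spatio-temporal clonal evolution of multiple
myeloma (MM) from multi-region, multi-timepoint bulk sequencing summaries:
per-sample somatic SNV read counts, sample purity, and allele-specific copy
number. This note records the models, the parameters that matter, the
numerical choices, and what the bundled simulator does and does not emulate.

## Cancer clonal fraction

For a mutation with variant allele fraction `f_s = alt/depth` in a sample of
purity `p` at a locus of total copy number `n_t`, the mutation copy number is

    n_mut = f_s * (1/p) * [ p * n_t + 2 * (1 - p) ]

The multiplicity `n_chr` (copies per tumor cell carrying the mutation) is
chosen by maximum binomial likelihood: for each candidate `C in {1..n_t}`
the expected allele fraction is `C * p / (p * n_t + 2(1-p))`, and `n_chr` is
the `C` maximizing `Binomial(alt | depth, vaf(C))`, ties toward smaller `C`.
The CCF is `n_mut / n_chr`, capped at 1 with a `capped` flag.

Numerical choices:

* expected VAFs are clipped to `[1e-12, 1 - 1e-12]` before the likelihood,
  so the degenerate purity-1, fully-mutated case keeps a finite likelihood;
* `alt = 0` returns `n_chr = 1` by convention (the CCF is 0 regardless);
* a locus inside a homozygous-deletion call (`n_t = 0`) or without a
  covering segment is *unevaluable* — flagged and excluded downstream, never
  silently defaulted;
* recovery checks average the raw ratio `n_mut / n_chr` rather than the
  capped CCF: capping makes the reported value biased low near CCF 1 (the
  mean of `min(1, x)` under symmetric noise is below 1, by as much as ~0.07
  at depth 121 and purity 0.5), while the raw ratio is unbiased. The capped
  value is the right thing to *report*; the raw ratio is the right thing to
  *average*.

## Inclusion filters and detection

Mutations enter a patient's analysis set only with depth strictly greater
than 20 in every sample, site quality passed everywhere (mapping and base
quality at least 20, carried as an upstream flag), position outside the
immunoglobulin loci, and a CCF of at least 0.20 in at least one sample. The
CCF floor uses provisional CCFs computed once on the unfiltered candidate
set (a single two-pass sweep, no iteration). When several rules fail, the
report records the first of coverage > quality > Ig > CCF-floor. A mutation
is *detected* in an individual sample when at least two variant reads are
present. Copy-number events are size-filtered at 5 Mb for global analyses
and at 1 Mb for deletions over driver genes (deletion = total copy number
below 2).

The packaged Ig intervals are the GRCh37 IGH/IGK/IGL gene spans; they are a
configuration file the user can replace, since different capture designs
warrant different exclusion regions.

## Paired-sample heterogeneity

For a pair of same-patient samples, each mutation detected in at least one
of the two is classified as: unshared (detected in exactly one; minor/major
by CCF < / ≥ 0.60 in the detected sample), shared-differential (detected in
both, at least a threefold CCF difference; subclonal/clonal by the larger
CCF against 0.60), or shared. The threefold comparison carries a 1e-9
relative epsilon so decimal boundaries (0.6 vs 0.2) behave as intended in
binary floats. Group comparisons of shared proportions use the two-sided
Mann-Whitney test: exact enumeration of all group assignments for combined
n ≤ 12 (ties handled by enumeration), tie-corrected normal approximation
above.

## Subclonal deconvolution

Mutations are clustered over multi-sample CCF profiles with a binomial
finite mixture. Cluster `k` has per-sample centroids `phi_{k,s} in [0,1]`;
variant `i`'s read counts in sample `s` are binomial with success
probability `phi_{k,s} * q_{i,s}`, where `q_{i,s}` is the variant's clonal
VAF (multiplicity, purity and local copy number folded in). This ties the
cluster model to the same generative equation as the CCF estimate and gives
deeper samples more say.

* Fitting: EM with k-means++-style seeding on naive CCF vectors; M-step
  centroid updates by clipped Newton (the per-entry objective is concave);
  2 restarts per k; seeded (default seed 1).
* Model selection: BIC over k = 1..8 with `k * S + (k - 1)` parameters.
* Only variants with depth ≥ 50 in all samples enter the fit; the rest are
  assigned post hoc to the maximum-likelihood cluster.
* Centroids closer than 0.10 (max-abs over samples) merge.
* The subclone evidence rule requires ≥ 2 member mutations or ≥ 1
  copy-number event; failing clusters merge into the nearest valid cluster.

Clone trees come from centroid geometry: the root is the cluster with the
largest total centroid (the MRCA clone); a parent must contain each child
in every sample up to a 0.10 CCF tolerance (pigeonhole); siblings may not
sum above their parent; crossing CCF vectors are forced onto separate
branches. For up to six non-root clusters all parent assignments are scored
exhaustively by total violation magnitude, preferring fewer leaves on ties
(linear over branched, a parsimony preference); larger trees fall back to a
greedy construction. When no violation-free tree exists the best-scoring
tree is returned **with** its violation report — the manual judgment such
cases received in practice cannot be mechanized, so the package surfaces the
conflict instead of guessing.

Per-sample clone proportions are terminal: a clone's own proportion is its
(parent-capped) centroid minus its children's, floored at zero. A clonal
sweep between consecutive timepoints at one site class requires a clone
rising from below 0.20 to at least 0.60 while a previously dominant clone
(≥ 0.60) falls below 0.20. The 0.60/0.20 defaults mirror the clonal cutoff
and the CCF floor; both are configuration.

Parallel evolution flags a gene (or a configured gene family, e.g. the
KDM/KMT lysine demethylase/methyltransferase prefixes) hit independently on
two incomparable branches with no common ancestor carrying the same event.

## Signature analysis and single-cell expansions

Branch-private mutation sets are binned into the standard 96 pyrimidine-
normalized trinucleotide classes and refit against a fixed catalog by
maximizing the multinomial log-likelihood under a signature mixture
(closed-form EM updates; convergence when the log-likelihood improves by
less than 1e-10; after convergence a KKT check zeroes components whose
multiplicative update factor is below 1 and whose exposure is already
tiny — the objective is concave, so such components are exactly zero at the
optimum but EM alone strands them near 1e-6).

The presence of a target treatment signature — the melphalan-exposure-like
barcode of a single-cell expansion — is tested by a likelihood-ratio
statistic between fits with and without the target, calibrated by
parametric bootstrap from the constrained fit (default B = 1000, seeded;
p = (1 + #{LR* ≥ LR}) / (B + 1)). Sets with fewer than 25 mutations are
reported *not evaluable*, never negative: at that size the test has
essentially no power. A branch is flagged as a single-cell expansion when
it reaches the 25-mutation gate, the presence test rejects at 0.05, and the
fitted target exposure is positive.

The default catalog is synthetic: seven smooth background profiles
(`BG1..BG7`, a fixed-seed Dirichlet draw) plus a sparse treatment profile
`TX1` concentrated on eight contexts. These are stand-ins, not COSMIC
signatures, and `TX1` is not the real melphalan profile; any COSMIC-format
catalog (including the real SBS-MM1) can be supplied at runtime and flows
through the identical machinery.

## Evolutionary patterns

A *branch* is the subtree under a child of the tree root. Branches whose
clones reach a 0.20 proportion in any follow-up sample count as relapse
branches. One branch → *single-cell expansion*; two or more branches
co-detected in the same sample at least once → *coexisting subclones*; two
or more branches never co-detected → *alternating spatial dominance*.
Patients with both co-located and site-unique extra branches are labelled
coexisting (co-location dominates) with the alternating evidence recorded.
A positive signature flag corroborates but is not required for the
single-cell label, matching how the barcode behaves in practice (detectable
in most but not all single-branch relapses). The 0.20 co-detection
threshold equals the CCF floor for consistency.

## Clinical associations

Fisher's exact test uses the point-probability two-sided convention
(sum of all tables with fixed margins whose probability does not exceed the
observed table's). The association layer builds the ≥3-vs-<3 PET-focal-
lesion by single-vs-multi-branch table and the CR-vs-non-CR by pattern
table. The GEP70 risk score is the mean log2 expression of 51 up-regulated
genes minus the mean of 19 down-regulated genes, high risk at ≥ 0.66; the
gene lists are configuration (placeholder identifiers ship for tests), and
the score refuses to compute when more than 20% of either list is missing,
otherwise averaging the available genes.

## The synthetic cohort

The simulator plants a clone tree per patient with scenario-scripted
per-sample terminal proportions, so truth labels are unambiguous rather
than emergent from a stochastic growth model:

* *single_cell_expansion*: chain root → baseline subclone → relapse clone
  that sweeps the marrow (baseline 0.65/0.35/0, follow-ups dominated by the
  relapse clone; one planted sweep);
* *coexisting*: two relapse branches co-detected at the iliac crest with
  dominance shifting across follow-ups;
* *alternating*: two relapse branches confined to distinct focal lesions;
* *null*: one clonal population;
* *mixed*: cohort-level mixture at the 7:10:4 proportion seen clinically.

Read counts are binomial at the VAF implied by inverting the CCF equation
from the planted lineage CCF, per-sample purity (uniform 0.5–0.95), local
copy number (one clonal gain and one clonal deletion per patient, diploid
elsewhere), and multiplicity 1. Depth is negative-binomial with mean 121
(the cohort-scale median coverage) and size 25. Per-branch mutation counts
are uniform on 25–400, echoing the fitted range of branch sizes; clonal
(root) mutations default to 150. Trinucleotide contexts are drawn from
per-branch signature mixtures; relapse branches receive a 0.3 treatment-
signature exposure (roughly the "one-third of new mutations" scale of
alkylator footprints). Baseline clinical features are scenario-linked
(single-cell patients draw 0–2 PET focal lesions and CR; multi-branch
patients 3–10 lesions) unless `clinical_null` decouples them.

What the simulator does **not** emulate: stochastic clone growth and
drift, subclonal copy number, sample contamination or purity estimation
error, sequencing artifacts beyond binomial noise, spatial geometry of the
marrow, germline variation, and translocations. Passing recovery tests
therefore demonstrate that the estimators invert the stated generative
model at realistic depth/purity — not that they are robust to every failure
mode of real tumor data.

## Problem sizes used in the checks

The recovery suites run 50 simulated patients per scenario (~600 mutations,
4 samples each), the CCF round-trip grid uses 200 replicate loci per
(CCF, purity, copy-number) cell at depth 121, the presence-test size check
runs 1000 null simulations of 200 mutations at B = 200 bootstrap, and the
Fisher implementation is checked against enumeration on every table with
total ≤ 40. These sizes make the full suite complete in minutes on one CPU
while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* The tree search scores violations linearly and cannot represent doublets
  or convergent copy-number states; mock trees drawn by hand from the same
  inputs may differ in ambiguous regions (the violation report marks them).
* The binomial mixture ignores overdispersion; very deep samples can split
  clusters that a beta-binomial would keep together (the 0.10 merge
  tolerance absorbs most of this at exome-scale depth).
* The parametric bootstrap calibrates the presence test under the fitted
  background; backgrounds far outside the catalog inflate its size.
* Exact Mann-Whitney enumeration is capped at combined n = 12; beyond that
  the tie-corrected normal approximation is used.
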