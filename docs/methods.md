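# Methods

## Problem and model

Plasma cell-free DNA (cfDNA) is a mixture of fragments shed by many
cell types; its per-region methylation profile is, to a good
approximation, a convex combination of the profiles of the
contributing tissues. Given a reference atlas of CpG count matrices
(D<sup>atlas</sup>, M<sup>atlas</sup>: total and methylated CpG counts
per entity and marker region) and matching cfDNA count matrices
(D<sup>cfdna</sup>, M<sup>cfdna</sup>), the deconvolution model
factorizes the cfDNA ratio matrix R = M/D as R ≈ A·G, where

* A (samples × entities, rows on the probability simplex) holds the
  per-sample tissue proportions;
* G (entities × regions, entries in [0,1]) holds a *refined* atlas —
  it starts at the observed atlas ratios but is allowed to deviate to
  absorb reference imperfections (tumor purity, conversion chemistry,
  replicate bias).

The fit minimizes a coverage-weighted mean absolute error

L(A,G) = Σ<sub>ik</sub> w<sub>ik</sub> |R<sub>ik</sub> − (AG)<sub>ik</sub>|
       + λ Σ<sub>jk</sub> v<sub>jk</sub> |G<sub>jk</sub> − R<sup>atlas</sup><sub>jk</sub>|

with w<sub>ik</sub> = D<sup>cfdna</sup><sub>ik</sub> / Σ<sub>k</sub>
D<sup>cfdna</sup><sub>ik</sub> (so low-coverage regions, whose ratio
estimates are noisier, count less; rows sum to one and zero-coverage
cells drop out entirely) and an L1 tether of strength λ pulling the
known rows of G toward the observed atlas ratios, weighted by
per-row-normalized atlas coverage v. The L1 tether was chosen to stay
in the same loss family as the MAE data term, and its coverage
weighting mirrors the confidence logic of the data term: well-covered
atlas cells are trusted more. Rows of G that model unknown
contributors carry no tether. λ defaults to 1.0 and is exposed in the
configuration.

## Unknown contributors

When the atlas is incomplete, up to *h* unknown rows are appended
before the fit. Each round: the samples are deconvolved by NNLS
against the current atlas; the unknown's seed profile per region is
the coverage-weighted mean (over samples) of the reconstruction plus
the coverage-weighted mean residual, clipped to [0,1]; the row is
appended with pseudo-counts at the per-region median atlas depth
(this depth only matters for bookkeeping — unknown rows are untethered,
so it never constrains the fit). The seed is deliberately crude: the
gradient fit afterwards is what shapes the unknown row, because the
unknown's free (untethered) G row is the only way the factorization
can explain the shared residual structure across many samples. This is
also why unknown inference benefits from large sample cohorts. After
fitting, rows of G are matched back to atlas entities by
maximum-similarity one-to-one assignment (Pearson similarity, Hungarian
algorithm; constant rows get similarity 0); unmatched rows become
`unknown_1 … unknown_h`.

## Optimization

A is parameterized as a row-wise softmax and G as an elementwise
logistic of unconstrained variables, so every iterate satisfies the
simplex and box constraints exactly, with no projection steps. The
objective is piecewise linear; Adam is run on the closed-form
subgradients (sign of the residual through the chain rule of
softmax/sigmoid). Defaults: learning rate 0.01, up to 5000 iterations,
standard moment decay (0.9/0.999), early stop when the objective has
improved by less than 1e-6 over the last 100 iterations. The
best-loss iterate is returned, which guarantees the final objective
never exceeds the objective at initialization. A is initialized from
per-sample NNLS (renormalized to the simplex; an all-zero NNLS
solution falls back to uniform proportions), G from the atlas ratios.
Zero-coverage atlas cells are imputed with the region's cross-entity
mean for initialization only; their tether weight is zero. The whole
pipeline is deterministic given its inputs — the seed parameter exists
for interface uniformity and for the simulator.

## Atlas construction

Marker selection is one-versus-all: a CpG is a differentially
methylated site (DMS) for an entity when its methylation ratio differs
from **each** other entity's ratio by ≥ 30 percentage points (the
margin is checked against every other entity individually, not the
pooled rest, which is what makes the marker *unique* to one entity; a
pooled-rest mode is available as a config switch). Replicates are first
aggregated per tissue by summing counts, after dropping CpGs whose
ratio range across replicates (among replicates with depth ≥ 5)
exceeds 0.25 — the variance cutoff is a judgment call and is exposed
in the config. DMS of the same entity, direction and chromosome are
chained greedily downstream while consecutive sites are ≤ 500 bp
apart; a chain is kept as a region if it has ≥ 4 sites and spans
≥ 100 bp (50/250 bp are the other supported working points). The gap
rule is applied between consecutive sites rather than across the
whole window, keeping regions contiguous. When regions are converted
to count matrices, *all* CpGs inside the final interval contribute,
not only the seed DMS — region-level validity is then re-established
by the significance test.

Each candidate region is tested with a two-sided Fisher's exact test
on the 2×2 table of region-summed methylated/unmethylated counts,
target entity vs the pooled remaining entities (one-sided alternatives
are switchable). Bonferroni correction multiplies by the number of
candidates entering the test, globally across entities. Three marker
lists are supported: all candidates, the significant subset
(corrected p ≤ 0.001 by default), and a "balanced" list of the top-23
most significant regions per entity (ties broken by longer region,
then coordinate, for deterministic output).

## Simulator

The generator emulates the count-level statistics of whole-genome
methylation sequencing: block-structured atlases (each entity owns
discriminative regions at ratio 0.9 vs 0.1, plus shared background
regions), Dirichlet-distributed mixture proportions (symmetric α = 1
by default), Poisson region depths with optional log-normal
heteroscedasticity across regions (σ ≈ 1.3 gives well over 10× spread,
exercising the coverage weighting), and binomial methylated counts.
Unknown contributors are injected with Uniform(0,1) per-region
profiles. An optional bias knob perturbs the mixing profiles with
additive Gaussian noise (clipped to [0,1]) before counts are drawn,
emulating systematic deviation between the reference atlas and the
profiles actually shed into circulation; i.i.d. per-cell noise is a
stand-in for whatever correlated bias structure real references
carry. Dilution series mix a tumor profile into a healthy
background at 12 fractions from 50% down to 0.1% at mean depth 6,
emulating shallow sequencing; the exact interior grid
{50, 25, 12.5, 10, 7.5, 5, 4, 3, 2, 1, 0.5, 0.1} is this package's
reconstruction — only the endpoints and the count are canonical.

What the simulator does **not** model: real marker-region length and
CpG-density distributions, mappability structure, conversion-chemistry
bias, correlated errors between neighboring regions, tumor purity
variation, or fragment-level effects. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not performance on real cfDNA.

## Evaluation

Pearson r and MSE compare estimated with true proportions (a constant
vector yields r = 0 with a warning). Tissue-of-origin calling
normalizes each case's cancer contributions by the per-entity maximum
across a healthy-control panel; the top normalized cancer contributor
is the call, "normal" iff every raw cancer contribution is zero, and
ties break by raw value then name. A zero control maximum maps
positive case values to +inf (detected above any finite competitor).
Cervical subtypes (CEAD/CESC) group to CERCA and colorectal
(COAD/READ) to COLCA; grouping is applied after the argmax by default
(so subtype resolution still influences the call), with a
group-before-argmax option. Cohen's kappa uses marginal-frequency
expected agreement; the degenerate single-label case returns 1 for
perfect agreement else 0, flagged. CBC-class aggregation sums
B + CD4T + CD8T + NK into lymphocytes, passes neutrophils and
monocytes through, and renormalizes over the three classes
(erythroblasts are excluded, as a differential blood count does not
report them).

The limit of detection scans a dilution series from the highest
fraction down: a replicate's LOD is the smallest fraction down to
which the true tumor entity keeps a positive estimated contribution
*and* remains the top cancer contributor; the first failure stops the
scan at the previous grid value. LODs are reported as grid values;
averaging over replicates naturally produces off-grid means.

## Problem sizes and numerical choices

The test-suite and acceptance scenarios use deliberately compact
problem sizes chosen to exercise every code path with stable
statistics: 13 entities × 500 regions × 100 samples for exact
recovery, 8 × 120 × 60 over 20 repeats for the weighting ablation,
13 entities × 200 regions × 150 samples at depth 200 for held-out
entity recovery, and 8 × 150 dilution series with 10 replicates at
depth 6. Fisher agreement is verified exhaustively over all 2×2
tables with row margins ≤ 30 (43 776 symmetry classes) against direct
hypergeometric enumeration.

Degenerate inputs are defined rather than rejected where a convention
is defensible: all-zero Fisher tables give p = 1; all-zero NNLS
solutions give uniform proportions; zero-coverage cfDNA cells are
masked out of both loss and gradient (so perturbing their ratio
values cannot change the result bitwise); a sample with zero coverage
everywhere is an error naming the sample.

## Known limitations

* The unknown-row seeding uses the coverage-weighted mean profile plus
  mean residual; with few samples or unknowns highly correlated with
  atlas entities, the fitted unknown can absorb known signal
  (proportions shift toward the unknown even as its profile is
  recovered well). Estimated unknown *proportions* are less reliable
  than the recovered *profile*.
* MAE fits at very shallow depth (≈6X) are noisy; the LOD at depth 6
  in the synthetic benchmark is accordingly much higher than at depth
  60. LOD values depend strongly on how separable the tumor profile is
  from the background.
* Bonferroni is conservative for correlated neighboring regions; no
  FDR alternative is currently wired in.
* The one-vs-all margin rule requires every entity to cover the CpG;
  sites missing in any entity are skipped, so marker yield drops with
  patchy references.
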