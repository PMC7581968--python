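# Methods

This note documents the models, estimators and numerical choices behind
`connectotype`, what the synthetic-data generator does and does not
emulate, and the limitations a user should know before applying the
pipeline to real data.

## Connectome model and connection classes

A subject's connectome is a dense symmetric nonnegative matrix of
streamline-derived weights over a fixed parcellation; no threshold is
applied at load (thresholding sparse weak edges is contentious upstream,
and density is simply reported, as a percentage of possible edges
present). Small numerical asymmetry (< 1e-6) is repaired by averaging with
the transpose; larger asymmetry is an error.

Cortical modules come from consensus Louvain clustering of the
control-group mean connectome: `n_runs` independent seeded runs, a
co-assignment matrix thresholded at its own off-diagonal mean, and
re-clustering of the thresholded matrix until all runs agree (at most 20
rounds). The control group is used for the group average because the
normalisation downstream is also control-referenced. Community detection
is `networkx.community.louvain_communities` (weighted, resolution
parameter, seeded); determinism per seed is part of the contract.

Connection classes are defined by module/hemisphere membership:
interhemispheric (left × right module), intrahemispheric (distinct modules
within a hemisphere), intramodular, and subcortical-cortical (the
per-hemisphere block of six deep structures — thalamus, caudate, putamen,
pallidum, accumbens, ventral diencephalon — against each ipsilateral
module; other subcortical regions are carried but unclassified). Each
cortical-cortical edge belongs to exactly one class, so the three cortical
class kinds partition the total cortical edge weight — an identity the
tests enforce to 1e-9. Modules are *required* to be hemisphere-pure;
enumeration fails loudly otherwise.

The **random-partition negative control** re-labels modules from a Louvain
run on a random graph with matched node and edge counts (observed nonzero
weights shuffled onto uniformly random edges). Such modules mix
hemispheres by construction, which is precisely what makes the control
informative: classes built from them blend edge types and should dilute
any connection-type-specific group effect below detectability. Because
mixed modules admit no hemisphere-typed classes, the null path enumerates
generic cortical module pairs (`intermodular`/`intramodular`) only.
Subcortical blocks are anatomical constants that module randomisation
cannot scramble, so block-module classes are excluded from the null path —
keeping them would simply re-test the main analysis.

Topological distance uses Dijkstra shortest paths with edge length
`1/weight`, the standard strength-to-length mapping; unreachable pairs are
returned as NaN with a warning.

## Loss scores and group contrasts

Summed class strengths are normalised against controls per class:
`z = (s − μ_ctrl)/σ_ctrl`, `loss = tanh(−z)`. The tanh of the *negated*
z-score makes loss positive when strength falls below the control mean,
bounded in (−1, 1), and strictly decreasing in strength. Classes with zero
control variance are excluded with a warning. Regional loss maps (the PLS
response) apply the same transform to each region's summed weight toward a
connection type's partner set — contralateral cortex, ipsilateral
subcortical block, or same-hemisphere cortex — averaged over the target
patient group.

The default per-class contrast is an ordinary least-squares fit of
`strength ~ group + age + sex` over the two patient groups, with the group
coefficient's two-sided t test and BH-FDR across all classes (q < 0.05).
Covariates supplied as text are reference-coded; numeric-looking columns
are coerced to numbers first (a regression test guards this: silently
dummifying age inflates the null rejection rate to ~8%). A mixed variant
(per connection kind, within-class standardised strengths, subject random
intercept, class-by-group interaction terms) is available behind
`mixed=True`; with one observation per subject and class the fixed-effects
model recovers the same per-class t structure and is the default.
Shapiro–Wilk normality screening is reported as a diagnostic, never used
as a gate. Summary-statistic utilities (pooled-variance t from means/SDs,
Yates-corrected χ² for 2×2 tables, tie-corrected Spearman) reproduce
cohort-table analyses from printed values.

## PLS, spin permutations, bootstrap, ranking

Expression is z-scored per gene across regions (zero-variance genes
dropped); the response is the regional loss map for one connection type,
left-hemisphere cortical regions only. PLS components are extracted with
scikit-learn (NIPALS; orthogonal score vectors), and the proportion of
response variance explained by component k is
`R²_k = c_k² ‖t_k‖² / ‖y − ȳ‖²`. The carried component is the one with
maximal `R²_k` — data-driven, not hard-coded to the second component —
and every component is oriented so its region scores correlate positively
with the loss map, making "upweighted" mean higher expression where loss
is greater.

Spin permutations draw uniformly random 3×3 rotations
(`scipy.stats.special_ortho_group`), rotate the unit-sphere centroids, and
match original to rotated positions by greedy one-to-one assignment on
sorted distances, so every null map is a permutation of the original
values (gene-wise null weights stay exchangeable for the FDR step). The
identity rotation maps to the identity permutation; duplicate centroids
are an error. The permutation p for the chosen component is
`(1 + #{spin statistic ≥ observed}) / (1 + n_perm)`, where both observed
and spin statistics are the *max-over-components* variance explained —
applying the component-selection rule identically to real and null data
keeps the two comparable.

Bootstrap gene-weight variability resamples regions with replacement,
refits, aligns the component at the chosen index to the original by the
sign of the score-vector correlation (evaluated on the full region set),
and reports `SE` and `z = weight/SE`. Two caveats are deliberate and
documented rather than hidden:

* **Bootstrap z is a ranking device, not a test.** Under a global null the
  observed weight vector is the data's own covariance-maximising
  direction, and sign-aligned bootstrap replicates cluster around it;
  empirically ~19% of pure-noise genes exceed |z| = 1.96. Error control
  therefore comes from the spin-null FDR, whose calibration is tested.
* **Parcellated one-to-one spin tests are approximate.** The rotation
  family realised through assignments is not a closed permutation group,
  so observed-vs-spun exchangeability cannot be exact. Measured on this
  package: with spatially rough response maps (the generator's regime) the
  test is conservative (rejection ≈ 0–3% at α = 0.05); with strongly
  smooth maps against a smooth expression block it is anti-conservative
  (12–21%), consistent with published critiques of parcellated spin tests.
  The p-value machinery itself is exact — substituting unrestricted random
  permutations for rotations yields the nominal 5% — and that check is
  part of the test suite. Users applying the pipeline to strongly
  autocorrelated maps should treat spin p-values near the threshold with
  caution.

Per-gene significance uses each gene's own spin-null weight distribution
(two-sided via absolute value), BH across genes; survivors are split by
weight sign into downweighted/upweighted lists and ranked by |weight|.
`top_fraction` extracts the top q% of a direction's survivors
(floor(q·n); q ∈ {10, 20, 30, 50}, default 20) for enrichment.

## Enrichment

Cell-type specificity is built from a cells × genes table: each cell is
first normalised to relative abundance (making the statistic invariant to
per-cell library size), expression is averaged per major cell-type class,
and each gene's row is normalised to sum to one. The EWCE statistic is the
target list's mean specificity per cell type, compared against bootstrap
gene lists drawn without replacement within joint transcript-length × GC
quantile strata (5 × 5 bins) matching the target's stratum counts; sparse
strata fall back to length-only bins, then to a single stratum, with a
warning. Empirical upper-tail p with BH across cell types;
`sd_from_mean = (obs − boot mean)/boot SD` is reported for effect size.
The default 100,000 bootstrap lists match common practice; tests use
2,000–10,000.

Gene-list overlap is an upper-tail hypergeometric test; annotation-set
enrichment is the same test per set with BH across sets, labelled
`hypergeometric+BH` in its output — it intentionally does not reimplement
service-specific corrections.

## Synthetic-data generator

The generator exists so that every stage runs against known ground truth.
Defaults are the study-scale conditions: 180 cortical regions per
hemisphere + 19 subcortical; 4 modules per hemisphere (contiguous
longitude sectors on per-hemisphere Fibonacci-lattice spheres —
hemisphere-pure by construction); 34 controls, 67 PD high visual
performers, 33 PD low visual performers with age distributions and sex
ratios matching the cohort table; attenuation {interhemispheric 20%,
subcortical-cortical 10%} planted in the low performers with per-subject
log-normal jitter (SD 0.35) so the composite loss score has a real
per-subject dose to track; density target 0.6.

Weights decay exponentially with inter-centroid distance (length scale
30 mm on an embedding where hemisphere spheres sit side by side and
subcortical blocks cluster deep near the midline, reproducing the
long-interhemispheric / short-intramodular length ordering); within-module
edges are boosted 2× so the planted modules are recoverable by community
detection; a shared Bernoulli mask fixes density; subjects get
multiplicative log-normal edge noise (SD 0.4), a global subject factor
(SD 0.15) and a mild age-related decline (0.4%/year). Streamline lengths
are the centroid distances.

Expression maps are Gaussian random fields on the sphere (von
Mises–Fisher kernel smoothing of white noise, length scale 0.3 rad); 30
signal genes load the standardised loss map with coefficient 0.7, half
positively, half negatively. Transcript lengths are log-normal, GC
fractions Beta(20, 28), independent of signal status. In the single-cell
table the signal genes behave as markers of one designated cell type
(30-fold boost there, 0.05 silencing elsewhere) — near-silence outside the
marker type is what makes specificity > 0.8 attainable under
library-normalised specificity.

What the generator does *not* emulate: spatial autocorrelation in the
connectome noise (its loss maps are spatially rough, Moran's I ≈ 0.003,
unlike real regional loss maps), donor-level microarray structure,
probe-to-gene collapsing, dropout and depth variation in single-cell
counts, and any true biology in the gene metadata. Passing tests
demonstrate correct inference under the generator's assumptions, not
robustness to those real-data complications.

## Problem sizes used in testing

Calibration and recovery suites are sized to run on one CPU: contrast
type-I uses 200 label permutations plus 300 independent null cohorts at
reduced parcellation (30 regions/hemisphere); spin type-I uses 200
replicates with fresh 20/20/20-subject cohorts (the level of a
permutation test does not depend on cohort size) and 99 rotations each;
planted-truth recovery and the random-partition control use 50 full-scale
replicates; gene-ranking recovery uses 500 spins; EWCE uses 20 replicates
at 5,000 bootstraps. Production parameters (1,000 rotations, 100,000
bootstrap lists) are the defaults in the API.

## Known limitations

* The spin-test calibration caveat above is the main statistical one.
* Consensus Louvain convergence is declared when all runs agree; on graphs
  with genuinely ambiguous structure the 20-round cap may return a
  non-consensus partition (with a warning).
* The mixed-model contrast standardises within class before pooling, which
  changes the scale of its coefficients relative to the per-class OLS.
* The EWCE stratification merges bins aggressively on small universes;
  with very small gene sets the control for length/GC is correspondingly
  coarse.
* `density` is reported as a percentage; printed density values in the
  motivating literature are internally inconsistent about units, so no
  numeric density value is used as an oracle anywhere.
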