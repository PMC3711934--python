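# Methods

This note documents the statistical models behind `phenonoise`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions a user auditing results will
want to know.

## Data model

The pipeline's currency is the **trait table**: rows are samples
(strain × replicate culture, ids `STRAIN.rep`), columns are CalMorph-style
parameters.  The default catalogue partitions 501 parameters into 220
single-cell trait means, their 220 paired coefficients of variation (CV),
and 61 "other" sample-level quantities.  Mean/CV pairing is a strict
bijection, and each parameter's cell-cycle stage is encoded in its name
suffix (`_A` → G1, `_A1B` → S/G2, `_C` → M; the convention is
overridable in the metadata file).  When summarising per-cell data, the
mean parameter is the arithmetic mean over the sample's cells of the
parameter's stage and the CV is sd/mean over the same cells.  **CVs use
the sample (n−1) standard deviation by default** (`ddof=1`), matching
common statistical software; the population convention is available via
`ddof=0` and the choice is recorded in the table's provenance.  The 61
"other" parameters are realised as 3 stage fractions plus 58
boolean-cell-feature proportions.

## Strain-effect screen and empirical FDR

Per trait, a Kruskal–Wallis test (midranks, standard tie correction in
the denominator; K = 0 and p = 1 when all values tie) across the strain
groups.  The multiple-testing calibration is empirical rather than
analytic: the full screen is recomputed on B permuted datasets (default
1000), where each trait's values are independently re-attributed to
samples.  For a threshold t on the statistic,

    FDR(t) = mean over permutations of #{K_perm ≥ t}  /  #{K_obs ≥ t}.

The threshold grid is the set of observed K values.  The raw curve is
monotonised by a running minimum over ascending thresholds (so FDR(t) is
nonincreasing in t), and K\* is the smallest threshold whose adjusted FDR
is at or below the target.  If no threshold qualifies the calibration is
returned with a warning status and zero discoveries.  Implementation
note: permuting a trait's values permutes its ranks, so ranks are
computed once and only re-partitioned per permutation; the tie correction
is permutation-invariant and reused.

The **origin-association test** averages the 5 replicates per strain
(one value per strain per trait) and applies Kruskal–Wallis across the
classes of the factor (ecology or geography), with a Bonferroni verdict
over the number of traits.  With ~37 strains this test has limited power;
it is a guard against gross confounding, not a GWAS.

A Monte-Carlo calibration utility draws random partitions of the ranks
1..185 into 37 groups of 5 and computes the exact tie-free statistic,
giving the expected null exceedance count for any threshold (e.g. K > 56)
without simulating data.

## Rank-sum morphospace

Per trait, all 185 samples are midranked and each strain receives the sum
of its 5 ranks — a 37 × 501 matrix whose columns each sum to
185·186/2 = 17,205.  Ranks make every downstream analysis invariant to
monotone per-trait transformations and insensitive to the wildly
different units of morphology parameters.

**PCA** is column-centered and unscaled (the R `prcomp` default).  How
many components are "real" is decided by a permutation chance threshold:
each replicate independently permutes every column across strains
(destroying inter-trait correlation while keeping column marginals),
reruns the PCA, and records the largest per-component variance share.
Components whose observed share exceeds the expected maximum chance share
are retained.  Variance shares are computed from the eigenvalues of the
small strain × strain Gram matrix for speed.

**Angle dissimilarity**: d(i,j) = arccos of the cosine similarity of two
strains' score vectors over the leading components (enough components to
cover 97% cumulative variance, capped at 28).  The uncentered cosine is
the default; `centered=True` gives the Pearson-equivalent variant.
Angular distance is symmetric, zero on the diagonal, and satisfies the
triangle inequality.

**AU cluster support.**  The reference tree is average linkage on the
angle matrix.  Bootstrap unit is the parameter column: for each scale r
in {0.5, …, 1.4}, B resamples of round(501·r) columns with replacement
are drawn and the full transform (PCA → scores → angles → tree) is
recomputed; BP_r is the fraction of replicate trees containing each
reference cluster.  The multiscale model is fitted per cluster:
z_r = Φ⁻¹(1 − BP_r) regressed on σ = √r through z(σ) = vσ + c/σ by
weighted least squares with delta-method binomial weights
B·φ(z)²/(BP(1−BP)); scales with BP ∈ {0, 1} are dropped, and if fewer
than two scales remain the AU value is clamped to the boundary with a
degenerate-fit flag.  AU = 1 − Φ(v − c), where v is the signed distance
(negative for supported clusters) and c the boundary curvature; at c = 0
AU equals BP at σ = 1, and v = c gives AU = 0.5.  Note the scale enters
as σ² = r (larger resamples = larger σ), the convention of the standard
multiscale-bootstrap formulation; the fit is validated in the tests by
recovering (v, c) exactly from model-generated BP curves.  A `cheap`
mode skips the per-replicate PCA (angles on raw resampled columns) for
fast tests.

**LDA class characterisation.**  Parameters are preselected by the
Kruskal–Wallis screen at p < 0.01/501 (Bonferroni over the full
catalogue — the divisor is the catalogue size, not the tested subset).
With classes I/II/III plus "other" as a fourth class, three discriminant
axes are computed; because parameters far outnumber strains the
within-class scatter is inverted by truncated-SVD pseudo-inverse
(relative tolerance 1e−8).  Per class: the center vector is the mean of
member-strain projections; the class's max angle is the largest angle
between a member's projection and the center; a parameter is
*discriminating* when its contribution angle to the center is below that
max angle; the representative score of each strain is the scalar
projection of its LD coordinates onto the center direction, and each
parameter's correlation with the representative scores is reported for
representative-parameter selection.  All angles are in degrees.
Design choice: the parameter's LD-space vector is its **structure
vector** — the covariance of the centered rank-sum column with the LD
coordinates across strains — rather than the raw discriminant weight row.
In the p ≫ n regime the pseudo-inverse whitening amplifies estimation
noise in individual weight rows to the point where planted block
structure is unrecoverable, while structure vectors (the standard
interpretive quantity in discriminant analysis) recover planted
discriminating sets reliably; the raw coefficient matrix remains
available as `LdaClassModel.axes`.  Resubstitution prediction (nearest
class centroid in LD space) is checked against the input labels for all
class-labelled strains.

## Genotype–phenotype structure

Genetic distance is the Hamming fraction over segregating sites of the
boolean SNP matrix.  Phenotypic similarity between two strains is the
Pearson correlation of their coordinate vectors along the first 28 pPCs.
The headline number is the plain Spearman correlation of the two
quantities over all C(n,2) = 666 pairs — pairs are not independent, and
the statistic is reported exactly as such; an optional Mantel-style
permutation p-value (joint row/column relabelling) is provided but not
used for headline output.  The clean-lineage variant restricts pairs to
strains flagged as non-mosaic.  The gPC × pPC screen computes Spearman
correlations between all genotypic and phenotypic PC score columns
(centered, unscaled PCA on the 0/1 matrix for genotypes) and calibrates
|ρ| thresholds by permuting strain identity in the phenotype matrix,
**recomputing the phenotypic PCA per permutation** — pPC orientation is
data-dependent, so the components must be re-derived under the null.

## Noise pipeline

Noise traits are residuals of a LOWESS regression of each CV parameter on
its paired mean across all samples: locally linear, tricube weights,
smoother span 0.4 (as the analysis prescribes), and 3 robustness
iterations — the default of the classic `lowess` smoother; the span is
the fraction of points in each local window and iterations are
configurable.  The fit goes through `statsmodels` with `delta=0` (exact
local fits, no interpolation shortcuts).  The decoupling is verified as a
property: on synthetic data with a monotone baseline cv0(m), per-trait
|Spearman(residual, mean)| < 0.05 at the 185-sample geometry.

Strain effects on noise traits use the same Kruskal–Wallis machinery with
Bonferroni correction over the number of noise traits (0.05/220 =
2.27 × 10⁻⁴ per test in the full geometry).

**Phenotypic potential**: the noise matrix is reduced to a non-redundant
medoid trait set (for real data an externally supplied list, e.g. 70
traits; for synthetic data PAM recomputes it with dissimilarity
1 − |Spearman| between noise traits — a deterministic build+swap PAM
implemented here, as no installed library provides k-medoids), and each
sample's potential is the mean of its top round(0.5·k) noise values
(35 of 70 by default).  Residuals are pooled **without per-trait
standardisation** (the literal construction); a z-scored variant is
available by flag and recorded in the result.  Ties in the top-k
selection are broken by trait id for determinism (ties cannot change the
mean, only the bookkeeping).  The potential is monotone nondecreasing in
every noise value and translation-equivariant.  A Kruskal–Wallis test on
the 5 replicate potentials per strain assesses the strain effect on
global noise.

**Noise PCA**: the significant noise traits are rank-sum transformed and
decomposed as in the morphospace; components are retained while their
variance share exceeds the permutation chance threshold.  Loadings are
expressed as correlations R between component scores and trait rank-sum
columns and tested with T = R·√((n−2)/(1−R²)) against t with n−2 df,
Bonferroni-corrected over (retained components × traits) — 532 tests in
the study's 7 × 76 geometry.  |R| = 1 yields an infinite T, reported as a
boundary flag and always significant.

## Synthetic generator

The generator emulates the study design, not yeast biology.  Cell-level
trait values are lognormal: for target mean m and CV v,
σ² = log(1 + v²) and μ = log m − σ²/2, so the mean and CV are controlled
independently.  Defaults are the study conditions: 37 strains × 5
replicates × 200 cells, 220 base traits expanded to 501 parameters,
stage probabilities 0.45/0.35/0.20 (G1 / S-G2 / M, an exponential-growth
budding-yeast mixture), trait means log-uniform on [5, 100].

Planted effects, all serialised in `GroundTruth`:

* **Strain mean effects** — a fraction (default 0.5, echoing that most
  traits varied between strains) of traits receive per-strain log-mean
  offsets with sd = 0.5 × the cell-level log-sd; because the baseline CV
  follows cv0(m), shifting a strain's mean also (correctly) shifts its
  baseline CV along the curve.
* **Baseline noise–mean dependency** — cv0(m) = a + b·mᵍ with presets
  g = −1 (decreasing, the default: a = 0.1, b = 2) and g = +1
  (increasing), reproducing both trend directions seen in real CV-vs-mean
  scatter.
* **Trait-specific noise** — 30% of traits get 3 affected strains each
  whose CV is multiplied by 2 (the fold used by the recovery analyses).
* **Global noise** — 3 strains get every trait's CV multiplied by 1.5 by
  default (a modest global effect, consistent with global noise being
  detectable but weaker than trait-specific noise); recovery tests use
  fold 2 explicitly.
* **Correlated blocks** — traits share a per-cell latent factor in blocks
  of 10 with correlation 0.5; an admitted simplification of the unknown
  real correlation structure among morphology parameters.
* **Genotypes** — Balding–Nichols-style subpopulation divergence
  (5 subpopulations, F = 0.2) over 101,343 boolean sites; 57% of strains
  are mosaic (per-site ancestry drawn at random across subpopulations),
  and the clean-lineage flag marks the non-mosaic strains (≈16 of 37).
* **Origin labels** — ecology and geography classes are assigned
  independently of phenotype (each used class covering ≥ 2 strains), so
  the origin-association test has a true null by default.

Determinism: one RNG stream per dataset seeded from the config, with
per-strain sub-streams spawned from it, so identical configs give
byte-identical outputs and single strains can be regenerated.

What the generator does **not** emulate: realistic cell-cycle dynamics
(stages are iid labels), the heavy-tailed and bounded distributions of
some real parameters (ratios, angles), the true inter-parameter
correlation structure, and linkage disequilibrium along the genome.
Passing recovery tests therefore demonstrate that the statistical
machinery detects the effects it is designed for at realistic effect
sizes and sample sizes — not that real morphological data satisfy the
generator's assumptions.

## Problem sizes used in tests and calibration

The test suite runs the full pipeline on down-scaled designs chosen to
keep the suite fast while preserving the relevant geometry: 12–20 strains
× 5 replicates × 60–100 cells and 20–30 base traits for recovery and
null-control suites, with the full 37-strain, 185-sample geometry used
where the property depends on it (null uniformity, decoupling, pair
counts, chance-PCA bound).  The calibration script uses the full
geometry: 200,000 Monte-Carlo rank partitions for the null exceedance
count and 1000 column permutations of a 37 × 501 null rank-sum matrix
for the chance-PCA bound.

## Known limitations

* The empirical-FDR construction divides a mean permuted count by an
  observed count; it is a plug-in estimate with no uncertainty attached,
  and at very small discovery counts it is unstable (hence the isotonic
  monotonisation and the warning status when no threshold qualifies).
* AU p-values inherit the multiscale model's asymptotics; with few
  informative columns or BP curves pinned at 0/1 the fit degenerates and
  is flagged rather than extrapolated.
* Pseudo-inverse LDA in the p ≫ n regime depends on the SVD truncation
  tolerance; discriminant axes are stable but individual weight rows are
  not (see the structure-vector design choice above).
* PAM is exact only in the sense of local (build+swap) optimality; the
  k = 1 case and duplicate handling are verified against brute force.
* The pair-level genotype–phenotype correlation treats non-independent
  pairs as observations, by construction; use the Mantel option when a
  calibrated p-value is needed.
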