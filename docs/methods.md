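# Methods

`platemorph` analyzes the mechanosensory sensilla on the paired mesostigmal
plates of female damselflies (*Enallagma anna* and *E. carunculatum* by
default; the species enum is extensible). The input is not imagery but
digitized coordinates: per female, an ordered polygon tracing the plate
outline and a set of (x, y) sensilla positions, in micrometres, with two
technical digitization replicates per female. The package covers the full
analysis chain — scalar trait extraction, population-pooled spatial density
comparison, Procrustes mean plate shapes, and the sympatry-vs-allopatry
statistical battery — together with a synthetic-data generator that
reproduces the study design so that every stage is testable without any
specimen data.

## Data model and conventions

* **Coordinates** use the image convention: y increases downward. Densities
  and contours render consistently as long as the convention is applied
  uniformly; nothing downstream depends on the sign of y.
* **Left plates** are mirrored about the vertical midline of the outline's
  bounding box and re-tagged as right-equivalent at ingestion. Any vertical
  mirror axis is equivalent because translation is removed later by centroid
  standardization; mirroring preserves all pairwise distances exactly.
* **Broken sensilla** (a socket with a central pore left where a sensillum
  broke off) count as sensilla everywhere; the flag is retained for QC only.
* **Units.** Coordinate files carry an optional `scale_um_per_unit` factor
  (default 1.0, i.e. already µm). Areas are µm², densities per 1000 µm².
* **Zero-sensilla plates** are rejected at load time rather than silently
  tolerated; the study design never produces them.
* A plate can be flagged `counts_only` (imaged at an angle that distorted
  geometry): it contributes its count but is excluded from area, density,
  spatial, and shape analyses.

## Scalar traits

Per plate: sensilla count; plate area (polygon area of the traced outline);
sensilla-region area — the area of the polygon through the outermost
sensilla, implemented as the convex hull (the unique parameter-free reading;
an alpha-shape alternative would introduce a free parameter with no value to
estimate it from); coverage proportion = hull / plate area; density =
1000 · count / hull area; and mean and median nearest-neighbor distance
(downstream analyses default to the mean). The polygon centroid is the area
centroid, not the vertex mean, so it is invariant to how densely the outline
was traced.

Plates with fewer than three non-collinear sensilla have undefined
hull-based traits; these propagate as missing values and are excluded from
aggregates field-wise rather than being coerced to zero. Replicates are
averaged field-wise after per-replicate trait computation (averaged counts
may be non-integer and are kept as reals); a missing field in either
replicate stays missing. Populations are aggregated to their mean over
females — one value per population per trait — to avoid pseudoreplication;
a population sampled once is represented by that single female. A `min_n`
filter reproduces the better-sampled-subset sensitivity analysis.

Body-size correction of counts is deliberately absent: the count–body-size
regression is available in the stats module, but no correction is ever
applied (the relationship is null in both the motivating data and the
generator's defaults).

The tactile-capacity operation returns `states**n` exactly (arbitrary
precision) with a 2-significant-figure scientific rendering: n binary
mechanoreceptors can in principle encode 2^n distinct contact patterns,
which is why counts serve as a sensory-resolution proxy.

## Spatial analysis

Each plate's outline is scaled to area 1 (points carried along by the same
factor) and translated so the outline's area centroid is the origin. This
makes sensilla clouds comparable across females of different sizes while
preserving relative positions; the transform is idempotent and preserves
pairwise distance ratios to 1e-9. Clouds are pooled within populations
with at least `min_n = 4` females, keeping per-point provenance.

Densities are Gaussian KDEs with an unconstrained 2×2 bandwidth matrix.
The default selector is the normal-scale rule
H = (4/(d+2))^(2/(d+4)) n^(−2/(d+4)) Σ̂ (d = 2), chosen because it is
closed-form, deterministic, and adequate for a permutation-calibrated test.
An optional `plugin` selector minimizes the estimated AMISE numerically,
with fourth-order integrated density-derivative functionals estimated on
pre-sphered data using a Gaussian pilot (normal-reference order n^(−1/8),
refit once to the stage-1 smoothing scale); it is a pragmatic iterated
plug-in, not a reproduction of any particular published pilot schedule.

The two-sample statistic is the integrated squared error
T = ∫(f̂_A − f̂_B)², evaluated **exactly** through the Gaussian convolution
identity ∫φ_{H1}(x−a) φ_{H2}(x−b) dx = φ_{H1+H2}(a−b) — no grid enters the
statistic. For two single points distance δ apart with H = I this reduces
to T = (2 − 2 e^{−δ²/4})/(4π), which the tests verify against fine-grid
quadrature. Significance comes from a permutation null whose unit is the
**female cloud**: points within a female share a plate and are not
exchangeable, so whole clouds are relabeled between the two populations
(point-level permutation exists behind a flag for comparison). Bandwidths
are re-selected inside every permutation replicate, and the p-value uses
the add-one estimator (1 + #{T_perm ≥ T_obs})/(n_perm + 1) with ties
counted against the observed statistic — identical samples give p = 1, and
the smallest attainable p is 1/(n_perm+1). Note that with equal group
sizes the complement relabeling reproduces T_obs exactly, so the p-value
floor is effectively reached only when group sizes differ or the number of
females is large. Pairwise tables apply Benjamini–Hochberg FDR across all
pairs; per-pair permutation seeds derive deterministically from the master
seed and the sorted pair label, so adding or removing a population does not
change the other pairs' results.

Density surfaces for display are evaluated on a 151×151 grid extending 3
bandwidth standard deviations beyond the data, refined automatically until
the Riemann sum is within 1% of 1. Percentile contours are
highest-density regions: the q-th percentile region collects the
highest-density cells holding the top (100 − q)% of probability mass, so
regions nest by construction.

An asymptotic-normal version of the test (as in kernel-smoothing packages'
default) is noted as future work; the permutation route was chosen because
its calibration is directly verifiable by simulation, whereas the exact
internals of the original tool cannot be recovered from a methods
description alone. For the same reason, archived-data quantities such as
specific pairwise adjusted p-values are not reproduction targets here.

## Shape analysis

Outlines (600–1100 digitized vertices) are resampled to 200 ordered
landmarks: the lower and upper medial plate corners are retained exactly as
fixed landmarks and 198 semilandmarks are placed between them. The default
placement is equal arc-length spacing within each corner-to-corner segment,
allocated proportionally to segment length — deterministic, unlike random
vertex subsampling, which is available as `mode="random"`
(seed-reproducible) for fidelity to the original random-subsampling
procedure. How a random scheme should allocate points between the two
segments is not specified anywhere authoritative; both modes are provided
rather than asserting one.

Generalized Procrustes analysis centers each configuration, scales it to
unit centroid size, and iteratively rotates it onto the running consensus
(SVD-based optimal rotation with reflections excluded — plates are already
orientation-standardized); the consensus is the renormalized mean, iterated
to a 1e-10 movement tolerance or 100 iterations. Semilandmark sliding is
optional and off by default: each semilandmark may slide along its local
outline tangent (estimated from cyclic neighbors) to the point nearest its
consensus counterpart, one Gauss–Seidel pass per refit; the projection can
only decrease the summed squared distance to the consensus, and the fixed
corners never move. Bending-energy sliding is out of scope; the
tangent-distance criterion is the simpler of the two standard choices and
is documented as a deviation from morphometrics tools whose default is
bending energy.

## Statistical battery

On population-mean traits: species contrast by Welch's unequal-variance t
(two-sided, Welch–Satterthwaite df); three-class patry contrast within
*E. carunculatum* by Kruskal–Wallis (tie-corrected, χ² reference with k−1
df); two-class patry contrast within *E. anna* by Welch; and a
sympatric-vs-allopatric Bartlett variance contrast (reduced variance in
sympatry is a displacement signature that need not move the mean).
Coverage proportions are arcsine-square-root transformed (asin√p, the
standard variance-stabilizing form) before parametric tests. No
multiple-testing correction is applied across the trait battery — FDR is
used only for the pairwise KDE table — and this asymmetry is intentional
and documented. Group summaries report mean ± SEM with SEM = sd/√n over
population means.

## Synthetic data generator

The generator defines the study conditions the tests certify:

* **Design**: the bundled manifest (28 sites; 29 *E. anna* females over 13
  populations, 74 *E. carunculatum* over 19; three patry classes; 103
  females total), or any user manifest.
* **Outlines**: superellipse |x/a|^p + |y/b|^p = 1 with exponent 3 and
  aspect 0.45, radius modulated by low-order cosine perturbations
  (amplitudes 0.03, 0.02), 600–1100 vertices, plate areas 44,000 µm²
  (*E. anna*) and 30,000 µm² (*E. carunculatum*). Corner vertices nearest
  the medial diagonals are designated the fixed landmarks.
* **Counts**: truncated normal (≥3), means 49 and 28 with within-population
  SDs 10 and 8 — large enough that a 2× count ratio between two females of
  one population is common — plus a between-population SD of 3.
* **Placement**: two-component truncated Gaussian mixtures in the
  unit-area frame, medially weighted for *E. anna* (covering ≈0.65 of the
  plate, density ≈1.7/1000 µm²) and laterally concentrated for
  *E. carunculatum* (≈0.27, ≈3.3), sampled by rejection against the actual
  outline. Mixture components are a modeling choice; the true within-female
  spatial dependence is unknown.
* **Replicates**: two per female. Outline jitter is spatially correlated
  (low-frequency Fourier modes, SD 1.5 µm) because independent per-vertex
  noise would self-intersect a dense trace; sensilla get independent
  1.5 µm click jitter plus integer count noise (SD 2.5, points dropped or
  re-drawn). These defaults put replicate count correlations near 0.95 and
  plate-area correlations near 0.99. Broken-socket flags (rate 2%) live on
  the latent truth, so they agree between replicates up to count noise.
* **Effects**: sympatry count and placement shifts are plantable and
  default to zero — the no-displacement condition. Latent truths are
  retained for parameter-recovery tests. About 20% of females are emitted
  as left plates to exercise the mirroring path.
* **Seeds**: every draw flows from a master seed via CRC-derived
  per-population seeds; identical configuration and seed reproduce the
  study exactly.

What passing tests on this generator do **not** show: real plates are not
superellipses, real sensilla patterns are probably neither Gaussian nor
two-component, nearest-neighbor spacing in real plates is more regular than
a clustered mixture produces (the generator's NND means run below the
motivating study's ~19 µm), and digitization error in real tracings may be
structured in ways the Fourier model misses. The tests certify the
*pipeline* — calibration, recovery of planted effects, oracle equivalence —
not any biological claim.

A note on the bundled design: the source tabulation lists 19
*E. carunculatum* populations while the accompanying text says 28 (28 is
the number of distinct sites across both species). The fixture follows the
tabulation; the discrepancy is surfaced here rather than resolved.

## Numerical choices and problem sizes

* Standardization, GPA, and mean-shape invariants are enforced at 1e-9;
  GPA convergence at 1e-10 (Frobenius), max 100 iterations.
* KDE grids: 151×151, 3-SD margins, refined (doubled) up to twice if the
  mass check fails; mass conservation tolerance 1%.
* Permutation defaults: n_perm = 999 in the pipeline; simulation studies in
  the test suite use n_perm = 199 (null calibration, 500 simulations) and
  n_perm = 99 (power curve, 100 simulations per shift; recovery, 100/50
  seeds; null battery, 500 seeds) — sizes chosen to give binomial
  confidence intervals tight enough to be informative while keeping the
  default test run fast.
* The QC specimen flag is a robust outlier rule on relative replicate count
  disagreement (median + 5·MAD, floored at 0.3) rather than a fixed cut,
  so it adapts to the cohort's noise level; the study-level gate is a 0.9
  replicate correlation threshold (configurable).
* Degenerate inputs error loudly (collinear polygons, singular covariances,
  <2 females per side for female-unit permutation) or propagate as missing
  (degenerate hulls) — never silently as zeros.

## Known limitations

* The ISE permutation test is the only implemented null; no asymptotic
  p-values.
* Bending-energy semilandmark sliding and shape-space statistics (PCA,
  allometry) are out of scope — shapes are computed for mean-shape display.
* 3D plate curvature is not modeled; all geometry is planar.
* The plug-in bandwidth selector is a pragmatic iterated scheme, suitable
  as an alternative smoother but not a benchmarked reproduction of
  published plug-in pipelines.
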