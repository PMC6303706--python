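# platemorph

Morphometrics and spatial point-pattern analysis of the mechanosensory
sensilla on female damselfly mesostigmal plates.

When a male damselfly takes a female in tandem, his terminal appendages
grasp the paired mesostigmal plates on her thorax; cuticular
mechanoreceptors (sensilla) concentrated on those plates are the female's
first sensory window on who is grasping her, and differences in how many
sensilla she carries and where they sit may underlie species recognition
and — under reproductive character displacement (RCD) — should diverge more
where two hybridizing species co-occur. `platemorph` is a library for
testing exactly those predictions from digitized plate coordinates: per
female, an ordered outline polygon and a set of sensilla (x, y) points in
µm, two technical replicates each, plus a manifest assigning populations to
species and patry class (sympatric / locally allopatric / allopatric).

The pipeline computes:

* **Scalar traits** per plate — sensilla count, plate area A, hull area
  A_s of the polygon through the outermost sensilla, coverage A_s/A,
  density 1000·n/A_s (per 1000 µm²), and mean/median nearest-neighbor
  distance — replicate-averaged and aggregated to population means.
* **Spatial comparison** — each cloud is standardized to its unit-area,
  centroid-at-origin plate frame; populations with ≥4 females are pooled
  and every pair is compared with the exact integrated-squared-error
  statistic T = ∫(f̂_A − f̂_B)² between Gaussian KDEs (unconstrained
  normal-scale bandwidth matrices, convolution identity — no grid), under
  a permutation null that relabels whole female clouds;
  Benjamini–Hochberg FDR across pairs; percentile (highest-density-region)
  contours for display.
* **Mean plate shapes** — outlines resampled to 200 landmarks (two fixed
  medial corners + 198 semilandmarks) and superimposed by generalized
  Procrustes analysis, with optional tangent sliding.
* **The statistical battery** — Welch species contrasts, Kruskal–Wallis
  patry contrasts, Bartlett variance contrasts, OLS trait regressions,
  arcsine-square-root transform for proportions.
* **Synthetic studies** — a generator reproducing the bundled study design
  (two species, 28 sites, 103 females; ~49 vs ~28 sensilla, medial vs
  lateral placement) with plantable sympatry effects, so the whole chain is
  testable without specimen data.

## Worked example

```python
from platemorph import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig(seed=1, n_perm=199, min_n=4))
print(bundle["battery"].query("trait == 'sensilla_count'")
      [["contrast", "test", "statistic", "df", "p_value"]])
```

prints

```
    contrast            test  statistic        df       p_value
     species         welch_t   6.099464 17.873296  9.485639e-06
    Ec_patry  kruskal_wallis   1.615466  2.000000  4.458678e-01
    Ea_patry         welch_t  -1.122727  2.507668  3.574648e-01
 Ec_variance        bartlett   2.667196  1.000000  1.024363e-01
```

Read: the two simulated species differ strongly in population-mean sensilla
count (Welch t ≈ 6.1, p ≈ 1e-5 — the planted ~21-sensilla difference), while
the within-species patry contrasts are null, because no displacement effect
is planted by default. The same bundle carries the per-female trait table,
the 15-pair KDE comparison for the six eligible *E. carunculatum*
populations (`bundle["kde_comparison"].table`), density contours, and six
GPA mean shapes. `examples/` walks through each capability:

```bash
python examples/01_simulate_study.py   # design + count regime (49 vs 28)
python examples/03_spatial_kde.py      # pairwise ISE tests, FDR, contours
python examples/05_tactile_capacity.py # 2^25 = 33,554,432 = 3.4 x 10^7 ...
```

A thin CLI mirrors the library (`platemorph simulate|traits|spatial|shapes|
stats|run|fixtures`); `platemorph run --out results/ --seed 1` writes all
tables as config-hash-stamped CSV plus a JSON run summary.

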