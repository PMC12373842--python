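# Methods

## The analysis model

A 3D-collagen morphology screen produces one image (and one row of
morphology features) per well of a set of 384-well plates. Two per-well
metrics carry the phenotype of interest — **median colony area** and
**percent colonies with lumens** — because re-epithelialized (cystic)
colonies are larger and lumen-bearing, while the untreated (spiky)
baseline is smaller and solid. The analysis treats a well's value of
each metric as

    value = baseline × plate effect × treatment effect
            + row effect + column effect + noise,

i.e. multiplicative plate-to-plate variation and treatment effects, with
additive within-plate positional artifacts. Two normalizations target
the two nuisance terms:

- **Fold change** (control-based): the well's value divided by the
  arithmetic mean of the same plate's DMSO wells. Removes the plate
  effect; does *not* remove positional artifacts. The mean of a plate's
  DMSO fold changes is exactly 1 by construction.
- **B-score** (control-independent): the plate is decomposed by two-way
  median polish into overall + row + column + residual; the B-score is
  the residual divided by 1.4826 × median(|residuals|) (the MAD scaled
  to match the SD under normality). Additive row/column artifacts are
  absorbed by the polish, so the B-score is invariant to them; it needs
  no control wells and is robust to the minority of true hits.

**Hit calling** requires a well to lie in the top 5% of the compound-well
population on all four scores (fold change and B-score, for both
metrics), after excluding cytotoxic wells whose colony count falls below
half the plate's DMSO median (boundary retained, controls never
excluded). Thresholds are the (100−5)th linear-interpolation percentile
of the population's values; wells at or above the threshold are flagged.
The population is compound wells screen-wide with controls excluded
(per-plate gating is available as an option). A compound is reported as
a hit if at least one of its concentration wells is. No multiple-testing
correction applies: the gate is a ranking, not a test.

An intrinsic property of this design: two (effectively independent)
top-q gates jointly flag ~q² of null wells, ≈0.25% at q = 5%, so a
~3200-well screen passes a handful of chance wells through the full
four-gate conjunction. The package therefore reports hit wells for
visual confirmation rather than claiming the gate is error-free.

**QC** compares positive-control and DMSO wells per metric with a
two-sided Wilcoxon rank-sum test (medians and IQRs reported, raw
p-values, pass = positive median above DMSO with p < 0.05). **PCA**
z-scores each feature (population SD), drops constant columns and
incomplete wells, eigendecomposes the sample covariance, and reports
loadings as eigenvector·√eigenvalue with a deterministic sign convention
(the dominant feature of each component loads positively); explained
variance ratios are eigenvalues over total variance and sum to 1.

## Segmentation and morphometry

Colonies: pixels ≥ a global intensity threshold (absolute counts or an
image quantile), 8-connected components, per-component hole filling
(filling is per label, never on the global foreground, so a pocket
enclosed only by the *union* of several colonies is never claimed),
inclusive size filtering, optional border exclusion, dense relabeling.
Lumens: below-threshold regions (4-connected, the standard dual of
8-connected foreground) inside a single colony's filled footprint,
rejected if any pixel is 4-adjacent to the footprint's complement —
this kills the classic artifact of gaps between adjacent colonies
scoring as lumens — then size-filtered and assigned to their colony.

Circularity is 4πA/P², clamped to ≤1 in `measure_colonies` only
(rasterization can push near-circles slightly above 1); the raw
`circularity` function is unclamped. The default perimeter estimator
traces the marching-squares 0.5-level contour of the padded region and
simplifies it with Douglas–Peucker at 1 px tolerance before summing
segment lengths. The simplification straightens the staircase that
raster contours produce on oblique edges while leaving axis-aligned
edges exact; measured accuracy is ~1% low on disks (r ≥ 20 px) and ~1%
on axis-aligned squares. A Crofton 4-direction estimator is available
(`perimeter_method="crofton"`), but note its angular discretization is
biased for shapes whose boundary directions are concentrated: the ideal
continuous 4-direction estimate of a square's perimeter is
π·s(1+√2)/2 ≈ 3.79s, ~5% low, inflating circularity ~11%, which is why
it is not the default.

## Numerical choices

- **Median polish**: alternating row/column nanmedian sweeps (tolerance
  1e-6, max 20 passes), effect-vector medians folded into the overall
  term, missing cells carrying no residual. The decomposition is
  *initialized with the least-squares two-way fit* (row/column mean
  sweeps). Median-polish fixed points are not unique, and the raw
  Tukey iteration lands on different fixed points for a plate and the
  same plate plus additive row/column vectors (deviations up to ~0.1
  B-score units at full convergence). The mean initialization is exactly
  additive-invariant on complete plates and pins down the fixed point,
  making B-scores invariant to additive perturbations to ~1e-14 while
  the subsequent median sweeps keep the fit robust to outlying wells.
  With missing cells the invariance is approximate.
- **Zero MAD**: if the median absolute residual is (numerically) zero,
  zero-residual wells score 0 and nonzero residuals are reported as
  unscorable (NaN) with a warning, rather than dividing by ~0. A
  relative tolerance of 1e-9 × max|residual| separates genuine zeros
  from floating-point dust.
- **B-score population**: only compound wells (minus dead-excluded
  wells) enter the polish; control positions are treated as missing.
  Controls sit in fixed columns with deliberate effects and would
  otherwise bias the column-effect estimates. Controls consequently get
  NaN B-scores (their fold changes are still computed).
- **Ties and degenerate gates**: gate rule is ≥ threshold; an all-equal
  population flags everything with a warning. NaN values are never
  flagged and missing wells propagate as missing, never as zeros.
- **Well naming**: "A1"/"A01" both accepted, stored zero-padded;
  coordinates are (row, col), 0-based, origin top-left.

## The synthetic screen generator

The generator exists so that every stage can be tested against known
ground truth. Defaults mirror the screen design it emulates: 1059
compounds × 3 doses (0.1/1/10 µM), one well each, 14 DMSO + 14
positive-control wells per 384-well plate (DMSO down column 2, positives
down column 23, rows A–N), 356 compound wells per plate → 9 plates with
27 trailing empty wells.

Noise model (parameters in `SyntheticScreenConfig`, all per-run
configurable):

| quantity | model | default |
| --- | --- | --- |
| median colony area | mean-preserving log-normal, CV `cv_noise` | baseline 2500 px², CV 0.10 |
| plate effect | exp(N(0, σ)), multiplicative on area | σ = 0.05 |
| row/col artifacts | additive ±amp linear gradients, random orientation per plate | 250 px² / 0.015 (area / lumen fraction) |
| colony count | Poisson | mean 60 |
| % colonies with lumens | beta-binomial given the well's colony count, overdispersion ρ | baseline 0.10, ρ = 0.02 |
| hits / positives | ×3 on area, +0.40 on lumen fraction | ≈15 and ≈7 plate-SD |
| cytotoxic compounds | survival fraction scaling the Poisson mean | 0.15 |

`cv_noise = 0` switches the whole generator deterministic (used by the
exactness tests). Positivity and overdispersion motivated the log-normal
/ Poisson / beta-binomial choices; positional effects are additive on
the metric scale because that is the structure median polish removes.
Four texture-like extra features carry the same cystic/spiky signal into
the PCA morphospace. A single master seed spawns per-plate substreams,
so identical configuration gives byte-identical tables.

Rendered well images (696×520 px, 16-bit, a stand-in for a low-
magnification projection) contain cystic colonies as bright annuli with
background-level lumens and spiky colonies as solid star polygons
r(θ) = R(1 + a·cos kθ), with Gaussian read noise and noise-free label
masks as ground truth. `simulate_gradient_plates` builds the positional
stress case: both metrics drifting along shared plate directions with no
planted hits.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: dose–response shapes (hit effects are constant
across affected doses), spatially correlated focus artifacts,
out-of-focus colonies and monolayers (the intensity threshold is assumed
adequate), segmentation errors feeding the feature table (table and
image paths are generated independently), compound-specific morphologies
beyond the two planted phenotypes, and any pharmacology. Thresholds for
real images must be user-calibrated; the defaults are calibrated to the
generator.

## Problem sizes

The validation suite simulates ten full 9-plate screens (~34,560 wells
total) for hit recovery, three 3-plate gradient screens for the
positional contrast, and a handful of 520×696 wells for segmentation —
all chosen so the whole suite and the reproduction script each complete
in well under a minute on a single CPU while keeping every estimate's
Monte-Carlo error far below the tested tolerances.

## Known limitations

- Zero false positives is not a stable property of a dual quantile gate
  (see above); planted-hit recall is 1.0 in the typical screen but a
  ≥2σ-unlucky noise draw on one planted well occasionally drops one
  below a screen-wide threshold.
- B-scores require plate-position information; tables without row/column
  structure can only be fold-change-gated.
- The lumen detector requires lumens resolved as below-threshold
  cavities in a 2D projection; stacked or off-equator lumens in real
  z-projections can be missed.
- InCarta/MetaXpress-specific texture features are not reimplemented;
  the extra synthetic features are generic stand-ins, labelled as such.
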