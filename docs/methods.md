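# Methods

Definitions, conventions and numerical choices behind each pipeline. All
statements here describe what the code computes; empirical performance
numbers live in the test suite and `results/`.

## High-content GFP-LC3 puncta screen (`punctaflux.hcs`)

**Nuclei.** The nuclear channel is thresholded (Otsu by default, or a
fixed `nuclear_threshold`), holes are filled, objects below
`min_nucleus_area` (20 px) are dropped, and 8-connected components are
labeled. An optional distance-transform watershed (`watershed_split`)
separates touching nuclei.

**Cell regions.** Each pixel within `cell_radius_px` of some nucleus
centroid is assigned to its nearest centroid (a Voronoi partition clipped
to discs). Regions are disjoint by construction. The default radius is
30 px; analyses of generated fields should pass the generator's
`cell_radius_px` (18 px for default `FieldSpec`) so regions cover the
rendered cytoplasm.

**Viability.** The EthD1 channel is binarized at `viability_threshold`
(default: median + 6 robust SDs, where robust SD = 1.4826·MAD). A cell is
**dead iff** the stained fraction of its region is **≥ 0.5** — the
threshold is inclusive, matching an "at least 50% overlap" rule. The
generator renders dead-cell stain discs covering ~0.8 of the region and
leaves live cells unstained, so generated overlaps avoid the ambiguous
band around 0.5.

**Puncta.** The punctum mask is `(gfp − median_filter(gfp, 15)) >
max(k·σ, floor)` with `k = 6` and σ the robust SD of the residual. The
`floor` is 0.15 × the residual's 99.8th percentile: on (near-)noiseless
images `k·σ` collapses toward zero and would admit the anti-aliased skirt
of every punctum, merging close neighbors; the relative floor keeps the
rule meaningful across noise levels without an absolute-intensity
assumption. A fixed `gfp_threshold` bypasses both. 8-connected components
are kept when area ≥ `min_punctum_area` (1 px, so single pixels survive)
and form factor ≥ `min_form_factor` (0.4, inclusive).

**Form factor.** FF = 4πA/P² with A the pixel count and P the
*edge-count* perimeter: the number of 4-neighbor edges from a region pixel
to a non-region pixel (image border counts as non-region). Under this
convention FF ∈ (0, π/4]; a single pixel and any solid square score
π/4 ≈ 0.785, a 1×10 line 0.260. The threshold 0.4 separates compact spots
from linear debris. The same statistic is exposed for arbitrary masks via
`edge_count_perimeter` / `form_factor`.

**Endpoint.** Per field: fraction of *live* cells with ≥ `min_puncta`
(default 5, inclusive) puncta, optionally divided by the mean fraction
over control-well summaries. Fields with zero live cells report the
endpoint as undefined rather than zero.

## Tandem mRFP-eGFP-LC3 flux and Lysotracker (`punctaflux.tandem`)

Each reporter channel is Gaussian-smoothed (σ = 1) and thresholded against
its local mean over an 11×11 window: `mask = smoothed > local_mean −
offset`. The default offset is −4 robust SDs of the smoothed channel — the
negative sign demands pixels *above* their neighborhood, the punctum
regime; the subtraction makes the mask invariant to uniform intensity
offsets. Components with area ≥ 3 px are puncta.

A red punctum is **yellow** (autophagosome) iff the best single green
punctum covers ≥ 50% of its pixels (inclusive); otherwise **red-only**
(autolysosome). Overlap is measured against one green punctum, not the
union. Per-cell ratios use centroid membership in the HCS cell regions;
the per-cell mean skips cells without yellow puncta, while the pooled
ratio Σ red-only / Σ yellow is always reported and flagged infinite when
no yellow puncta exist.

The Lysotracker metric is `(mean gray − background mean) / n_nuclei` on
the unadjusted LTR image, with background the below-Otsu mask eroded 2 px
and nuclei counted on the nuclear channel; zero nuclei → undefined.

## Enzyme kinetics (`punctaflux.enzymology`, `punctaflux.models`)

- Initial rates: OLS slope of RFU vs time over the longest initial window
  in which estimated product stays below 10% of the starting substrate
  (minimum 3 points), divided by the standard-curve slope (RFU/M).
- Dose response: 4PL `bottom + (top − bottom)/(1 + (C/IC50)^h)`; transition
  direction auto-detected; flat responses are flagged `no dose effect`.
- Saturation kinetics: Michaelis–Menten with Hanes–Woolf start values.
- Inhibition models (single site): uncompetitive
  `v = Vmax·S/(KM + S(1+I/Ki))` (both apparent parameters scaled by
  `1/(1+I/Ki)`), competitive (`KM·(1+I/Ki)`), noncompetitive
  (`(KM+S)(1+I/Ki)`).
- Mode diagnosis mirrors how a kineticist reads the apparent-parameter
  plots: per-[I] MM fits give Vmax_app and KM_app; each is regressed on
  [I] with SE weights and converted to a relative change over the tested
  range. A parameter is *flat* when |relative change| < 0.10 **or** the
  trend is not significant (|t| < 3; the conservative cutoff keeps noisy
  but trendless parameters from masquerading as a mode). Both down →
  uncompetitive; KM up, Vmax flat → competitive; Vmax down, KM flat →
  noncompetitive; both flat → none; else mixed.
- Global Ki: one fit of the uncompetitive surface over the full substrate
  × inhibitor grid; the result carries the apparent-parameter consistency
  check `Vmax_app/Vmax = KM_app/KM = 1/(1+I/Ki)`.
- Binding: `signal = F_free + ΔF·fb(L)` with the depletion-corrected
  quadratic fraction bound for protein concentration P0; reduces to the
  hyperbola `L/(L+KD)` when P0 ≪ KD.
- MS cleavage: fraction A/(A+B) of cleaved (27885 Da) vs parent
  (72904 Da) peak heights per timepoint, plus its OLS slope over time.

**Numerics.** All nonlinear fits run through one wrapper around
`scipy.optimize.curve_fit` that rescales both parameters (`x_scale =
|p0|`) and the response (divide by max |y|): rates near 1e-8 M/s
against Ki near 1e-5 M otherwise stall the optimizer at its start values.
CIs are seeded case-resampling bootstrap percentile intervals (default
1000 resamples), widened when necessary to contain the point estimate,
with a Wald fallback when fewer than half the resamples converge; `method
= "wald"` selects the asymptotic interval directly.

## Densitometry, Baf additivity, PK (`punctaflux.bench`)

Band quantification starts from numeric densities (gel-image extraction is
out of scope): relative level = (band/loading) / mean control ratio,
invariant to rescaling the whole blot. The bafilomycin-additivity ratio is
`R = mean(drug+Baf − drug) / mean(vehicle+Baf − vehicle)`; flux is called
blocked iff R ≤ 0.25 (inclusive) — an operational default, not an
inference from the original data. R is undefined when the vehicle
increment is ≤ 0. PK summaries are noncompartmental: observed Cmax/Tmax,
linear-trapezoid AUC over the sampled interval, dose-normalized versions,
and the dose-proportionality ratio. Closed forms for the one-compartment
oral model (`C(t) = F·D·ka/(V_F(ka−ke))·(e^{−ke·t} − e^{−ka·t})`, Tmax,
AUC∞, including the ka→ke limit) live in `punctaflux.models`; the model's
concentration unit follows its inputs (a mg/kg dose over an L/kg volume
gives mg/L; multiply by 1000/MW for µM).

## Synthetic-data generator (`punctaflux.synthgen`)

Fields are rendered as anti-aliased discs: nuclei and cytoplasm per cell,
puncta placed uniformly inside the cell disc with a minimum separation of
`2·r + 3` px, per-cell punctum counts drawn from a Poisson (mean 4)
truncated by rejection at `max_puncta_per_cell` (8) so every drawn count
is placeable. Dead cells get a viability-stain disc sized to cover
`dead_overlap_fraction` (0.8) of the cell area. Optional per-cell
lognormal brightness (σ = 0.15), linear background gradient, Gaussian
read noise (σ = 8) and Poisson shot noise. Tandem fields render red-only
puncta in the red channel only and yellow puncta in both; each punctum's
class is an independent Bernoulli draw of `red_only_fraction`.

Assay tables are emitted long-format with one exact `is_truth` row per
design point plus noisy replicates (relative `noise_cv` and/or additive
`noise_sd` Gaussian). Default truths and designs are study-scale: IC50
24.5 µM (hill 1), Vmax 1e-8 M/s, KM 50 µM, Ki 20 µM over substrate
10–124.4 µM (6-point geometric) × inhibitor 0/6/18/54 µM; KD 16 µM at
P0 = 0.17 µM over a 16-point 1:1 dilution from 800 µM; oral PK ka =
2 h⁻¹, ke = 0.3 h⁻¹, V/F = 0.85 L/kg, MW 400 at 30–200 mg/kg.

Determinism: every generator consumes a single integer seed through
`numpy.random.SeedSequence`, with independent child streams per rendering
stage, so outputs are bit-identical across runs and platforms.

## Scope and limitations

- The generator renders circular cells and puncta without occlusion by
  neighboring cells, texture, or illumination vignetting beyond a linear
  gradient; recovery statistics on it bound algorithmic, not biological,
  error.
- Live/dead ground truth avoids stain overlaps near the 0.5 decision
  boundary by construction; classification accuracy on ambiguous staining
  is untested.
- Gel-image and raw-spectrum processing are out of scope; densitometry and
  MS inputs are numeric intensities.
- The bootstrap assumes exchangeable residual structure across design
  points; heteroscedastic designs beyond the relative-noise model are not
  modeled.
- Mode diagnosis assumes classical single-site mechanisms and a design
  that includes an uninhibited baseline; slow-binding or cooperative
  inhibition will read as `mixed`.
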