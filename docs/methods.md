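# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Raman preprocessing

A hyperspectral map holds an n-channels × m-pixels matrix `A` on a strictly
ascending wavenumber axis; pixel order is row-major over (y, x), y outer.
The chain applied by `preprocess_map`, in fixed order:

1. **Truncation** to the analysis window, default 400–2000 cm⁻¹ inclusive.
   The fingerprint region carries the collagen/GAG bands; channels outside
   it mostly add detector noise and silicon/quartz background.
2. **Cosmic-spike removal.** Each pixel's spectrum is compared per channel
   against the median spectrum of its 3×3 spatial neighborhood; residuals
   are scored with a per-channel robust scale (1.4826 × MAD over pixels) and
   positive excursions above `spike_z = 8` robust deviations are replaced by
   the neighborhood median. One-sided flagging reflects the physics: cosmic
   events only add counts. Two limitations are inherent to neighbor-based
   despiking and are covered by tests: a spike hitting the same channel of
   every pixel moves the median with it and is invisible; and the detector
   assumes composition varies smoothly at the pixel scale — structures of
   ~1-pixel extent inflate the residuals. A single-pixel map falls back to a
   within-spectrum median filter (width 5), logged.
3. **SNIP baseline.** The statistics-sensitive non-linear iterative
   peak-clipping recurrence, half-window m = 1…M:
   `y_i ← min(y_i, (y_{i−m} + y_{i+m})/2)`, channels within m of either edge
   left untouched at each pass. Default `M = 40` channels (≈80 cm⁻¹ at the
   default 2 cm⁻¹ spacing): structures wider than ~2M channels are treated
   as baseline, which passes tissue autofluorescence while preserving Raman
   bands of ≤30 cm⁻¹ width. The log-log-sqrt (LLS) compression
   `v = ln(ln(√(y+1)+1)+1)` runs around the loop by default; it damps the
   influence of tall peaks on the clipping average. Exact properties:
   baseline ≤ input pointwise always (the LLS round-trip is clamped to keep
   this exact); constants and — for the *plain* recurrence — linear ramps
   are exact fixed points. Under LLS a linear ramp is concave in the
   compressed domain and is clipped by a small amount, so the fixed-point
   guarantee is stated (and tested) for the recurrence in its plain form.
   The subtracted result is clipped at zero (the factorization downstream
   requires non-negativity); clip events are counted and logged.
4. **Savitzky–Golay smoothing**, 9-point window, polynomial order 3, mirror
   padding at the edges. Order 3 with 9 points is the conventional choice
   that preserves band shape while reducing noise variance; the filter
   reproduces polynomials up to degree 3 exactly on interior channels. Under
   mirror padding a reflected cubic is no longer a cubic, so exactness at
   the first/last 4 channels is not claimed; edge behavior is tested against
   an explicit convolution of the mirror-padded signal instead.
5. **Area normalization** to unit trapezoid integral per pixel, correcting
   intensity variations from changing focus conditions. A non-positive area
   signals a dead pixel and raises an error rather than silently passing
   garbage downstream.

The chain is a pure function: identical input and config give bit-identical
output.

## NMF unmixing

`A ≈ W·S` is fitted by minimizing the squared Frobenius reconstruction error
with Lee–Seung multiplicative updates (ε = 1e-12 guards against division by
zero). Multiplicative updates never increase the objective; the per-iteration
objective trace is recorded and asserted non-increasing to 1e-10 relative
slack. Defaults: 10 seeded random restarts (uniform init in (0, max A]),
`tol = 1e-6` relative objective change, `max_iter = 500`. The component
count k is user-chosen; `scree_over_k` reports the best objective per k,
warm-starting each k from the previous best solution so the reported curve
is monotone by construction.

NMF is identifiable only up to permutation and scale, and only when the data
contain near-pure observations of each component. The scale/permutation
indeterminacy is resolved by normalizing W columns to unit trapezoid area
(inverse scale absorbed into S) and sorting components by total abundance
descending. Cross-checks in the test suite compare the converged objective
against two independent solvers of the same problem — an alternating
non-negative-least-squares loop built on `scipy.optimize.nnls`, and
scikit-learn's NMF — within 1%.

Peak annotation detects local maxima by prominence (default threshold 5% of
the component maximum) and assigns the label whose reference peaks have the
highest match fraction within ±10 cm⁻¹; ties and best fractions below 0.5
yield "unassigned". The bundled reference table carries generic literature
positions for collagen and glycosaminoglycan bands and is meant to be edited
per instrument.

## AFM maps

Surface roughness of a height grid: `Z_avg` is the mean height and

* rms variant (default): `Sa = sqrt((1/N) Σ (Z_i − Z_avg)²)`
* mean-absolute variant (ISO Sa): `Sa = (1/N) Σ |Z_i − Z_avg|`.

The rms reading is the default because a plain mean of squared deviations
would carry squared length units; the ISO variant is available explicitly
and `mean_abs ≤ rms` holds for every map (Jensen). NaN entries are masked
and excluded from N; translation invariance and |c|-homogeneity are asserted
by `sa_properties_check`. Scan-grid geometry follows the inclusive-endpoint
convention: a 50 µm extent at 5 µm steps gives 11 points per axis.

Young's-modulus maps are consumed as data — the contact-model fit that
produces them is upstream instrument software — and only summarized
(masked-aware location/dispersion statistics and a histogram in kPa).

## Follicle staging and the puberty score

Staging is rule-based with fixed precedence: records without a visible
oocyte nucleus are excluded; an antrum makes a follicle antral (a
contradictory flattened-single-layer antral record is classified antral with
a consistency warning); otherwise granulosa shape decides — flattened →
primordial, mixed cuboidal/squamous → primary, cuboidal with ≥2 layers →
secondary (a single cuboidal layer is treated as a transitional primary).
The classifier is total: every valid record gets exactly one label.

MVH⁺ oocyte counts proxy total follicles and ZP3⁺ counts proxy growing
follicles; the difference MVH − ZP3 is reported with a configurable label:
`paper_literal` (default) calls it the primary pool, `zp3_semantics` calls
it the primordial pool — the marker logic supports the latter, the
conventional counting sentence the former, so both are explicit rather than
silently chosen. A negative difference is reported as 0 with a warning.

The puberty score takes the six largest healthy antral diameters and maps
the class of the single largest to the score: SF < 250 µm → −5,
F1 250–300 → −4, F2 (300, 350] → −3, F3 (350, 400] → −2, F4 > 400 → −1.
The printed integer class bounds (250–300 / 301–350 / 351–400) leave 1-µm
gaps; the half-open convention `250 ≤ d ≤ 300 → F1, 300 < d ≤ 350 → F2, …`
makes the classifier total over real-valued diameters while preserving every
integer boundary assignment. Fewer than six healthy antral follicles is
allowed with a warning; none at all scores −5 with flag `no_antral`. The
score is monotone in the largest diameter by construction.

## Matrisome omics

Reference tables are CSV (identifier, division, category) with the
core/associated consistency enforced at load: collagens, proteoglycans and
glycoproteins belong to the core matrisome; ECM regulators, ECM-affiliated
and secreted factors to the matrisome-associated division. Matching is
case-folded exact symbol match only — alias and ortholog resolution is
deliberately out of scope, so inputs must be pre-standardized. Input
duplicates are collapsed (counted) before annotation; unmatched identifiers
are non-matrisome; percentages are per-category fractions of the matrisome
total. Cross-species overlaps are exact set algebra over case-folded sets,
reporting all 2^s − 1 exclusive Venn regions, whose counts sum to the union
size.

The DEG criterion is strict on both sides: |log2FC| > 1 and p < 0.05, so a
gene exactly at either boundary is excluded. The nine-quadrant concordance
classifies each gene by its joint axis states (down/unchanged/up per the
same criterion); quadrant = 3·mRNA_state + protein_state + 1, so quadrant 1
is both-down, 5 both-unchanged, 9 both-up. Pearson r is computed over all
supplied pairs (reported with n); on degenerate input (fewer than 3 pairs or
zero variance) it is NaN rather than an error, since the counts remain
meaningful.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known latent truth, one seeded
`numpy.random.Generator` per call.

* **Raman phantom**: pure spectra are sums of Gaussian peaks (real component
  spectra are empirical, but Gaussians exercise the same recovery problem);
  abundance fields are smooth blobs spread around the grid so each component
  dominates a region and near-pure pixels exist — the spatial separability
  that makes NMF identifiable, mirroring cell-vs-matrix contrast. A small
  floor (0.04) keeps all components weakly present everywhere. The baseline
  is a broad polynomial scaled per pixel by a *smoothly varying* focus
  factor (spatially white baseline variation would defeat any
  neighborhood-median despiker and does not occur physically). Spikes are
  additive single-channel positive outliers, default magnitude 20× the
  noise sd so flagging is unambiguous. The standard test phantom
  (`default_raman_phantom`) uses 801 channels over 400–2000 cm⁻¹, noise at
  1% of peak signal and a 0.1% spike rate. Not emulated: detector response,
  wavelength-dependent noise, focus drift within a spectrum, histology
  structure — so passing recovery tests demonstrates correctness of the
  algorithms under the stated noise model, not instrument robustness.
* **Surface phantom**: Gaussian white noise smoothed to a correlation
  length, mean-centered, then rescaled so the rms Sa equals the target
  exactly (a final exact correction pass removes float drift); two seeds
  give different surfaces with identical Sa.
* **Follicle cohort**: stages are drawn from the specified proportions;
  morphology fields are generated consistently with the stage label, so the
  classifier recovers the truth exactly; diameters are per-stage truncated
  normals (defaults: primordial 20±4 µm through antral 320±70 µm, the scale
  of 4-week mouse ovaries); health is Bernoulli(1 − atresia_rate).
* **Omics table**: log2 fold changes are bivariate normal with the requested
  correlation ρ (sd 1.5 per axis); a `fraction_significant` subset receives
  p < 0.05 on both axes. ρ = 1 is handled exactly. The generator calibration
  is verified by sampling: at ρ = 0.5, n = 5000, the sample r lands in
  [0.45, 0.55] for ≥95% of seeds.

## Problem sizes and determinism

The test suite runs phantom recovery at 50×40 pixels × 801 channels with
k = 3 and 10 restarts (tens of seconds), solver cross-checks on 20×12
matrices, and generator calibration over 100 seeds — sizes chosen so the
full suite completes in well under a minute of compute while still
exercising every claim at meaningful scale. All randomness flows through
explicit seeds; every CLI report embeds the tool version, config hash,
seeds and input checksums, and re-running with the same config reproduces a
byte-identical report.

## Known limitations

* NMF recovery guarantees are stated for separable phantoms at ≤1% noise;
  heavily overlapping abundance fields or correlated spectra degrade
  identifiability, which no solver can fully overcome.
* The despiker cannot detect coherent spikes shared by all pixels of a
  neighborhood, and over-flags maps whose composition varies at the
  single-pixel scale.
* Quantitative concentration calibration, vendor file formats (SPC/WDF),
  Hertz/Sneddon force-curve fitting, tip deconvolution and image-based
  follicle measurement are out of scope.
* Matrisome annotation does no alias or ortholog mapping; identifier hygiene
  is the caller's responsibility.
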