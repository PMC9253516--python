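# Methods notes

This note records the models implemented in `cpcquant`, their assumptions,
the defaults that matter, and the choices made where the underlying
procedures admit more than one reasonable convention.

## ITC forward model and fitter (`cpcquant.itc`)

The forward model is the standard single-site (1:1) isotherm for a
perfusion (overfill) calorimeter cell. Total cell concentrations after a
cumulative injected volume V use the rational displacement factors
`(1 − V/2V₀)/(1 + V/2V₀)` for the analyte and `(V/V₀)/(1 + V/2V₀)` for the
titrant — the form used by the common Origin-based analysis packages. An
exponential-dilution variant exists in the literature; the two differ by
O((V/V₀)²) and are indistinguishable at the ≤20% cumulative dilutions of
the schemes modelled here. Measured heats include the trapezoid correction
for complex carried out in the displaced plug,
ΔQᵢ = Qᵢ − Qᵢ₋₁ + (vᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2, and are normalized per mole of
injectant. The heat of dilution is modelled as a fitted constant offset per
injection; a blank-subtracted isotherm can equivalently be supplied via the
CSV input path.

Defaults mirror the modelled instrument protocol: 200 µl cell, one 0.5-µl
priming injection followed by 15 × 2.5 µl, 180 s spacing, 20 °C. The
priming injection is simulated but excluded from fitting by default
(`exclude_first`), the universal practice for small first aliquots.

The fitter runs Levenberg–Marquardt (via lmfit) over (N, log₁₀ K_D, ΔH,
offset), multi-started from an 8-point log-spaced K_D grid spanning
10⁻¹¹–10⁻⁴ M to avoid local minima; it is deterministic and seed-free.
Standard errors are asymptotic (Jacobian-based); the K_D error is mapped
from the log-parameterization by the delta method. A flat isotherm or a
fitted enthalpy smaller than ~3× the residual RMS is reported with
`converged=False` rather than as silent nonsense, and a Wiseman c-value
(N·[cell]/K_D) outside [1, 1000] is attached as a warning because K_D is
poorly identified outside that window.

Free energies use ΔG = RT ln K_D with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹
and −TΔS = ΔG − ΔH; the identity ΔG = ΔH + (−TΔS) is exact by
construction.

Two physical caveats the tests make explicit: plateau heats in the
stoichiometric (c→∞) limit deviate from ΔH by a few 10⁻³ kcal/mol because
of the displacement correction, and total heat equals N·M₀·V₀·ΔH only when
saturation is reached early in the injection series — analyte displaced
before its partner arrives never reacts, leaving a deficit of roughly
V_eq/2V₀.

## Synthetic data generator (`cpcquant.synthetic`)

Foci are isotropic 2-D Gaussians sampled at pixel centers on a constant
per-channel background; noise is additive Gaussian with optional Poisson
shot noise on the expectation. Defaults: pixel size 0.0645 µm (a 6.45-µm
camera pixel behind a 100× objective), spot σ ≈ 0.12–0.15 µm (near the
diffraction limit at these wavelengths), backgrounds of 50–100 intensity
units with noise SD a few units, giving peak SNR in the tens — typical of
deconvolved wide-field immunofluorescence. All randomness flows through a
single integer seed per scene; identical scenes are bit-identical.

Chromosome-spread scenes place kinetochore pairs at random positions and
orientations, two ACA foci per pair at the requested separation (capped at
the 1.5-µm pairing limit), and a marker channel in one of three patterns
along the pair axis: `inner_only` (one Gaussian at the midpoint),
`dual_pool` (two Gaussians at ±80% of the ACA half-separation by default,
i.e. kinetochore-proximal), or `both`. The truth table stores the analytic
outermost-crossing FWHM of the continuous marker profile (root-finder
accuracy), which is what the measured FWHM is scored against.

What the generator does **not** emulate: 3-D stacks and out-of-focus light,
PSF asymmetry and chromatic shifts, photobleaching, cell-to-cell biological
variability beyond what is configured, and spatially structured
(non-cytoplasmic-mode) background. Passing tests therefore demonstrate
correctness of the measurement pipeline under its stated image model, not
robustness to every real-microscope artifact.

Mass-photometry events are draws from a Gaussian mixture; phenotype counts
(e.g. anaphase cells with lagging chromosomes/bridges) are binomial draws
per condition. The default regimes used in tests take the biological
values as generator parameters: a 193 ± 29 kD complex species, and error
rates near 6% (control/rescue) vs 27–29% (interaction mutants).

## Centromere quantification (`cpcquant.centromere`)

Detection: difference-of-Gaussians band-pass (σ 1→4 px), threshold at
median + 5 robust SD (1.4826×MAD) of the enhanced image, connected
components within 3–400 px, intensity-weighted centroids. The centromere
mask is re-derived per focus by Otsu thresholding inside a 9×9-px window
around the centroid (an absolute threshold can be supplied instead) —
the defining channel is the ACA staining, but the exact masking rule is a
package convention.

The ring is a morphological dilation of the mask by a disk of radius 3 px
minus the mask, so ring and mask are disjoint by construction; rings
touching the image border are flagged and excluded by default. Background
is the mean over a user-supplied cytoplasm region, or, when absent, over an
automatically selected region around the per-image intensity mode (a
stand-in for the manually selected cytoplasm area of interactive
workflows). Corrected intensities may be negative; they are kept but
flagged and excluded from normalization reference means. Rings are averaged
per centromere and then per cell before condition-level statistics — a
convention; pooling pixels first would weight large centromeres more.
Normalization divides by the mean corrected intensity of the reference
(rescue) condition, which therefore maps to exactly 1.0.

Tethering recruitment is the background-corrected marker over
background-corrected GFP measured over the focus mask itself (a LacO-array
focus is a single large locus, not a ring); nonpositive corrected GFP
raises, and pipeline callers treat such cells as excluded.

## Pair profiles and FWHM (`cpcquant.profiles`)

Pairing is mutual-nearest-neighbour with the 1.5-µm cap: deterministic,
local, and invariant to input order (inputs are canonicalized by
lexicographic sort; distance ties resolve to the lexicographically smaller
partner). A greedy global matching was the alternative; mutual-NN matches
what spot-tracker post-processing typically does and cannot chain distant
points into pairs.

Profiles sample each channel by bilinear interpolation along the pair axis
over ±1 µm about the midpoint, default step half a pixel (Nyquist for the
sampled grid). Normalization to [0, 1] is per profile, per channel;
profiles are normalized individually before any averaging for display.

FWHM uses baseline = profile minimum within the 2-µm window, half level
= (max + baseline)/2, crossings by linear interpolation between bracketing
samples, and the width between the **outermost** left and right crossings.
For a two-peak (dual-pool) profile whose valley dips below half maximum
this reports the full envelope breadth — the only convention under which
"broader signal" is monotone in pool separation; the number of crossings is
reported so callers can distinguish single- from multi-peak shapes. FWHM is
invariant under affine intensity maps with positive gain.

## Mass photometry (`cpcquant.massphot`)

KDE with Gaussian kernel; bandwidth defaults to Silverman's rule on the
event list (instrument-software settings being generally unknown). Peaks
are local maxima of the density above 5% of its global maximum
(configurable); maxima closer than two bandwidths are merged onto the
highest-density representative to suppress finite-sample ripple. Each peak
is summarized by the mean ± SD of events within ±2 bandwidths of the
maximum — note this SD reflects the truncated local population, not a
fitted component width, and is intentionally narrower than a full mixture
SD. Assignment picks the candidate stoichiometry minimizing the absolute
mass distance, accepts it within `tol_sd` × peak SD, breaks exact ties
toward the smaller calculated mass (recorded), and reports unassignable
peaks explicitly.

## Statistics (`cpcquant.stats`)

Kruskal–Wallis H (tie-corrected, via scipy) with Dunn's post hoc z tests
computed from pooled ranks with the standard tie correction; the
multiplicity adjustment inside Dunn's procedure defaults to Holm
(uniformly more powerful than Bonferroni at the same family-wise level;
Bonferroni and Šidák are selectable). One-way ANOVA with Dunnett's
many-to-one comparisons (scipy) serves the tethering ratios; the choice of
rank-based vs parametric route is an explicit configuration, not an
automatic decision. Phenotype rates use the uncorrected Pearson χ² on 2×2
collapses of each group against the control. Chromosome alignment is
scored 0 → complete, 1–3 → mild, >3 → severe misalignment, and
significance stars follow the 0.05/0.01/0.001/0.0001 convention.

## Pipeline (`cpcquant.pipeline`, `cpcquant.cli`)

One YAML document selects one analysis with per-module parameter sections;
schema violations are reported with field paths before any computation.
Per-condition and per-cell seeds are spawned from the single config seed
via `numpy.random.SeedSequence`, so runs are reproducible end-to-end and
re-running a persisted config byte-reproduces all tables. CSV tables are
always written; figures (isotherm with fit, normalized line profiles,
scatter-with-mean panels) are opt-in.

## Problem sizes used in the checks

The validation suite runs detection/quantification on 128–256 px images
with 10–50 spots or pairs per condition, 100 replicate noisy isotherm
fits, 15–20 cells per synthetic condition, 10³–10⁴ mass events, 1000
random point sets for the pairing oracle, and 2000 null simulations for
family-wise error control — sizes at which every Monte-Carlo bound tested
has comfortable margin while the whole suite completes in a few minutes.

## Known limitations

- The ITC dilution-correction form and first-point policy of specific
  commercial packages are not published; reported standard errors may
  differ slightly from instrument-software values.
- Ring quantification assumes maximum-intensity-projection-like 2-D input;
  no 3-D quantification, deconvolution or mitotic staging.
- KDE peak SDs are local-window SDs (see above), not mixture-component SDs.
- The synthetic image model is the validation ground truth; conclusions
  about real data require the usual visual QC of detection and masks.
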