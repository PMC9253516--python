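# cpcquant

Quantitative analyses for the biophysics and cell biology of the chromosomal
passenger complex (CPC) binding to Shugoshin 1 (Sgo1): isothermal titration
calorimetry (ITC) isotherm simulation and fitting with free-energy
decomposition, centromere-intensity ring quantification, kinetochore-pair
line-profile FWHM analysis of CPC localization pools, mass-photometry peak
calling with complex mass accounting, and the accompanying group statistics.
Every analysis can be exercised end-to-end on synthetic, ground-truthed data
produced by the package's own generators, so detection, quantification and
fitting can be validated against known answers.

Intended users: structural/biophysics groups characterizing protein-protein
affinities by ITC and mass photometry, and cell-biology groups quantifying
centromeric fluorescence and inner-centromere vs kinetochore-proximal
protein pools on chromosome spreads.

## The models

**1:1 binding isotherm.** A titrant X (syringe) is injected in a series of
aliquots into an analyte M in a perfusion cell of active volume V₀. After
cumulative injected volume Vᵢ, total concentrations carry the standard
displacement corrections

    Mᵢ = M₀ (1 − Vᵢ/2V₀) / (1 + Vᵢ/2V₀),   Xᵢ = X_syr (Vᵢ/V₀) / (1 + Vᵢ/2V₀),

the bound concentration follows the single-site quadratic

    [MX]ᵢ = ½ [ (N·Mᵢ + Xᵢ + K_D) − √((N·Mᵢ + Xᵢ + K_D)² − 4 N Mᵢ Xᵢ) ],

and the measured heat of injection i is ΔQᵢ = Qᵢ − Qᵢ₋₁ + (vᵢ/V₀)(Qᵢ+Qᵢ₋₁)/2
with Qᵢ = [MX]ᵢ·ΔH·V₀, normalized per mole of injectant, plus a constant
heat-of-dilution offset. Fitting minimizes least squares over
(N, K_D, ΔH, offset) with multi-start Levenberg–Marquardt; the free energy
splits as ΔG = RT ln K_D = ΔH − TΔS.

**Ring quantification.** Centromeres are detected in the ACA reference
channel (difference-of-Gaussians band-pass, robust threshold, connected
components, intensity-weighted centroids); the marker signal is averaged in
a 3-pixel-wide ring immediately outside each centromere mask, a cytoplasmic
background is subtracted, and per-cell means are normalized to a reference
(rescue) condition.

**Pair profiles.** On chromosome spreads, kinetochores are paired as mutual
closest neighbours capped at 1.5 µm separation; each channel is sampled
along a 2-µm line through the pair centroids centered on the midpoint, and
the marker's full width at half maximum — measured between the *outermost*
half-maximum crossings — separates a narrow single inner-centromere pool
from the broader combination of inner and kinetochore-proximal pools.

**Mass photometry.** Event masses (kD) are summarized by a Gaussian kernel
density estimate; local maxima above a floor become peaks (mean ± SD of
nearby events) and are assigned to candidate stoichiometries by their summed
monomer masses, e.g. a 2:2 assembly of a 108.8-kD dimer and a 94.8-kD dimer
at 203.6 kD.

## Worked example

```python
from cpcquant import itc

scheme = itc.TitrationScheme(cell_conc_uM=5.0, syringe_conc_uM=50.0)   # 200 ul cell,
params = itc.BindingParameters(N=1.0, KD_M=52.83e-9,                   # 0.5 + 15 x 2.5 ul
                               dH_kcal_mol=-6.58,                      # injections, 20 C
                               dilution_offset_kcal_mol=0.05)
iso = itc.simulate_isotherm(scheme, params, noise_sd_kcal_mol=0.05, seed=42)
res = itc.fit_isotherm(iso, scheme)
print(f"K_D   = {res.KD_nM:.2f} +/- {res.se['KD_M']*1e9:.2f} nM")
print(f"N     = {res.params.N:.3f}")
print(f"dH    = {res.params.dH_kcal_mol:.3f} kcal/mol")
print(f"dG    = {res.dG_kcal_mol:.3f} kcal/mol")
print(f"-TdS  = {res.minus_TdS_kcal_mol:.3f} kcal/mol")
print(f"c     = {itc.c_value(scheme, res.params.KD_M, res.params.N):.1f}")
```

prints

```
K_D   = 52.86 +/- 3.00 nM
N     = 1.001
dH    = -6.619 kcal/mol
dG    = -9.761 kcal/mol
-TdS  = -3.142 kcal/mol
c     = 94.7
```

The fit recovers the simulation's dissociation constant (52.83 nM) and
enthalpy (−6.58 kcal/mol) within the scatter set by 0.05 kcal/mol of heat
noise; the stoichiometry refines to 1:1, the free energy splits into a
dominant enthalpic and a smaller favourable entropic term, and the Wiseman
c-value (~95) confirms the scheme determines K_D well.

The same analyses run from the command line via YAML configs, e.g.

```sh
cpcquant itc --config itc.yaml --seed 1 --outdir out/       # isotherm + fit CSVs
cpcquant spread --config spread.yaml --outdir out/ --figures
cpcquant itc decompose --kd-nm 52.83 --dh -6.58             # dG / -TdS only
```

## Layout

- `cpcquant.itc` — titration schemes, isotherm simulation/fitting, thermodynamics
- `cpcquant.synthetic` — ground-truthed image, spread and mass-event generators
- `cpcquant.centromere` — focus detection, ring measurement, normalization, tethering ratios
- `cpcquant.profiles` — kinetochore pairing, line profiles, FWHM
- `cpcquant.massphot` — complex masses, KDE peaks, species assignment
- `cpcquant.stats` — Kruskal–Wallis/Dunn, ANOVA/Dunnett, χ² rates, alignment scoring
- `cpcquant.pipeline`, `cpcquant.cli` — YAML-configured orchestration and the `cpcquant` command

See `docs/methods.md` for the modelling choices, defaults and limitations.
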