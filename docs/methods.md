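# Methods

## Scope and model

`lagoonwq` implements the empirical workflow used to retrieve water-quality
variables of a hypertrophic coastal lagoon from 4-band very-high-resolution
multispectral imagery (blue 450–520 nm, green 530–590 nm, red 630–700 nm,
NIR 752–885 nm at 2.8 m; a NAOMI-class sensor). Five variables are handled:
chlorophyll-a (Chl-a, µg/L), Secchi disk depth (SDD, m), total suspended
matter (TSM, mg/L) and its inorganic/organic fractions (PIM/POM, mg/L),
with the gravimetric identity TSM = PIM + POM.

The workflow has five stages.

**Radiometry.** Raw digital numbers convert to TOA radiance through a
per-band affine calibration. Both conventions found in sensor handbooks
are supported — `L = DN/gain + bias` (default, the NAOMI/Airbus product
convention) and `L = DN·gain + bias` — because the typography of published
calibration equations is genuinely ambiguous between them; the `convention`
field makes the choice explicit and testable. Surface reflectance comes
from inverting the Lambertian TOA model

    L = L0 + (I0 · Tg · T↓↑ / π) · ρ / (1 − S·ρ)

whose closed-form inverse is ρ = y/(1 + S·y) with
y = π(L − L0)/(I0·Tg·T↓↑). The atmospheric terms (path radiance L0,
composite solar irradiance I0 — already scaled by Earth–Sun distance and
solar zenith cosine, since published workflows do not decompose it — gas
transmittance Tg, two-way scattering transmittance T↓↑, spherical albedo S)
are **inputs**: computing them from atmospheric state is a radiative-transfer
problem outside this package's scope. Negative retrieved reflectance over
dark water is retained down to −0.05 and flagged rather than zeroed, so
downstream index computation can exclude it deliberately; values beyond
[−0.05, 1] are clipped with counts recorded. In-situ hyperspectral Rrs is
band-averaged under a rectangular spectral response (no public SRFs exist
for the sensor), treating the spectrum as piecewise linear.

**Matchups.** A field sample pairs with the nearest-in-time scene within a
3-day window (the accepted limit for matchup validity in inland-water
validation practice); equidistant ties break toward the earlier scene, and
dates are calendar days. ROI spectra are per-band means over the water
pixels of a square window grown in steps of 2 from 12×12 until the
water-pixel count enters 100–150 (squares give translation invariance; the
12×12 start yields the canonical 144-pixel ROI on open water). Spectral
stability between image and sampling dates uses a paired two-sided
Student's t-test per band (a pooled two-sample variant is exposed);
identical spectra give t = 0, p = 1, and a zero-variance nonzero shift is
reported unstable with p = 0 by convention. Cross-correlation of field
variables is normality-gated: Shapiro–Wilk at α = 0.05 on both
pairwise-complete margins selects Pearson (both normal) or Spearman,
with n reported per pair.

**Index calibration.** All 18 two-band indices of a 4-band sensor are
enumerated — 12 ordered simple ratios Ra/Rb and 6 normalized differences
(Ra−Rb)/(Ra+Rb), the latter once per unordered pair in a canonical
longer-wavelength-first orientation since reversal is a sign flip any fit
with a free slope absorbs. Each index is fitted with five function
families (linear, exponential, power, logarithmic, polynomial of default
degree 2 — no published degree exists, so the smallest nonlinear one) by
least squares, nonlinear families through their linearizing transforms,
with statistics always computed on the original scale. Validation uses
10-fold cross-validation: one seeded shuffle, near-equal folds, fit on
k−1, score the held-out fold; RMSE/MAE/R² are fold-averaged (pooled
variants are also emitted), bias = mean(predicted − observed) pooled over
held-out predictions, and NRMSE = 100·RMSE/(observed min–max range). The
min–max normalizer is a verified inference: it uniquely reproduces the
published integer NRMSE values from the published RMSEs and ranges for
all five variables (e.g. 100·50.8/(331−21) ≈ 16.4 → "16").

Ranking is by ascending cross-validated RMSE with a **one-standard-error
parsimony rule** (the glmnet/ESL convention): among combinations whose CV
RMSE lies within one fold standard error of the minimum, the fewest-
parameter fit ranks first, then lower RMSE, then higher R², then lexical
index name. Without it, a degree-2 polynomial that nests the true linear
relation wins on CV noise alone in roughly a third of repetitions, which
makes "the search recovers the generating algorithm" a coin flip rather
than a property; with it, recovery is essentially certain on synthetic
truth. Plain RMSE ordering is available via `parsimony="none"`. Samples
with undefined index values (zero denominators, flagged bands) are
dropped per combination with a count, never imputed; domain-violating
family/index pairs (e.g. power on negative indices) are recorded as
failures rather than aborting the search.

**Registry and mapping.** The five published 4-band models are stored
verbatim (Chl-a = 323.77·ND(B4,B1) + 198.95; SDD = −0.2539·ND(B4,B1) +
0.2608; TSM = −38.259·(B1/B4) + 129.38; PIM = 116.08·ND(B3,B1) + 31.36;
POM = −18.775·(B3/B4) + 70.925), alongside the five Sentinel-2 Albufera
models on named wavelengths (R490…R783), including the three-band Chl-a
model TBDO = R740·(1/R665 − 1/R705). The TSM working range is stored as
39–136 mg/L: the summary table prints 50–136, but only 39–136 (stated in
the results text) reproduces the printed NRMSE of 11%. One Sentinel-2
formula prints R704 once; it is treated as a typo for R705. Water is
masked by NIR reflectance < 0.2 (hypertrophic water stays well below
vegetated-land NIR; no published threshold exists, so it is a parameter).
Model outputs are clamped to a valid range — the observed calibration
range with 50% headroom above the maximum, floored at 0 (SDD at 0.01 m) —
with clamp counts recorded; empirical regressions extrapolate poorly and
published maps use bounded palettes. Maps order by meteorological season
(DJF/MAM/JJA/SON), then date.

## Synthetic data: what it emulates and what it does not

No field or image data were deposited with the study this workflow
reproduces, so a generator stands in for the campaigns.

**Field campaigns.** A latent trophic factor t ~ U(0,1) drives every
variable through u = λ·t + (1−λ)·ε with ε ~ U(0,1) independent, mapped
linearly onto the observed ranges (Chl-a 21–331 µg/L, SDD 0.16–0.42 m
decreasing in t, PIM 2–75, POM 7–60 mg/L); TSM = PIM + POM exactly, and
draws whose TSM leaves 39–136 mg/L are rejected and redrawn. Loadings
were set analytically from
corr(u_a,u_b) = λ_aλ_b/√((λ_a²+(1−λ_a)²)(λ_b²+(1−λ_b)²)):
λ = 0.7 for Chl-a and SDD reproduces the observed −0.845 Chl-a–SDD
correlation, and λ_PIM = 0.45, λ_POM = 0.85 target the observed ≈0.87
TSM–POM correlation (measured ≈ −0.83 and ≈ 0.86 at n = 1000 after
rejection). The published scatter magnitudes are unknown; the independent-ε
construction is the modelling choice, with reflectance noise defaulting to
a 5% coefficient of variation.

**Reflectance.** Spectra are synthesized by inverting the two headline
published equations: the Chl-a equation fixes ND(B4,B1) around a blue
baseline B1 = 0.08 (plausible for bright sediment-laden hypertrophic
water, and low enough that even the brightest water keeps B4 below the
0.2 water-mask threshold), and the POM equation fixes B3/B4. B2 is the
B1/B3 mean plus noise — no published algorithm uses it. The three index
constraints (Chl-a, POM, PIM) would over-determine three bands, so only
the Chl-a and POM constraints hold exactly; the PIM relation holds only
statistically through PIM = TSM − POM. Consequently only the Chl-a and
POM models round-trip exactly (to < 1e-6 relative at zero noise), which
is the designed trade-off: exact recoverability for the two headline
models, realism for the rest. Any implied reflectance outside (0, 1)
raises an error naming the band — e.g. POM = 70.925 mg/L implies B3 = 0.

**Scenes.** Smooth latent fields (seeded Gaussian noise smoothed at a
configurable 12-pixel correlation length, rank-normalized to U(0,1))
drive per-pixel variables over water; a second smooth field thresholded
at the water-fraction quantile shapes the water body; land pixels carry a
fixed bright-NIR spectrum (B4 = 0.35). Reflectance runs forward through
the Lambertian model and the calibration in reverse to integer DN at a
default 12-bit depth (typical for this sensor class; configurable). The
default calibration spans, per band, the radiance between ρ = 0 and a
per-band maximum (0.21/0.25/0.26/0.27) sized just above the brightest
expected surface — land NIR saturates at the top DN, as real detectors do
over bright targets — so quantization steps stay small where water
signals live: the end-to-end chain simulate → correct → published Chl-a
model reproduces the truth raster to better than 1% everywhere at zero
noise, 12-bit quantization being the only error source. (The POM chain's
worst-case quantization error slightly exceeds 1% at the 7 mg/L end of
the range, where the B3/B4 ratio is most sensitive; it stays within the
propagated per-pixel quantization bound.)

The generator does **not** emulate: IOP-based radiative transfer in
water, sun glint, adjacency effects, clouds, geolocation error, or
sub-daily time differences. Passing tests therefore demonstrate the
correctness and self-consistency of the pipeline's algebra, statistics
and selection machinery — not retrieval skill on real imagery.

## Numerical choices and degenerate inputs

- Forward/inverse Lambertian transfer is exact algebra; round trips hold
  to 1e-12 across the physical parameter grid. ρ ≥ 1/S raises.
- Zero index denominators yield NaN with a warning (a raster pixel must
  not abort a map); fits drop non-finite pairs and require ≥ 3.
- Constant x or constant y is rank-deficient and raises; a constant
  target therefore fails every combination and the search reports the
  per-combination failure log.
- Cross-validation requires n ≥ k and suggests reducing k otherwise;
  n = 21 with k = 10 gives folds of size 2 and 3 summing to 21.
- R² of a held-out fold with fewer than 2 points or zero variance is
  skipped in the fold average; fold-mean R² and pooled R² are both
  reported since the reference tooling's choice is unknown (fold-mean is
  the default).
- Ties in ranking are broken deterministically (stable mergesort on
  RMSE, then R², then index name).
- Scene rasters carry a plain (x0, dx, y0, dy) affine transform; raster
  IO is multiband TIFF with a JSON metadata tag (state, band labels,
  transform, units, provenance).

## Problem sizes

Simulated studies use n = 22 samples (the emulated campaign size) for
pipeline demonstrations, n = 200 for recovery experiments, n = 500–1000
for statistical-consistency checks, and 100×100–120×120-pixel scenes —
sizes at which every documented property is already stable.

## Known limitations

- The atmospheric terms are trusted inputs; no closure against a
  radiative-transfer code is possible here.
- The published 22-sample calibration database is not public, so the
  published R²/RMSE values themselves are registry metadata, not
  recomputable quantities; desk-reproducible consistency checks (NRMSE
  definition, intercepts, fold structure) stand in for them.
- Sentinel-2 models require 6-value named-wavelength spectra; no
  cross-sensor spectral resampling is attempted.
- The linearizing-transform fits minimize error in transformed space
  (standard practice for these regressions), which differs from direct
  nonlinear least squares when noise is large.
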