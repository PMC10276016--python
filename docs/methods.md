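# Methods

This note documents the models, conventions and numerical choices behind
`foveamorph`, and what its synthetic validation does and does not show.

## Coordinate and scan conventions

A B-scan raster is indexed `[axial, lateral]` with axial pixel 0 the most
anterior (vitreous) row, increasing posteriorly. A-scan index runs
temporal→nasal for right eyes (OD) and nasal→temporal for left eyes
(OS); thickness profiles resolve this into a signed lateral axis in µm
with nasal positive for both eyes, so mirroring a scan and toggling
laterality is an exact no-op for every derived quantity. Default
geometry follows macular-cube conventions: 512 A-scans over 6 mm
(11.72 µm/A-scan) and 1024 axial pixels over 2 mm (1.95 µm/px); all of
it is configurable.

Boundary polylines are stored as **float** pixel positions, one value
per A-scan for each of ILM, GCL+ inner/outer, ONL inner/outer, IS/OS and
posterior RPE, validated to be single-valued, inside the raster and
ordered anterior→posterior. On ingestion, gaps of ≤ 3 consecutive
A-scans per boundary are linearly interpolated and logged; longer gaps
and crossing boundaries are rejected with the offending A-scan named.

## Flattening

Scans are flattened to the posterior RPE by shifting each A-scan column
by the integer nearest to `median(RPE) − RPE[i]` (`floor(x + 0.5)`
rounding, which makes the transform idempotent). Because all boundaries
in a column share one integer shift, every inter-boundary distance —
hence every thickness — is preserved to float-addition precision
(~10⁻¹² px); no resampling or interpolation touches the data. Thickness
and IS/OS elevation are boundary *differences* and therefore
shift-invariant, so metric extraction gives identical results on
flattened and unflattened annotations; flattening matters for image
display and any raster-based processing.

## Landmarks and parameters

- **Foveal centre (FC).** A-scan of maximum smoothed IS/OS elevation
  (RPE − IS/OS) within ±750 µm of the scan centre. If the elevation
  range in the window is < 2 µm the IS/OS peak is considered
  uninformative and the A-scan of minimum smoothed retinal thickness is
  used instead (flagged). Ties resolve toward the window centre; an
  exact symmetric tie resolves to the temporal candidate (documented,
  arbitrary). An FC on the window edge is flagged.
- **Foveal wall maximum (FWM).** Per side, the A-scan of maximum
  smoothed GCL+ thickness with 300–3000 µm lateral distance from FC.
  The inner bound keeps thick-centred immature eyes from placing the
  "rim" at the fovea itself; the outer bound stays within a 6-mm scan.
  Ties resolve toward FC. If the outer window edge attains (or ties)
  the maximum the rim may lie outside the scan and the eye is flagged
  rather than rejected — scan-quality triage is a human step upstream of
  this pipeline.
- **Smoothing.** A centred moving average over 5 A-scans (~59 µm,
  edge-replicated) is used **only** for argmax localization; all
  reported values are read from the raw profile, so degenerate cases
  (zero GCL+ at FC) are exact. Window 1 disables smoothing.
- **Parameters.** `GCL+@FC`, `ONL@FC`, `RT@FC` at the FC A-scan;
  `RT@FWM` at each rim; `FD = mean(RT@FWM) − RT@FC`, an identity that
  holds exactly on every output record; `GCL+@Q2Q` is the mean of GCL+
  at the two quarter points located 25 % of the FC→FWM distance from FC
  on each side (nearest A-scan). Retinal thickness is defined ILM →
  posterior RPE, consistent with the flattening reference.

## Normative analysis

Control limits are the control sample mean ± 2 sample SD (n−1
denominator): upper limits for thickness parameters, a lower limit for
FD. Outside means strict exceedance; equality counts as within. Limits
are stored at full precision and *displayed* at 0.1 µm.
`compare_with_published` checks recomputed limits against externally
printed one-decimal limits at printed precision (|Δ| ≤ 0.05 µm) and
flags mismatches instead of adopting them — the published ONL@FC limit
(136.9) is internally inconsistent with its own printed mean/SD
(107.78 + 2·12.43 = 132.64) and is flagged by exactly this check.
Outside-proportions carry exact Clopper–Pearson 95 % intervals.

With normally distributed parameters, ~2.3 % of an independent control
cohort falls outside its own mean + 2 SD limit; the test suite verifies
the simulated false-positive rate per parameter lies in [0.01, 0.04] at
n = 10 000.

## Cohort simulator

Four parameters are sampled directly — `GCL+@FC`, `GCL+@Q2Q`, `ONL@FC`,
`FD` — from a **Gaussian copula with left-truncated-normal marginals**
(truncation at 0 µm; inverse-CDF transform of a latent standard MVN).
The copula, rather than joint rejection sampling, is deliberate: with
rejection, the strong truncation of central GCL+ (its mean sits ~1.2 SD
above zero in immature eyes) would drag every correlated marginal
upward; the copula keeps each marginal exactly the stated truncated
normal. Note a truncated normal's mean exceeds its location parameter —
e.g. location 13.95, scale 11.66 gives a realized mean ≈ 16.4 µm.

`RT@FC` is **structural**: GCL+@FC + ONL@FC + a residual-layer
thickness (INL, OPL, IS/OS and RPE bands) drawn independently as a
truncated normal. The residual means are fixed so the group RT@FC means
are reproduced exactly (control 97.11 ± 8, EPT 82.62 ± 10 µm); the
residual is floored at 50 µm because those layers cannot vanish in an
intact retina. Structural RT guarantees RT ≥ GCL+ + ONL per eye and —
with `RT@FWM = RT@FC + FD` plus a small nasal/temporal split
(half-difference ~ N(0, 4 µm)) — makes the FD identity hold by
construction. A published RT SD for the immature cohort (4.49 µm) is
incompatible with its own printed range and is not calibrated to.

Default correlations (sampled parameters): immature cohort 0.7 among
thickness parameters and −0.7 with FD; control cohort decouples central
GCL+ (0 with everything except 0.4 with Q2Q) and keeps only weak
structure elsewhere. RT correlations are induced by the structural sums
and reproduce the qualitative published pattern: strong positive
thickness coupling and negative FD coupling in immature eyes, with
ONL–RT the strongest pair in both groups and rim thickness essentially
uncoupled. Cohort defaults: 92 control eyes (all left) and 37 immature
eyes (both eyes of ~21 subjects, `subject_id` recorded to allow
clustering sensitivity analyses, which the pipeline itself does not
perform).

## Boundary construction (inverse problem)

Given target metrics, `build_boundaries` constructs a raised-rim pit:

- Retinal thickness per side: `RT(u) = RT@FC + (RT@FWM − RT@FC)·s(u)`
  with `u` = |lateral − pit centre| / rim radius, `s(u) = sin²(πu/2)`
  inside the rim (zero slope at centre and rim, so small landmark
  errors perturb RT only to second order) and a Gaussian decay to a 0.9
  shoulder beyond.
- GCL+ per side: a monotonicity-preserving cubic (PCHIP) through
  (0, GCL+@FC) with zero slope, (0.25, Q2Q) and (1, annulus peak =
  max(GCL+@FC, Q2Q) + 25 µm), decaying to 75 % of the peak beyond the
  rim so the in-window maximum sits exactly at the rim. This handles
  both immature (rising) and mature (dip-then-rise) central profiles.
- ONL: Gaussian mound peaking at the pit centre (σ = 500 µm, shoulder
  60 µm); IS/OS band: 35 µm plus a 10 µm Gaussian bump (σ = 80 µm) at
  the pit centre, which is what makes the IS/OS peak mark the FC.
- The remaining thickness budget `RT − GCL+ − ONL − IS/OS-band` is split
  15 % RNFL, 55 % INL+OPL, 30 % inner-segment gap; if it goes negative
  anywhere the targets are rejected with the constraint named.

Default rim radii are ~1000 µm (nasal) and ~1060 µm (temporal), jittered
per eye together with a ±30 µm pit-centre offset. Round-trip accuracy
(generator targets → boundaries → extractor) is ≤ 1 µm for all thickness
parameters and ≤ 2 µm for FD across mixed 100-eye cohorts, typically
≤ 0.03 µm; Q2Q is recovered to ~0.6 µm, limited by quarter-point
rounding to the A-scan grid.

## Rendering

Rasters are piecewise constant per region (vitreous, RNFL, GCL+,
INL/OPL, ONL, inner segments, OS+RPE, choroid) with configurable
reflectivities, multiplied by unit-mean gamma speckle with SD =
`noise_level` (shape 1/noise²). This is a deliberately parameter-light
stand-in: no point-spread function, depth attenuation, vascular shadows
or motion artefacts are modelled. Images are exported as 16-bit
PNG/TIFF with a JSON sidecar carrying the physical scales.

## Statistics layer

Shapiro–Wilk (scipy, verified against an independent reference
implementation to 10⁻⁶), pairwise-complete Pearson correlations with
two-sided p-values and α = 0.001 flags (verified against the
definitional formula to 10⁻¹²), per-eye layer proportions (additive by
construction: (GCL+ + ONL)/RT = GCL+/RT + ONL/RT exactly), and
two-sided independent t-tests with Welch–Satterthwaite correction,
accepting either raw data or summary statistics (mean, SD, n per group)
so published subgroup tables can be re-derived. Degenerate zero-variance
comparisons return t = 0, p = 1 for equal means. Missing data: pairwise
deletion for correlations, listwise per variable for t-tests.

## Pipeline and determinism

One root seed fans out to per-stage seeds via `SeedSequence.spawn`
(recorded in `provenance.json`), so stages are independently
reproducible and full reruns are bit-identical for all CSV outputs.
Figures are regenerable artefacts and excluded from the bit-exactness
guarantee. Pipeline problem sizes default to the cohort scale of the
normative design (92 + 37 eyes, boundaries/images for a handful of eyes);
the validation suite uses 10 000-eye cohorts for distributional checks
and 100 eyes for boundary round trips, sizes at which binomial and
standard-error noise is far below the tolerances being asserted.

## What the synthetic validation does not show

The generator realizes the *marginal and correlation* calibration of the
reference cohorts under normality assumptions, not their empirical
distributions: published outside-percentages (68–76 % for thicknesses)
depend on the real cohort's shape and are reproduced only qualitatively
(majority outside). Boundary annotations are taken as ground truth —
manual or automatic segmentation error, media opacity, signal-strength
variation and eye motion are all out of scope, so passing round-trip
tests demonstrates correctness of the *measurement definitions*, not
robustness of segmentation on clinical images.
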