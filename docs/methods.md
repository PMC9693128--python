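# Methods

This note documents the models behind `pelletpat`, the default parameter
choices and their rationale, the numerical decisions, and what the
synthetic data generator does and does not emulate.

## Process and monitoring model

A Wurster coating run sprays an aqueous polymer suspension (dry-matter
fraction ω) at rate R [g/min] onto a load m_cores [g] of drug-layered
pellets. A fraction γ of the sprayed solids (the process yield) deposits as
film; the rest is lost to spray-drying and wall effects. The in-line
monitor sees only the per-minute median diameter D50 of the circulating
pellet population and estimates film thickness as half the D50 increase
over a reference.

### Film growth: exact shell mass balance

The simulator does not use a thin-film linear growth law. Deposited dry
mass after τ minutes of spraying is γ·ω·R·τ; dividing by the film density
ρ_coat and the pellet count N = N_m·m_cores gives the film volume per
pellet, and the thickness follows by inverting the spherical-shell volume
on the monodisperse-equivalent core radius r₀ = √(SSA_m/4πN_m):

    h(τ) = ( r₀³ + 3v(τ)/4π )^{1/3} − r₀ ,   v(τ) = γωRτ / (N ρ_coat)

This closed form is what makes the pipeline self-consistent: the
film-density estimator (`metrics.coating_density`) inverts exactly the
same geometry, so a simulated run stopped at thickness h returns the
configured ρ_coat to floating-point precision, and the consumed-suspension
prediction for the reference P4 parameterisation (441.5 g at h = 8 µm)
matches the recorded 442 g within 0.2 %. A thin-film approximation
(surface × h) would be ~1.5 % off at an 8 µm film on ~540 µm cores, which
is why the shell form is used throughout. h(τ) is consequently slightly
sub-linear in time.

### Warm-up dip and the reference

Early in a run the pellets shrink by a few micrometres (attrition,
over-drying) before film growth dominates, so the D50 series has an
initial minimum which the instrument uses as its thickness reference. The
simulator models this as a deterministic linear shrink of `dip_depth`
(default 6 µm in diameter) over `dip_duration` (default 6 min) applied to
every particle, with spraying and deposition starting at the end of the
dip. Starting the consumption clock with growth keeps the mass balance
exact (deposited = γ·ω·consumed, a tested 1e-6 invariant) and makes
(D50(t) − D50_ref)/2 an unbiased estimator of true thickness once the
reference is taken at the dip bottom. The dip magnitude and shape are a
stand-in — real dips are stochastic and partially recoverable — but the
monitor only needs the structural feature: a clear early minimum.

### Frame sampling and uncertainty

Each frame draws a fresh lognormal core sample (median
`core_median_diameter`, default 1094.2 µm; coefficient of variation
`core_diameter_cv`, default 0.025) of size uniform in
`frame_particle_count_range` (default 25 000–50 000, the instrument's
stated per-minute population), shifted by 2·h(t) and the dip. D50 is the
sample median; the reported SE is the standard error of the *mean*
diameter (SD/√n), used by the instrument as the uncertainty proxy for the
median. The propagated thickness SE is ½√(SE_ref² + SE_t²).

The CV default comes from the core material: neutral cores are a
700–810 µm sieve cut, an absolute spread of roughly width/4 ≈ 27 µm, which
layering preserves while the median grows to ~1094 µm — CV ≈ 0.025. This
single choice controls all monitor noise; it was fixed from the sieve
argument, not fitted.

### Endpoint detection

The endpoint is the first thickness point at or above target (≥, so an
exact hit counts), with no smoothing — matching manual operation where the
run is stopped at the first crossing. An optional `consecutive=k` rule
guards against single-frame outliers but defaults to k = 1. The simulator
additionally supports a `true_thickness` endpoint (stop exactly at the
analytic crossing of the deposited thickness — the deterministic
mass-balance endpoint used for reproduction runs) and a `mass` endpoint
(fixed suspension quantity, the classic no-PAT operation). Unreachable
endpoints (e.g. zero spray rate) are reported as a distinct no-endpoint
condition after `max_duration`.

Measured on the defaults (200 seeded runs): the estimate stays within
3·SE of true thickness on ≈98 % of coating-phase frames, and the detected
endpoint falls within one frame interval of the analytic crossing in
≈92 % of runs. During the warm-up dip the estimator reports shrinkage, not
film, so those frames are excluded from the coverage statement.

## Geometry and density metrics

Pellets are treated as spheroids with the maximum Feret a as polar axis
and the perpendicular Feret b as equatorial diameter: V = (π/6)ab²,
surface taken as that of the volume-equivalent sphere (d_eq = (ab²)^{1/3}).
SSA_V = ΣS/ΣV; granular density ρ = m/(N·V̄); SSA_m = SSA_V/ρ holds as an
exact identity by construction and is verified per batch. Unit conversions
(g↔mg, µm³↔cm³) are exact constants.

The film-density estimator interprets "suspension transferred to pellets"
as the yield-corrected sprayed mass γ·m_susp. This is the interpretation
under which the estimator reproduces all five reference film densities
(1.76, 1.78, 1.72, 2.24, 2.23 g/cm³) from the printed process and core
tables to ±0.01; using the sprayed mass uncorrected gives ≈2.5–2.8 g/cm³.
r₀ is always derived from the *core* batch's SSA_m and N_m, not from the
coated pellets'. Note these densities are knowingly slight overestimates —
cores also shrink during drying, and no correction is applied.

Process yield may exceed 1 on inconsistent inputs; it is returned as
computed with a `YieldWarning` rather than clipped, since an impossible
yield is diagnostic information.

## Imaging

Segmentation is a global threshold (Otsu default, fixed value supported)
plus connected-component labelling; border-touching regions are excluded
(truncated projections would bias calipers low) and sub-`min_area_px`
regions dropped, both with counts reported. The maximum Feret is the exact
convex-hull diameter of the region's pixel centers (the rotating-calipers
maximum); its *direction* is taken from a 0.5°-step caliper sweep, which
is far more stable under pixel quantisation than the maximising chord
(whose angle can tilt by several degrees on elongated regions and inflate
the perpendicular width); the perpendicular Feret is the hull width at 90°
to it. CED = 2√(area/π) with area = pixel count; no sub-pixel refinement.

Calipers are reported uncorrected: with anti-aliased rendering and a
half-intensity threshold, region edges land on the particle outline, and
measured biases are small and slightly negative (mean ≈ −0.2 px for the
max Feret, ≈ 0 for CED over rendered 20–100 px circles/ellipses). The
synthetic renderer draws 256-gon ellipse approximations at 8× resolution
and box-downsamples, giving coverage-accurate anti-aliasing, and returns a
ground-truth table per particle. Overlapping-particle splitting is out of
scope; the renderer only produces non-overlapping scenes.

## Dissolution model and analytics

Release through the film follows a reservoir-membrane law
dm/dt = (S/h)·K·Δc with K = k/ρ_coat — permeability inversely proportional
to film density, the mechanism by which denser films slow release. While
undissolved drug remains (up to `sink_fraction`, default 0.9 of the dose)
the gradient is constant and release is linear; afterwards the residual
dissolved reservoir depletes exponentially with the time constant that
makes dm/dt continuous. The closed form is tested against a fine-step
explicit integration. Default parameters (surface = 260 mg sample ×
SSA_m, Δc = 2×10⁻¹⁰ mg/µm³, k = 0.30 µm²·(g/cm³)/s) are calibrated so the
reference 8 µm / 1.76 g/cm³ film releases ≈93 % of a 100 mg dose in 6 h,
the intended near-90 % operating point. Measurement noise is additive
Gaussian (default SD 0.5 %-points), clipped to [0, 100] and made
non-decreasing.

f2 uses all sampled time points by default (the 2,3,4,5,6 h grid); the
regulatory convention of truncating after both profiles pass 85 % release
is available behind a flag but off. Similarity grouping is by connected
components of the f2 ≥ 50 graph with deterministic ordering. The
correlation screen is the plain Pearson coefficient per covariate with a
configurable strong-correlation flag at |K| > 0.9; constant covariates are
reported as undefined (NaN), not dropped silently.

The covariate generator emulates the water-loss mechanism: the 6 h release
is base − slope·ΔLOD + noise with slope 11 %-points per %-LOD (the spread
between low- and high-water-change runs) and ΔLOD uniform on 0.1–1.3 %.

## What the synthetic data does not capture

Real instrument streams have inter-frame correlation (the same pellets are
re-imaged), occasional window-fouling artefacts, and agglomeration events;
frames here are independent fresh samples. The LOD relaxation
(first-order toward `lod_equilibrium`) is a non-mechanistic stand-in that
produces plausible ΔLOD values for the correlation screen, not a
psychrometric model. Dissolution profiles come from one idealised release
law, so passing tests demonstrate the analytics, not the pharmacology.
Wet-vs-dry thickness is represented only by an optional multiplicative
`drying_shrink` factor (default 1.0).

## Numerical and interface decisions

- All randomness flows from one `numpy` Generator seeded by the config;
  identical configs are bit-identical on re-run.
- Negative thickness estimates are reported, never clipped, so the dip is
  visible in monitor output.
- Reference selection: minimum D50 within a configurable window (default
  10 min), earliest frame on ties.
- Problem sizes in stochastic tests (200 seeds for monitor and imaging
  recovery, 25 seeds in unit-level bias checks) keep the default suite
  under half a minute while leaving binomial noise well below the margins
  being asserted.
- CSV formats carry a `# pelletpat <kind> v1` header line; configs are
  flat YAML key/value files with unknown keys rejected by name.
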