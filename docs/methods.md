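# Methods

This note documents the models, defaults and numerical choices behind
`waxstrace`, and what the synthetic validation does and does not establish.

## Geometry and reduction

Momentum transfer is computed exactly for a flat detector:
2θ = arctan(r/L), q = 4π sin(θ)/λ, with λ = 1.2398420/E (keV·nm). Defaults
follow a synchrotron WAXS setup: sample–detector distance L = 170.21 mm,
photon energy 12.4 keV (λ ≈ 0.09999 nm), square 0.172 mm pixels
(Pilatus-class). The mapping is strictly monotone in r; its inverse
(`q_to_radius`) round-trips to better than 1e-9 relative error and is used
for ring-position checks. The printed instrument q-range (0.72–45 nm⁻¹)
depends on the beam-center placement on the real detector, which is a
config input here; the simulated default detector (700×700 pixels, beam at
the center) covers the full 3.25–21 nm⁻¹ analysis grid.

Azimuthal integration assigns each unmasked pixel to the q bin containing
its center — bins half-open [lo, hi), final bin closed, bin label the
midpoint — and reports the **mean** counts per pixel (not the sum), so bins
with different pixel populations are comparable. Poisson errors propagate
through the mean: σ_b = sqrt(Σ counts)/n_b. This binning rule is declared
bit-exactly and enforced against an independent per-pixel double-loop
oracle. Under count scaling I → αI, intensities scale by α and so does σ
(the scaled-counts convention; σ is derived from the summed counts in the
bin, which are assumed to be raw photons before any scaling). Geometric
(solid-angle) and absorption corrections are exposed as an optional
multiplicative pixel-weight map, off by default: no formula is imposed,
the weight map is the extension point. Beam centering is taken from the
geometry config; there is no auto-centering.

Masks combine a circular beamstop shadow (radius in mm; radius 0 means no
beamstop), listed dead pixels and user pixels, each tracked by provenance
bits; dilation uses a disk structuring element and only ever adds
exclusions. Frame normalization scales counts by
(reference_monitor/monitor)/exposure, recording the applied factor;
repeated exposures at one position are averaged pixelwise (10 frames of
100 ms is the emulated acquisition pattern).

## Composite peak model and fitting

Profiles are fitted with y(q) = Σᵢ Aᵢ exp(−(q−μᵢ)²/2σᵢ²) + B/q⁴ + C. The
two physical peaks seed at 13.5 and 18.0 nm⁻¹ and are refined to the local
maximum of a lightly smoothed profile within ±1.5 nm⁻¹; C seeds at the
window minimum, B by one-parameter least squares on the lowest-q decile,
amplitudes from the smoothed profile above that baseline, widths at
1.0 nm⁻¹. The default fit window is the biomarker window 10–20.5 nm⁻¹;
full-grid fitting is available through the window argument/config.

The fit minimizes Σ((y−ŷ)/σ)² with bounds A ≥ 0, B ≥ 0, σ ∈ [0.2, 5] nm⁻¹,
μ within ±2 nm⁻¹ of its seed. Optimization uses bounded least squares with
an analytic Jacobian (cost tolerance 1e-10, at most 10⁴ evaluations).
An unbounded Levenberg–Marquardt solve is tried first and accepted only
when its solution lies strictly inside the bounds (an interior
unconstrained optimum is also the bounded optimum); otherwise the bounded
trust-region solver runs. Parameter uncertainties are the square roots of
the diagonal of (JᵀJ)⁻¹ scaled by the reduced chi-square; a singular
Jacobian marks them unavailable. Non-convergence sets a flag rather than
raising, and peaks are relabeled by sorted center before any downstream
assignment, which resolves ties when two centers land in one window.

**The third peak.** The model sums up to three Gaussians while the two
physical peaks carry the science; the default variant allows a third,
*broad* Gaussian (width bounded to 2.5–5 nm⁻¹, position free in the
window) that can absorb slowly varying residual background. It is kept only
when its fitted amplitude exceeds its own 1σ uncertainty. Because the full
3-peak solve is expensive and usually rejected, a linearized amplitude
screen runs first: the converged 2-peak Jacobian is augmented with the
broad component's profile and the normal equations give the amplitude
estimate and standard error directly. Only a significant screen triggers
the full 3-peak fit (warm-started from the 2-peak solution, evaluation
budget capped), after which the same amplitude-vs-uncertainty drop rule
applies, plus a degeneracy guard: if adding the broad component drags a
seeded peak center more than 1 nm⁻¹ from its 2-peak position, the broad
component is re-describing a physical peak and the 2-peak solution is
kept. On nominal synthetic data the screen's keep/drop decisions were
concordant with the always-fit-3-peaks procedure in 100/100 trials. The
width floor also prevents the broad component from impersonating the
(narrower) physical peaks. A side effect worth knowing: a *genuine* broad
third component with width ≈ 3 nm⁻¹ inside a 10.5 nm⁻¹ window is nearly
degenerate with C, B/q⁴ and the peak tails at realistic counting noise,
so it is rarely detectable — that is a statement about identifiability,
not a bug.

The power-law diagnostic (`fit_power_law_exponent`) checks the amorphous
term: the negated slope of log(I−offset) vs log(q). Points non-positive
after offset removal are excluded (Poisson tails at high q produce zeros),
and the fit is count-weighted (w = counts ≈ 1/Var[log I]), which suppresses
the low-count tail whose log is biased. Noiseless power laws are recovered
exactly; at default noise the quartic exponent is recovered within 0.2.

"Peak intensity" is interpreted as the fitted Gaussian height Aᵢ; the
integrated area A·σ·√(2π) is reported alongside in every biomarker record,
with height as the primary quantity.

## Preprocessing

Declared stage order: remove_nan → subtract_background (optional) →
restrict_q → l1_normalize → clean_profiles. L1 normalization divides
intensity and σ by Σ|I| over the profile's current window — i.e. over the
3.25–21 nm⁻¹ analysis window after restriction — treating the normalizer
as a constant (its own variance is an O(1/n_bins) correction). Whether a
study normalizes before or after windowing changes only a global factor
per profile; the order here is fixed and exposed in config.

Cleaning is an automated, fully reported surrogate for manual curation:
a profile is dropped when its finite fraction is below 0.95, its total
absolute mass is non-positive, or its L1 distance to the median profile of
its (group, lobe) stratum exceeds median + 5·(1.4826·MAD); distances are
computed on internally normalized copies so the rule is scale-free. Every
decision and threshold appears in the cleaning report, and the pipeline
manifest conserves counts (input = retained + rejected) at every stage.
On nominal synthetic cohorts the rules retain ≥ 99% of profiles; the rare
rejection is an animal whose composition jitter draw is extreme, which is
the rule working as designed. Group averaging uses the arithmetic mean
(median available via the `statistic` argument) with the standard error of
the mean as σ.

## Synthetic cohorts: what they emulate

The generator is the package's study-conditions definition, not a tuning
surface. Control-group truth (not printed in any reference, fixed here
once): lipid peak A = 1.0, μ = 13.5, σ = 1.2; water peak A = 0.6,
μ = 18.0, σ = 1.5; B = 120, C = 0.06 — the background then carries ≈ 30%
of the total signal on the analysis grid (within the intended 20–40%
band), and the peaks are resolved yet overlapping. Disease progression
multiplies the left-lobe amplitudes only (positions and widths fixed):

| group | lipid × | water × | height ratio (lipid/water) |
|-------|--------:|--------:|---------------------------:|
| Control | 1.00 | 1.00 | 1.67 |
| Day2    | 0.97 | 1.03 | 1.57 |
| Day4    | 0.92 | 1.10 | 1.39 |
| Day7    | 0.75 | 1.25 | 1.00 |
| Day16   | 0.45 | 1.60 | 0.47 |

Day 2/4 sit near baseline, the two Gaussian heights are exactly equal at
Day 7, and the water peak strictly dominates by Day 16; the right lobe is
always (1.0, 1.0). Counting noise is Poisson with an expected
10⁵ total counts per profile (a realistic order for an azimuthally
averaged, background-dominated tissue exposure; per-point expectations run
from ~40 to ~650 counts).

Inter-animal variability is lognormal and decomposes into a shared
per-(animal, lobe) brightness multiplier with CV 0.15 applied to the whole
profile (thickness/positioning/illumination — exactly what L1
normalization removes) and independent per-peak composition jitter with
CV 0.05 (which survives normalization and drives the biomarker's
between-animal spread). A single undecomposed CV 0.15 per amplitude would
make the animal-level ratio CV ≈ 0.21, large enough that strict
monotonicity of a five-animal group mean across the Day2→Day4 step would
fail in a sizable fraction of cohorts; the decomposition reflects that most
of the amplitude variation in practice is common-mode brightness.

Control animals are assigned sacrifice days cycling over (2, 4, 7, 16) so
temporal control matching is exercised; the cohort spec also accommodates
the alternative two-controls-per-time-point design. All randomness derives
from one root seed through named substreams (per animal/lobe/position), so
adding a stage never shifts another stage's draws and all outputs are
bit-reproducible.

Simulated 2D frames place the same composite model on the detector
radially (circularly symmetric in expectation), scaled to a target total
count, Poisson-sampled, with beamstop and random dead-pixel masking.
Azimuthal integration of a simulated frame correlates > 0.99 with the
generating 1D model at ≥ 10⁶ counts.

**What passing does not show.** The generator has ideal circular symmetry,
no detector panel gaps, no polarization or absorption physics, no
anisotropy, Gaussian-only line shapes, group-independent peak positions
and widths, and an effect model chosen to be recoverable. Passing the
suite demonstrates the pipeline's correctness and statistical calibration
under these conditions; it does not validate the biological effect sizes,
the manual-cleaning equivalence, or performance on real detector
artifacts.

## Problem sizes and trajectory statistics

The trajectory study simulates complete cohorts (5 groups × 5 animals ×
2 lobes × 25 positions = 1250 measurements) and fits every measurement
individually, repeated over 50 seeds — 62 500 fits — which the screened
fitting strategy completes in a few minutes on one core. Aggregation is
positions → animal mean → group mean ± sd (n = animals), matching the
convention that published error bars reflect animal-level replication; how
the 25 grid positions collapse into an animal value is a design choice
(arithmetic mean here). Records that fail fitting or peak assignment are
excluded and counted in the report. The ratio direction (lipid/water,
falling with progression) is printed in every report header so it can
never be silently inverted. Both the ratio trajectory and the per-peak
height trajectories are emitted, since either view may be wanted.

## Known limitations

- The broad third component is near-unidentifiable at realistic counts in
  the default window (see above); users fitting data with true broad
  features should widen the window or raise counts.
- The MAD cleaning rule needs ≥ 3 profiles per stratum and a shared grid
  within the stratum; otherwise the shape rule is skipped (the finite and
  mass rules always apply).
- First-order ratio error propagation assumes small relative height
  errors; it was verified against Monte-Carlo resampling at the ~5–8%
  error level typical here.
- σ under background subtraction combines in quadrature, which assumes
  independent Poisson realizations of profile and background.
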