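# Methods

## The model

`trapquench` analyzes concentration self-quenching of fluorophore-lipids in
supported lipid bilayers under the *transfer-to-trap* model. Fluorophores at
surface number density C_N (nm⁻²) are treated as a homogeneous 2D Poisson
point process in one leaflet. Two fluorophores transiently closer than a
critical radius R_C form a non-fluorescent trap ("statistical pair" — no
aggregation or ground-state dimer is assumed). The probability that a given
fluorophore has at least one neighbor within R_C is

    f_T = 1 − exp(−π R_C² C_N),

which defines a critical concentration C_C = 1/(π R_C²) at which
f_T = 1 − 1/e ≈ 0.63. Excitons hop between fluorophores by FRET with
nearest-neighbor transfer probability

    P_FRET = R₀⁶ / (R₀⁶ + (π C_N)⁻³),

where R₀ follows from the spectral overlap integral J via
R₀⁶ = 8.79×10⁻⁵ J κ² n⁻⁴ φ (R₀ in Å for J in M⁻¹cm⁻¹nm⁴). The probability
that an exciton is transferred to a trap is P_ETT = P_FRET · f_T, which is
the observable quenching efficiency QE = 1 − τ/τ₀.

Above roughly 1.5 mol % labeling P_FRET ≈ 1 for the dyes considered here, so
the working laws reduce to

    τ/τ₀ = exp(−π R_C² C_N)          (dynamic, transfer-to-trap)
    F/F₀ = exp(−2π R_C² C_N)         (dynamic + static: trap members are dark)

The factor-of-two relationship between the lifetime and intensity laws gives
the quenching correction F₀ = F·(τ₀/τ)² used to convert measured intensity
back to concentration, and the semi-log form ln(τ₀/τ) = π R_C² C_N turns the
critical radius into the slope of a straight line — the package's central
estimator, R_C = √(slope/π).

Assumptions worth keeping in mind: single-leaflet statistics with identically
labeled leaflets (mol % converts to C_N with no factor of 2, which reproduces
the 4.69 nm mean separation at 1 %); nearest-neighbor-only FRET; traps
immobile and quasi-stable over an excited-state lifetime (lateral diffusion
moves a dye only ~0.2 nm per lifetime, √(4Dτ₀), which is also why collisional
quenching is ruled out); κ² = 2/3 (isotropic dynamic averaging) and
n = 1.45 fixed.

## Fluorophore presets

| preset | τ₀ (ns) | φ | J (M⁻¹cm⁻¹nm⁴) | R₀ (nm) | R_C (nm) | D (μm²/s) |
|---|---|---|---|---|---|---|
| texas_red | 4.23 | 0.93 | 3.08×10¹⁵ | 5.73 | 2.02 | 2.27 |
| nbd | 6.99 | 0.40 | 0.28×10¹⁵ | 3.32 | 1.14 | 2.27 |
| bodipy | 5.40 | 0.99 | 2.13×10¹⁵ | 5.41 | 2.70 | 2.27 |

The unquenched lifetimes of NBD and BODIPY are back-calculated from their
published quenched lifetimes and quenching efficiencies (5.31 ns at 24.0 % →
6.99 ns; 2.75 ns at 49.1 % → 5.40 ns); τ₀ is deliberately *not* taken from a
0.5 % (w/w) pre-electrophoresis film, which is already a few percent
quenched. Only the diffusion constant of the Texas Red lipid is measured;
the other presets reuse 2.27 μm²/s as a typical value for headgroup-labeled
lipids in a fluid DOPC bilayer. D enters only the displacement check and the
electrophoresis gradient length, never the R_C estimate.

Evaluating the R₀ formula with the 3-significant-figure J values reproduces
the tabulated radii to within ~1.3 % (e.g. 5.80 vs 5.73 nm for Texas Red);
the residual is input rounding, so tests accept 2 % there.

## Spectral overlap

J = ∫ F̄_em(λ) ε(λ) λ⁴ dλ with the emission spectrum area-normalized, ε in
molar extinction units, λ in nm. Quadrature is trapezoidal on the union of
the two wavelength grids with linear interpolation; against a 0.01 nm
brute-force oracle this is accurate to <10⁻⁴ relative for smooth (Gaussian)
spectra at 1 nm sampling. Absorption inputs must already be scaled to
M⁻¹cm⁻¹; the package ships no measured spectra, so the preset J values are
constants, not recomputed quantities.

## Electrophoresis simulator

In-membrane electrophoresis is reduced to 1D along the field axis (the
analysis averages the perpendicular direction anyway). Drift at v_d toward
the impenetrable corral edge at x = 0 against diffusion D relaxes to the
exponential steady state

    C(x) = C₀ (L/λ) e^(−x/λ) / (1 − e^(−L/λ)),   λ = D/v_d,

evaluated as bin averages so the total amount of dye is conserved exactly.
The time-dependent solver is an explicit conservative finite-difference
scheme (central advection + Fickian diffusion on cell faces, zero-flux
boundaries); it refuses to run if dt exceeds dx²/(2D) or dx/v_d and conserves
mass to round-off. On a 200-bin grid it converges to the closed form within
1 % L∞. Default conditions follow the measured system: 100×100 μm corrals,
E = 45 V/cm (metadata only — v_d is an empirical input, 0.27–0.31 μm/s),
initial loading 0.5 mol %, giving λ ≈ 7.3 μm and ~14-fold edge accumulation.
Electrostatic saturation of the accumulated dye is not modeled; an optional
concentration cap is provided instead, because no functional form is
established. Consequently the simulator's intensity fold-changes are not
meant to reproduce experimental ones quantitatively.

## Synthetic FLIM data

Each image pixel draws Poisson photons at an expected rate
k·c·exp(−2π R_C² C_N) (k = `photons_per_molpercent`, a free calibration
scale; the real instrument's fluence-to-photon mapping is not modeled) with
single-exponential arrival times τ(c) = τ₀ exp(−π R_C² C_N), truncated to
the 100 ns repetition window (10 MHz), jittered by a Gaussian IRF
(110 ps FWHM — the IRF convolution is implemented as per-photon jitter,
with window wrap-around), and binned into 250 × 0.4 ns channels. A
multi-exponential truth option exists for fitter stress tests, with photon
numbers weighted by aᵢτᵢ as physics dictates. Not emulated: photobleaching,
singlet-singlet annihilation, detector afterpulsing, scan artifacts, and
vendor file formats. Pixels are statistically independent given the profile,
so passing recovery tests demonstrates estimator correctness under the
stated noise model, not robustness to instrument systematics.

## Decay fitting

Poisson maximum likelihood (not least squares — correct at low counts) on
either the tail window (default: 3×IRF-FWHM past the peak, valid here since
τ = 2.7–7 ns ≫ 0.11 ns IRF) or the full window with an analytic
Gaussian⊗exponential re-convolution model. Initialization is a
count-weighted log-linear regression on the tail; the single-component tail
fit profiles the amplitude out analytically and reduces to a 1D bounded
search, which keeps image-scale fitting fast. Model selection takes the
smallest component count whose Pearson reduced χ² is below 1.1; χ² is
evaluated over bins with model expectation ≥ 1 count, because near-empty
far-tail bins make the Pearson statistic degenerate in both directions.
Histograms under 100 photons are flagged invalid and propagate as missing
pixels. The reported summary is always the amplitude-weighted mean lifetime
Σaᵢτᵢ/Σaᵢ.

## Analysis pipeline and the R_C fit

Per-column profiles are mean intensity and intensity-weighted mean lifetime
over valid (unmasked, fitted) pixels. Concentration is reconstructed as
c = F·(τ₀/τ)²/slope with the slope from a standard curve; calibration points
are taken in (or corrected to) the dilute regime. Lifetimes marginally above
τ₀ are clamped to τ₀ (equivalently QE clamps at 0) since they occur in
low-count pixels. The R_C regression of ln(τ₀/τ) on C_N is unweighted and
constrained through the origin by default — the law has no intercept — with
a free-intercept mode as a diagnostic for offsets; uncertainty is reported
as slope-SE propagation only, R_C_se = slope_se/(2π R_C). Depleted columns
(configurable count threshold) and user-supplied defect ROIs are excluded;
there is no automatic defect detection.

## Problem sizes and verification

The end-to-end round trip (steady-state profile → FLIM image → per-column
decay fits → calibration → reconstruction → R_C fit) runs on a 64×64-pixel,
100 μm corral at 2000 expected counts per mol % per pixel, i.e. of order
10⁵ photons per image column near the accumulation edge — enough that the
recovered R_C lands within 5 % of the generating value for all three presets
(observed: within ~1 %), with the BODIPY > TR > NBD ordering preserved.
Monte-Carlo trap fractions are validated against the closed form on
(C_N, R_C) grids with ~10⁴–10⁵ points per pattern, allowing twice the
binomial variance because near-neighbor trap events are pairwise correlated.

## Known limitations

- The preset J values cannot be recomputed without measured spectra and
  absolute extinction coefficients; they are constants.
- Inter-leaflet FRET and orientation-resolved κ² are out of scope.
- The exponential steady state is an idealization; real equilibrium profiles
  are only roughly exponential once electrostatic crowding matters.
- Tail fitting discards early-window photons; for lifetimes approaching the
  IRF width use the re-convolution mode.
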