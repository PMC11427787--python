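# trapquench

Transfer-to-trap fluorescence quenching analysis for FLIM of supported lipid
bilayers.

Fluorescent lipid probes (Texas Red, NBD, BODIPY and friends) self-quench
when crowded: as the labeling density rises, both the fluorescence intensity
per fluorophore and the fluorescence lifetime drop. `trapquench` implements
the statistical-pair *transfer-to-trap* model of this process and the full
analysis chain for extracting its key parameter — the critical radius for
trap formation, R_C — from fluorescence-lifetime-imaging (FLIM) data of
membrane corrals in which in-membrane electrophoresis has built a
concentration gradient. It is aimed at membrane biophysicists who need to
quantify (or correct for) concentration quenching in supported lipid
bilayers.

## The model in brief

For fluorophores at number density C_N (nm⁻²) placed at random in a 2D film,
the fraction engaged in non-fluorescent "trap" pairs closer than R_C is
f_T = 1 − exp(−π R_C² C_N). Excitons reach traps by FRET
(P_FRET = R₀⁶/(R₀⁶ + (πC_N)⁻³), R₀⁶ = 8.79×10⁻⁵ J κ² n⁻⁴ φ), and in the
strong-FRET regime the observables obey

    τ/τ₀ = e^(−π R_C² C_N)        F/F₀ = e^(−2π R_C² C_N)

so ln(τ₀/τ) is linear in C_N with slope π R_C², and intensity can be
quench-corrected as F₀ = F·(τ₀/τ)². The package provides:

- `trapquench.core` — the closed-form photophysics and unit conversions,
  with presets for TR, NBD, BODIPY;
- `trapquench.spectra` — the spectral overlap integral J;
- `trapquench.membrane` — drift–diffusion electrophoresis profiles and
  Poisson point-pattern Monte Carlo oracles;
- `trapquench.synth` — a synthetic TCSPC/FLIM forward model (Poisson
  photons, Gaussian IRF, multi-page TIFF I/O);
- `trapquench.fitting` — Poisson-MLE multi-exponential decay fits and
  amplitude-weighted mean-lifetime maps;
- `trapquench.pipeline` — profiles → concentration reconstruction → QE
  curves → the R_C regression, plus the `trapquench` CLI
  (`simulate`, `fit-decays`, `analyze`, `theory-curves`, `snapshot`).

## Worked example

Simulate a Texas Red corral at electrophoretic equilibrium, fit every
column's decay, reconstruct the concentration profile from the
quench-corrected intensity, and re-estimate R_C:

```python
import trapquench as tq
from trapquench.synth import InstrumentModel

f = tq.get_preset("texas_red")           # tau0 4.23 ns, true R_C 2.02 nm
res = tq.recover_critical_radius(
    f, inst=InstrumentModel(photons_per_molpercent=2000.0), seed=42
)
fit = res["fit"]
print(f"slope = {fit.slope_nm2:.2f} +/- {fit.slope_se_nm2:.2f} nm^2")
print(f"R_C   = {fit.rc_nm:.3f} +/- {fit.rc_se_nm:.3f} nm")
print(f"R^2   = {fit.r_squared:.4f}   points: {fit.n_points}")
```

prints

```
slope = 12.79 +/- 0.05 nm^2
R_C   = 2.018 +/- 0.004 nm
R^2   = 0.9993   points: 25
```

The slope of the ln(τ₀/τ) vs C_N regression (12.79 nm² here) is π R_C²; its
square root over π recovers the generating critical radius to within the
quoted standard error. The analogous run for the NBD and BODIPY presets
recovers their radii (1.14 and 2.70 nm) and preserves the
BODIPY > TR > NBD quenching-strength ordering.

Closed-form quantities are one-liners:

```python
from trapquench import core
cn = core.mol_percent_to_number_density(1.0)   # 0.0145 nm^-2
core.mean_separation(cn)                       # 4.69 nm
core.forster_radius(3.08e15, 0.93)             # 5.80 nm
core.qe_theoretical(core.mol_percent_to_number_density(2.0), 2.02)  # 0.310
```

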