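"""End-to-end quenching analysis: profiles, concentration reconstruction,
QE curves, and the critical-radius fit.

The chain mirrors how an in-membrane-electrophoresis FLIM experiment is
analyzed.  Lifetime and intensity maps of a corral are averaged down the
field-perpendicular axis into 1D profiles; the intensity profile is corrected
for quenching with the measured lifetimes (``F0 = F (tau0/tau)^2``) and
converted to concentration via a standard curve; lifetime and concentration
are then related point-by-point, and the regression

    ln(tau0/tau) = pi R_C^2 C_N

yields the critical radius for trap formation ``R_C = sqrt(slope/pi)``.
Points from corrals at different initial loadings pool onto one master curve,
so fits may combine any number of profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import core
from .membrane import (
    ConcentrationProfile,
    CorralGeometry,
    ElectrophoresisParams,
    sample_point_pattern,
    steady_state_profile,
)
from .synth import FLIMImage, InstrumentModel, simulate_flim_image
from .fitting import fit_decay, fit_image
from .synth import DecayHistogram

__all__ = [
    "ROISpec",
    "CalibrationCurve",
    "CriticalRadiusFit",
    "extract_profiles",
    "calibrate",
    "reconstruct_concentration",
    "build_qe_curve",
    "fit_critical_radius",
    "theory_overlays",
    "trap_site_snapshot",
    "simulate_calibration_points",
    "analyze_maps",
    "recover_critical_radius",
]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest in image coordinates (um, half-open)."""

    x0_um: float
    x1_um: float
    y0_um: float
    y1_um: float
    role: str = "full_corral"  # full_corral | accumulation_edge | excluded_defect

    def __post_init__(self) -> None:
        if self.x1_um <= self.x0_um or self.y1_um <= self.y0_um:
            raise ValueError("ROI must have positive extent")
        if self.role not in ("full_corral", "accumulation_edge", "excluded_defect"):
            raise ValueError(f"unknown ROI role {self.role!r}")

    @classmethod
    def accumulation_edge(
        cls, geom: CorralGeometry, fraction: float = 0.15
    ) -> "ROISpec":
        """ROI spanning ``fraction`` of the corral area at the x = 0 edge."""
        return cls(0.0, fraction * geom.length_um, 0.0, geom.width_um,
                   role="accumulation_edge")

    @classmethod
    def full(cls, geom: CorralGeometry) -> "ROISpec":
        return cls(0.0, geom.length_um, 0.0, geom.width_um)

    def to_slices(self, pixel_size_um: float) -> tuple[slice, slice]:
        """(row, column) pixel slices of this ROI (half-open)."""
        return (
            slice(int(round(self.y0_um / pixel_size_um)),
                  int(round(self.y1_um / pixel_size_um))),
            slice(int(round(self.x0_um / pixel_size_um)),
                  int(round(self.x1_um / pixel_size_um))),
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-vs-concentration standard curve (counts per mol %)."""

    slope: float
    intercept: float = 0.0
    r_squared: float = np.nan
    points: tuple = ()

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_concentration(self, f0_counts):
        """Invert the standard curve: unquenched counts -> mol %."""
        c = (np.asarray(f0_counts, dtype=float) - self.intercept) / self.slope
        return np.clip(c, 0.0, None)


@dataclass(frozen=True)
class CriticalRadiusFit:
    """Result of the ln(tau0/tau) vs C_N regression.

    ``slope_nm2`` estimates ``pi R_C^2``; ``rc_nm = sqrt(slope/pi)`` with the
    standard error propagated as ``rc_se = slope_se / (2 pi rc)``.
    """

    slope_nm2: float
    slope_se_nm2: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def rc_nm(self) -> float:
        return float(np.sqrt(self.slope_nm2 / np.pi))

    @property
    def rc_se_nm(self) -> float:
        return float(self.slope_se_nm2 / (2.0 * np.pi * self.rc_nm))


def extract_profiles(
    tau_map: np.ndarray,
    intensity_map: np.ndarray,
    pixel_size_um: float,
    roi: ROISpec | None = None,
    excluded: tuple[ROISpec, ...] = (),
) -> pd.DataFrame:
    """Collapse lifetime/intensity maps into 1D profiles along the field axis.

    Averages across the vertical (field-perpendicular) direction: per-column
    mean intensity over valid pixels and intensity-weighted mean lifetime.
    ``pixel_size_um`` is the column width of the supplied maps (maps may be
    row-binned relative to the raw image).  Excluded-defect ROIs are masked
    out; fully masked columns yield NaN.

    Returns a DataFrame with columns ``x_um``, ``intensity``, ``tau_ns``,
    ``n_pixels``.
    """
    tau_map = np.asarray(tau_map, dtype=float)
    inten = np.asarray(intensity_map, dtype=float)
    if tau_map.shape != inten.shape or tau_map.ndim != 2:
        raise ValueError("maps must be matching 2D arrays")
    ny, nx = tau_map.shape
    # row extent of the (possibly row-binned) maps in um is unknown to the
    # maps themselves; ROI rows are interpreted on the map's own row grid.
    row_um = None
    valid = np.isfinite(tau_map) & np.isfinite(inten)
    for ex in excluded:
        if ex.role != "excluded_defect":
            raise ValueError("excluded ROIs must have role 'excluded_defect'")
        rs, cs = ex.to_slices(pixel_size_um)
        valid[_clip_rows(rs, ny), cs] = False

    if roi is not None:
        rs, cs = roi.to_slices(pixel_size_um)
        col_slice = cs
        row_slice = _clip_rows(rs, ny)
    else:
        col_slice = slice(0, nx)
        row_slice = slice(0, ny)

    cols = np.arange(nx)[col_slice]
    x = (cols + 0.5) * pixel_size_um
    inten_prof = np.full(cols.size, np.nan)
    tau_prof = np.full(cols.size, np.nan)
    n_pix = np.zeros(cols.size, dtype=int)
    for k, j in enumerate(cols):
        v = valid[row_slice, j]
        if not v.any():
            continue
        i_col = inten[row_slice, j][v]
        t_col = tau_map[row_slice, j][v]
        n_pix[k] = v.sum()
        inten_prof[k] = i_col.mean()
        w = i_col.sum()
        tau_prof[k] = np.sum(i_col * t_col) / w if w > 0 else np.nan
    return pd.DataFrame(
        {"x_um": x, "intensity": inten_prof, "tau_ns": tau_prof, "n_pixels": n_pix}
    )


def _clip_rows(rs: slice, ny: int) -> slice:
    # ROI rows are specified on the raw-image grid; clamp to the map's rows
    return slice(min(rs.start, ny), min(rs.stop, ny))


def calibrate(
    points, fit_intercept: bool = False
) -> CalibrationCurve:
    """Least-squares standard curve from (concentration, intensity) pairs.

    Points should come from the dilute regime or be quenching-corrected
    (``F0``) beforehand.  Zero intercept by default.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, intensity) pairs")
    c, f = pts[:, 0], pts[:, 1]
    if fit_intercept:
        (slope, intercept), res = np.polyfit(c, f, 1), None
    else:
        slope = float(np.sum(c * f) / np.sum(c * c))
        intercept = 0.0
    pred = slope * c + intercept
    ss_tot = np.sum((f - f.mean()) ** 2)
    r2 = 1.0 - np.sum((f - pred) ** 2) / ss_tot if ss_tot > 0 else np.nan
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return CalibrationCurve(float(slope), float(intercept), float(r2),
                            tuple(map(tuple, pts)))


def reconstruct_concentration(
    profile: pd.DataFrame,
    tau0_ns: float,
    cal: CalibrationCurve,
) -> ConcentrationProfile:
    """Quenching-corrected concentration profile from intensity + lifetime.

    Per column: ``F0 = F (tau0/tau)^2`` undoes both static and dynamic
    quenching, then the standard curve converts ``F0`` to mol %.  Lifetimes
    above ``tau0`` (noise) are clamped to ``tau0``; missing lifetimes give
    missing concentrations.
    """
    tau = np.minimum(profile["tau_ns"].to_numpy(dtype=float), tau0_ns)
    f = profile["intensity"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        f0 = f * (tau0_ns / tau) ** 2
    c = np.where(np.isfinite(f0), cal.to_concentration(np.nan_to_num(f0)), np.nan)
    return ConcentrationProfile(profile["x_um"].to_numpy(dtype=float), c)


def build_qe_curve(
    conc: ConcentrationProfile,
    profile: pd.DataFrame,
    tau0_ns: float,
    cfg: core.ModelConfig = core.DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Pointwise quench-curve table relating concentration and lifetime.

    One row per profile column: concentration (mol % and nm^-2), lifetime,
    quenching efficiency ``QE = 1 - tau/tau0`` and mean separation ``r``.
    Tables from multiple corrals/samples can be pooled with ``pd.concat`` —
    for a single quenching mechanism they fall on one master curve.
    """
    if not np.allclose(conc.x_um, profile["x_um"].to_numpy(), equal_nan=True):
        raise ValueError("concentration and lifetime profiles are misaligned")
    c = conc.c_molpercent
    tau = profile["tau_ns"].to_numpy(dtype=float)
    cn = np.where(np.isfinite(c), core.mol_percent_to_number_density(
        np.nan_to_num(c), cfg), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qe = 1.0 - np.clip(tau, None, tau0_ns) / tau0_ns
    with np.errstate(divide="ignore"):
        r = np.where(cn > 0, 1.0 / np.sqrt(np.pi * np.maximum(cn, 1e-300)), np.inf)
    return pd.DataFrame(
        {"x_um": conc.x_um, "c_molpercent": c, "cn_per_nm2": cn,
         "tau_ns": tau, "qe": qe, "r_nm": r}
    )


def fit_critical_radius(
    curve: pd.DataFrame,
    tau0_ns: float,
    constrain_origin: bool = True,
) -> CriticalRadiusFit:
    """Estimate R_C from the linear law ``ln(tau0/tau) = pi R_C^2 C_N``.

    Unweighted least squares, constrained through the origin by default
    (the model has no intercept); the free-intercept mode is a diagnostic
    for systematic offsets.  Points with missing data or ``tau >= tau0``
    (no quenching information) are dropped; at least 3 must remain.
    """
    cn = curve["cn_per_nm2"].to_numpy(dtype=float)
    tau = curve["tau_ns"].to_numpy(dtype=float)
    ok = np.isfinite(cn) & np.isfinite(tau) & (tau > 0) & (tau < tau0_ns)
    if ok.sum() == 0:
        raise ValueError("no quenched points: all lifetimes >= tau0")
    if ok.sum() < 3:
        raise ValueError("need >= 3 valid quenched points")
    x = cn[ok]
    y = np.log(tau0_ns / tau[ok])
    n = x.size
    if constrain_origin:
        m = float(np.sum(x * y) / np.sum(x * x))
        resid = y - m * x
        m_se = float(np.sqrt(np.sum(resid**2) / (n - 1) / np.sum(x * x)))
        intercept = 0.0
    else:
        A = np.vstack([x, np.ones_like(x)]).T
        (m, intercept), res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - (m * x + intercept)
        sxx = np.sum((x - x.mean()) ** 2)
        m_se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
        m, intercept = float(m), float(intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    if m <= 0:
        raise ValueError("non-positive quenching slope; no trap signal")
    return CriticalRadiusFit(m, m_se, intercept, float(r2), n)


def theory_overlays(
    rc_nm: float,
    r0_nm: float | None = None,
    cfg: core.ModelConfig = core.DEFAULT_CONFIG,
    c_max_molpercent: float = 15.0,
    n_points: int = 400,
) -> pd.DataFrame:
    """Dense theoretical curves for overlay on experimental quench data.

    Columns: concentration (mol % and nm^-2), mean separation, simplified
    quenching efficiency (= trap fraction), ``ln(tau0/tau)``,
    ``ln(F0/F)``, and — when ``r0_nm`` is given — ``p_fret`` and ``p_ett``
    of the exact model.
    """
    c = np.linspace(0.0, c_max_molpercent, n_points)
    cn = core.mol_percent_to_number_density(c, cfg)
    out = pd.DataFrame(
        {
            "c_molpercent": c,
            "cn_per_nm2": cn,
            "r_nm": core.mean_separation(cn),
            "f_T": core.trap_fraction(cn, rc_nm),
            "qe": core.qe_theoretical(cn, rc_nm),
            "ln_tau0_over_tau": np.pi * rc_nm**2 * cn,
            "ln_F0_over_F": 2.0 * np.pi * rc_nm**2 * cn,
        }
    )
    if r0_nm is not None:
        out["p_fret"] = core.prob_fret(cn, r0_nm)
        out["p_ett"] = core.prob_ett(cn, r0_nm, rc_nm)
    return out


def trap_site_snapshot(
    c_molpercent: float,
    rc_nm: float,
    box_nm: tuple[float, float] = (10.0, 10.0),
    rng: np.random.Generator | int | None = None,
    cfg: core.ModelConfig = core.DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Random fluorophore arrangement with trap/fluorescent labels.

    Draws a Poisson point pattern at the requested concentration and labels
    as traps the points whose (periodic) nearest neighbor lies within R_C.
    The trap-label fraction matches ``1 - exp(-pi R_C^2 C_N)`` on average.
    """
    cn = core.mol_percent_to_number_density(c_molpercent, cfg)
    pts = sample_point_pattern(cn, box_nm, rng)
    if len(pts) == 0:
        return pd.DataFrame(columns=["x_nm", "y_nm", "is_trap"])
    if len(pts) == 1 or rc_nm == 0:
        is_trap = np.zeros(len(pts), dtype=bool)
    else:
        tree = cKDTree(pts, boxsize=box_nm)
        d, _ = tree.query(pts, k=2)
        is_trap = d[:, 1] < rc_nm
    return pd.DataFrame({"x_nm": pts[:, 0], "y_nm": pts[:, 1], "is_trap": is_trap})


# ---------------------------------------------------------------------------
# end-to-end composition (simulate -> fit -> reconstruct -> R_C)
# ---------------------------------------------------------------------------

def simulate_calibration_points(
    f: core.FluorophoreParams,
    cfg: core.ModelConfig,
    inst: InstrumentModel,
    concentrations_molpercent=(0.05, 0.1, 0.2, 0.3),
    n_pixels: int = 64,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[float, float]]:
    """Standard-curve points from simulated dilute uniform membranes.

    For each known concentration, simulates ``n_pixels`` worth of photons,
    fits the pooled decay, and quench-corrects the mean counts per pixel
    (``F0 = F (tau0/tau)^2``) so the curve is linear down to zero.
    """
    rng = np.random.default_rng(rng)
    from .synth import local_emission_rate, local_quenched_lifetime, simulate_decay

    points = []
    for c in concentrations_molpercent:
        rate = local_emission_rate(c, f, cfg, inst) * n_pixels
        tau_true = local_quenched_lifetime(c, f, cfg)
        h = simulate_decay(tau_true, rate, inst, rng)
        r = fit_decay(h, inst, max_components=1, warn=False)
        if not r.valid:
            continue
        mean_counts = h.total / n_pixels
        tau_hat = min(r.mean_lifetime_ns, f.tau0_ns)
        points.append((c, mean_counts * (f.tau0_ns / tau_hat) ** 2))
    return points


def analyze_maps(
    tau_map: np.ndarray,
    intensity_map: np.ndarray,
    pixel_size_um: float,
    tau0_ns: float,
    cal: CalibrationCurve,
    roi: ROISpec | None = None,
    excluded: tuple[ROISpec, ...] = (),
    min_column_counts: float = 0.0,
    cfg: core.ModelConfig = core.DEFAULT_CONFIG,
    constrain_origin: bool = True,
) -> dict:
    """Analyze fitted maps: profiles -> concentration -> QE curve -> R_C.

    ``min_column_counts`` drops depleted columns whose mean per-pixel counts
    are too low for a reliable lifetime (the dim far side of the corral).
    Returns a dict with ``profile``, ``concentration``, ``qe_curve``, and
    ``fit`` (a :class:`CriticalRadiusFit`).
    """
    prof = extract_profiles(tau_map, intensity_map, pixel_size_um, roi, excluded)
    if min_column_counts > 0:
        low = prof["intensity"] < min_column_counts
        prof.loc[low, ["intensity", "tau_ns"]] = np.nan
    conc = reconstruct_concentration(prof, tau0_ns, cal)
    curve = build_qe_curve(conc, prof, tau0_ns, cfg)
    fit = fit_critical_radius(curve, tau0_ns, constrain_origin=constrain_origin)
    return {"profile": prof, "concentration": conc, "qe_curve": curve, "fit": fit}


def recover_critical_radius(
    f: core.FluorophoreParams,
    geom: CorralGeometry | None = None,
    params: ElectrophoresisParams | None = None,
    inst: InstrumentModel | None = None,
    cfg: core.ModelConfig = core.DEFAULT_CONFIG,
    seed: int | None = None,
    row_binning: int | None = None,
    min_column_counts: float = 30.0,
) -> dict:
    """Full pipeline round-trip on one synthetic corral.

    Simulates the electrophoretic steady state and its FLIM acquisition for
    fluorophore ``f``, fits per-column decays (rows binned for photon
    statistics), builds a standard curve from separate dilute simulations,
    reconstructs the concentration profile, and fits R_C.

    Returns the :func:`analyze_maps` dict plus ``truth`` (the generating
    parameters) and ``calibration``.
    """
    if f.critical_radius_nm is None:
        raise ValueError("fluorophore needs a critical radius to simulate")
    geom = geom or CorralGeometry(pixel_size_um=100.0 / 64)
    params = params or ElectrophoresisParams(
        drift_velocity_um_s=0.31,
        diffusion_um2_s=f.diffusion_um2_s or 2.27,
        initial_conc_molpercent=0.5,
    )
    inst = inst or InstrumentModel()
    rng = np.random.default_rng(seed)

    profile = steady_state_profile(geom, params)
    img = simulate_flim_image(profile, geom, f, cfg, inst, rng)

    by = row_binning or geom.n_y  # default: collapse full columns
    tau_map, inten_map = fit_image(
        img, inst, binning=(by, 1), max_components=1, min_counts=200
    )
    cal_points = simulate_calibration_points(f, cfg, inst, rng=rng)
    cal = calibrate(cal_points)

    out = analyze_maps(
        tau_map,
        inten_map,
        geom.pixel_size_um,
        f.tau0_ns,
        cal,
        min_column_counts=min_column_counts,
        cfg=cfg,
    )
    out["truth"] = {
        "rc_nm": f.critical_radius_nm,
        "profile": profile,
        "photons_per_molpercent": inst.photons_per_molpercent,
    }
    out["calibration"] = cal
    return out
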