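"""Electrophoretic redistribution of charged dye-lipids in a membrane corral.

An in-plane electric field drifts charged fluorophore-lipids toward one wall
of a corral (a lipid-bilayer patch fenced by polymerized lipid), where they
pile up against diffusion.  The competition of constant drift ``v_d`` toward
``x = 0`` and diffusion ``D`` relaxes to the exponential dynamic equilibrium

    C(x) = C0 (L/lambda) exp(-x/lambda) / (1 - exp(-L/lambda)),
    lambda = D / v_d,

which conserves the total amount of dye.  The module also provides spatial
Monte-Carlo oracles for the trap statistics: homogeneous Poisson point
patterns and the empirical nearest-neighbor trap fraction that the
closed-form ``f_T = 1 - exp(-pi R_C^2 C_N)`` predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CorralGeometry",
    "ElectrophoresisParams",
    "ConcentrationProfile",
    "steady_state_profile",
    "evolve_profile",
    "sample_point_pattern",
    "mc_trap_fraction",
]


@dataclass(frozen=True)
class CorralGeometry:
    """Rectangular membrane corral discretized into square pixels (um)."""

    length_um: float = 100.0
    width_um: float = 100.0
    pixel_size_um: float = 100.0 / 128

    def __post_init__(self) -> None:
        if min(self.length_um, self.width_um, self.pixel_size_um) <= 0:
            raise ValueError("geometry dimensions must be positive")
        for dim in (self.length_um, self.width_um):
            n = dim / self.pixel_size_um
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "pixel_size_um must evenly divide length and width"
                )

    @property
    def n_x(self) -> int:
        return round(self.length_um / self.pixel_size_um)

    @property
    def n_y(self) -> int:
        return round(self.width_um / self.pixel_size_um)

    @property
    def x_centers_um(self) -> np.ndarray:
        """Pixel-column centers; x = 0 is the accumulation edge."""
        return (np.arange(self.n_x) + 0.5) * self.pixel_size_um


@dataclass(frozen=True)
class ElectrophoresisParams:
    """Drift/diffusion parameters of one electrophoresis run.

    ``drift_velocity_um_s`` is the magnitude of the field-driven drift toward
    ``x = 0``; ``field_strength_V_cm`` is carried as metadata only (drift is
    measured empirically, not derived from the field).
    """

    drift_velocity_um_s: float
    diffusion_um2_s: float
    initial_conc_molpercent: float
    duration_s: float = 3600.0
    field_strength_V_cm: float = 45.0

    def __post_init__(self) -> None:
        if self.drift_velocity_um_s < 0:
            raise ValueError("drift velocity must be >= 0")
        if self.diffusion_um2_s <= 0:
            raise ValueError("diffusion constant must be positive")
        if self.initial_conc_molpercent < 0:
            raise ValueError("initial concentration must be >= 0")
        if self.duration_s < 0:
            raise ValueError("duration must be >= 0")

    @property
    def gradient_length_um(self) -> float:
        """Decay length lambda = D / v_d of the equilibrium exponential."""
        if self.drift_velocity_um_s == 0:
            return np.inf
        return self.diffusion_um2_s / self.drift_velocity_um_s


@dataclass
class ConcentrationProfile:
    """1D concentration profile across a corral (bin centers, mol %)."""

    x_um: np.ndarray
    c_molpercent: np.ndarray

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.c_molpercent = np.asarray(self.c_molpercent, dtype=float)
        if self.x_um.shape != self.c_molpercent.shape or self.x_um.ndim != 1:
            raise ValueError("x and c must be matching 1D arrays")
        if np.any(self.c_molpercent < -1e-12):
            raise ValueError("concentrations must be >= 0")

    @property
    def bin_width_um(self) -> float:
        return float(np.diff(self.x_um).mean()) if self.x_um.size > 1 else 0.0

    def total_amount(self) -> float:
        """Integral of c over x (mol % * um), for conservation checks."""
        return float(np.sum(self.c_molpercent) * self.bin_width_um)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"x_um": self.x_um, "c_molpercent": self.c_molpercent}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationProfile":
        df = pd.read_csv(path)
        return cls(df["x_um"].to_numpy(), df["c_molpercent"].to_numpy())


def steady_state_profile(
    geom: CorralGeometry,
    params: ElectrophoresisParams,
    max_conc_molpercent: float | None = None,
) -> ConcentrationProfile:
    """Dynamic-equilibrium exponential profile of drift against diffusion.

    Values are bin averages of the analytic exponential so that the total
    amount of dye equals the initial uniform loading exactly.  With zero
    drift the profile is uniform at the initial concentration.
    ``max_conc_molpercent`` optionally caps the profile (a crude stand-in for
    electrostatic saturation at the accumulation edge; excess is *not*
    redistributed).
    """
    x = geom.x_centers_um
    dx = geom.pixel_size_um
    c0, lam, L = (
        params.initial_conc_molpercent,
        params.gradient_length_um,
        geom.length_um,
    )
    if not np.isfinite(lam):
        c = np.full_like(x, c0)
    else:
        edges = np.concatenate([x - dx / 2, [x[-1] + dx / 2]])
        # bin-averaged C(x) = C0 (L/lam) e^(-x/lam) / (1 - e^(-L/lam))
        cdf = -np.expm1(-edges / lam)  # integral of e^(-x/lam)/lam from 0
        norm = -np.expm1(-L / lam)
        c = c0 * L * np.diff(cdf) / (dx * norm)
    if max_conc_molpercent is not None:
        c = np.minimum(c, max_conc_molpercent)
    return ConcentrationProfile(x, c)


def evolve_profile(
    geom: CorralGeometry,
    params: ElectrophoresisParams,
    dt_s: float,
    n_steps: int,
    c_init: np.ndarray | None = None,
    store_every: int | None = None,
) -> list[ConcentrationProfile]:
    """Explicit finite-difference drift-diffusion with zero-flux walls.

    Conservative scheme on pixel columns: face fluxes combine central-
    difference advection (drift toward x = 0) and Fickian diffusion; both
    boundary faces are impenetrable, so the total amount of dye is conserved
    to round-off at every step.  Converges to :func:`steady_state_profile`
    as t -> inf.

    Raises before running if ``dt`` violates the stability conditions
    ``dt <= dx^2/(2D)`` and ``dt <= dx/v_d``.

    Returns the list of stored profiles (every ``store_every`` steps plus
    the final state; by default only the final state).
    """
    dx = geom.pixel_size_um
    D, v = params.diffusion_um2_s, params.drift_velocity_um_s
    dt_max = dx**2 / (2.0 * D)
    if dt_s > dt_max:
        raise ValueError(f"unstable dt: {dt_s} > dx^2/(2D) = {dt_max:.3g}")
    if v > 0 and dt_s > dx / v:
        raise ValueError(f"unstable dt: {dt_s} > dx/v_d = {dx / v:.3g}")

    c = (
        np.full(geom.n_x, params.initial_conc_molpercent, dtype=float)
        if c_init is None
        else np.asarray(c_init, dtype=float).copy()
    )
    if c.shape != (geom.n_x,):
        raise ValueError("c_init shape mismatch with geometry")

    out: list[ConcentrationProfile] = []
    x = geom.x_centers_um
    for step in range(1, n_steps + 1):
        # interior face fluxes (toward +x positive); drift is toward x=0
        adv = -v * 0.5 * (c[:-1] + c[1:])
        dif = -D * (c[1:] - c[:-1]) / dx
        flux = np.concatenate([[0.0], adv + dif, [0.0]])
        c = c - dt_s / dx * np.diff(flux)
        np.clip(c, 0.0, None, out=c)
        if store_every and step % store_every == 0:
            out.append(ConcentrationProfile(x, c.copy()))
    if not out or store_every is None or n_steps % store_every != 0:
        out.append(ConcentrationProfile(x, c.copy()))
    return out


def sample_point_pattern(
    cn_per_nm2: float,
    box_nm: tuple[float, float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Homogeneous 2D Poisson point pattern in a box, as an (N, 2) array (nm).

    The count is Poisson(``cn * area``) and positions are uniform —
    the spatial model behind the closed-form trap fraction.
    """
    if cn_per_nm2 < 0:
        raise ValueError("number density must be >= 0")
    w, h = box_nm
    if w <= 0 or h <= 0:
        raise ValueError("box dimensions must be positive")
    expected = cn_per_nm2 * w * h
    if expected > 1e7:
        raise ValueError("expected point count exceeds 1e7")
    rng = np.random.default_rng(rng)
    n = rng.poisson(expected)
    return rng.uniform(0.0, [w, h], size=(n, 2))


def mc_trap_fraction(
    points: np.ndarray, rc_nm: float, box_nm: tuple[float, float] | None = None
) -> float:
    """Empirical trap fraction: points whose nearest neighbor is closer than R_C.

    With ``box_nm`` given, distances are periodic (minimum image), removing
    edge bias so the estimate is directly comparable to the closed form.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("points must be a non-empty (N, 2) array")
    if rc_nm < 0:
        raise ValueError("critical radius must be >= 0")
    if pts.shape[0] == 1 or rc_nm == 0:
        return 0.0
    tree = cKDTree(pts, boxsize=box_nm)
    d, _ = tree.query(pts, k=2)
    return float(np.mean(d[:, 1] < rc_nm))
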