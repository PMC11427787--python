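"""Closed-form photophysics of transfer-to-trap concentration quenching.

Fluorophores confined to a 2D lipid film self-quench as their surface density
rises.  The model treats quenching as a two-step process: excitons hop between
fluorophores by Förster resonance energy transfer (FRET) until they reach a
*trap* — a statistical pair of fluorophores transiently closer than a critical
radius ``R_C`` — where the energy dissipates non-radiatively.  For a spatially
random (Poisson) arrangement of fluorophores at number density ``C_N`` the
fraction of fluorophores engaged in traps is ``f_T = 1 - exp(-pi R_C^2 C_N)``,
and in the strong-FRET regime the observable consequences are

* lifetime:   ``tau/tau0   = exp(-pi R_C^2 C_N)``
* intensity:  ``F/F0       = exp(-2 pi R_C^2 C_N)``  (trapping quenches the
  intensity twice: statically, by removing trap members from the emitting
  pool, and dynamically, through transfer-to-trap)

so ``ln(tau0/tau)`` is linear in ``C_N`` with slope ``pi R_C^2`` — the
relationship used downstream to estimate ``R_C`` from FLIM data.

All lengths are in nm, times in ns, diffusion constants in um^2/s, and
concentrations either in mol/mol percent (``c_molpercent``) or number density
per nm^2 (``cn_per_nm2``); conversions are centralized here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "ModelConfig",
    "FluorophoreParams",
    "DEFAULT_CONFIG",
    "PRESETS",
    "get_preset",
    "load_fluorophore",
    "save_fluorophore",
    "mol_percent_to_number_density",
    "number_density_to_mol_percent",
    "weight_percent_to_mol_percent",
    "mean_separation",
    "nearest_neighbor_mean_separation",
    "separation_to_number_density",
    "diffusion_displacement",
    "forster_radius",
    "critical_concentration",
    "trap_fraction",
    "prob_fret",
    "prob_ett",
    "qe_from_lifetimes",
    "qe_theoretical",
    "lifetime_ratio",
    "intensity_ratio",
    "unquench_intensity",
]

# conversion: 1 um^2/s = 1e6 nm^2 / 1e9 ns
_UM2_PER_S_TO_NM2_PER_NS = 1.0e-3


@dataclass(frozen=True)
class ModelConfig:
    """Membrane/optical constants shared by all photophysics calculations.

    Parameters
    ----------
    area_per_lipid : float
        Area occupied by one lipid in the leaflet plane, nm^2.  A fluorophore-
        lipid is assumed to occupy the same area as an unlabeled lipid.
    kappa_sq : float
        Dipole orientation factor kappa^2 for FRET; 2/3 is the isotropic
        dynamic-averaging value appropriate for laterally and rotationally
        mobile lipid-tethered dyes.
    refractive_index : float
        Refractive index of the optical medium around the dye; 1.45 is
        halfway between water (1.33) and the lipid acyl region (1.55).
    """

    area_per_lipid: float = 0.69
    kappa_sq: float = 2.0 / 3.0
    refractive_index: float = 1.45

    def __post_init__(self) -> None:
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be positive")
        if not 0.0 <= self.kappa_sq <= 4.0:
            raise ValueError("kappa_sq must lie in [0, 4]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class FluorophoreParams:
    """Photophysical constants of one dye-lipid species.

    Attributes
    ----------
    name : str
        Label, e.g. ``"texas_red"``.
    tau0_ns : float
        Unquenched fluorescence lifetime, ns (from a dilute reference).
    phi : float
        Fluorescence quantum yield, in (0, 1].
    diffusion_um2_s : float
        Lateral diffusion constant of the lipid in the bilayer, um^2/s.
    overlap_J : float or None
        Donor-emission/self-absorption spectral overlap integral,
        M^-1 cm^-1 nm^4.
    forster_radius_nm : float or None
        Förster radius R0, nm (separation at 50% FRET probability).
    critical_radius_nm : float or None
        Critical radius for trap formation R_C, nm.
    charge : float
        Net charge of the dye-lipid in elementary charges (drives
        electrophoretic drift; does not enter the photophysics).
    """

    name: str
    tau0_ns: float
    phi: float
    diffusion_um2_s: float = 0.0
    overlap_J: float | None = None
    forster_radius_nm: float | None = None
    critical_radius_nm: float | None = None
    charge: float = -1.0

    def __post_init__(self) -> None:
        if self.tau0_ns <= 0:
            raise ValueError("tau0_ns must be positive")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("phi must lie in (0, 1]")
        if self.diffusion_um2_s < 0:
            raise ValueError("diffusion_um2_s must be >= 0")
        if self.forster_radius_nm is not None and self.forster_radius_nm <= 0:
            raise ValueError("forster_radius_nm must be positive when set")
        if self.critical_radius_nm is not None and self.critical_radius_nm < 0:
            raise ValueError("critical_radius_nm must be >= 0 when set")


# Shipped presets for the three dye-lipids studied with this pipeline.
# tau0 for NBD and BODIPY follow from their dilute-limit QE bookkeeping
# (quenched lifetime / (1 - QE)); J, R0, R_C are the published constants.
PRESETS: dict[str, FluorophoreParams] = {
    "texas_red": FluorophoreParams(
        name="texas_red", tau0_ns=4.23, phi=0.93, diffusion_um2_s=2.27,
        overlap_J=3.08e15, forster_radius_nm=5.73, critical_radius_nm=2.02,
    ),
    "nbd": FluorophoreParams(
        name="nbd", tau0_ns=6.99, phi=0.40, diffusion_um2_s=2.27,
        overlap_J=0.28e15, forster_radius_nm=3.32, critical_radius_nm=1.14,
    ),
    "bodipy": FluorophoreParams(
        name="bodipy", tau0_ns=5.40, phi=0.99, diffusion_um2_s=2.27,
        overlap_J=2.13e15, forster_radius_nm=5.41, critical_radius_nm=2.70,
    ),
}


def get_preset(name: str) -> FluorophoreParams:
    """Return a shipped fluorophore preset by name (case-insensitive)."""
    key = name.lower().replace("-", "_").replace(" ", "_")
    aliases = {"tr": "texas_red", "texasred": "texas_red"}
    key = aliases.get(key, key)
    try:
        return PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown fluorophore preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_fluorophore(path: str | Path) -> FluorophoreParams:
    """Load a fluorophore parameter record from a JSON file."""
    with open(path) as fh:
        return FluorophoreParams(**json.load(fh))


def save_fluorophore(f: FluorophoreParams, path: str | Path) -> None:
    """Write a fluorophore parameter record to a JSON file."""
    with open(path, "w") as fh:
        json.dump(asdict(f), fh, indent=2)


# ---------------------------------------------------------------------------
# concentration conversions
# ---------------------------------------------------------------------------

def _nonnegative(x: ArrayLike, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{what} must be >= 0")
    return arr


def mol_percent_to_number_density(
    c_molpercent: ArrayLike, cfg: ModelConfig = DEFAULT_CONFIG
) -> np.ndarray | float:
    """Convert mol/mol % of labeled lipid to fluorophores per nm^2.

    ``C_N = (C_% / 100) / A_lip`` — each lipid occupies ``A_lip`` nm^2, so a
    mole fraction maps directly to an in-plane number density (single-leaflet
    treatment; both leaflets are assumed identically labeled).
    """
    c = _nonnegative(c_molpercent, "concentration")
    out = (c / 100.0) / cfg.area_per_lipid
    return out if out.ndim else float(out)


def number_density_to_mol_percent(
    cn_per_nm2: ArrayLike, cfg: ModelConfig = DEFAULT_CONFIG
) -> np.ndarray | float:
    """Inverse of :func:`mol_percent_to_number_density` (exact round-trip)."""
    cn = _nonnegative(cn_per_nm2, "number density")
    out = cn * cfg.area_per_lipid * 100.0
    return out if out.ndim else float(out)


def weight_percent_to_mol_percent(
    w_percent: ArrayLike, mw_dye_lipid: float, mw_bulk_lipid: float
) -> np.ndarray | float:
    """Convert a w/w percentage of dye-lipid to mol/mol percent.

    ``mol% = 100 (w/M_dye) / (w/M_dye + (100-w)/M_bulk)`` for molecular
    weights in g/mol.
    """
    if mw_dye_lipid <= 0 or mw_bulk_lipid <= 0:
        raise ValueError("molecular weights must be positive")
    w = np.asarray(w_percent, dtype=float)
    if np.any((w < 0) | (w > 100)):
        raise ValueError("weight percent must lie in [0, 100]")
    moles_dye = w / mw_dye_lipid
    moles_bulk = (100.0 - w) / mw_bulk_lipid
    out = 100.0 * moles_dye / (moles_dye + moles_bulk)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# geometry of the random 2D arrangement
# ---------------------------------------------------------------------------

def mean_separation(cn_per_nm2: ArrayLike) -> np.ndarray | float:
    """Mean center-to-center separation ``r = (pi C_N)^(-1/2)`` in nm.

    Derived from assigning each molecule an effective circular area
    ``1/C_N = pi r^2``.  Zero density maps to ``inf`` (an isolated
    fluorophore), which arises naturally in depleted profile tails.
    """
    cn = _nonnegative(cn_per_nm2, "number density")
    with np.errstate(divide="ignore"):
        out = 1.0 / np.sqrt(np.pi * cn)
    return out if out.ndim else float(out)


def nearest_neighbor_mean_separation(cn_per_nm2: ArrayLike) -> np.ndarray | float:
    """Mean nearest-neighbor distance of a 2D Poisson process, ``0.5 C_N^(-1/2)``.

    The exact first moment of the 2D Poisson nearest-neighbor distribution;
    differs from :func:`mean_separation` only by the constant factor
    ``sqrt(pi)/2 ~ 0.886``.
    """
    cn = _nonnegative(cn_per_nm2, "number density")
    with np.errstate(divide="ignore"):
        out = 0.5 / np.sqrt(cn)
    return out if out.ndim else float(out)


def separation_to_number_density(r_nm: ArrayLike) -> np.ndarray | float:
    """Invert :func:`mean_separation`: ``C_N = 1/(pi r^2)``."""
    r = np.asarray(r_nm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    out = 1.0 / (np.pi * r**2)
    return out if out.ndim else float(out)


def diffusion_displacement(f: FluorophoreParams) -> float:
    """RMS lateral displacement ``<x> = sqrt(4 D tau0)`` during one lifetime, nm.

    Gauges whether collisional quenching is plausible: for lipid-tethered
    dyes this is ~0.2 nm, far below typical inter-fluorophore separations, so
    excited molecules are effectively static and quenching must proceed by
    energy transfer instead of contact.
    """
    d_nm2_ns = f.diffusion_um2_s * _UM2_PER_S_TO_NM2_PER_NS
    return float(np.sqrt(4.0 * d_nm2_ns * f.tau0_ns))


# ---------------------------------------------------------------------------
# FRET and trapping probabilities
# ---------------------------------------------------------------------------

def forster_radius(
    overlap_J: float, phi: float, cfg: ModelConfig = DEFAULT_CONFIG
) -> float:
    """Förster radius ``R0`` in nm from the spectral overlap integral.

    ``R0^6 = 8.79e-5 J kappa^2 n^-4 phi`` with J in M^-1 cm^-1 nm^4 yields
    R0 in Angstrom; the result is returned in nm.
    """
    if overlap_J < 0:
        raise ValueError("overlap integral must be >= 0")
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must lie in (0, 1]")
    r0_ang6 = (
        8.79e-5 * overlap_J * cfg.kappa_sq * cfg.refractive_index**-4 * phi
    )
    return float(r0_ang6 ** (1.0 / 6.0) / 10.0)


def critical_concentration(rc_nm: float) -> float:
    """Number density at which the trap fraction reaches 1 - 1/e: ``1/(pi R_C^2)``."""
    if rc_nm <= 0:
        raise ValueError("critical radius must be positive")
    return float(1.0 / (np.pi * rc_nm**2))


def trap_fraction(cn_per_nm2: ArrayLike, rc_nm: float) -> np.ndarray | float:
    """Fraction of fluorophores engaged in trap pairs, ``1 - exp(-pi R_C^2 C_N)``.

    The probability that a Poisson-distributed fluorophore has at least one
    neighbor within ``R_C``.
    """
    cn = _nonnegative(cn_per_nm2, "number density")
    if rc_nm < 0:
        raise ValueError("critical radius must be >= 0")
    out = -np.expm1(-np.pi * rc_nm**2 * cn)
    return out if out.ndim else float(out)


def prob_fret(cn_per_nm2: ArrayLike, r0_nm: float) -> np.ndarray | float:
    """Probability of FRET to the mean-separation neighbor.

    ``P_FRET = R0^6 / (R0^6 + r^6)`` with ``r = (pi C_N)^(-1/2)``, i.e.
    ``R0^6 / (R0^6 + (pi C_N)^-3)``.
    """
    cn = _nonnegative(cn_per_nm2, "number density")
    if r0_nm <= 0:
        raise ValueError("Förster radius must be positive")
    r0_6 = r0_nm**6
    with np.errstate(divide="ignore"):
        r6 = (np.pi * cn) ** -3.0
    out = r0_6 / (r0_6 + r6)
    return out if out.ndim else float(out)


def prob_ett(
    cn_per_nm2: ArrayLike, r0_nm: float, rc_nm: float
) -> np.ndarray | float:
    """Probability of excitation transfer to a trap, ``P_FRET x f_T``.

    The exact model's quenching efficiency: an exciton must both transfer
    (FRET) and land in a trap pair.
    """
    out = np.asarray(prob_fret(cn_per_nm2, r0_nm)) * np.asarray(
        trap_fraction(cn_per_nm2, rc_nm)
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# observable quenching laws (strong-FRET simplification, P_FRET ~ 1)
# ---------------------------------------------------------------------------

def qe_from_lifetimes(tau_ns: ArrayLike, tau0_ns: float) -> np.ndarray | float:
    """Quenching efficiency ``QE = 1 - tau/tau0`` from measured lifetimes.

    Fitted lifetimes marginally above ``tau0`` (low-count noise) are clamped
    to ``QE = 0`` with a warning rather than reported as negative quenching.
    """
    if tau0_ns <= 0:
        raise ValueError("tau0 must be positive")
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    out = 1.0 - tau / tau0_ns
    if np.any(out < 0):
        warnings.warn(
            "lifetime(s) exceed tau0; clamping QE to 0", stacklevel=2
        )
        out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


def qe_theoretical(cn_per_nm2: ArrayLike, rc_nm: float) -> np.ndarray | float:
    """Model quenching efficiency ``QE = 1 - exp(-pi R_C^2 C_N)``.

    Identical to :func:`trap_fraction`: in the strong-FRET regime every
    exciton that can reach a trap does, so QE equals the trap fraction.
    """
    return trap_fraction(cn_per_nm2, rc_nm)


def lifetime_ratio(cn_per_nm2: ArrayLike, rc_nm: float) -> np.ndarray | float:
    """``tau/tau0 = exp(-pi R_C^2 C_N)``; ``ln(tau0/tau)`` is linear in C_N."""
    cn = _nonnegative(cn_per_nm2, "number density")
    out = np.exp(-np.pi * rc_nm**2 * cn)
    return out if out.ndim else float(out)


def intensity_ratio(cn_per_nm2: ArrayLike, rc_nm: float) -> np.ndarray | float:
    """``F/F0 = exp(-2 pi R_C^2 C_N)`` — the square of :func:`lifetime_ratio`.

    Intensity is quenched twice: statically (trap members are dark) and
    dynamically (transfer-to-trap), each contributing a factor ``1 - f_T``.
    """
    cn = _nonnegative(cn_per_nm2, "number density")
    out = np.exp(-2.0 * np.pi * rc_nm**2 * cn)
    return out if out.ndim else float(out)


def unquench_intensity(
    counts: ArrayLike, tau_ns: ArrayLike, tau0_ns: float
) -> np.ndarray | float:
    """Recover the unquenched intensity ``F0 = F (tau0/tau)^2``.

    The working formula of the concentration reconstruction: the lifetime
    drop measures the dynamic quenching, whose square is the total intensity
    quench, so dividing it out restores the intensity a dilute film of the
    same density would emit.
    """
    if tau0_ns <= 0:
        raise ValueError("tau0 must be positive")
    tau = np.asarray(tau_ns, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    f = np.asarray(counts, dtype=float)
    out = f * (tau0_ns / tau) ** 2
    return out if out.ndim else float(out)
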