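"""Photon beam-quality characterization: HVL, attenuation, effective energy.

The quality of an x-ray beam is summarized by its first and second half-value
layers (HVL, mm Al).  The HVL defines a linear attenuation coefficient
mu = ln2 / HVL; the *effective energy* of the beam is the monoenergetic
photon energy whose aluminium mass-attenuation coefficient matches
mu / rho_Al.  The Al mu/rho grid ships as a fixture (standard NIST/XCOM
total-with-coherent values; a without-coherent toggle point is the caller's
choice of fixture); it is strictly decreasing over 5-1500 keV so the
inversion is unique.

The Co-60 beam carries no HVL: its tabulated equivalent energy, the mean of
the two gamma lines (1044.7 keV), is stored verbatim in the registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ConfigurationError, RangeError

__all__ = [
    "RHO_AL",
    "BeamQuality",
    "AttenuationTable",
    "load_al_attenuation",
    "mu_from_hvl",
    "effective_energy",
    "hvl_from_energy",
    "homogeneity",
    "get_beam",
    "available_beams",
]

RHO_AL = 2.699  # g/cm^3


@dataclass(frozen=True)
class BeamQuality:
    """One photon beam: HVLs in mm Al plus its tabulated equivalent energy."""

    name: str
    tube_potential: str  # "20" ... "160" (kV) or "Co60"
    added_filter: str
    hvl1: float | None  # mm Al
    hvl2: float | None  # mm Al
    effective_energy: float  # keV

    def __post_init__(self):
        if self.hvl1 is not None and self.hvl1 <= 0:
            raise ConfigurationError("hvl1 must be > 0")
        if self.hvl2 is not None and self.hvl1 is not None and self.hvl2 < self.hvl1:
            raise ConfigurationError("hvl2 must be >= hvl1 (beam hardening)")
        if self.effective_energy <= 0:
            raise ConfigurationError("effective energy must be > 0")

    @property
    def is_co60(self) -> bool:
        return self.tube_potential.lower() == "co60"


@dataclass(frozen=True)
class AttenuationTable:
    """mu/rho (cm^2/g) for one absorber on a strictly increasing energy grid."""

    energies: np.ndarray  # keV
    mu_over_rho: np.ndarray  # cm^2/g
    density: float  # g/cm^3
    absorber: str = "Al"

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ConfigurationError("attenuation grid must be strictly increasing")
        if np.any(np.diff(m) >= 0):
            raise ConfigurationError(
                "mu/rho must be strictly decreasing (no edges expected here)"
            )
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", m)

    def mu_rho_at(self, energy_keV: float) -> float:
        """Log-log interpolated mu/rho at an energy inside the grid."""
        e = float(energy_keV)
        if e < self.energies[0] or e > self.energies[-1]:
            raise RangeError(
                f"energy {e} keV outside attenuation grid "
                f"[{self.energies[0]}, {self.energies[-1]}]"
            )
        return float(
            np.exp(
                np.interp(np.log(e), np.log(self.energies), np.log(self.mu_over_rho))
            )
        )


def load_al_attenuation() -> AttenuationTable:
    """The bundled aluminium attenuation fixture."""
    text = resources.files("letfilm.data").joinpath("al_mu_rho.tsv").read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    arr = np.array(rows, dtype=float)
    return AttenuationTable(energies=arr[:, 0], mu_over_rho=arr[:, 1], density=RHO_AL)


def mu_from_hvl(hvl_mm: float) -> float:
    """Linear attenuation coefficient (cm^-1) from an HVL in mm."""
    if hvl_mm <= 0:
        raise ConfigurationError("HVL must be > 0")
    return float(np.log(2.0) / (hvl_mm / 10.0))


def effective_energy(hvl1_mm: float, table: AttenuationTable | None = None) -> float:
    """Effective photon energy (keV) matching the HVL-derived mu/rho.

    Solves mu/rho(E) = ln2 / (hvl/10) / rho on the (monotone) log-log
    interpolant of the attenuation grid; unique by monotonicity.
    """
    table = table if table is not None else load_al_attenuation()
    target = mu_from_hvl(hvl1_mm) / table.density
    m = table.mu_over_rho
    if target > m[0] or target < m[-1]:
        raise RangeError(
            f"mu/rho = {target:.4g} cm^2/g outside attenuation grid "
            f"[{m[-1]:.4g}, {m[0]:.4g}]"
        )
    # mu/rho decreasing in E -> interpolate ln E against descending ln(mu/rho)
    ln_e = np.interp(np.log(target), np.log(m[::-1]), np.log(table.energies[::-1]))
    return float(np.exp(ln_e))


def hvl_from_energy(energy_keV: float, table: AttenuationTable | None = None) -> float:
    """Inverse companion: the Al HVL (mm) a monoenergetic beam would show."""
    table = table if table is not None else load_al_attenuation()
    mu = table.mu_rho_at(energy_keV) * table.density  # cm^-1
    return float(np.log(2.0) / mu * 10.0)


def homogeneity(hvl1_mm: float, hvl2_mm: float) -> float:
    """Homogeneity coefficient hvl1/hvl2 (<= 1 for hardening beams)."""
    if hvl1_mm <= 0 or hvl2_mm <= 0:
        raise ConfigurationError("HVLs must be > 0")
    return hvl1_mm / hvl2_mm


# ---------------------------------------------------------------------------
# bundled beam registry

_BEAMS: dict[str, BeamQuality] | None = None


def _load_beams() -> dict[str, BeamQuality]:
    text = resources.files("letfilm.data").joinpath("beams.tsv").read_text()
    beams = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, kvp, filt, hvl1, hvl2, eff = line.split("\t")
        beams[name] = BeamQuality(
            name=name,
            tube_potential=kvp,
            added_filter=filt,
            hvl1=None if hvl1 == "-" else float(hvl1),
            hvl2=None if hvl2 == "-" else float(hvl2),
            effective_energy=float(eff),
        )
    return beams


def _beams() -> dict[str, BeamQuality]:
    global _BEAMS
    if _BEAMS is None:
        _BEAMS = _load_beams()
    return _BEAMS


def available_beams() -> list[str]:
    """Study beams in ascending equivalent-energy order."""
    return sorted(_beams(), key=lambda n: _beams()[n].effective_energy)


def get_beam(name: str) -> BeamQuality:
    try:
        return _beams()[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown beam {name!r}; known: {available_beams()}"
        ) from None
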