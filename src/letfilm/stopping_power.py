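"""Electron collision stopping powers, unrestricted and restricted.

Analytic Bethe theory for the mean collision energy loss of electrons, with
the Møller close-collision term for identical particles and the
Sternheimer-Peierls density-effect correction computed from the material's
mean excitation energy and electron density.  Radiative losses are excluded
throughout: LET is a collision quantity.  Shell corrections are omitted from
the analytic backend; a tabulated backend can be loaded from a two-column
fixture when higher accuracy is needed.

Conventions
-----------
* energies in keV, mass stopping powers in MeV cm^2/g;
* restricted stopping power L_Delta(E) counts energy transfers below the
  cutoff Delta; because the maximum transfer between identical particles is
  E/2, L_Delta(E) == S(E) exactly whenever Delta >= E/2;
* validity window 1 keV <= E <= 10 MeV (electron cross sections below 1 keV
  are not trusted, mirroring the Delta = 1 keV floor used for LET).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FormatError, RangeError
from .materials import Material

__all__ = [
    "E_MIN_KEV",
    "E_MAX_KEV",
    "collision_stopping_power",
    "restricted_stopping_power",
    "linear_let",
    "density_effect_delta",
    "StoppingPowerTable",
    "build_table",
    "load_table",
    "load_water_reference",
]

MC2_KEV = 510.99895  # electron rest energy, keV
# 2 pi r_e^2 m_e c^2 N_A  (MeV cm^2 / mol); multiplied by Z/A -> MeV cm^2/g
_K_COEF = 0.1535374
E_MIN_KEV = 1.0
E_MAX_KEV = 10_000.0

_LN10 = np.log(10.0)


def _check_window(E_keV: np.ndarray) -> np.ndarray:
    E = np.asarray(E_keV, dtype=float)
    if np.any(E < E_MIN_KEV - 1e-12) or np.any(E > E_MAX_KEV + 1e-9):
        raise RangeError(
            f"electron energy outside validity window "
            f"[{E_MIN_KEV}, {E_MAX_KEV}] keV"
        )
    return E


def _plasma_energy_ev(material: Material) -> float:
    """hbar omega_p = 28.8159 sqrt(rho <Z/A>) eV."""
    mean_za = material.electrons_per_gram / 6.02214076e23
    return 28.8159 * float(np.sqrt(material.density * mean_za))


def density_effect_delta(material: Material, E_keV) -> np.ndarray:
    """Sternheimer-Peierls general-prescription density-effect correction.

    Parameters C, x0, x1, a (m = 3) are derived from the material's I and
    plasma energy with the standard non-conductor rules; x = log10(beta*gamma).
    """
    E = np.asarray(E_keV, dtype=float)
    tau = E / MC2_KEV
    gamma2 = (1.0 + tau) ** 2
    beta2 = 1.0 - 1.0 / gamma2
    x = 0.5 * np.log10(beta2 * gamma2)

    I = material.I_eV
    if I <= 0:
        raise ConfigurationError("mean excitation energy must be positive")
    hw_p = _plasma_energy_ev(material)
    c_bar = 2.0 * np.log(I / hw_p) + 1.0
    if I < 100.0:
        x1 = 2.0
        x0 = 0.2 if c_bar < 3.681 else 0.326 * c_bar - 1.0
    else:
        x1 = 3.0
        x0 = 0.2 if c_bar < 5.215 else 0.326 * c_bar - 1.5
    a = (c_bar - 2.0 * _LN10 * x0) / (x1 - x0) ** 3

    delta = np.zeros_like(x)
    mid = (x >= x0) & (x < x1)
    high = x >= x1
    delta[mid] = 2.0 * _LN10 * x[mid] - c_bar + a * (x1 - x[mid]) ** 3
    delta[high] = 2.0 * _LN10 * x[high] - c_bar
    return np.maximum(delta, 0.0)


def _bracket_common(material: Material, E: np.ndarray):
    tau = E / MC2_KEV
    gamma2 = (1.0 + tau) ** 2
    beta2 = 1.0 - 1.0 / gamma2
    i_ratio = material.I_eV * 1e-3 / MC2_KEV  # I in units of mc^2
    ln_term = np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio**2))
    return tau, beta2, ln_term


def collision_stopping_power(
    material: Material, E_keV, density_effect: bool = True
) -> np.ndarray | float:
    """Unrestricted collision mass stopping power S(E), MeV cm^2/g.

    Bethe formula with the Moller close-collision term:
    S = k (Z/A) / beta^2 [ ln(tau^2(tau+2)/2(I/mc^2)^2) + F(tau) - delta ]
    with F(tau) = 1 - beta^2 + [tau^2/8 - (2 tau + 1) ln 2] / (tau+1)^2.
    """
    E = _check_window(E_keV)
    scalar = E.ndim == 0
    E = np.atleast_1d(E)
    tau, beta2, ln_term = _bracket_common(material, E)
    f_tau = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (
        tau + 1.0
    ) ** 2
    delta = density_effect_delta(material, E) if density_effect else 0.0
    mean_za = material.electrons_per_gram / 6.02214076e23
    s = _K_COEF * mean_za / beta2 * (ln_term + f_tau - delta)
    return float(s[0]) if scalar else s


def restricted_stopping_power(
    material: Material, E_keV, delta: float, density_effect: bool = True
) -> np.ndarray | float:
    """Restricted collision mass stopping power L_Delta(E), MeV cm^2/g.

    Moller theory counting only energy transfers below Delta (keV).  With
    eta = Delta/E clamped at 1/2:
    G(tau, eta) = -1 - beta^2 + ln[4 (1-eta) eta] + 1/(1-eta)
                  + (1-beta^2) [tau^2 eta^2 / 2 + (2 tau + 1) ln(1-eta)]
    and G(tau, 1/2) reduces exactly to the unrestricted F(tau).
    """
    if delta <= 0:
        raise ConfigurationError("restriction cutoff Delta must be > 0")
    E = _check_window(E_keV)
    scalar = E.ndim == 0
    E = np.atleast_1d(E)
    tau, beta2, ln_term = _bracket_common(material, E)
    eta = np.minimum(delta / E, 0.5)
    one_m = 1.0 - eta
    g = (
        -1.0
        - beta2
        + np.log(4.0 * one_m * eta)
        + 1.0 / one_m
        + (1.0 - beta2) * (tau**2 * eta**2 / 2.0 + (2.0 * tau + 1.0) * np.log(one_m))
    )
    d = density_effect_delta(material, E) if density_effect else 0.0
    mean_za = material.electrons_per_gram / 6.02214076e23
    l = _K_COEF * mean_za / beta2 * (ln_term + g - d)
    return float(l[0]) if scalar else l


def linear_let(mass_stopping: float, density: float) -> float:
    """Convert a mass stopping power (MeV cm^2/g) to linear LET (keV/um).

    keV/um = MeV cm^2/g * g/cm^3 * 0.1 (unit identity).
    """
    if mass_stopping <= 0 or density <= 0:
        raise ConfigurationError("mass stopping power and density must be > 0")
    return mass_stopping * density * 0.1


# ---------------------------------------------------------------------------
# tabulated backend

@dataclass(frozen=True)
class StoppingPowerTable:
    """S(E) and L_Delta(E) for one material on a strictly increasing grid.

    Lookup between grid points is log-log linear (stopping power is close to
    a power law over any small interval).
    """

    material: Material
    energies: np.ndarray  # keV
    S: np.ndarray  # MeV cm^2/g
    L_delta: np.ndarray  # MeV cm^2/g
    delta_cut: float  # keV
    density_effect_enabled: bool = True

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ConfigurationError("energy grid must be strictly increasing")
        s = np.asarray(self.S, dtype=float)
        l = np.asarray(self.L_delta, dtype=float)
        if np.any(s <= 0) or np.any(l <= 0):
            raise ConfigurationError("stopping powers must be positive")
        if np.any(l > s * (1 + 1e-12)):
            raise ConfigurationError("L_delta must not exceed S")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "S", s)
        object.__setattr__(self, "L_delta", l)

    def _interp(self, values: np.ndarray, E_keV) -> np.ndarray | float:
        E = np.asarray(E_keV, dtype=float)
        scalar = E.ndim == 0
        E = np.atleast_1d(E)
        if np.any(E < self.energies[0] * (1 - 1e-12)) or np.any(
            E > self.energies[-1] * (1 + 1e-12)
        ):
            raise RangeError(
                f"lookup energy outside table range "
                f"[{self.energies[0]}, {self.energies[-1]}] keV"
            )
        out = np.exp(
            np.interp(np.log(E), np.log(self.energies), np.log(values))
        )
        return float(out[0]) if scalar else out

    def lookup_S(self, E_keV):
        return self._interp(self.S, E_keV)

    def lookup_L(self, E_keV):
        return self._interp(self.L_delta, E_keV)


def build_table(
    material: Material,
    grid_keV,
    delta: float,
    density_effect: bool = True,
) -> StoppingPowerTable:
    """Evaluate the analytic backend on a grid and wrap it as a table."""
    grid = np.asarray(grid_keV, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("grid must be strictly increasing")
    s = collision_stopping_power(material, grid, density_effect)
    l = restricted_stopping_power(material, grid, delta, density_effect)
    return StoppingPowerTable(
        material=material,
        energies=grid,
        S=np.asarray(s),
        L_delta=np.minimum(np.asarray(l), np.asarray(s)),
        delta_cut=delta,
        density_effect_enabled=density_effect,
    )


def load_table(path: str | Path, material: Material) -> StoppingPowerTable:
    """Load a tabulated backend from the two/three-column fixture dialect.

    Comment-prefixed header lines (``# material:``, ``# delta_keV:``), then
    whitespace-delimited rows ``energy_keV  S_MeVcm2g  [Ldelta_MeVcm2g]``.
    When the L_delta column is absent it defaults to S (unrestricted table).
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns")
        rows.append([float(p) for p in parts])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.array([r + [r[1]] * (3 - len(r)) for r in rows], dtype=float)
    delta_cut = float(header.get("delta_keV", "inf"))
    return StoppingPowerTable(
        material=material,
        energies=arr[:, 0],
        S=arr[:, 1],
        L_delta=arr[:, 2],
        delta_cut=delta_cut,
    )


def load_water_reference() -> tuple[np.ndarray, np.ndarray]:
    """Bundled reference water collision stopping powers (validation fixture).

    Returns (energies_keV, S_MeVcm2g).
    """
    text = resources.files("letfilm.data").joinpath("water_reference_sp.tsv").read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    arr = np.array(rows, dtype=float)
    return arr[:, 0], arr[:, 1]
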