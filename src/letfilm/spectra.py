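"""Binned electron-fluence spectra per unit absorbed dose.

A :class:`FluenceSpectrum` holds a histogram of electron fluence differential
in energy, normalized per unit absorbed dose (cm^-2 keV^-1 Gy^-1), with
per-bin standard errors and provenance metadata (medium, beam, and whether it
is the total fluence TEF, the photon-set-in-motion primaries PE, or the
electron-set-in-motion secondaries SE).

Bins are half-open [lo, hi) on a strictly increasing edge grid whose first
edge is at or above the 1 keV floor below which electron cross sections are
not trusted; the representative energy of a bin is its arithmetic midpoint,
matching Monte Carlo tally practice.  Per-bin uncertainties are treated as
uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import AlignmentError, ConfigurationError, FormatError, RangeError
from .stopping_power import StoppingPowerTable

__all__ = [
    "ENERGY_FLOOR_KEV",
    "UNITS_TAG",
    "GY_PER_MEV_G",
    "FluenceSpectrum",
    "RatioSpectrum",
    "read_spectrum",
    "write_spectrum",
    "se_fraction",
    "cema",
    "rebin",
]

ENERGY_FLOOR_KEV = 1.0
UNITS_TAG = "per_cm2_per_keV_per_Gy"
#: Gy per (MeV/g): 1 MeV = 1.602176634e-13 J; 1/g = 1e3/kg.
GY_PER_MEV_G = 1.602176634e-10

_KINDS = ("TEF", "PE", "SE")


@dataclass(frozen=True)
class FluenceSpectrum:
    """Electron fluence differential in energy per unit absorbed dose."""

    bin_edges: np.ndarray  # keV, strictly increasing, first edge >= 1 keV
    phi: np.ndarray  # cm^-2 keV^-1 Gy^-1, one per bin
    sigma_phi: np.ndarray  # same units
    kind: str  # TEF | PE | SE
    medium: str
    beam: str

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        sig = np.asarray(self.sigma_phi, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("bin edges must be strictly increasing")
        if edges[0] < ENERGY_FLOOR_KEV - 1e-9:
            raise ConfigurationError(
                f"first bin edge below the {ENERGY_FLOOR_KEV} keV floor"
            )
        if len(phi) != len(edges) - 1 or len(sig) != len(phi):
            raise ConfigurationError("phi/sigma_phi length must be n_edges - 1")
        if np.any(phi < 0) or np.any(sig < 0):
            raise ConfigurationError("phi and sigma_phi must be non-negative")
        if self.kind not in _KINDS:
            raise ConfigurationError(f"kind must be one of {_KINDS}")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "sigma_phi", sig)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def e_max(self) -> float:
        return float(self.bin_edges[-1])

    @property
    def total_fluence(self) -> float:
        """Integral of phi dE over all bins, cm^-2 Gy^-1."""
        return float(np.sum(self.phi * self.widths))


@dataclass(frozen=True)
class RatioSpectrum:
    """Bin-wise dimensionless ratio of two spectra (e.g. SE/TEF)."""

    bin_edges: np.ndarray
    ratio: np.ndarray
    sigma: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# file dialect

_MANDATORY_KEYS = ("kind", "medium", "beam", "units")


def read_spectrum(path: str | Path) -> FluenceSpectrum:
    """Read a spectrum from the text dialect.

    ``#``-prefixed header with mandatory keys ``kind``, ``medium``, ``beam``,
    ``units: per_cm2_per_keV_per_Gy``; then whitespace-delimited columns
    ``e_lo_keV  e_hi_keV  phi  sigma_phi``.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric field") from None
    for key in _MANDATORY_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing mandatory header key {key!r}")
    if header["units"] != UNITS_TAG:
        raise FormatError(f"{path}: units must be {UNITS_TAG!r}")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    edges = np.append(arr[:, 0], arr[-1, 1])
    if not np.allclose(arr[1:, 0], arr[:-1, 1], rtol=0, atol=1e-9):
        raise FormatError(f"{path}: bins are not contiguous")
    try:
        return FluenceSpectrum(
            bin_edges=edges,
            phi=arr[:, 2],
            sigma_phi=arr[:, 3],
            kind=header["kind"],
            medium=header["medium"],
            beam=header["beam"],
        )
    except ConfigurationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_spectrum(spectrum: FluenceSpectrum, path: str | Path) -> None:
    """Write the dialect; emits bit-identical round trips for parsed files."""
    path = Path(path)
    lines = [
        f"# kind: {spectrum.kind}",
        f"# medium: {spectrum.medium}",
        f"# beam: {spectrum.beam}",
        f"# units: {UNITS_TAG}",
        "# e_lo_keV e_hi_keV phi sigma_phi",
    ]
    for lo, hi, p, s in zip(
        spectrum.bin_edges[:-1], spectrum.bin_edges[1:], spectrum.phi, spectrum.sigma_phi
    ):
        lines.append(f"{float(lo)!r} {float(hi)!r} {float(p)!r} {float(s)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# operations

def se_fraction(se: FluenceSpectrum, tef: FluenceSpectrum) -> RatioSpectrum:
    """Bin-wise SE/TEF fraction with uncorrelated quotient error propagation.

    Empty-over-empty bins (0/0) are reported as 0.  The ratio is clipped to
    [0, 1] with tolerance 1e-9 (noise can push SE marginally above TEF).
    """
    if not np.array_equal(se.bin_edges, tef.bin_edges):
        raise AlignmentError("SE and TEF spectra have different bin edges")
    if se.medium != tef.medium or se.beam != tef.beam:
        raise AlignmentError("SE and TEF spectra are for different medium/beam")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tef.phi > 0, se.phi / np.where(tef.phi > 0, tef.phi, 1.0), 0.0)
        rel2 = np.zeros_like(ratio)
        ok = (tef.phi > 0) & (se.phi > 0)
        rel2[ok] = (se.sigma_phi[ok] / se.phi[ok]) ** 2 + (
            tef.sigma_phi[ok] / tef.phi[ok]
        ) ** 2
        sigma = ratio * np.sqrt(rel2)
    ratio = np.clip(ratio, 0.0, 1.0)
    return RatioSpectrum(bin_edges=se.bin_edges.copy(), ratio=ratio, sigma=sigma)


def cema(spectrum: FluenceSpectrum, table: StoppingPowerTable) -> float:
    """Converted energy per unit mass from the fluence, in Gy.

    CEMA = sum_i S(E_mid,i) phi_i dE_i, converted from MeV/g to Gy.  For a
    spectrum correctly normalized per unit absorbed dose this is ~1 Gy/Gy
    (it is the self-consistency check the generator uses to normalize).
    """
    if table.material.name != spectrum.medium:
        raise AlignmentError(
            f"table material {table.material.name!r} != spectrum medium "
            f"{spectrum.medium!r}"
        )
    if spectrum.total_fluence == 0.0:
        return 0.0
    lo, hi = table.energies[0], table.energies[-1]
    mids = spectrum.midpoints
    if mids[0] < lo * (1 - 1e-12) or mids[-1] > hi * (1 + 1e-12):
        raise RangeError("stopping-power table does not cover the spectrum")
    s_mid = table.lookup_S(mids)
    mev_per_g = float(np.sum(s_mid * spectrum.phi * spectrum.widths))
    return mev_per_g * GY_PER_MEV_G


def rebin(spectrum: FluenceSpectrum, new_edges) -> FluenceSpectrum:
    """Rebin onto new edges, conserving fluence (phi * dE) exactly.

    Treats phi as piecewise-constant density within each old bin; the new
    density is the conserved content of the overlap divided by the new width.
    New edges must lie within the old range.  Sigma is combined in quadrature
    over the overlapped content (uncorrelated bins).
    """
    new = np.asarray(new_edges, dtype=float)
    if new.ndim != 1 or len(new) < 2 or np.any(np.diff(new) <= 0):
        raise ConfigurationError("new edges must be strictly increasing")
    old = spectrum.bin_edges
    if new[0] < old[0] - 1e-9 or new[-1] > old[-1] + 1e-9:
        raise RangeError("new edges outside the old spectrum range")

    # cumulative content C(E) = integral of phi up to E (piecewise linear)
    content = np.concatenate([[0.0], np.cumsum(spectrum.phi * spectrum.widths)])
    var_content = np.concatenate(
        [[0.0], np.cumsum((spectrum.sigma_phi * spectrum.widths) ** 2)]
    )
    c_new = np.interp(new, old, content)
    v_new = np.interp(new, old, var_content)
    widths = np.diff(new)
    phi_new = np.diff(c_new) / widths
    sig_new = np.sqrt(np.maximum(np.diff(v_new), 0.0)) / widths
    return replace(
        spectrum, bin_edges=new, phi=phi_new, sigma_phi=sig_new
    )
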