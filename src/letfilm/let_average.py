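"""Track-average and dose-average LET of an electron-fluence spectrum.

The two ICRU averages of the restricted LET L_Delta over a fluence spectrum
Phi(E), evaluated as discrete bin sums with a track-end term:

    L_T = [ sum_i L_i phi_i dE_i + S(D) phi(D) D ] /
          [ sum_i     phi_i dE_i +      phi(D) D ]

    L_D = [ sum_i L_i^2 phi_i dE_i + S(D)^2 phi(D) D ] /
          [ sum_i L_i   phi_i dE_i + S(D)   phi(D) D ]

where D = Delta (1 keV by default), L_i = L_Delta at the bin midpoint and
S(D) phi(D) D accounts for the electrons that slow below Delta, where spectra
are not scored; phi(Delta) is read as the fluence density of the lowest bin.
The dose average weights each spectral component by its contribution to the
absorbed dose, so L_D >= L_T always (Cauchy-Schwarz).  Uncertainties come
from a parametric bootstrap over the per-bin fluence errors.

The module also derives the headline ratio statistics a study grid of
results supports: SE/TEF ratios, beam-to-Co60 ratios, and the percent excess
of the dose average over the track average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LetfilmError
from .spectra import FluenceSpectrum
from .stopping_power import StoppingPowerTable, linear_let

__all__ = [
    "LETConfig",
    "LETResult",
    "track_average_let",
    "dose_average_let",
    "compute_let",
    "let_uncertainties",
    "let_ratio",
    "cross_statistics",
    "load_printed_let_grid",
]


@dataclass(frozen=True)
class LETConfig:
    """Cutoff and conversion settings for the LET averages."""

    delta: float = 1.0  # keV
    density: float | None = None  # g/cm^3; None -> table material density
    include_track_end: bool = True

    def __post_init__(self):
        if self.delta <= 0:
            raise ConfigurationError("delta must be > 0")


@dataclass(frozen=True)
class LETResult:
    """Both LET averages for one spectrum, in keV/um."""

    L_track: float
    L_dose: float
    u_track: float
    u_dose: float
    delta: float
    spectrum_kind: str
    medium: str
    beam: str


def _sums(
    spectrum: FluenceSpectrum, table: StoppingPowerTable, config: LETConfig
) -> tuple[float, float, float]:
    """Return (sum L phi dE, sum L^2 phi dE, sum phi dE) + track-end terms.

    All L in mass-stopping units (MeV cm^2/g); conversion to keV/um happens
    once at the end.
    """
    if config.delta > spectrum.bin_edges[0] + 1e-9:
        raise ConfigurationError(
            f"delta = {config.delta} keV lies above the first bin edge "
            f"{spectrum.bin_edges[0]} keV"
        )
    if spectrum.total_fluence == 0.0:
        raise LetfilmError("spectrum is empty: LET averages are undefined")
    mids = spectrum.midpoints
    w = spectrum.phi * spectrum.widths
    L = np.asarray(table.lookup_L(mids))
    s0 = float(np.sum(w))
    s1 = float(np.sum(L * w))
    s2 = float(np.sum(L * L * w))
    if config.include_track_end:
        # phi(Delta): fluence density of the lowest bin
        phi_d = float(spectrum.phi[0])
        s_delta = float(table.lookup_S(config.delta)) if phi_d > 0 else 0.0
        wd = phi_d * config.delta
        s0 += wd
        s1 += s_delta * wd
        s2 += s_delta**2 * wd
    return s1, s2, s0


def _density(table: StoppingPowerTable, config: LETConfig) -> float:
    return config.density if config.density is not None else table.material.density


def track_average_let(
    spectrum: FluenceSpectrum, table: StoppingPowerTable, config: LETConfig = LETConfig()
) -> float:
    """Fluence-weighted mean restricted LET, keV/um."""
    s1, _, s0 = _sums(spectrum, table, config)
    return linear_let(s1 / s0, _density(table, config))


def dose_average_let(
    spectrum: FluenceSpectrum, table: StoppingPowerTable, config: LETConfig = LETConfig()
) -> float:
    """Dose-weighted mean restricted LET, keV/um (second over first moment)."""
    s1, s2, _ = _sums(spectrum, table, config)
    return linear_let(s2 / s1, _density(table, config))


def let_uncertainties(
    spectrum: FluenceSpectrum,
    table: StoppingPowerTable,
    config: LETConfig = LETConfig(),
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bootstrap standard uncertainties of (L_track, L_dose), keV/um.

    Each replicate resamples phi_i ~ Normal(phi_i, sigma_phi_i) truncated at
    zero and recomputes both averages; deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    if seed is None:
        raise ConfigurationError("a seed is mandatory for the bootstrap")
    if np.all(spectrum.sigma_phi == 0):
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    mids = spectrum.midpoints
    widths = spectrum.widths
    L = np.asarray(table.lookup_L(mids))
    s_delta = float(table.lookup_S(config.delta))
    rho = _density(table, config)
    tracks = np.empty(n_boot)
    doses = np.empty(n_boot)
    for b in range(n_boot):
        phi = np.maximum(
            rng.normal(spectrum.phi, spectrum.sigma_phi), 0.0
        )
        w = phi * widths
        s0 = w.sum()
        s1 = float(np.sum(L * w))
        s2 = float(np.sum(L * L * w))
        if config.include_track_end and phi[0] > 0:
            wd = phi[0] * config.delta
            s0 += wd
            s1 += s_delta * wd
            s2 += s_delta**2 * wd
        tracks[b] = s1 / s0 * rho * 0.1
        doses[b] = s2 / s1 * rho * 0.1
    return float(np.std(tracks, ddof=1)), float(np.std(doses, ddof=1))


def compute_let(
    spectrum: FluenceSpectrum,
    table: StoppingPowerTable,
    config: LETConfig = LETConfig(),
    n_boot: int = 0,
    seed: int | None = None,
) -> LETResult:
    """Evaluate both averages (and, if n_boot > 0, their uncertainties)."""
    lt = track_average_let(spectrum, table, config)
    ld = dose_average_let(spectrum, table, config)
    if n_boot:
        ut, ud = let_uncertainties(spectrum, table, config, n_boot, seed)
    else:
        ut = ud = 0.0
    return LETResult(
        L_track=lt,
        L_dose=ld,
        u_track=ut,
        u_dose=ud,
        delta=config.delta,
        spectrum_kind=spectrum.kind,
        medium=spectrum.medium,
        beam=spectrum.beam,
    )


def let_ratio(result: LETResult) -> float:
    """L_dose / L_track; >= 1 by Cauchy-Schwarz, 1 for monoenergetic spectra."""
    return result.L_dose / result.L_track


# ---------------------------------------------------------------------------
# cross statistics over a study grid

_CO60_NAMES = ("Co60", "co60", "CO60")
_LOW_ENERGY_CUT_KEV = 100.0


def load_printed_let_grid() -> pd.DataFrame:
    """The published study LET grid as a DataFrame (input data for ratios).

    Columns: film, kind, beam, equivalent_energy_keV, L_track, L_dose.
    """
    from importlib import resources

    with resources.files("letfilm.data").joinpath("printed_let_grid.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", header=None,
                         names=["film", "kind", "beam", "equivalent_energy_keV",
                                "L_track", "L_dose"])
    return df


def cross_statistics(grid: pd.DataFrame) -> dict:
    """Derived ratio statistics of a beam x kind x film grid of LET results.

    Expects columns film, kind, beam, equivalent_energy_keV, L_track, L_dose.
    Per film, computes:

    * ``se_tef_track_ratio``: per-beam SE/TEF ratio of L_track, with min/max
      rounded to the nearest integer;
    * ``rel_to_co60``: per kind, each beam's L_track (and L_dose) relative to
      the Co-60 value, x-ray min/max rounded to the nearest integer;
    * ``dose_track_ratio``: per kind, L_dose/L_track per beam; below-100 keV
      min/max to one decimal and the Co-60 value rounded to the nearest
      integer;
    * ``dose_track_percent_excess``: per kind, percent excess of L_dose over
      L_track, below-100 keV min/max rounded to integer percent.

    Missing grid cells are skipped and listed under ``warnings``.
    """
    required = {"film", "kind", "beam", "equivalent_energy_keV", "L_track", "L_dose"}
    missing = required - set(grid.columns)
    if missing:
        raise ConfigurationError(f"grid is missing columns: {sorted(missing)}")
    report: dict = {"films": {}, "warnings": []}
    for film, g in grid.groupby("film"):
        entry: dict = {}
        by = {(r.kind, r.beam): r for r in g.itertuples()}
        beams = sorted(
            {r.beam for r in g.itertuples()},
            key=lambda b: float(g[g.beam == b].equivalent_energy_keV.iloc[0]),
        )
        co60 = next((b for b in beams if b in _CO60_NAMES), None)

        # SE/TEF track-average ratio per beam
        ratios = {}
        for b in beams:
            se, tef = by.get(("SE", b)), by.get(("TEF", b))
            if se is None or tef is None:
                report["warnings"].append(f"{film}/{b}: missing SE or TEF cell")
                continue
            ratios[b] = se.L_track / tef.L_track
        entry["se_tef_track_ratio"] = {
            "per_beam": ratios,
            "min": round(min(ratios.values())) if ratios else None,
            "max": round(max(ratios.values())) if ratios else None,
        }

        # each beam relative to Co-60, per kind
        rel = {}
        for kind in ("TEF", "SE"):
            if co60 is None or (kind, co60) not in by:
                report["warnings"].append(f"{film}/{kind}: no Co60 reference cell")
                continue
            ref = by[(kind, co60)]
            track = {
                b: by[(kind, b)].L_track / ref.L_track
                for b in beams
                if (kind, b) in by
            }
            xray = [v for b, v in track.items() if b != co60]
            rel[kind] = {
                "track_per_beam": track,
                "track_min": round(min(xray)) if xray else None,
                "track_max": round(max(xray)) if xray else None,
            }
        entry["rel_to_co60"] = rel

        # L_dose vs L_track, per kind
        dt = {}
        for kind in ("TEF", "SE"):
            rows = [by[(kind, b)] for b in beams if (kind, b) in by]
            if not rows:
                continue
            ratio = {r.beam: r.L_dose / r.L_track for r in rows}
            excess = {
                r.beam: (r.L_dose / r.L_track - 1.0) * 100.0 for r in rows
            }
            low = [
                r.beam
                for r in rows
                if float(r.equivalent_energy_keV) < _LOW_ENERGY_CUT_KEV
            ]
            dt[kind] = {
                "ratio_per_beam": ratio,
                "ratio_low_min": round(min(ratio[b] for b in low), 1) if low else None,
                "ratio_low_max": round(max(ratio[b] for b in low), 1) if low else None,
                "ratio_co60": round(ratio[co60]) if co60 in ratio else None,
                "excess_low_min_pct": round(min(excess[b] for b in low)) if low else None,
                "excess_low_max_pct": round(max(excess[b] for b in low)) if low else None,
            }
        entry["dose_track"] = dt
        report["films"][film] = entry
    return report
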