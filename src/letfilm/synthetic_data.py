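"""Synthetic electron-fluence spectra and film dose-response curves.

Monte Carlo fluence tallies and film calibration experiments are expensive;
this module generates data with the same statistical structure so every
pipeline stage is testable.  The spectra emulate the qualitative anatomy of
photon-generated electron fluence in film sensitive volumes:

* a *photoelectric peak* at the beam's effective energy (the dominant
  feature for lightly filtered 20-50 kV beams, still present above);
* a *Compton continuum* ending at the Compton edge
  T_max = 2 E^2 / (m_e c^2 + 2 E) of the effective photon energy, plus a
  low-energy degraded-primary tail ~ E^-q (primaries slow down through every
  intermediate energy, so the total fluence rises toward the 1 keV floor);
* K-shell photoionization lines at 1.07, 1.56, 2.47 and 2.82 keV (Na, Al, S,
  Cl), with amplitudes tied to the medium's content of those elements;
* a *secondary-electron tail* ~ E^-2 on [1 keV, E_max/2] (free-electron
  close-collision transfer spectrum), which is also emitted separately as
  the SE spectrum.

TEF = SE + everything else; both are normalized so that the CEMA of the
total fluence is 1 Gy per Gy of absorbed dose (computed on an independent
fine grid), then perturbed by truncated-normal per-bin noise.  Dose-response
curves use a saturating netOD(D) = a (1 - exp(-b s_Q D)) with a per-beam
sensitivity scale s_Q; by construction the ground-truth relative efficiency
of beam Q against Co-60 (s = 1) is exactly s_Q at every netOD level.

All generators are pure functions of (config, seed).  No transport claim is
made beyond the qualitative features above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .beam_quality import BeamQuality, get_beam
from .errors import ConfigurationError
from .materials import Material, get_material
from .spectra import (
    GY_PER_MEV_G,
    FluenceSpectrum,
    write_spectrum,
)
from .stopping_power import collision_stopping_power
from .relative_efficiency import DoseResponseCurve, write_curve

__all__ = [
    "KSHELL_LINES_KEV",
    "PhotoPeak",
    "ComptonContinuum",
    "SETail",
    "KShellLine",
    "SpectrumGenConfig",
    "ResponseGenConfig",
    "compton_edge_kev",
    "default_spectrum_config",
    "default_response_config",
    "simulate_fluence_spectrum",
    "simulate_dose_response",
    "make_study_fixture",
]

#: K-shell electron line energies (keV) by emitting element.
KSHELL_LINES_KEV = {"Na": 1.07, "Al": 1.56, "S": 2.47, "Cl": 2.82}

_FLOOR = 1.0  # keV; spectra are not representable below this


def compton_edge_kev(photon_energy_kev: float) -> float:
    """Maximum Compton-electron energy for a photon energy (keV)."""
    e = photon_energy_kev
    return 2.0 * e * e / (510.99895 + 2.0 * e)


@dataclass(frozen=True)
class PhotoPeak:
    """Gaussian photoelectron peak: center/width in keV, amplitude >= 0."""

    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class ComptonContinuum:
    """Continuum to the Compton edge plus a degraded-primary tail.

    density = amplitude * [floor + (1-floor) (E/edge)^shape] * smoothcut(E<=edge)
              + lowtail * E^-lowtail_index

    ``shape`` > 0 makes the continuum rise toward the edge, as Compton
    electron spectra do; ``lowtail`` models primaries degrading through
    every intermediate energy on their way to rest.
    """

    edge: float  # keV
    amplitude: float
    shape: float = 1.5
    floor: float = 0.2
    lowtail: float = 0.0
    lowtail_index: float = 1.15


@dataclass(frozen=True)
class SETail:
    """Secondary-electron power-law tail A * E^-index on [floor, e_max/2]."""

    amplitude: float
    index: float = 2.0


@dataclass(frozen=True)
class KShellLine:
    energy: float  # keV
    area: float  # integrated fluence density (narrow gaussian)


@dataclass(frozen=True)
class SpectrumGenConfig:
    beam: BeamQuality
    medium: Material
    photopeaks: tuple = ()
    compton: ComptonContinuum | None = None
    se_tail: SETail = SETail(amplitude=0.0)
    kshell_lines: tuple = ()
    n_bins: int = 120
    e_max: float = 100.0
    noise_rel: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.e_max <= _FLOOR * 2:
            raise ConfigurationError("e_max must exceed 2 keV")
        amps = [p.amplitude for p in self.photopeaks] + [self.se_tail.amplitude]
        if self.compton is not None:
            amps += [self.compton.amplitude, self.compton.lowtail]
        if any(a < 0 for a in amps):
            raise ConfigurationError("component amplitudes must be >= 0")
        for p in self.photopeaks:
            if p.center >= self.e_max:
                raise ConfigurationError("photopeak center above e_max")


@dataclass(frozen=True)
class ResponseGenConfig:
    """Saturating netOD(D) = a (1 - exp(-b s_Q D)) with per-beam scales."""

    film: str
    a: float  # saturation netOD
    b: float  # 1/Gy
    scales: dict  # beam name -> s_Q; the Co-60 entry must be 1
    dose_grid: tuple  # Gy
    channel: str = "red"
    noise_rel: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("a and b must be > 0")
        if any(s < 0 for s in self.scales.values()):
            raise ConfigurationError("sensitivity scales must be >= 0")
        if len(self.dose_grid) < 2 or np.any(np.diff(self.dose_grid) <= 0):
            raise ConfigurationError("dose grid must be strictly increasing")


# ---------------------------------------------------------------------------
# continuous component densities (arbitrary units before normalization)

def _gauss(E, center, width):
    return np.exp(-0.5 * ((E - center) / width) ** 2) / (width * np.sqrt(2 * np.pi))


def _pe_density(config: SpectrumGenConfig, E: np.ndarray) -> np.ndarray:
    """Primary (non-SE) fluence density: peaks + continuum + K lines."""
    out = np.zeros_like(E)
    for p in config.photopeaks:
        out += p.amplitude * np.exp(-0.5 * ((E - p.center) / p.width) ** 2)
    c = config.compton
    if c is not None:
        if c.edge > _FLOOR and c.amplitude > 0:
            # smooth cut over ~3% of the edge energy
            arg = np.clip((E - c.edge) / (0.03 * c.edge), -50.0, 50.0)
            profile = c.floor + (1.0 - c.floor) * (E / c.edge) ** c.shape
            out += c.amplitude * profile / (1.0 + np.exp(arg))
        out += c.lowtail * E ** (-c.lowtail_index)
    for line in config.kshell_lines:
        out += line.area * _gauss(E, line.energy, 0.08)
    return out


def _se_density(config: SpectrumGenConfig, E: np.ndarray) -> np.ndarray:
    t = config.se_tail
    out = t.amplitude * E ** (-t.index)
    out[E > config.e_max / 2.0] = 0.0
    return out


def simulate_fluence_spectrum(
    config: SpectrumGenConfig,
) -> tuple[FluenceSpectrum, FluenceSpectrum]:
    """Generate the (TEF, SE) spectrum pair for one beam/medium config.

    Both are normalized by the same factor so that the CEMA of the total
    fluence — evaluated by fine-grid quadrature of the continuous densities
    against the analytic unrestricted stopping power — equals 1 Gy/Gy,
    then perturbed by independent truncated-normal noise per bin
    (sd = noise_rel * phi).  SE noise is drawn separately from PE noise and
    TEF = PE + SE, so TEF >= SE bin-wise even after noise.
    """
    edges = np.geomspace(_FLOOR, config.e_max, config.n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    pe = _pe_density(config, mids)
    se = _se_density(config, mids)

    # fine-grid CEMA normalization (independent of the binned representation)
    fine = np.geomspace(_FLOOR, config.e_max, 4001)
    dens = _pe_density(config, fine) + _se_density(config, fine)
    s_fine = collision_stopping_power(config.medium, fine)
    cema_raw = np.trapezoid(dens * s_fine, fine) * GY_PER_MEV_G
    if cema_raw <= 0:
        raise ConfigurationError("all components are zero: cannot normalize")
    k = 1.0 / cema_raw
    pe *= k
    se *= k

    rng = np.random.default_rng(config.seed)
    sig_pe = config.noise_rel * pe
    sig_se = config.noise_rel * se
    if config.noise_rel > 0:
        pe_n = np.maximum(rng.normal(pe, sig_pe), 0.0)
        se_n = np.maximum(rng.normal(se, sig_se), 0.0)
    else:
        pe_n, se_n = pe, se

    meta = dict(medium=config.medium.name, beam=config.beam.name)
    tef = FluenceSpectrum(
        bin_edges=edges,
        phi=pe_n + se_n,
        sigma_phi=np.hypot(sig_pe, sig_se),
        kind="TEF",
        **meta,
    )
    se_spec = FluenceSpectrum(
        bin_edges=edges, phi=se_n, sigma_phi=sig_se, kind="SE", **meta
    )
    return tef, se_spec


# ---------------------------------------------------------------------------
# per-beam default configurations (the study conditions)

def _kshell_lines(medium: Material, scale: float) -> tuple:
    """Line areas proportional to the medium's content of the emitter."""
    fracs = {ef.element: ef.atomic_fraction for ef in medium.composition}
    lines = []
    for sym, e_kev in KSHELL_LINES_KEV.items():
        f = fracs.get(sym, 0.0)
        if f > 0:
            lines.append(KShellLine(energy=e_kev, area=3.0 * scale * f))
    return tuple(lines)


def default_spectrum_config(
    beam_name: str,
    medium: Material | str,
    seed: int = 0,
    noise_rel: float = 0.005,
) -> SpectrumGenConfig:
    """The default generator configuration for one of the study beams.

    Amplitudes are calibrated so that (i) the Co-60 SE/TEF fraction spans
    roughly 0.4-0.9 between 1 and 10 keV, (ii) the x-ray SE fraction at
    1 keV stays below 0.30, and (iii) softer beams yield higher LET.
    """
    beam = get_beam(beam_name)
    if isinstance(medium, str):
        medium = get_material(medium)
    e_eff = beam.effective_energy

    if beam.is_co60:
        # Compton-dominated: continuum rising to the edge of the 1.25 MeV
        # line carries the bulk of the fluence at high energy (low LET); the
        # degraded-primary tail and the SE amplitude set the 0.4-0.9 band.
        e_max = 1100.0
        compton = ComptonContinuum(
            edge=compton_edge_kev(1250.0),
            amplitude=3.0,
            shape=2.0,
            floor=0.0015,
            lowtail=0.3,
        )
        peaks: tuple = ()
        # fast primaries hand their SEs a flatter, further-reaching transfer
        # spectrum, so the Co-60 SE tail is much shallower than the x-ray one
        se = SETail(amplitude=0.6, index=1.2)
        kshell = _kshell_lines(medium, scale=compton.lowtail * 0.1)
    else:
        e_max = float(beam.tube_potential)
        width = max(0.12 * e_eff, 1.2)
        peaks = (PhotoPeak(center=e_eff, width=width, amplitude=1.0),)
        edge = compton_edge_kev(e_eff)
        # softer beams keep relatively more degraded-primary and SE fluence
        # near the floor (they transfer less energy per interaction), which
        # is what drives their higher LET; the Compton bump only enters the
        # representable range above ~80 kV, giving those beams their second,
        # lower-energy peak
        tail, se_amp, se_index = {
            "20kV": (0.50, 0.180, 2.0),
            "50kV": (0.35, 0.130, 1.9),
            "80kV": (0.25, 0.090, 1.75),
            "120kV": (0.20, 0.070, 1.6),
            "160kV": (0.15, 0.055, 1.5),
        }.get(beam.name, (0.25, 0.09, 1.8))
        compton_amp = 0.3 if edge > 2.5 else 0.0
        compton = ComptonContinuum(
            edge=edge, amplitude=compton_amp, shape=1.5, floor=0.2, lowtail=tail
        )
        se = SETail(amplitude=se_amp, index=se_index)
        kshell = _kshell_lines(medium, scale=1.0)

    return SpectrumGenConfig(
        beam=beam,
        medium=medium,
        photopeaks=peaks,
        compton=compton,
        se_tail=se,
        kshell_lines=kshell,
        e_max=e_max,
        noise_rel=noise_rel,
        seed=seed,
    )


_FILM_RESPONSE = {
    # saturation netOD a and sensitivity b chosen so the default netOD
    # evaluation levels of each film sit inside every curve's range
    "EBT3": {"a": 0.8, "b": 0.08},
    "MDV3": {"a": 0.3, "b": 0.05},
}


def default_response_config(
    film: str,
    scales: dict,
    seed: int = 0,
    noise_rel: float = 0.01,
) -> ResponseGenConfig:
    try:
        shape = _FILM_RESPONSE[film]
    except KeyError:
        raise ConfigurationError(
            f"no default response shape for film {film!r}"
        ) from None
    return ResponseGenConfig(
        film=film,
        a=shape["a"],
        b=shape["b"],
        scales=dict(scales),
        dose_grid=tuple(np.geomspace(0.1, 25.0, 24).round(4)),
        noise_rel=noise_rel,
        seed=seed,
    )


def simulate_dose_response(
    config: ResponseGenConfig, beams: list[str] | None = None
) -> list[DoseResponseCurve]:
    """One netOD(D) curve per beam; ground-truth RE of beam Q is s_Q."""
    beams = list(config.scales) if beams is None else list(beams)
    rng = np.random.default_rng(config.seed)
    dose = np.asarray(config.dose_grid, dtype=float)
    curves = []
    for beam in beams:
        s_q = config.scales[beam]
        clean = config.a * (1.0 - np.exp(-config.b * s_q * dose))
        sigma = config.noise_rel * clean
        netod = np.maximum(rng.normal(clean, sigma), 0.0) if config.noise_rel else clean
        curves.append(
            DoseResponseCurve(
                film=config.film,
                beam=beam,
                channel=config.channel,
                dose=dose,
                netod=netod,
                sigma_netod=sigma,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# full study fixture

def _scale_from_let(l_dose: float, l_min: float, l_max: float) -> float:
    """Monotone RE(LET) ground truth: flat, rapid rise, then slow rise.

    Hill-type map of the normalized LET u in [0, 1]: s = 1 + 3 u^2/(u^2+0.12),
    spanning 1 (lowest-LET beam, Co-60) to ~3.7 (softest beam).
    """
    u = (l_dose - l_min) / (l_max - l_min) if l_max > l_min else 0.0
    return 1.0 + 3.0 * u * u / (u * u + 0.12)


def make_study_fixture(
    seed: int,
    out_dir: str | Path,
    films: tuple = ("EBT3", "MDV3"),
    noise_rel_spectrum: float = 0.005,
    noise_rel_curve: float = 0.005,
) -> Path:
    """Write a full synthetic study: 6 beams x 2 films, spectra + curves.

    Files use the module dialects (``spectrum_{film}_{beam}_{kind}.tsv``,
    ``curve_{film}_{beam}.tsv``) plus a ``manifest.json`` carrying the
    ground-truth sensitivity scales and generator parameters.  The per-beam
    scale s_Q is a monotone function of the dose-average LET computed from
    each film's synthetic TEF spectrum, so the assembled RE-vs-LET curve is
    non-decreasing with the flat / rapid-rise / slow-rise shape.
    """
    from .let_average import LETConfig, compute_let  # local: avoid cycle
    from .stopping_power import build_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    beam_names = ["20kV", "50kV", "80kV", "120kV", "160kV", "Co60"]
    manifest: dict = {
        "seed": seed,
        "spectrum_noise_rel": noise_rel_spectrum,
        "curve_noise_rel": noise_rel_curve,
        "films": {},
    }
    children = root.spawn(len(films) * (len(beam_names) + 1))
    child_iter = iter(children)
    for film in films:
        medium = get_material(f"{film}_active")
        grid = np.geomspace(1.0, 1200.0, 200)
        table = build_table(medium, grid, delta=1.0)
        let_dose: dict[str, float] = {}
        spectra = {}
        for beam in beam_names:
            sub_seed = int(next(child_iter).generate_state(1)[0] % (2**31))
            cfg = default_spectrum_config(
                beam, medium, seed=sub_seed, noise_rel=noise_rel_spectrum
            )
            tef, se = simulate_fluence_spectrum(cfg)
            spectra[beam] = (tef, se)
            res = compute_let(tef, table, LETConfig(delta=1.0))
            let_dose[beam] = res.L_dose
            write_spectrum(tef, out / f"spectrum_{film}_{beam}_TEF.tsv")
            write_spectrum(se, out / f"spectrum_{film}_{beam}_SE.tsv")
        l_min, l_max = min(let_dose.values()), max(let_dose.values())
        scales = {
            b: round(_scale_from_let(l, l_min, l_max), 6)
            for b, l in let_dose.items()
        }
        scales["Co60"] = 1.0  # Co-60 is the reference by convention
        resp_seed = int(next(child_iter).generate_state(1)[0] % (2**31))
        resp_cfg = default_response_config(
            film, scales, seed=resp_seed, noise_rel=noise_rel_curve
        )
        for curve in simulate_dose_response(resp_cfg):
            write_curve(curve, out / f"curve_{film}_{curve.beam}.tsv")
        manifest["films"][film] = {
            "medium": medium.name,
            "response": {"a": resp_cfg.a, "b": resp_cfg.b},
            "beams": {
                b: {"s_q": scales[b], "L_dose_TEF_keV_um": round(let_dose[b], 6)}
                for b in beam_names
            },
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
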