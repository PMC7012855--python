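"""Full-study analysis: spectra + curves in, structured report tables out.

`run_full_analysis` wires every stage over a study directory (the synthetic
fixture layout or user data in the same dialects):

1. stopping-power tables for each film's active layer (``materials``);
2. read and validate all fluence spectra (``spectra``);
3. LET averages with bootstrap uncertainties per film/beam/kind
   (``let_average``);
4. SE/TEF fraction tables (``spectra``);
5. relative efficiency per beam from the dose-response curves
   (``relative_efficiency``);
6. report assembly (``reporting``): five machine-readable TSV tables — the
   LET grid, the dose/track ratio grid, the SE-fraction spectra, dose-for-
   netOD vs LET and weighted RE vs LET (all four {track,dose} x {TEF,SE}
   variants) — plus a human-readable summary.

Any stage failure aborts with a stage-named diagnostic and removes partial
outputs; reports are written to a temporary directory and moved into place
only on success.  The whole pipeline is a pure function of
(inputs, config, seed): one root seed is split deterministically per stage.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .beam_quality import available_beams, get_beam
from .errors import LetfilmError, PipelineStageError
from .let_average import LETConfig, LETResult, compute_let, cross_statistics
from .materials import FIXTURE_VERSIONS, get_material
from .relative_efficiency import (
    DEFAULT_NETOD_LEVELS,
    dose_for_netod,
    read_curve,
    relative_efficiency_result,
)
from .spectra import read_spectrum, se_fraction
from .stopping_power import build_table

import pandas as pd

__all__ = ["RunConfig", "run_full_analysis", "REPORT_FILES"]

REPORT_FILES = (
    "let_grid.tsv",
    "let_ratios.tsv",
    "se_fraction.tsv",
    "dose_vs_let.tsv",
    "re_vs_let.tsv",
)


@dataclass(frozen=True)
class RunConfig:
    """Paths, physics settings and seed for one full analysis run."""

    study_dir: Path
    out_dir: Path
    delta: float = 1.0  # keV
    n_boot: int = 200
    seed: int = 0
    films: tuple = ("EBT3", "MDV3")
    table_grid: tuple = (1.0, 1200.0, 200)  # keV lo, hi, n (log-spaced)

    def __post_init__(self):
        object.__setattr__(self, "study_dir", Path(self.study_dir))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.delta <= 0:
            raise PipelineStageError("config", "delta must be > 0")
        if not self.study_dir.is_dir():
            raise PipelineStageError(
                "config", f"study directory {self.study_dir} does not exist"
            )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _write_tsv(path: Path, columns: list[str], rows: list[tuple], header: list[str]):
    lines = [f"# {h}" for h in header]
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(v) if isinstance(v, float) else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns a summary dict."""
    header = [
        f"letfilm {__version__}",
        f"seed: {config.seed}  delta_keV: {config.delta}  n_boot: {config.n_boot}",
        "fixture_versions: "
        + " ".join(f"{k}={v}" for k, v in FIXTURE_VERSIONS.items()),
    ]
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    let_seed = int(seeds[0].generate_state(1)[0] % (2**31))

    # --- stage: materials -------------------------------------------------
    try:
        lo, hi, n = config.table_grid
        grid = np.geomspace(lo, hi, int(n))
        tables = {
            film: build_table(get_material(f"{film}_active"), grid, config.delta)
            for film in config.films
        }
    except LetfilmError as exc:
        raise PipelineStageError("materials", str(exc)) from exc

    # --- stage: spectra ---------------------------------------------------
    spectra: dict[tuple, object] = {}
    try:
        beams = available_beams()
        for film in config.films:
            for beam in beams:
                for kind in ("TEF", "SE"):
                    path = config.study_dir / f"spectrum_{film}_{beam}_{kind}.tsv"
                    if not path.exists():
                        raise LetfilmError(f"missing spectrum file {path.name}")
                    spectra[(film, beam, kind)] = read_spectrum(path)
    except LetfilmError as exc:
        raise PipelineStageError("spectra", str(exc)) from exc

    # --- stage: let_average ----------------------------------------------
    let_results: list[LETResult] = []
    try:
        cfg = LETConfig(delta=config.delta)
        for i, ((film, beam, kind), spec) in enumerate(sorted(spectra.items())):
            let_results.append(
                compute_let(
                    spec,
                    tables[film],
                    cfg,
                    n_boot=config.n_boot,
                    seed=let_seed + i,
                )
            )
    except LetfilmError as exc:
        raise PipelineStageError("let_average", str(exc)) from exc
    by_key = {(r.medium, r.beam, r.spectrum_kind): r for r in let_results}

    # --- stage: se_fraction ----------------------------------------------
    try:
        fractions = {
            (film, beam): se_fraction(
                spectra[(film, beam, "SE")], spectra[(film, beam, "TEF")]
            )
            for film in config.films
            for beam in beams
        }
    except LetfilmError as exc:
        raise PipelineStageError("spectra", str(exc)) from exc

    # --- stage: relative_efficiency --------------------------------------
    re_results: dict[str, list] = {}
    curves: dict[tuple, object] = {}
    try:
        for film in config.films:
            ref_path = config.study_dir / f"curve_{film}_Co60.tsv"
            if not ref_path.exists():
                raise LetfilmError(f"missing Co-60 reference curve {ref_path.name}")
            ref = read_curve(ref_path)
            curves[(film, "Co60")] = ref
            rows = []
            for beam in beams:
                path = config.study_dir / f"curve_{film}_{beam}.tsv"
                if not path.exists():
                    raise LetfilmError(f"missing curve file {path.name}")
                test = read_curve(path)
                curves[(film, beam)] = test
                rows.append(relative_efficiency_result(ref, test))
            re_results[film] = rows
    except LetfilmError as exc:
        raise PipelineStageError("relative_efficiency", str(exc)) from exc

    # --- stage: reporting -------------------------------------------------
    try:
        tmp = Path(tempfile.mkdtemp(prefix="letfilm_report_"))
        grid_rows = []
        ratio_rows = []
        for (film, beam, kind), r in sorted(by_key.items()):
            film_name = film.replace("_active", "")
            eq_e = get_beam(beam).effective_energy
            grid_rows.append(
                (film_name, beam, eq_e, kind, r.L_track, r.u_track, r.L_dose, r.u_dose)
            )
            ratio_rows.append((film_name, beam, eq_e, kind, r.L_dose / r.L_track))
        _write_tsv(
            tmp / "let_grid.tsv",
            ["film", "beam", "equivalent_energy_keV", "kind",
             "L_track_keV_um", "u_track", "L_dose_keV_um", "u_dose"],
            grid_rows, header,
        )
        _write_tsv(
            tmp / "let_ratios.tsv",
            ["film", "beam", "equivalent_energy_keV", "kind", "L_dose_over_L_track"],
            ratio_rows, header,
        )
        frac_rows = []
        for (film, beam), frac in sorted(fractions.items()):
            for e, v, s in zip(frac.midpoints, frac.ratio, frac.sigma):
                frac_rows.append((film, beam, float(e), float(v), float(s)))
        _write_tsv(
            tmp / "se_fraction.tsv",
            ["film", "beam", "energy_keV", "se_fraction", "sigma"],
            frac_rows, header,
        )
        dose_rows = []
        re_rows = []
        for film in config.films:
            medium = f"{film}_active"
            levels = DEFAULT_NETOD_LEVELS.get(film)
            for rr in re_results[film]:
                for axis in ("track", "dose"):
                    for kind in ("TEF", "SE"):
                        lr = by_key[(medium, rr.beam, kind)]
                        let = lr.L_track if axis == "track" else lr.L_dose
                        u_let = lr.u_track if axis == "track" else lr.u_dose
                        re_rows.append(
                            (film, rr.beam, axis, kind, let, u_let,
                             rr.re_weighted, rr.re_weighted_sigma)
                        )
                        if levels:
                            for y in levels:
                                d, sd = dose_for_netod(
                                    curves[(film, rr.beam)], y, with_sigma=True
                                )
                                dose_rows.append(
                                    (film, rr.beam, axis, kind, let, y, d, sd)
                                )
        _write_tsv(
            tmp / "dose_vs_let.tsv",
            ["film", "beam", "axis", "kind", "LET_keV_um", "netOD", "dose_Gy", "u_dose"],
            dose_rows, header,
        )
        _write_tsv(
            tmp / "re_vs_let.tsv",
            ["film", "beam", "axis", "kind", "LET_keV_um", "u_LET", "RE", "u_RE"],
            re_rows, header,
        )

        # human-readable summary with the grid's cross statistics
        grid_df = pd.DataFrame(
            grid_rows,
            columns=["film", "beam", "equivalent_energy_keV", "kind",
                     "L_track", "u_track", "L_dose", "u_dose"],
        )
        stats = cross_statistics(grid_df)
        text = ["# letfilm full-analysis report"] + [f"# {h}" for h in header[1:]]
        text.append("")
        text.append(json.dumps(stats, indent=2, default=float))
        (tmp / "report.txt").write_text("\n".join(text) + "\n")

        config.out_dir.mkdir(parents=True, exist_ok=True)
        for name in REPORT_FILES + ("report.txt",):
            shutil.move(str(tmp / name), str(config.out_dir / name))
        shutil.rmtree(tmp, ignore_errors=True)
    except LetfilmError as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise PipelineStageError("reporting", str(exc)) from exc

    return {
        "n_spectra": len(spectra),
        "n_let_results": len(let_results),
        "films": list(config.films),
        "reports": [str(config.out_dir / n) for n in REPORT_FILES + ("report.txt",)],
        "stats": stats,
    }
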