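"""Film relative efficiency from dose-response (netOD) curves.

The relative efficiency of a radiochromic film for a test beam Q is

    RE = D_Co60(netOD) / D_Q(netOD),

the ratio of the Co-60 dose to the test-beam dose producing the same net
optical density.  Inversion D(netOD) uses a monotone shape-preserving
piecewise-cubic (PCHIP) through the measured curve and never extrapolates:
the relation is only defined where both curves respond.

Because film response is level-independent in RE (dose-scaled curves give
the same RE at every netOD), a single per-beam number is formed as the
inverse-variance weighted mean over the evaluation levels (equal weights
when no uncertainties are available).  Level defaults follow the red-channel
values used in the experimental companion study: 0.053/0.176/0.510 for EBT3
and 0.009/0.023/0.095 for MD-V3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import AlignmentError, ConfigurationError, FormatError, RangeError

__all__ = [
    "DEFAULT_NETOD_LEVELS",
    "DoseResponseCurve",
    "REResult",
    "read_curve",
    "write_curve",
    "dose_for_netod",
    "relative_efficiency",
    "relative_efficiency_result",
    "weighted_average_re",
    "assemble_re_vs_let",
]

#: Red-channel netOD evaluation levels per film model.
DEFAULT_NETOD_LEVELS = {
    "EBT3": (0.053, 0.176, 0.510),
    "MDV3": (0.009, 0.023, 0.095),
}

#: Relative tolerance for netOD monotonicity violations attributed to noise.
_MONOTONE_NOISE_TOL = 3.0  # in units of combined sigma


@dataclass(frozen=True)
class DoseResponseCurve:
    """(dose, netOD, sigma_netOD) points for one film/beam/channel."""

    film: str
    beam: str
    channel: str
    dose: np.ndarray  # Gy, strictly increasing
    netod: np.ndarray  # dimensionless >= 0
    sigma_netod: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.netod, dtype=float)
        s = np.asarray(self.sigma_netod, dtype=float)
        if d.ndim != 1 or len(d) < 2 or np.any(np.diff(d) <= 0):
            raise ConfigurationError("doses must be strictly increasing")
        if len(n) != len(d) or len(s) != len(d):
            raise ConfigurationError("dose/netOD/sigma lengths differ")
        if np.any(n < 0) or np.any(s < 0):
            raise ConfigurationError("netOD and sigma_netOD must be >= 0")
        drops = np.diff(n)
        if np.any(drops < 0):
            tol = _MONOTONE_NOISE_TOL * np.sqrt(s[1:] ** 2 + s[:-1] ** 2)
            if np.any(drops < -np.maximum(tol, 1e-12)):
                raise ConfigurationError(
                    f"netOD decreases with dose beyond noise tolerance "
                    f"({self.film}/{self.beam})"
                )
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "netod", n)
        object.__setattr__(self, "sigma_netod", s)

    @property
    def netod_range(self) -> tuple[float, float]:
        return float(self.netod.min()), float(self.netod.max())

    def forward(self, dose: float) -> float:
        """netOD at a dose inside the measured range (PCHIP)."""
        d = float(dose)
        if d < self.dose[0] or d > self.dose[-1]:
            raise RangeError("dose outside measured range")
        return float(PchipInterpolator(self.dose, self._monotone_netod())(d))

    def _monotone_netod(self) -> np.ndarray:
        """netOD forced non-decreasing (running max) for stable inversion."""
        return np.maximum.accumulate(self.netod)


@dataclass(frozen=True)
class REResult:
    """Relative efficiency of one film/beam pair over netOD levels."""

    film: str
    beam: str
    netod_levels: tuple
    re_values: tuple
    re_sigmas: tuple
    re_weighted: float
    re_weighted_sigma: float


# ---------------------------------------------------------------------------
# file dialect

def read_curve(path: str | Path) -> DoseResponseCurve:
    """Read the curve dialect: ``#`` header (film, beam, channel), then
    columns ``dose_Gy netOD sigma_netOD``."""
    path = Path(path)
    header: dict[str, str] = {}
    rows = []
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
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        rows.append([float(p) for p in parts])
    for key in ("film", "beam", "channel"):
        if key not in header:
            raise FormatError(f"{path}: missing mandatory header key {key!r}")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    try:
        return DoseResponseCurve(
            film=header["film"],
            beam=header["beam"],
            channel=header["channel"],
            dose=arr[:, 0],
            netod=arr[:, 1],
            sigma_netod=arr[:, 2],
        )
    except ConfigurationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_curve(curve: DoseResponseCurve, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# film: {curve.film}",
        f"# beam: {curve.beam}",
        f"# channel: {curve.channel}",
        "# dose_Gy netOD sigma_netOD",
    ]
    for d, n, s in zip(curve.dose, curve.netod, curve.sigma_netod):
        lines.append(f"{float(d)!r} {float(n)!r} {float(s)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# operations

def dose_for_netod(
    curve: DoseResponseCurve, netod: float, with_sigma: bool = False
):
    """Invert the curve: the dose (Gy) producing a given netOD.

    Root-finds on the monotone shape-preserving (PCHIP) forward interpolant
    netOD(D), so inversion and forward evaluation are exact companions;
    strictly interpolating, never extrapolating.  With ``with_sigma`` the
    dose uncertainty is propagated through the local slope from the
    interpolated sigma_netOD.
    """
    from scipy.optimize import brentq

    y = float(netod)
    n = curve._monotone_netod()
    lo, hi = float(n[0]), float(n[-1])
    if y < lo or y > hi:
        raise RangeError(
            f"netOD {y} outside measured range [{lo}, {hi}] "
            f"({curve.film}/{curve.beam}); extrapolation is not allowed"
        )
    if hi <= lo:
        raise ConfigurationError("curve has no dynamic range")
    fwd = PchipInterpolator(curve.dose, n)
    if y <= lo:
        dose = float(curve.dose[0])
    elif y >= hi:
        dose = float(curve.dose[-1])
    else:
        dose = float(
            brentq(lambda d: float(fwd(d)) - y, curve.dose[0], curve.dose[-1],
                   xtol=1e-12, rtol=1e-14)
        )
    if not with_sigma:
        return dose
    slope = float(fwd(dose, 1))  # d netOD / d dose
    sig_n = float(np.interp(y, n, curve.sigma_netod))
    sigma = sig_n / slope if slope > 0 else 0.0
    return dose, abs(sigma)


def relative_efficiency(
    curve_co60: DoseResponseCurve, curve_q: DoseResponseCurve, netod: float
) -> float:
    """RE = D_Co60(netOD) / D_Q(netOD) at one netOD level."""
    if curve_co60.film != curve_q.film or curve_co60.channel != curve_q.channel:
        raise AlignmentError("curves are for different film or channel")
    return dose_for_netod(curve_co60, netod) / dose_for_netod(curve_q, netod)


def _re_with_sigma(
    curve_co60: DoseResponseCurve, curve_q: DoseResponseCurve, netod: float
) -> tuple[float, float]:
    d0, s0 = dose_for_netod(curve_co60, netod, with_sigma=True)
    dq, sq = dose_for_netod(curve_q, netod, with_sigma=True)
    re = d0 / dq
    # inversion uncertainties combined in quadrature on the log scale
    rel = np.sqrt((s0 / d0) ** 2 + (sq / dq) ** 2) if d0 > 0 and dq > 0 else 0.0
    return re, re * float(rel)


def weighted_average_re(re_values, re_sigmas=None) -> tuple[float, float]:
    """Inverse-variance weighted mean RE and its standard error.

    Falls back to equal weights (and the standard error of the mean) when
    sigmas are absent or all zero.
    """
    v = np.asarray(re_values, dtype=float)
    if v.size == 0:
        raise ConfigurationError("no RE values to average")
    s = None if re_sigmas is None else np.asarray(re_sigmas, dtype=float)
    if s is not None and np.any(s < 0):
        raise ConfigurationError("sigmas must be >= 0")
    if s is None or np.all(s == 0):
        mean = float(v.mean())
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return mean, sem
    if np.any(s == 0):
        # a zero-sigma level dominates; treat it as exact
        exact = v[s == 0]
        return float(exact.mean()), 0.0
    w = 1.0 / s**2
    mean = float(np.sum(w * v) / np.sum(w))
    return mean, float(np.sqrt(1.0 / np.sum(w)))


def relative_efficiency_result(
    curve_co60: DoseResponseCurve,
    curve_q: DoseResponseCurve,
    netod_levels=None,
) -> REResult:
    """RE at each netOD level plus the per-beam weighted average."""
    if netod_levels is None:
        try:
            netod_levels = DEFAULT_NETOD_LEVELS[curve_q.film]
        except KeyError:
            raise ConfigurationError(
                f"no default netOD levels for film {curve_q.film!r}; "
                "pass netod_levels explicitly"
            ) from None
    res = [_re_with_sigma(curve_co60, curve_q, y) for y in netod_levels]
    values = tuple(r[0] for r in res)
    sigmas = tuple(r[1] for r in res)
    mean, sem = weighted_average_re(values, sigmas)
    return REResult(
        film=curve_q.film,
        beam=curve_q.beam,
        netod_levels=tuple(netod_levels),
        re_values=values,
        re_sigmas=sigmas,
        re_weighted=mean,
        re_weighted_sigma=sem,
    )


def assemble_re_vs_let(
    re_results: list[REResult],
    let_results: list,
    axis: str = "track",
    kind: str = "TEF",
):
    """Join weighted RE per beam with its LET abscissa, sorted by LET.

    ``axis`` selects track- or dose-average LET, ``kind`` the spectrum (TEF
    or SE) the LET was computed from; the RE values themselves never depend
    on either choice.  Returns a list of dicts (beam, LET, u_LET, RE, u_RE).
    Beams present in only one input raise a join error naming them.
    """
    if axis not in ("track", "dose"):
        raise ConfigurationError("axis must be 'track' or 'dose'")
    lets = {r.beam: r for r in let_results if r.spectrum_kind == kind}
    res = {r.beam: r for r in re_results}
    missing = sorted(set(res) ^ set(lets))
    if missing:
        raise AlignmentError(f"beams missing from one input: {missing}")
    rows = []
    for beam, rr in res.items():
        lr = lets[beam]
        let = lr.L_track if axis == "track" else lr.L_dose
        u_let = lr.u_track if axis == "track" else lr.u_dose
        rows.append(
            {
                "beam": beam,
                "LET_keV_um": let,
                "u_LET_keV_um": u_let,
                "RE": rr.re_weighted,
                "u_RE": rr.re_weighted_sigma,
            }
        )
    rows.sort(key=lambda r: r["LET_keV_um"])
    return rows
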