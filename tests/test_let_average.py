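import numpy as np
import pandas as pd
import pytest

from letfilm.errors import ConfigurationError, LetfilmError
from letfilm.let_average import (
    LETConfig,
    LETResult,
    compute_let,
    cross_statistics,
    dose_average_let,
    let_ratio,
    let_uncertainties,
    load_printed_let_grid,
    track_average_let,
)
from letfilm.materials import Material, ElementFraction
from letfilm.spectra import FluenceSpectrum
from letfilm.stopping_power import StoppingPowerTable

from conftest import random_spectrum


def spectrum(edges, phi, medium="water", sigma=None):
    phi = np.asarray(phi, dtype=float)
    sig = np.zeros_like(phi) if sigma is None else np.asarray(sigma, float)
    return FluenceSpectrum(
        bin_edges=np.asarray(edges, float), phi=phi, sigma_phi=sig,
        kind="TEF", medium=medium, beam="testbeam",
    )


@pytest.fixture(scope="module")
def mock_table():
    """Unit-density material, L = 20 and 40 MeV cm^2/g at E = 1.5 and 3 keV
    (2 and 4 keV/um after conversion)."""
    mat = Material("mock", [ElementFraction("H", 1.0)], density=1.0)
    return StoppingPowerTable(
        material=mat,
        energies=np.array([1.0, 1.5, 3.0]),
        S=np.array([50.0, 25.0, 45.0]),
        L_delta=np.array([50.0, 20.0, 40.0]),
        delta_cut=1.0,
    )


class TestClosedForms:
    def test_monoenergetic_spectrum_returns_table_let(self, water_table):
        # single populated bin far above delta; empty lowest bin -> no
        # track-end term; both averages collapse to L_delta(E0)
        edges = np.array([1.0, 2.0, 99.0, 101.0])
        s = spectrum(edges, [0.0, 0.0, 5.0])
        cfg = LETConfig(delta=1.0)
        expected = water_table.lookup_L(100.0) * water_table.material.density * 0.1
        assert track_average_let(s, water_table, cfg) == pytest.approx(expected, rel=1e-12)
        assert dose_average_let(s, water_table, cfg) == pytest.approx(expected, rel=1e-12)

    def test_two_equal_fluence_bins_mock_values(self, mock_table):
        # bins [1,2] and [2,4]: midpoints 1.5 and 3, L = 2 and 4 keV/um;
        # equal fluence content (phi*dE), no track-end term
        s = spectrum([1.0, 2.0, 4.0], [1.0, 0.5], medium="mock")
        cfg = LETConfig(delta=1.0, include_track_end=False)
        assert track_average_let(s, mock_table, cfg) == pytest.approx(3.0, rel=1e-12)
        assert dose_average_let(s, mock_table, cfg) == pytest.approx(
            (4.0 + 16.0) / (2.0 + 4.0), rel=1e-12
        )

    def test_empty_spectrum_is_undefined(self, water_table):
        s = spectrum([1.0, 2.0, 4.0], [0.0, 0.0])
        with pytest.raises(LetfilmError):
            track_average_let(s, water_table)

    def test_delta_above_first_edge_rejected(self, water_table):
        s = spectrum([2.0, 4.0, 8.0], [1.0, 1.0])
        with pytest.raises(ConfigurationError):
            track_average_let(s, water_table, LETConfig(delta=4.0))


class TestProperties:
    def test_dose_average_dominates_track_average(self, water_table):
        """Cauchy-Schwarz: L_dose >= L_track for random spectra."""
        for seed in range(200):
            s = random_spectrum(np.random.default_rng(seed))
            lt = track_average_let(s, water_table)
            ld = dose_average_let(s, water_table)
            assert ld >= lt * (1 - 1e-12)

    def test_invariant_under_fluence_rescaling(self, water_table):
        s = random_spectrum(np.random.default_rng(5))
        s10 = spectrum(s.bin_edges, 10.0 * s.phi)
        assert track_average_let(s10, water_table) == pytest.approx(
            track_average_let(s, water_table), rel=1e-12
        )
        assert dose_average_let(s10, water_table) == pytest.approx(
            dose_average_let(s, water_table), rel=1e-12
        )

    def test_stable_under_bin_refinement(self, water_table):
        """Refining every bin x10 at constant density moves both averages by
        less than 0.2% (smooth stopping power across each bin)."""
        s = random_spectrum(np.random.default_rng(17), n_bins=60)
        fine_edges = np.concatenate(
            [
                np.linspace(lo, hi, 11)[:-1]
                for lo, hi in zip(s.bin_edges[:-1], s.bin_edges[1:])
            ]
            + [[s.bin_edges[-1]]]
        )
        fine_phi = np.repeat(s.phi, 10)
        fine = spectrum(fine_edges, fine_phi)
        for f in (track_average_let, dose_average_let):
            assert f(fine, water_table) == pytest.approx(
                f(s, water_table), rel=2e-3
            )

    def test_track_end_term_shifts_sums_analytically(self, water_table):
        """Adding the track-end term changes each sum by exactly
        S(delta) phi(delta) delta (numerators) and phi(delta) delta
        (fluence)."""
        s = random_spectrum(np.random.default_rng(23))
        cfg_on = LETConfig(delta=1.0, include_track_end=True)
        cfg_off = LETConfig(delta=1.0, include_track_end=False)
        rho = water_table.material.density
        mids = s.midpoints
        w = s.phi * s.widths
        L = np.asarray(water_table.lookup_L(mids))
        s_delta = float(water_table.lookup_S(1.0))
        wd = s.phi[0] * 1.0
        num1 = float(np.sum(L * w))
        num2 = float(np.sum(L * L * w))
        den = float(np.sum(w))
        expected_track = (num1 + s_delta * wd) / (den + wd) * rho * 0.1
        expected_dose = (num2 + s_delta**2 * wd) / (num1 + s_delta * wd) * rho * 0.1
        assert track_average_let(s, water_table, cfg_on) == pytest.approx(expected_track, rel=1e-12)
        assert dose_average_let(s, water_table, cfg_on) == pytest.approx(expected_dose, rel=1e-12)
        assert track_average_let(s, water_table, cfg_off) == pytest.approx(
            num1 / den * rho * 0.1, rel=1e-12
        )


class TestUncertainties:
    def test_zero_sigma_gives_zero_uncertainty(self, water_table):
        s = spectrum([1.0, 2.0, 4.0], [1.0, 1.0])
        assert let_uncertainties(s, water_table, seed=1) == (0.0, 0.0)

    def test_same_seed_is_deterministic(self, water_table):
        s = random_spectrum(np.random.default_rng(9))
        a = let_uncertainties(s, water_table, n_boot=200, seed=42)
        b = let_uncertainties(s, water_table, n_boot=200, seed=42)
        assert a == b

    def test_averaging_suppresses_flat_spectrum_noise(self, water_table):
        """1% relative per-bin noise on a many-bin spectrum yields a
        relative track-average uncertainty well below 1%."""
        edges = np.geomspace(1.0, 500.0, 51)
        phi = np.full(50, 3.0)
        s = spectrum(edges, phi, sigma=0.01 * phi)
        ut, ud = let_uncertainties(s, water_table, n_boot=400, seed=7)
        lt = track_average_let(s, water_table)
        assert ut / lt < 0.01

    def test_seed_is_mandatory(self, water_table):
        s = random_spectrum(np.random.default_rng(1))
        with pytest.raises(ConfigurationError):
            let_uncertainties(s, water_table, seed=None)


class TestRatiosAndStatistics:
    def test_ratio_of_printed_co60_cells(self):
        grid = load_printed_let_grid()
        ebt3 = grid[(grid.film == "EBT3") & (grid.beam == "Co60")]
        tef = ebt3[ebt3.kind == "TEF"].iloc[0]
        se = ebt3[ebt3.kind == "SE"].iloc[0]
        assert tef.L_dose / tef.L_track == pytest.approx(8.49, abs=0.01)
        assert se.L_dose / se.L_track == pytest.approx(3.78, abs=0.01)
        r = LETResult(se.L_track, se.L_dose, 0, 0, 1.0, "SE", "EBT3", "Co60")
        assert round(let_ratio(r)) == 4

    def test_monoenergetic_ratio_is_one(self, water_table):
        s = spectrum([1.0, 2.0, 99.0, 101.0], [0.0, 0.0, 5.0])
        r = compute_let(s, water_table)
        assert let_ratio(r) == pytest.approx(1.0, rel=1e-12)

    def test_single_beam_grid_reports_unity_co60_ratios(self):
        grid = load_printed_let_grid()
        sub = grid[grid.beam == "Co60"]
        rep = cross_statistics(sub)
        for kind in ("TEF", "SE"):
            per = rep["films"]["EBT3"]["rel_to_co60"][kind]["track_per_beam"]
            assert per["Co60"] == pytest.approx(1.0)

    def test_missing_cells_warned_not_fatal(self):
        grid = load_printed_let_grid()
        sub = grid[(grid.kind == "TEF") | (grid.beam != "20kV")]
        rep = cross_statistics(sub)
        assert any("20kV" in w for w in rep["warnings"])
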