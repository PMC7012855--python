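import json

import numpy as np
import pytest

from letfilm.materials import get_material
from letfilm.spectra import cema, se_fraction
from letfilm.synthetic_data import (
    SETail,
    default_response_config,
    default_spectrum_config,
    make_study_fixture,
    simulate_dose_response,
    simulate_fluence_spectrum,
)
from letfilm.relative_efficiency import relative_efficiency_result


from dataclasses import replace


class TestSpectrumGenerator:
    def test_deterministic_under_seed(self, ebt3_active):
        cfg = default_spectrum_config("50kV", ebt3_active, seed=5)
        t1, s1 = simulate_fluence_spectrum(cfg)
        t2, s2 = simulate_fluence_spectrum(cfg)
        assert np.array_equal(t1.phi, t2.phi)
        assert np.array_equal(s1.phi, s2.phi)

    def test_zero_se_amplitude_gives_zero_se(self, ebt3_active):
        cfg = replace(
            default_spectrum_config("50kV", ebt3_active, seed=5),
            se_tail=SETail(amplitude=0.0),
        )
        tef, se = simulate_fluence_spectrum(cfg)
        assert np.all(se.phi == 0)
        assert np.allclose(se_fraction(se, tef).ratio, 0.0)

    def test_tef_dominates_se_binwise(self, ebt3_active):
        for beam in ("20kV", "Co60"):
            tef, se = simulate_fluence_spectrum(
                default_spectrum_config(beam, ebt3_active, seed=3)
            )
            assert np.all(tef.phi >= se.phi)

    def test_co60_se_fraction_in_discussion_band(self, ebt3_active):
        """SE contributes ~40-90% of the total fluence between 1 and 10 keV
        for the Co-60 beam."""
        tef, se = simulate_fluence_spectrum(
            default_spectrum_config("Co60", ebt3_active, seed=42)
        )
        f = se_fraction(se, tef)
        band = f.ratio[(f.midpoints >= 1.0) & (f.midpoints <= 10.0)]
        assert band.min() >= 0.40
        assert band.max() <= 0.90

    def test_xray_se_fraction_below_30pct_at_1kev(self, ebt3_active):
        for beam in ("20kV", "50kV", "80kV", "120kV", "160kV"):
            tef, se = simulate_fluence_spectrum(
                default_spectrum_config(beam, ebt3_active, seed=42)
            )
            f = se_fraction(se, tef)
            assert f.ratio[0] < 0.30

    def test_xray_fraction_decreasing_above_crossover(self, ebt3_active):
        # strictly decreasing except through the narrow K-shell lines
        # (< 3 keV), where the TEF briefly bumps and the ratio dips/recovers
        cfg = default_spectrum_config("20kV", ebt3_active, seed=0, noise_rel=0.0)
        tef, se = simulate_fluence_spectrum(cfg)
        f = se_fraction(se, tef)
        above_lines = f.midpoints[:-1] > 3.2
        assert np.all(np.diff(f.ratio)[above_lines] <= 1e-12)
        assert f.ratio[0] == f.ratio.max()

    def test_cema_normalization_against_binned_integral(self, ebt3_active, film_table):
        """Generated spectra integrate to 1 Gy/Gy within 2% when re-measured
        with the binned CEMA estimator."""
        for beam in ("20kV", "160kV", "Co60"):
            tef, _ = simulate_fluence_spectrum(
                default_spectrum_config(beam, ebt3_active, seed=1)
            )
            assert cema(tef, film_table) == pytest.approx(1.0, rel=0.02)

    def test_softer_beams_have_higher_let(self, ebt3_active, film_table):
        from letfilm.let_average import LETConfig, compute_let

        results = []
        for beam in ("20kV", "50kV", "80kV", "120kV", "160kV", "Co60"):
            tef, _ = simulate_fluence_spectrum(
                default_spectrum_config(beam, ebt3_active, seed=2)
            )
            results.append(compute_let(tef, film_table, LETConfig()))
        tracks = [r.L_track for r in results]
        doses = [r.L_dose for r in results]
        assert np.all(np.diff(tracks) < 0)
        assert np.all(np.diff(doses) < 0)


class TestResponseGenerator:
    def test_unit_scales_recover_unity(self):
        cfg = default_response_config(
            "EBT3", {"Co60": 1.0, "80kV": 1.0}, seed=11, noise_rel=0.01
        )
        co, q = simulate_dose_response(cfg)
        res = relative_efficiency_result(co, q)
        assert res.re_weighted == pytest.approx(1.0, rel=0.02)

    def test_noiseless_scale_four_is_exact(self):
        cfg = default_response_config(
            "EBT3", {"Co60": 1.0, "20kV": 4.0}, seed=0, noise_rel=0.0
        )
        co, q = simulate_dose_response(cfg)
        res = relative_efficiency_result(co, q)
        for v in res.re_values:
            assert v == pytest.approx(4.0, rel=1e-3)

    def test_deterministic_under_seed(self):
        cfg = default_response_config("MDV3", {"Co60": 1.0, "50kV": 2.0}, seed=9)
        a = simulate_dose_response(cfg)
        b = simulate_dose_response(cfg)
        assert np.array_equal(a[1].netod, b[1].netod)


class TestStudyFixture:
    def test_regeneration_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_study_fixture(7, d1, films=("EBT3",))
        make_study_fixture(7, d2, films=("EBT3",))
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_manifest_carries_ground_truth(self, study_fixture):
        mani = json.loads((study_fixture / "manifest.json").read_text())
        assert mani["seed"] == 1
        for film in ("EBT3", "MDV3"):
            beams = mani["films"][film]["beams"]
            assert set(beams) == {"20kV", "50kV", "80kV", "120kV", "160kV", "Co60"}
            assert beams["Co60"]["s_q"] == 1.0
            # s_q is a monotone function of the computed dose-average LET
            pairs = sorted(
                (b["L_dose_TEF_keV_um"], b["s_q"]) for b in beams.values()
            )
            s_sorted = [s for _, s in pairs]
            assert np.all(np.diff(s_sorted) >= 0)

    def test_fixture_files_complete(self, study_fixture):
        names = {p.name for p in study_fixture.iterdir()}
        for film in ("EBT3", "MDV3"):
            for beam in ("20kV", "50kV", "80kV", "120kV", "160kV", "Co60"):
                assert f"spectrum_{film}_{beam}_TEF.tsv" in names
                assert f"spectrum_{film}_{beam}_SE.tsv" in names
                assert f"curve_{film}_{beam}.tsv" in names
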