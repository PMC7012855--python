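import numpy as np
import pytest

from letfilm.errors import AlignmentError, ConfigurationError, FormatError, RangeError
from letfilm.let_average import LETResult
from letfilm.relative_efficiency import (
    DoseResponseCurve,
    assemble_re_vs_let,
    dose_for_netod,
    read_curve,
    relative_efficiency,
    relative_efficiency_result,
    weighted_average_re,
    write_curve,
)


def curve(dose, netod, film="EBT3", beam="20kV", channel="red", sigma=None):
    dose = np.asarray(dose, float)
    netod = np.asarray(netod, float)
    sig = np.zeros_like(netod) if sigma is None else np.asarray(sigma, float)
    return DoseResponseCurve(
        film=film, beam=beam, channel=channel, dose=dose, netod=netod, sigma_netod=sig
    )


def saturating_curve(scale, beam, a=0.8, b=0.08, film="EBT3", n=20):
    d = np.geomspace(0.1, 25.0, n)
    return curve(d, a * (1 - np.exp(-b * scale * d)), film=film, beam=beam)


class TestInversion:
    def test_tabulated_point_returns_exact_dose(self):
        c = curve([1, 2, 5, 10], [0.1, 0.25, 0.5, 0.7])
        assert dose_for_netod(c, 0.25) == pytest.approx(2.0, rel=1e-12)

    def test_linear_curve_closed_form(self):
        d = np.linspace(0.5, 10, 20)
        c = curve(d, 0.1 * d)
        assert dose_for_netod(c, 0.5) == pytest.approx(5.0, rel=1e-9)

    def test_roundtrip_forward_inverse(self):
        rng = np.random.default_rng(2)
        d = np.sort(rng.uniform(0.1, 20, 15))
        n = np.cumsum(rng.uniform(0.01, 0.1, 15))
        c = curve(d, n)
        for y in np.linspace(n[0], n[-1], 11):
            assert c.forward(dose_for_netod(c, y)) == pytest.approx(float(y), abs=1e-6)

    def test_extrapolation_rejected(self):
        c = curve([1, 2, 5], [0.1, 0.2, 0.4])
        with pytest.raises(RangeError):
            dose_for_netod(c, 0.5)
        with pytest.raises(RangeError):
            dose_for_netod(c, 0.05)

    def test_nonmonotone_beyond_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            curve([1, 2, 3], [0.3, 0.1, 0.4])


class TestRelativeEfficiency:
    def test_identical_curves_give_unity(self):
        c = saturating_curve(1.0, "Co60")
        for y in (0.053, 0.176, 0.510):
            assert relative_efficiency(c, c, y) == pytest.approx(1.0, rel=1e-9)

    def test_dose_scaled_curves_recover_scale_at_every_level(self):
        """netOD_q(D) = netOD_co(4 D) implies RE = 4 independent of level."""
        co = saturating_curve(1.0, "Co60")
        q = saturating_curve(4.0, "20kV")
        for y in (0.053, 0.176, 0.510):
            assert relative_efficiency(co, q, y) == pytest.approx(4.0, rel=1e-3)

    def test_invariant_under_common_netod_rescaling(self):
        co = saturating_curve(1.0, "Co60")
        q = saturating_curve(3.0, "50kV")
        co2 = curve(co.dose, 2.5 * co.netod, beam="Co60")
        q2 = curve(q.dose, 2.5 * q.netod, beam="50kV")
        y, y2 = 0.176, 2.5 * 0.176
        assert relative_efficiency(co2, q2, y2) == pytest.approx(
            relative_efficiency(co, q, y), rel=1e-9
        )

    def test_film_mismatch_rejected(self):
        co = saturating_curve(1.0, "Co60", film="EBT3")
        q = saturating_curve(2.0, "20kV", film="MDV3")
        with pytest.raises(AlignmentError):
            relative_efficiency(co, q, 0.1)

    def test_noisy_pair_recovers_scale_within_2pct(self):
        from letfilm.synthetic_data import default_response_config, simulate_dose_response

        cfg = default_response_config(
            "EBT3", {"Co60": 1.0, "20kV": 3.0}, seed=7, noise_rel=0.01
        )
        co, q = simulate_dose_response(cfg, ["Co60", "20kV"])
        res = relative_efficiency_result(co, q)
        assert res.re_weighted == pytest.approx(3.0, rel=0.02)


class TestWeightedAverage:
    def test_single_value_is_itself(self):
        assert weighted_average_re([2.5])[0] == pytest.approx(2.5)

    def test_constant_values_any_sigmas(self):
        m, _ = weighted_average_re([2.0, 2.0, 2.0], [0.1, 0.5, 2.0])
        assert m == pytest.approx(2.0)

    def test_two_values_equal_sigmas_closed_form(self):
        m, s = weighted_average_re([1.0, 3.0], [1.0, 1.0])
        assert m == pytest.approx(2.0)
        assert s == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            weighted_average_re([])


class TestAssembly:
    def _let(self, beam, lt, ld, kind="TEF"):
        return LETResult(lt, ld, 0.01, 0.02, 1.0, kind, "EBT3_active", beam)

    def _re(self, beam, value):
        from letfilm.relative_efficiency import REResult

        return REResult("EBT3", beam, (0.1,), (value,), (0.01,), value, 0.01)

    def test_single_beam_single_row(self):
        rows = assemble_re_vs_let([self._re("Co60", 1.0)], [self._let("Co60", 0.5, 4.3)])
        assert len(rows) == 1
        assert rows[0]["LET_keV_um"] == 0.5

    def test_sorted_by_let_and_axis_switch_preserves_re(self):
        res = [self._re("Co60", 1.0), self._re("20kV", 4.0)]
        lets = [self._let("Co60", 0.5, 4.3), self._let("20kV", 7.1, 12.0)]
        track = assemble_re_vs_let(res, lets, axis="track")
        dose = assemble_re_vs_let(res, lets, axis="dose")
        assert [r["LET_keV_um"] for r in track] == [0.5, 7.1]
        assert [r["RE"] for r in track] == [r["RE"] for r in dose]

    def test_missing_beam_join_error_names_beam(self):
        with pytest.raises(AlignmentError, match="20kV"):
            assemble_re_vs_let([self._re("20kV", 4.0)], [self._let("Co60", 0.5, 4.3)])


class TestFileDialect:
    def test_roundtrip(self, tmp_path):
        c = saturating_curve(2.0, "50kV")
        p = tmp_path / "c.tsv"
        write_curve(c, p)
        c2 = read_curve(p)
        assert np.array_equal(c.dose, c2.dose)
        assert np.array_equal(c.netod, c2.netod)
        assert (c2.film, c2.beam, c2.channel) == ("EBT3", "50kV", "red")

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("# film: EBT3\n1 0.1 0.0\n2 0.2 0.0\n")
        with pytest.raises(FormatError):
            read_curve(p)
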