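"""DAM ratio LUT: construction, inversion, ambiguity angle, round trips."""

import numpy as np
import pytest

from b1dam.bloch import SliceSelection, default_z_grid
from b1dam.lut import (RatioLUT, build_ratio_lut, dam_naive_fa, invert_lut,
                       rectangular_ratio_lut, simulate_integrated_signals)


class TestNaiveDam:
    @pytest.mark.parametrize("s1,s2,expected", [
        (1.0, 1.0, 60.0), (1.0, 0.0, 90.0), (1.0, 2.0, 0.0)])
    def test_closed_form(self, s1, s2, expected):
        assert dam_naive_fa(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_ratio_above_two_clips_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = dam_naive_fa(1.0, 2.5)
        assert out == 0.0
        assert any("clip" in r.message for r in caplog.records)

    def test_nonpositive_s1_rejected(self):
        with pytest.raises(ValueError):
            dam_naive_fa(0.0, 1.0)


class TestRectangularProfile:
    def test_ratio_is_two_cos_alpha(self):
        lut = rectangular_ratio_lut()
        i65 = np.argwhere(lut.fa_grid == 65.0)[0][0]
        assert lut.ratios[i65] == pytest.approx(2 * np.cos(np.radians(65)), abs=1e-6)

    def test_ambiguity_angle_is_90(self):
        lut = rectangular_ratio_lut()
        assert abs(lut.ambiguity_angle - 90.0) <= 0.5

    def test_ratio_one_inverts_to_60(self):
        lut = rectangular_ratio_lut()
        assert invert_lut(lut, 1.0) == pytest.approx(60.0, abs=0.02)

    def test_out_of_range_ratio_clips_to_fa_min(self, caplog):
        import logging
        lut = rectangular_ratio_lut()
        with caplog.at_level(logging.WARNING):
            fa = invert_lut(lut, 2.05)
        assert fa == lut.fa_grid[0]
        assert any("clip" in r.message.lower() for r in caplog.records)


class TestHwsLut:
    def test_ambiguity_angle_near_95(self, lut):
        assert abs(lut.ambiguity_angle - 95.0) <= 1.0

    def test_small_angle_limit_ratio_two(self, lut):
        assert lut.ratios[0] == pytest.approx(2.0, rel=5e-3)   # FA = 1 deg

    def test_monotone_decreasing_below_ambiguity(self, lut):
        fa_b, r_b = lut.monotone_branch
        assert np.all(np.diff(r_b) < 0)
        assert fa_b[-1] <= lut.ambiguity_angle + 1.0
        assert np.all(lut.ratios >= 0)

    def test_interpolation_identity_at_grid_point(self, lut):
        i70 = np.argwhere(lut.fa_grid == 70.0)[0][0]
        assert invert_lut(lut, lut.ratios[i70]) == pytest.approx(70.0, abs=1e-9)

    def test_nan_ratio_maps_to_missing(self, lut):
        out = invert_lut(lut, np.array([np.nan, lut.ratios[64]]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_csv_round_trip(self, lut, tmp_path):
        lut.to_csv(tmp_path / "lut.csv", tmp_path / "lut.yaml")
        back = RatioLUT.from_csv(tmp_path / "lut.csv", tmp_path / "lut.yaml")
        assert np.allclose(back.fa_grid, lut.fa_grid)
        assert np.allclose(back.ratios, lut.ratios)
        assert back.ambiguity_angle == pytest.approx(lut.ambiguity_angle)

    def test_invalid_fa_grid_rejected(self, pulse, slice_sel, tissue):
        with pytest.raises(ValueError):
            build_ratio_lut(pulse, slice_sel, 11.0, tissue,
                            np.array([10.0, 5.0]))


@pytest.mark.parametrize("b1_true", [0.59, 0.8, 1.0, 1.14])
def test_on_resonance_round_trip_recovers_b1(b1_true, pulse, slice_sel,
                                             tissue, lut, te):
    """Forward-simulate the DAM pair on resonance and invert via the LUT."""
    sig = simulate_integrated_signals(
        pulse, slice_sel, te, tissue,
        np.array([65.0, 130.0]) * b1_true)
    fa = invert_lut(lut, sig[1] / sig[0])
    assert fa / 65.0 == pytest.approx(b1_true, abs=1e-3)


def test_naive_underestimates_while_lut_is_exact(pulse, slice_sel, tissue,
                                                 lut, te):
    """With the slice profile included, the naive arccos inversion biases
    the flip angle low while the LUT inversion recovers it."""
    sig = simulate_integrated_signals(pulse, slice_sel, te, tissue,
                                      np.array([65.0, 130.0]))
    naive = dam_naive_fa(sig[0], sig[1])
    assert naive < 65.0 - 0.5
    assert invert_lut(lut, sig[1] / sig[0]) == pytest.approx(65.0, abs=0.065)


class TestInversionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0.05, max_value=1.95))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_lut_inversion_round_trip(self, ratio):
        """invert_lut is the piecewise-linear inverse of the monotone
        branch: mapping the flip angle back through the table recovers the
        ratio."""
        lut = rectangular_ratio_lut()
        fa = invert_lut(lut, ratio, warn=False)
        fa_b, r_b = lut.monotone_branch
        r_back = np.interp(fa, fa_b, r_b)
        assert abs(r_back - ratio) < 1e-9

    @given(st.floats(min_value=0.5, max_value=89.5))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_naive_dam_inverts_ideal_ratio(self, fa):
        """arccos inversion is exact on ideal rectangular-profile signals."""
        s1, s2 = np.sin(np.radians(fa)), np.sin(np.radians(2 * fa))
        assert dam_naive_fa(s1, s2) == pytest.approx(fa, abs=1e-9)


def test_constant_offset_ratio_invariance(pulse, tissue, te):
    """A constant off-resonance cancels in the DAM magnitude ratio when the
    simulation window fully covers the (shifted) excited profile."""
    ss = SliceSelection(gradient=2.54, z_grid=default_z_grid(1.0, 401))
    ratios = []
    for off in (0.0, 50.0):
        s = simulate_integrated_signals(pulse, ss, te, tissue,
                                        np.array([65.0, 130.0]),
                                        np.full(401, off))
        ratios.append(s[1] / s[0])
    assert abs(ratios[1] - ratios[0]) / ratios[0] < 1e-6
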