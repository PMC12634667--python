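"""Geometry module: layout construction, porosity, hydraulic diameter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pillarmps.geometry import (
    FenestraGeometry,
    FenestraKind,
    FluidProperties,
    GapConvention,
    PillarLayout,
    build_pillar_layout,
    hydraulic_diameter,
    porosity,
    porous_volume,
)


class TestHydraulicDiameter:
    @pytest.mark.parametrize("h, w, expected", [
        (4.0, 4.0, 4.0),                 # square duct: D_h equals the side
        (2.0, 2.0, 2.0),
        (2.0, 8.0, 3.2),                 # the fenestra cross-section
    ])
    def test_values(self, h, w, expected):
        assert hydraulic_diameter(h, w) == pytest.approx(expected)

    def test_width_inverts_to_8_um(self):
        # solve 2hw/(h+w) = 3.2 with h = 2 -> w = 8
        h, dh = 2.0, 3.2
        w = dh * h / (2 * h - dh)
        assert w == pytest.approx(8.0)
        assert hydraulic_diameter(h, w) == pytest.approx(dh)

    @pytest.mark.parametrize("h, w", [(0, 1), (1, 0), (-2, 3)])
    def test_non_positive_rejected(self, h, w):
        with pytest.raises(ValueError):
            hydraulic_diameter(h, w)


class TestBuildPillarLayout:
    def test_eight_pillars_8um_pores(self):
        lay = build_pillar_layout(8, 8.0, 708.0)
        assert lay.pillar_diameter == pytest.approx(79.5)

    def test_eight_pillars_2um_pores(self):
        lay = build_pillar_layout(8, 2.0, 708.0)
        assert lay.pillar_diameter == pytest.approx(86.25)

    def test_single_pillar_zero_pore_spans_region(self):
        lay = build_pillar_layout(1, 0.0, 50.0)
        assert lay.pillar_diameter == pytest.approx(50.0)
        assert porosity(lay) < 1.0

    def test_centers_equally_spaced_and_fit(self):
        lay = build_pillar_layout(8, 8.0, 708.0)
        c = lay.pillar_centers()
        assert np.allclose(np.diff(c), lay.pitch)
        assert c[0] - lay.pillar_diameter / 2 == pytest.approx(lay.pore_size)
        assert 708.0 - (c[-1] + lay.pillar_diameter / 2) == pytest.approx(8.0)

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            build_pillar_layout(8, 100.0, 708.0)

    def test_internal_only_convention(self):
        lay = build_pillar_layout(4, 8.0, 100.0,
                                  GapConvention.internal_only)
        # 4 d + 3 g = 100
        assert lay.pillar_diameter == pytest.approx((100 - 24) / 4)


class TestPorosity:
    def test_no_pillars_is_unity(self):
        lay = PillarLayout(region_length=100.0, region_width=50.0,
                           n_pillars=0, pillar_diameter=0.0, pore_size=0.0,
                           height=2.0)
        assert porosity(lay) == pytest.approx(1.0)

    def test_closed_form_device_layout(self):
        lay = build_pillar_layout(8, 8.0, 708.0, region_width=125.0)
        expected = 1 - 8 * math.pi * 39.75**2 / (125 * 708)
        assert porosity(lay) == pytest.approx(expected)
        assert porosity(lay) == pytest.approx(0.551, abs=5e-4)

    def test_monte_carlo_oracle(self):
        # independent plan-area integration agrees within 0.5% at 1e6 points
        lay = build_pillar_layout(8, 8.0, 708.0, region_width=125.0)
        rng = np.random.default_rng(42)
        pts = rng.uniform([0, 0], [708.0, 125.0], size=(1_000_000, 2))
        centers = lay.pillar_centers()
        r2 = (lay.pillar_diameter / 2) ** 2
        d2 = ((pts[:, 0, None] - centers) ** 2
              + (pts[:, 1, None] - 62.5) ** 2)
        void = ~(d2 <= r2).any(axis=1)
        assert void.mean() == pytest.approx(porosity(lay), rel=5e-3)

    @given(pore=st.floats(0.5, 20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_pore_size(self, pore):
        # larger pores shrink pillars, so porosity increases
        lo = build_pillar_layout(8, pore, 708.0)
        hi = build_pillar_layout(8, pore + 0.5, 708.0)
        assert porosity(hi) > porosity(lo)


class TestPorousVolume:
    @given(h=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exactly_linear_in_height(self, h):
        base = build_pillar_layout(8, 8.0, 708.0, height=h)
        dbl = build_pillar_layout(8, 8.0, 708.0, height=2 * h)
        assert porous_volume(dbl) == pytest.approx(2 * porous_volume(base))
        assert porous_volume(base) / h == pytest.approx(
            porous_volume(dbl) / (2 * h))


class TestFenestraAndFluids:
    def test_straight_fenestra_dh(self):
        fen = FenestraGeometry(kind=FenestraKind.straight_channel,
                               height=2.0, width_or_layout=8.0, length=125.0)
        assert fen.hydraulic_diameter == pytest.approx(3.2)

    def test_pillar_fenestra_dh_from_pore(self):
        lay = build_pillar_layout(8, 8.0, 708.0, height=2.0)
        fen = FenestraGeometry(kind=FenestraKind.pillar_array,
                               height=2.0, width_or_layout=lay, length=125.0)
        assert fen.hydraulic_diameter == pytest.approx(3.2)

    def test_fluid_invariants(self):
        with pytest.raises(ValueError):
            FluidProperties(contact_angle_deg=0.0)
        with pytest.raises(ValueError):
            FluidProperties(surface_tension=-1.0)
        f = FluidProperties()
        assert f.contact_angle == pytest.approx(math.radians(66.0))


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        from pillarmps.geometry import load_device_config
        cfg = tmp_path / "device.yaml"
        cfg.write_text(
            "units: um\n"
            "device:\n  chamber_width: 300\n  channel_width: 100\n"
            "barrier:\n  kind: pillar_array\n  height: 2\n  length: 125\n"
            "  layout:\n    n_pillars: 8\n    pore_size: 8\n"
            "    region_length: 708\n"
        )
        dev = load_device_config(cfg)
        assert dev.chamber_width == 300.0
        assert dev.barrier.hydraulic_diameter == pytest.approx(3.2)
        assert dev.barrier.width_or_layout.pillar_diameter == pytest.approx(79.5)

    def test_wrong_units_rejected(self, tmp_path):
        from pillarmps.geometry import load_device_config
        cfg = tmp_path / "device.yaml"
        cfg.write_text("units: mm\ndevice: {}\n")
        with pytest.raises(ValueError):
            load_device_config(cfg)
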