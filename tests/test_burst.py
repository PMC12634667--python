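"""Capillary burst valve: nondimensionalisation, pinning and bursting."""

import math

import numpy as np
import pytest

from pillarmps.burst import (
    find_burst_pressure,
    nondimensional_pressure,
    pillar_fenestra_domain,
    simulate_invasion,
    straight_fenestra_domain,
    straight_exit_pinning_bounds,
)
from pillarmps.geometry import FluidProperties

FLUIDS = FluidProperties()


def short_domain(dx=1.0, **kw):
    """Shortened straight fenestra for fast invasion tests."""
    kw.setdefault("fen_len", 30.0)
    kw.setdefault("inlet_len", 16.0)
    kw.setdefault("outlet_len", 20.0)
    kw.setdefault("chamber_width", 40.0)
    return straight_fenestra_domain(dx=dx, **kw)


class TestNondimensionalPressure:
    def test_zero(self):
        assert nondimensional_pressure(0.0, 3.2, 0.072) == 0.0

    def test_identity(self):
        # p = gamma/D_h gives exactly 1
        p = 0.072 / 3.2e-6
        assert nondimensional_pressure(p, 3.2, 0.072) == pytest.approx(1.0)

    def test_printed_scale(self):
        assert nondimensional_pressure(4050.0, 3.2, 0.072) == pytest.approx(
            0.18, abs=5e-3)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ValueError):
            nondimensional_pressure(100.0, 3.2, 0.0)


class TestDomains:
    def test_hydraulic_diameters_match(self):
        s = straight_fenestra_domain(dx=1.0)
        p = pillar_fenestra_domain(dx=1.0)
        assert s.hydraulic_diameter == pytest.approx(3.2)
        assert p.hydraulic_diameter == pytest.approx(3.2)

    def test_unresolved_pore_rejected(self):
        with pytest.raises(ValueError):
            straight_fenestra_domain(dx=2.0)   # 8 um pore needs >= 6 cells

    def test_fenestra_connects_inlet_to_outlet(self):
        dom = straight_fenestra_domain(dx=1.0)
        j = dom.solid.shape[1] // 2
        assert not dom.solid[:, j].any()


class TestInvasion:
    def test_pinned_at_zero_pressure(self):
        st = simulate_invasion(short_domain(), 0.0, FLUIDS)
        assert st.outcome == "pinned"

    def test_burst_far_above_threshold(self):
        st = simulate_invasion(short_domain(), 60_000.0, FLUIDS)
        assert st.outcome == "burst"

    def test_zero_surface_tension_bursts(self):
        no_gamma = FluidProperties(surface_tension=0.0)
        st = simulate_invasion(short_domain(), 500.0, no_gamma)
        assert st.outcome == "burst"

    def test_phase_indicator_bounded(self):
        st = simulate_invasion(short_domain(), 10_000.0, FLUIDS,
                               max_steps=2000)
        assert st.phi.min() >= 0.0 and st.phi.max() <= 1.0

    def test_liquid_volume_nondecreasing_under_pressure(self):
        st = simulate_invasion(short_domain(), 60_000.0, FLUIDS)
        vol = st.volume_history
        drops = np.diff(vol)
        # monotone advance up to reinitialisation jitter
        assert drops.min() > -2e-3


@pytest.fixture(scope="module")
def short_result():
    return find_burst_pressure(short_domain(), FLUIDS, tol_frac=0.05)


class TestBurstPressure:
    def test_within_young_laplace_bracket(self, short_result):
        # quasi-static exit-pinning analysis brackets the simulated value
        lo, hi = straight_exit_pinning_bounds(8.0, FLUIDS)
        assert lo <= short_result.burst_pressure <= hi

    def test_p_star_consistent(self, short_result):
        expected = nondimensional_pressure(short_result.burst_pressure,
                                           3.2, 0.072)
        assert short_result.p_star == pytest.approx(expected)

    def test_bracket_contains_result(self, short_result):
        lo, hi = short_result.bracket
        assert lo <= short_result.burst_pressure <= hi

    def test_invalid_bracket_rejected(self):
        with pytest.raises(ValueError):
            find_burst_pressure(short_domain(), FLUIDS,
                                p_lo=0.0, p_hi=50.0)   # p_hi pinned

    def test_gamma_scaling(self, short_result):
        """Doubling gamma doubles the burst pressure (p* unchanged)."""
        doubled = FluidProperties(surface_tension=0.144)
        res2 = find_burst_pressure(short_domain(), doubled, tol_frac=0.05)
        ratio = res2.burst_pressure / short_result.burst_pressure
        assert ratio == pytest.approx(2.0, rel=0.12)
        assert res2.p_star == pytest.approx(short_result.p_star, rel=0.12)

    def test_grid_refinement(self, short_result):
        """Burst pressure stable (<10%) under halving the grid spacing."""
        fine = find_burst_pressure(short_domain(dx=0.5), FLUIDS,
                                   tol_frac=0.05)
        rel = abs(fine.burst_pressure - short_result.burst_pressure) \
            / short_result.burst_pressure
        assert rel < 0.10 + 0.10   # discretisation + two bisection tolerances
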