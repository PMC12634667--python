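"""Depth-averaged flow and solute transport across the barrier."""

import numpy as np
import pytest

from pillarmps.transport import (
    ConcentrationTrace,
    DeviceGrid,
    NotReachedError,
    TransportConfig,
    build_device_grid,
    chamber_mean_velocity,
    equilibration_time,
    peclet_number,
    permeability_at_half_saturation,
    simulate_solute_transport,
    solve_flow,
)

_UM = 1e-6


def channel_grid(dx=4.0, width=100.0, length=708.0, height=150.0,
                 flow_rate=20.0):
    """Plain rectangular channel as a manually built DeviceGrid."""
    cfg = TransportConfig(flow_rate=flow_rate)
    nx, ny = int(width / dx), int(length / dx)
    depth = np.full((nx, ny), height * _UM)
    idx = np.arange(nx * ny).reshape(nx, ny)
    return cfg, DeviceGrid(
        dx=dx * _UM, depth=depth,
        chamber=np.zeros((nx, ny), bool), barrier=np.zeros((nx, ny), bool),
        inlet_cells=idx[:, 0], outlet_cells=idx[:, -1], config=cfg,
    )


class TestFlow:
    def test_zero_flow_rate_zero_field(self):
        cfg = TransportConfig(flow_rate=0.0)
        flow = solve_flow(cfg, dx_um=5.0)
        assert np.allclose(flow.velocity, 0.0)

    def test_plain_channel_mean_velocity(self):
        # cross-section mean of the axial velocity equals Q/A
        cfg, grid = channel_grid()
        flow = solve_flow(cfg, grid=grid)
        v_in = 20.0 * 1e-9 / 3600.0 / (100e-6 * 150e-6)
        ny = grid.depth.shape[1]
        axial = flow.velocity[1][:, ny // 2]
        assert axial.mean() == pytest.approx(v_in, rel=1e-3)
        # side-wall drag shapes the profile: centreline above the mean
        assert axial[len(axial) // 2] > 1.2 * v_in
        assert flow.mass_error < 1e-3

    def test_stokes_linearity(self):
        # velocity fields at two flow rates are exact scalar multiples
        cfg1 = TransportConfig(flow_rate=20.0)
        cfg2 = TransportConfig(flow_rate=40.0)
        f1 = solve_flow(cfg1, dx_um=5.0)
        f2 = solve_flow(cfg2, dx_um=5.0)
        assert np.allclose(f2.velocity, 2.0 * f1.velocity,
                           rtol=1e-6, atol=1e-12)
        # hence Pe is proportional to Q
        assert f2.peclet() == pytest.approx(2.0 * f1.peclet(), rel=1e-6)

    def test_chamber_average_of_uniform_field(self):
        cfg = TransportConfig()
        flow = solve_flow(cfg, dx_um=5.0)
        flow.velocity[:] = 0.0
        flow.velocity[0][flow.grid.chamber] = 3.0e-6
        assert chamber_mean_velocity(flow) == pytest.approx(3.0)

    def test_pillars_slow_the_chamber(self):
        vp = solve_flow(TransportConfig(flow_rate=4800.0, pore_size=8.0),
                        dx_um=5.0).mean_chamber_speed
        vn = solve_flow(TransportConfig(flow_rate=4800.0, pore_size=0.0,
                                        n_pillars=0),
                        dx_um=5.0).mean_chamber_speed
        assert vn > vp > 0.0


class TestPeclet:
    def test_zero_velocity(self):
        assert peclet_number(0.0, 300.0, 9.3e-7) == 0.0

    def test_printed_pair_implies_length(self):
        # v = 0.476 um/s with Pe = 1.40 back-solves L ~ 273 um
        pe = peclet_number(0.476, 273.0, 9.3e-7)
        assert pe == pytest.approx(1.40, abs=0.01)

    def test_ratio_equals_velocity_ratio(self):
        r_v = 3.45 / 0.476
        r_pe = (peclet_number(3.45, 300.0, 9.3e-7)
                / peclet_number(0.476, 300.0, 9.3e-7))
        assert r_pe == pytest.approx(r_v, rel=1e-12)


def exponential_trace(k_per_h, t_end=60.0, n=601, c0=7.46,
                      V=3.19e-11, A=2.12e-7):
    t = np.linspace(0.0, t_end, n)
    return ConcentrationTrace(t_hours=t, c_frac=1.0 - np.exp(-k_per_h * t),
                              c0=c0, chamber_volume=V, barrier_area=A)


class TestPermeability:
    def test_exponential_closed_form(self):
        # c = c0 (1 - e^{-kt}) gives P = k V / A exactly
        k = 0.12
        tr = exponential_trace(k)
        expected = (k / 3600.0) * tr.chamber_volume / tr.barrier_area * 100.0
        assert permeability_at_half_saturation(tr) == pytest.approx(
            expected, rel=1e-3)

    def test_flat_trace_raises(self):
        tr = exponential_trace(0.12)
        tr.c_frac[:] = 0.1
        with pytest.raises(NotReachedError):
            permeability_at_half_saturation(tr)


class TestEquilibrationTime:
    def test_exponential_closed_form(self):
        k = 0.2
        tr = exponential_trace(k)
        assert equilibration_time(tr, 0.95) == pytest.approx(
            np.log(20.0) / k, rel=1e-3)

    def test_trace_starting_at_c0(self):
        tr = exponential_trace(0.1)
        tr.c_frac[:] = 1.0
        assert equilibration_time(tr, 0.95) == 0.0

    def test_not_reached_raises(self):
        tr = exponential_trace(0.01, t_end=5.0)
        with pytest.raises(NotReachedError):
            equilibration_time(tr, 0.95)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            equilibration_time(exponential_trace(0.1), 1.5)


@pytest.fixture(scope="module")
def coarse_run():
    cfg = TransportConfig(flow_rate=20.0, barrier_height=4.0, pore_size=8.0)
    flow = solve_flow(cfg, dx_um=5.0)
    return simulate_solute_transport(cfg, flow, t_end_h=40.0, dt_h=0.1)


class TestSoluteTransport:
    def test_zero_inlet_concentration(self):
        cfg = TransportConfig(flow_rate=20.0, c0=0.0)
        flow = solve_flow(cfg, dx_um=5.0)
        tr = simulate_solute_transport(cfg, flow, t_end_h=0.5, dt_h=0.1)
        assert np.allclose(tr.c_frac * tr.c0, 0.0)

    def test_bounded_and_monotone(self, coarse_run):
        c = coarse_run.c_frac
        assert c.min() >= -1e-12 and c.max() <= 1.0 + 1e-9
        assert np.all(np.diff(c) >= -1e-12)

    def test_mass_balance(self, coarse_run):
        assert coarse_run.mass_balance_error < 0.01

    def test_equilibration_monotone_in_height(self):
        # taller fenestrations equilibrate faster
        teq = []
        for h in (2.0, 10.0):
            cfg = TransportConfig(flow_rate=20.0, barrier_height=h,
                                  pore_size=8.0)
            flow = solve_flow(cfg, dx_um=5.0)
            tr = simulate_solute_transport(cfg, flow, t_end_h=80.0, dt_h=0.1)
            teq.append(equilibration_time(tr, 0.95))
        assert teq[1] < teq[0]


class TestAreaConvention:
    def test_conventions_differ_and_are_finite(self):
        g1 = build_device_grid(TransportConfig(area_convention="chamber_face"))
        g2 = build_device_grid(TransportConfig(area_convention="open_pore"))
        assert g1.barrier_area > g2.barrier_area > 0.0

    def test_chamber_face_area_value(self):
        g = build_device_grid(TransportConfig())
        assert g.barrier_area == pytest.approx(2 * 708e-6 * 150e-6)
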