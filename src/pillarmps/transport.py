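"""Flow and solute transport across the pillar barrier.

The device is modelled plan-view with a depth-averaged (Hele-Shaw /
lubrication) approximation: each plan location carries a local depth h(x,y)
(150 um in the media channels and cell chamber, the fenestration height 2-10
um in the barrier strips, zero inside pillars and walls), and the pressure
solves the variable-conductance problem

    div( (h^3 / 12 mu) grad p ) = 0

with a prescribed inflow at the media-channel inlets and zero reference
pressure at the outlets.  The depth-averaged velocity is
u = -(h^2 / 12 mu) grad p.  Solute (albumin) transport couples to this flow
through a transient advection-diffusion equation for the depth-integrated
concentration, solved implicitly (backward Euler, upwind advection) with a
factorised operator reused over all time steps.

Derived quantities follow the device-characterisation conventions: the
chamber volume-averaged speed, the Peclet number Pe = v L / D, the
permeability at half inlet concentration P = V_ch (dc/dt) / (A_b (c0 - 0.5
c0)), and the equilibration time to a threshold fraction of c0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DeviceGeometry

__all__ = [
    "TransportConfig",
    "DeviceGrid",
    "FlowSolution",
    "ConcentrationTrace",
    "build_device_grid",
    "solve_flow",
    "chamber_mean_velocity",
    "peclet_number",
    "simulate_solute_transport",
    "permeability_at_half_saturation",
    "equilibration_time",
]

_UM = 1e-6
_ULH = 1e-9 / 3600.0     # uL/h -> m3/s


class NotReachedError(RuntimeError):
    """A trace never reached the requested concentration level."""


@dataclass(frozen=True)
class TransportConfig:
    """Inputs of a transport characterisation run.

    ``flow_rate`` is the infusion rate per media channel (uL/h); both
    channels are perfused symmetrically.  ``peclet_length`` defaults to the
    chamber width.
    """

    device: DeviceGeometry = field(default_factory=DeviceGeometry)
    diffusivity: float = 9.3e-7          # cm^2/s (albumin)
    c0: float = 7.46                     # nM at the inlets
    flow_rate: float = 20.0              # uL/h per media channel
    viscosity: float = 1.0e-3            # Pa s
    barrier_height: float = 2.0          # um fenestration height
    pore_size: float = 8.0               # um; None/0 -> no-pillar slot
    n_pillars: int = 8
    barrier_length: float = 125.0        # um, flow-direction extent
    device_length: float = 708.0         # um along the channels
    peclet_length: float = 300.0         # um
    #: permeability reference area: "chamber_face" (both chamber side walls,
    #: device_length x chamber_height, the vessel-wall convention that makes
    #: the values comparable to in-vivo endothelial permeabilities) or
    #: "open_pore" (fenestration height x total open pore length)
    area_convention: str = "chamber_face"

    def __post_init__(self) -> None:
        if self.diffusivity <= 0:
            raise ValueError("diffusivity must be positive")
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be non-negative")
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")

    @property
    def diffusivity_si(self) -> float:
        return self.diffusivity * 1e-4   # cm^2/s -> m^2/s


@dataclass
class DeviceGrid:
    """Plan-view grid: depth map, region masks and boundary index sets."""

    dx: float                            # m
    depth: np.ndarray                    # (nx, ny) m; 0 = solid
    chamber: np.ndarray                  # bool mask
    barrier: np.ndarray                  # bool mask (open barrier cells)
    inlet_cells: np.ndarray              # flat indices (y = 0 channel cells)
    outlet_cells: np.ndarray             # flat indices (y = L channel cells)
    config: TransportConfig

    @property
    def open(self) -> np.ndarray:
        return self.depth > 0.0

    @property
    def chamber_volume(self) -> float:
        """Chamber volume in m^3 (depth-integrated plan area)."""
        return float(self.depth[self.chamber].sum() * self.dx**2)

    @property
    def barrier_area(self) -> float:
        """Permeability reference area (m^2) per ``config.area_convention``."""
        c = self.config
        if c.area_convention == "chamber_face":
            return 2.0 * c.device_length * _UM * c.device.chamber_height * _UM
        if c.area_convention == "open_pore":
            if c.pore_size and c.n_pillars:
                open_len = (c.n_pillars + 1) * c.pore_size
            else:
                open_len = c.device_length
            return 2.0 * c.barrier_height * _UM * open_len * _UM
        raise ValueError(f"unknown area_convention {c.area_convention!r}")


def build_device_grid(config: TransportConfig, dx_um: float = 2.0) -> DeviceGrid:
    """Rasterise the device plan onto a uniform grid.

    Across the device (x): channel | barrier | chamber | barrier | channel.
    Channels are open at both y ends (inlet y=0, outlet y=L); chamber and
    barrier strips are walled there.  Pillars (barrier and in-chamber) are
    solid disks.
    """
    c = config
    dev = c.device
    widths = [dev.channel_width, c.barrier_length, dev.chamber_width,
              c.barrier_length, dev.channel_width]
    x_edges = np.concatenate([[0.0], np.cumsum(widths)])
    Lx, Ly = x_edges[-1], c.device_length
    nx, ny = int(round(Lx / dx_um)), int(round(Ly / dx_um))
    xc = (np.arange(nx) + 0.5) * dx_um
    yc = (np.arange(ny) + 0.5) * dx_um
    X, Y = np.meshgrid(xc, yc, indexing="ij")

    depth = np.zeros((nx, ny))
    in_ch1 = X < x_edges[1]
    in_b1 = (X >= x_edges[1]) & (X < x_edges[2])
    in_cham = (X >= x_edges[2]) & (X < x_edges[3])
    in_b2 = (X >= x_edges[3]) & (X < x_edges[4])
    in_ch2 = X >= x_edges[4]
    depth[in_ch1 | in_ch2] = dev.channel_height
    depth[in_cham] = dev.chamber_height
    depth[in_b1 | in_b2] = c.barrier_height

    if c.pore_size and c.n_pillars:
        # barrier pillars: diameter from the gap convention (n+1 end gaps)
        d = (c.device_length - (c.n_pillars + 1) * c.pore_size) / c.n_pillars
        pitch = d + c.pore_size
        centers_y = c.pore_size + d / 2.0 + pitch * np.arange(c.n_pillars)
        for bx in (0.5 * (x_edges[1] + x_edges[2]), 0.5 * (x_edges[3] + x_edges[4])):
            for cy in centers_y:
                depth[(X - bx) ** 2 + (Y - cy) ** 2 <= (d / 2.0) ** 2] = 0.0

    if dev.chamber_pillars:
        cxm = 0.5 * (x_edges[2] + x_edges[3])
        mid = Ly / 2.0
        k = dev.chamber_pillar_count
        cys = mid + dev.chamber_pillar_spacing * (np.arange(k) - (k - 1) / 2.0)
        for cy in cys:
            depth[(X - cxm) ** 2 + (Y - cy) ** 2
                  <= (dev.chamber_pillar_diameter / 2.0) ** 2] = 0.0

    depth *= _UM
    chan = (in_ch1 | in_ch2) & (depth > 0)
    idx = np.arange(nx * ny).reshape(nx, ny)
    inlet = idx[:, 0][chan[:, 0]]
    outlet = idx[:, -1][chan[:, -1]]
    return DeviceGrid(
        dx=dx_um * _UM,
        depth=depth,
        chamber=in_cham & (depth > 0),
        barrier=(in_b1 | in_b2) & (depth > 0),
        inlet_cells=inlet,
        outlet_cells=outlet,
        config=config,
    )


@dataclass
class FlowSolution:
    """Steady depth-averaged flow: pressure, velocity, face fluxes."""

    grid: DeviceGrid
    pressure: np.ndarray                 # (nx, ny) Pa
    velocity: np.ndarray                 # (2, nx, ny) m/s depth-averaged
    face_flux_x: np.ndarray              # (nx+1, ny) m^3/s volumetric
    face_flux_y: np.ndarray              # (nx, ny+1) m^3/s
    mass_error: float                    # |in - out| / in

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity[0], self.velocity[1])

    @property
    def mean_chamber_speed(self) -> float:
        """Chamber volume-averaged speed in um/s."""
        return chamber_mean_velocity(self)

    def peclet(self, length_um: Optional[float] = None) -> float:
        c = self.grid.config
        L = c.peclet_length if length_um is None else length_um
        return peclet_number(self.mean_chamber_speed, L, c.diffusivity)


def solve_flow(config: TransportConfig, dx_um: float = 2.0,
               grid: Optional[DeviceGrid] = None) -> FlowSolution:
    """Steady incompressible depth-averaged flow through the device.

    Depth-averaged Stokes-Brinkman on a staggered (MAC) grid:

        mu lap_2D(u) - (12 mu / h^2) u - grad p = 0,   div(h u) = 0

    The Brinkman drag 12 mu/h^2 is the Poiseuille bottom/top-wall friction
    of the local depth h; the resolved in-plane viscous term carries the
    side-wall drag of channels, pores and pillars that a pure Hele-Shaw
    conductance model misses.  Inflow ``config.flow_rate`` enters each media
    channel at y=0 as a uniform depth-averaged velocity; the outlets see a
    zero reference pressure; all other boundaries and solids are no-slip
    walls.
    """
    g = grid if grid is not None else build_device_grid(config, dx_um)
    nx, ny = g.depth.shape
    dx = g.dx
    mu = config.viscosity
    open2 = g.open
    if g.inlet_cells.size == 0 or g.outlet_cells.size == 0:
        raise RuntimeError("blocked device: no open inlet/outlet cells")

    inlet2 = np.zeros((nx, ny), dtype=bool)
    inlet2.ravel()[g.inlet_cells] = True
    outlet2 = np.zeros((nx, ny), dtype=bool)
    outlet2.ravel()[g.outlet_cells] = True
    Q = config.flow_rate * _ULH                  # m^3/s per channel
    h_chan = config.device.channel_height * _UM
    w_chan = config.device.channel_width * _UM
    v_in = Q / (w_chan * h_chan)                 # depth-averaged inlet speed

    # face depths (harmonic mean; zero toward solids)
    hx = np.zeros((nx + 1, ny))
    hy = np.zeros((nx, ny + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        a, b2 = g.depth[:-1, :], g.depth[1:, :]
        hx[1:-1, :] = np.where((a > 0) & (b2 > 0), 2 * a * b2 / (a + b2), 0.0)
        a, b2 = g.depth[:, :-1], g.depth[:, 1:]
        hy[:, 1:-1] = np.where((a > 0) & (b2 > 0), 2 * a * b2 / (a + b2), 0.0)
    hy[:, -1][outlet2[:, -1]] = g.depth[:, -1][outlet2[:, -1]]
    hy[:, 0][inlet2[:, 0]] = g.depth[:, 0][inlet2[:, 0]]

    # active (unknown) velocity faces
    act_u = hx > 0                                  # interior open-open only
    act_v = np.zeros_like(hy, dtype=bool)
    act_v[:, 1:-1] = hy[:, 1:-1] > 0
    act_v[:, -1] = outlet2[:, -1]                   # free outflow faces
    # inlet faces carry the prescribed v_in (not unknowns)

    iu = -np.ones(act_u.shape, dtype=np.int64)
    iv = -np.ones(act_v.shape, dtype=np.int64)
    nu = int(act_u.sum()); nv = int(act_v.sum())
    iu[act_u] = np.arange(nu)
    iv[act_v] = nu + np.arange(nv)
    ip = -np.ones((nx, ny), dtype=np.int64)
    ncell = int(open2.sum())
    ip[open2] = nu + nv + np.arange(ncell)
    ntot = nu + nv + ncell

    rows: list = []; cols: list = []; vals: list = []
    rhs = np.zeros(ntot)
    visc = mu / dx**2

    def add(r, c, v):
        r = np.atleast_1d(r)
        rows.append(r); cols.append(np.atleast_1d(c))
        vals.append(np.broadcast_to(np.asarray(v, dtype=float), r.shape).copy())

    # --- u-momentum (vectorised over active u-faces) ----------------------
    ui, uj = np.nonzero(act_u)
    rr = iu[ui, uj]
    diag = -12.0 * mu / hx[ui, uj] ** 2 - 4.0 * visc
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ni, nj = ui + di, uj + dj
        inside = (ni >= 0) & (ni <= nx) & (nj >= 0) & (nj < ny)
        nb_act = np.zeros(ui.shape, dtype=bool)
        nb_act[inside] = act_u[ni[inside], nj[inside]]
        add(rr[nb_act], iu[ni[nb_act], nj[nb_act]], visc)
        if dj != 0:
            # y-domain boundary: free slip along open channel ends, no-slip
            # along chamber/barrier walls
            at_bnd = ~((nj >= 0) & (nj < ny))
            if at_bnd.any():
                # active u-faces are interior: 1 <= i <= nx-1
                ib = ui[at_bnd]
                if dj < 0:
                    chan_end = inlet2[ib - 1, 0] | inlet2[ib, 0]
                else:
                    chan_end = outlet2[ib - 1, -1] | outlet2[ib, -1]
                bnd_idx = np.flatnonzero(at_bnd)
                diag[bnd_idx[chan_end]] += visc
                diag[bnd_idx[~chan_end]] -= visc
    add(rr, rr, diag)
    add(rr, ip[ui, uj], -1.0 / dx)
    add(rr, ip[ui - 1, uj], 1.0 / dx)

    # --- v-momentum -------------------------------------------------------
    vi, vj = np.nonzero(act_v)
    rr = iv[vi, vj]
    diag = -12.0 * mu / hy[vi, vj] ** 2 - 4.0 * visc
    for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ni, nj = vi + di, vj + dj
        inside = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj <= ny)
        nb_act = np.zeros(vi.shape, dtype=bool)
        nb_act[inside] = act_v[ni[inside], nj[inside]]
        add(rr[nb_act], iv[ni[nb_act], nj[nb_act]], visc)
        if di == 0:
            # prescribed inlet neighbour below
            is_in = (nj == 0) & inlet2[vi, 0]
            rhs[rr[is_in]] -= visc * v_in
            # beyond the outlet: free slip
            diag[nj > ny] += visc
    add(rr, rr, diag)
    interior_v = vj < ny
    add(rr[interior_v], ip[vi[interior_v], vj[interior_v]], -1.0 / dx)
    add(rr, ip[vi, vj - 1], 1.0 / dx)   # outlet faces see ghost p = 0 ahead

    # --- continuity div(h u) = 0 -----------------------------------------
    ci, cj = np.nonzero(open2)
    rr = ip[ci, cj]
    for arr, iarr, face_i, face_j, sgn in (
        (act_u, iu, ci + 1, cj, 1.0), (act_u, iu, ci, cj, -1.0),
        (act_v, iv, ci, cj + 1, 1.0), (act_v, iv, ci, cj, -1.0),
    ):
        hface = hx if arr is act_u else hy
        m = arr[face_i, face_j]
        add(rr[m], iarr[face_i[m], face_j[m]], sgn * hface[face_i[m], face_j[m]])
    is_in = (cj == 0) & inlet2[ci, 0]
    rhs[rr[is_in]] += hy[ci[is_in], 0] * v_in

    A = sp.csr_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows).astype(np.int64),
          np.concatenate(cols).astype(np.int64))),
        shape=(ntot, ntot),
    )

    if Q == 0.0:
        sol = np.zeros(ntot)
    else:
        # the system spans ~13 decades (Brinkman drag in 2 um gaps vs h-
        # weighted continuity); equilibrate and iteratively refine so the
        # tiny chamber velocities survive the factorisation roundoff
        r = 1.0 / np.sqrt(np.maximum(np.abs(A).max(axis=1).toarray().ravel(), 1e-300))
        c = 1.0 / np.sqrt(np.maximum(np.abs(A).max(axis=0).toarray().ravel(), 1e-300))
        R = sp.diags(r); C = sp.diags(c)
        As = (R @ A @ C).tocsc()
        lu = spla.splu(As)
        bs = r * rhs
        y = lu.solve(bs)
        for _ in range(3):                   # iterative refinement
            y += lu.solve(bs - As @ y)
        sol = c * y

    U = np.zeros(act_u.shape)
    V = np.zeros(act_v.shape)
    U[act_u] = sol[:nu]
    V[act_v] = sol[nu:nu + nv]
    V[:, 0][inlet2[:, 0]] = v_in
    P = np.zeros((nx, ny))
    P[open2] = sol[nu + nv:]

    # face volumetric fluxes (m^3/s)
    fx = hx * U * dx
    fy = hy * V * dx
    total_in = float(fy[:, 0].sum())
    total_out = float(fy[:, -1].sum())
    mass_error = abs(total_in - total_out) / total_in if total_in else 0.0

    # cell-centred depth-averaged velocity from fluxes over the cell's depth
    vel = np.zeros((2, nx, ny))
    hcell = np.maximum(g.depth, 1e-30)
    vel[0] = 0.5 * (fx[:-1, :] + fx[1:, :]) / (dx * hcell)
    vel[1] = 0.5 * (fy[:, :-1] + fy[:, 1:]) / (dx * hcell)
    vel[:, ~open2] = 0.0

    return FlowSolution(grid=g, pressure=P, velocity=vel,
                        face_flux_x=fx, face_flux_y=fy, mass_error=mass_error)


def chamber_mean_velocity(flow: FlowSolution,
                          device: Optional[DeviceGeometry] = None) -> float:
    """Volume-weighted mean speed over the cell-chamber region (um/s)."""
    g = flow.grid
    mask = g.chamber
    if not mask.any():
        raise ValueError("empty chamber mask")
    w = g.depth[mask]
    s = flow.speed[mask]
    return float((s * w).sum() / w.sum()) / _UM


def peclet_number(v_um_s: float, length_um: float, diffusivity_cm2_s: float) -> float:
    """Pe = v L / D with v in um/s, L in um, D in cm^2/s."""
    return (v_um_s * _UM) * (length_um * _UM) / (diffusivity_cm2_s * 1e-4)


@dataclass
class ConcentrationTrace:
    """Chamber space-averaged solute transient, as a fraction of c0."""

    t_hours: np.ndarray
    c_frac: np.ndarray
    c0: float                            # nM
    chamber_volume: float                # m^3
    barrier_area: float                  # m^2
    mass_balance_error: float = 0.0

    def __post_init__(self) -> None:
        self.t_hours = np.asarray(self.t_hours, dtype=float)
        self.c_frac = np.asarray(self.c_frac, dtype=float)
        if self.t_hours.shape != self.c_frac.shape:
            raise ValueError("time and concentration arrays must match")


def simulate_solute_transport(
    config: TransportConfig,
    flow: FlowSolution,
    t_end_h: float,
    *,
    dt_h: float = 0.05,
    store_every: int = 1,
) -> ConcentrationTrace:
    """Transient advection-diffusion of the solute through the device.

    Backward-Euler in time (unconditionally stable; the operator is
    factorised once), first-order upwind advection on the steady face
    fluxes, inlet concentration c0, advective outflow at the outlets,
    no-flux at solids.  Returns the chamber average at each stored step and
    the global solute mass-balance error (inflow - outflow - accumulation,
    relative to total inflow).
    """
    if t_end_h <= 0:
        raise ValueError("t_end_h must be positive")
    g = flow.grid
    nx, ny = g.depth.shape
    n = nx * ny
    D = config.diffusivity_si
    dt = dt_h * 3600.0
    idx = np.arange(n).reshape(nx, ny)
    open_ = g.open

    # cell "volumes" (m^3)
    vol = (g.depth * g.dx**2).ravel()

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs_const = np.zeros(n)

    # diffusion: harmonic-mean depth conductance h D / dx * dx = h D
    hx = np.zeros((nx + 1, ny))
    hy = np.zeros((nx, ny + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        a, b2 = g.depth[:-1, :], g.depth[1:, :]
        hx[1:-1, :] = np.where((a > 0) & (b2 > 0), 2 * a * b2 / (a + b2), 0.0)
        a, b2 = g.depth[:, :-1], g.depth[:, 1:]
        hy[:, 1:-1] = np.where((a > 0) & (b2 > 0), 2 * a * b2 / (a + b2), 0.0)

    for axis, hface, fflux in ((0, hx[1:-1, :], flow.face_flux_x[1:-1, :]),
                               (1, hy[:, 1:-1], flow.face_flux_y[:, 1:-1])):
        sl_lo = [slice(None)] * 2
        sl_hi = [slice(None)] * 2
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        i = idx[tuple(sl_lo)].ravel()
        j = idx[tuple(sl_hi)].ravel()
        gd = (hface * D).ravel()         # diffusive conductance (m^3/s)
        q = fflux.ravel()                # volumetric face flux i->j (m^3/s)
        qp = np.maximum(q, 0.0)          # upwind from i
        qm = np.minimum(q, 0.0)          # upwind from j
        # flux_i->j = qp*ci + qm*cj - gd*(cj-ci)
        np.add.at(diag, i, qp + gd)
        np.add.at(diag, j, -qm + gd)
        rows.extend([i, j]); cols.extend([j, i])
        vals.extend([qm - gd, -qp - gd])

    # inlet: inflow carries c0; outlet: advective outflow with interior c
    Q = config.flow_rate * _ULH
    xs = g.inlet_cells // ny
    left = g.inlet_cells[xs < nx // 2]
    right = g.inlet_cells[xs >= nx // 2]
    for cells in (left, right):
        if cells.size:
            rhs_const[cells] += (Q / cells.size) * 1.0   # carries frac=1
    out_flux = flow.face_flux_y[:, -1].copy()
    out2d = np.zeros((nx, ny), dtype=bool)
    out2d.ravel()[g.outlet_cells] = True
    oc = g.outlet_cells
    np.add.at(diag, oc, np.maximum(out_flux[oc // ny], 0.0))

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    Aop = sp.csr_matrix((np.concatenate(vals),
                         (np.concatenate(rows), np.concatenate(cols))),
                        shape=(n, n))

    M = vol / dt
    sys = (sp.diags(np.where(open_.ravel(), M, 1.0)) + Aop).tocsc()
    lu = spla.splu(sys)

    c = np.zeros(n)
    nsteps = int(round(t_end_h / dt_h))
    cham = g.chamber.ravel()
    wch = vol[cham]
    times = [0.0]
    means = [0.0]
    inflow_total = 0.0
    outflow_total = 0.0
    mass0 = float((vol * c).sum())
    for step in range(1, nsteps + 1):
        rhs = M * c + rhs_const
        rhs[~open_.ravel()] = 0.0
        c = lu.solve(rhs)
        inflow_total += 2 * Q * dt
        outflow_total += float((np.maximum(out_flux[oc // ny], 0.0) * c[oc]).sum()) * dt
        if step % store_every == 0 or step == nsteps:
            times.append(step * dt_h)
            means.append(float((c[cham] * wch).sum() / wch.sum()))
    mass_now = float((vol * c).sum())
    denom = inflow_total if inflow_total > 0 else 1.0
    mb_err = abs(inflow_total - outflow_total - (mass_now - mass0)) / denom

    return ConcentrationTrace(
        t_hours=np.asarray(times),
        c_frac=np.asarray(means),
        c0=config.c0,
        chamber_volume=g.chamber_volume,
        barrier_area=g.barrier_area,
        mass_balance_error=mb_err,
    )


def permeability_at_half_saturation(
    trace: ConcentrationTrace,
    chamber_volume: Optional[float] = None,
    barrier_area: Optional[float] = None,
) -> float:
    """Barrier permeability (cm/s) evaluated where the chamber average
    crosses 0.5 c0:  P = V_ch (dc/dt) / (A_b (c0 - 0.5 c0)).

    The derivative is a centered difference on the stored trace,
    interpolated to the crossing time.
    """
    V = trace.chamber_volume if chamber_volume is None else chamber_volume
    A = trace.barrier_area if barrier_area is None else barrier_area
    t = trace.t_hours * 3600.0
    f = trace.c_frac
    above = np.flatnonzero(f >= 0.5)
    if above.size == 0 or above[0] == 0:
        raise NotReachedError("trace never crosses 0.5 c0 (or starts above it)")
    dfdt = np.gradient(f, t)
    i = above[0]
    # linear interpolation of the derivative to the exact crossing
    t_cross = np.interp(0.5, [f[i - 1], f[i]], [t[i - 1], t[i]])
    d = np.interp(t_cross, t, dfdt)
    return float(V * d / (A * 0.5)) * 100.0     # m/s -> cm/s


def equilibration_time(trace: ConcentrationTrace,
                       threshold_fraction: float = 0.95) -> float:
    """First time (hours) the chamber average reaches threshold*c0,
    linearly interpolated between stored samples."""
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    f = trace.c_frac
    t = trace.t_hours
    above = np.flatnonzero(f >= threshold_fraction)
    if above.size == 0:
        raise NotReachedError(
            f"threshold {threshold_fraction} not reached within {t[-1]:.3g} h"
        )
    i = above[0]
    if i == 0:
        return float(t[0])
    return float(np.interp(threshold_fraction, [f[i - 1], f[i]], [t[i - 1], t[i]]))
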