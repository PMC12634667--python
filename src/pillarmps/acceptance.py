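"""End-to-end recomputation of the pipeline's headline quantities.

Each function reruns one stage of the characterisation from scratch at a
desk-scale resolution and returns the scalar the study quotes; `run_acceptance`
collects them all.  Nothing here is looked up or memoised - every number is
produced by the solvers at call time.
"""

from __future__ import annotations

import numpy as np

from .burst import (
    find_burst_pressure,
    pillar_fenestra_domain,
    straight_fenestra_domain,
)
from .collapse import ScalingCollapse
from .geometry import FluidProperties
from .oxygen import OxygenParameters, TissueDomain, solve_oxygen_steady
from .pom import SOCRDistribution, run_pom
from .transport import (
    TransportConfig,
    equilibration_time,
    simulate_solute_transport,
    solve_flow,
)

__all__ = ["run_acceptance"]

#: diffusivity band (m2/s) over which the viability bound is swept
DIFFUSIVITY_BAND = (1.0e-9, 2.0e-9, 3.0e-9)


def min_oxygen_v3(shape=(40, 120, 20)) -> dict:
    """Worst-case minimum oxygen in V3 at the high-end sOCR across the
    tissue-diffusivity band."""
    dom = TissueDomain.V3(shape=shape)
    cmins = []
    for D in DIFFUSIVITY_BAND:
        sol = solve_oxygen_steady(dom, OxygenParameters(socr=6.1e-17,
                                                        diffusivity=D))
        cmins.append(sol.c_min)
    return {"value": float(min(cmins)), "n": int(np.prod(shape))}


def scaling_exponent(seed: int, n_population: int = 1200) -> dict:
    """PoM over V1-V3 with the measured sOCR distribution, then the
    finite-size scaling collapse; returns delta (alpha)."""
    geoms = [TissueDomain.V1(), TissueDomain.V2(), TissueDomain.V3()]
    res = run_pom(geoms, SOCRDistribution(), OxygenParameters(),
                  n_population=n_population, seed=seed)
    model = ScalingCollapse.from_samples(res.ocr, res.masses)
    fit = model.fit(seed=seed + 1)
    return {"value": float(fit.delta), "n": n_population}


def burst_pressures(dx: float = 1.0) -> dict:
    """Bisected burst pressures of both fenestrae (Pa) and p*."""
    fluids = FluidProperties()
    straight = find_burst_pressure(straight_fenestra_domain(dx=dx), fluids)
    pillar = find_burst_pressure(pillar_fenestra_domain(dx=dx), fluids)
    n = int(np.prod(pillar_fenestra_domain(dx=dx).solid.shape))
    return {
        "straight": straight, "pillar": pillar,
        "ratio": pillar.burst_pressure / straight.burst_pressure,
        "n": n,
    }


def chamber_velocity(pore_size: float, dx_um: float = 2.0) -> dict:
    """Chamber volume-averaged speed (um/s) at 4800 uL/h."""
    cfg = TransportConfig(flow_rate=4800.0, barrier_height=2.0,
                          pore_size=pore_size,
                          n_pillars=8 if pore_size else 0)
    flow = solve_flow(cfg, dx_um=dx_um)
    n = int(np.prod(flow.grid.depth.shape))
    return {"value": float(flow.mean_chamber_speed), "n": n}


def max_equilibration_time(heights=(2.0, 4.0, 10.0), dx_um: float = 2.0,
                           t_end_h: float = 70.0) -> dict:
    """Slowest 95% chamber-albumin equilibration (h) across fenestration
    heights at 20 uL/h."""
    teqs = []
    n = 0
    for h in heights:
        cfg = TransportConfig(flow_rate=20.0, barrier_height=h, pore_size=8.0)
        flow = solve_flow(cfg, dx_um=dx_um)
        trace = simulate_solute_transport(cfg, flow, t_end_h=t_end_h)
        teqs.append(equilibration_time(trace, 0.95))
        n = int(np.prod(flow.grid.depth.shape))
    return {"value": float(max(teqs)), "n": n}


def run_acceptance(seed: int = 1, fast: bool = False) -> dict:
    """Recompute every reported target quantity; returns {id: {value, n}}."""
    rng_seed = int(seed) % (2**31 - 1)
    out: dict = {}

    ox = min_oxygen_v3(shape=(20, 60, 10) if fast else (40, 120, 20))
    out["t1"] = ox

    sc = scaling_exponent(rng_seed, n_population=300 if fast else 1200)
    out["t2"] = sc

    bp = burst_pressures(dx=1.0)
    out["t3"] = {"value": float(bp["ratio"]), "n": bp["n"]}
    out["t4"] = {"value": float(bp["straight"].p_star), "n": bp["n"]}

    dx = 4.0 if fast else 2.0
    out["t5"] = chamber_velocity(pore_size=8.0, dx_um=dx)
    out["t6"] = chamber_velocity(pore_size=0.0, dx_um=dx)

    out["t7"] = max_equilibration_time(dx_um=4.0 if fast else 2.0)
    return out
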