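"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:
the observed microtissue morphometrics (volume mean 1.91e7 um^3 with cv
0.33, cell density mean 1.95e14 cells/m^3 with cv 0.26, hence cell count
~3700 with cv ~0.4), sOCR variability, exponential chamber-filling traces
with known permeability, and tissue-OCR ensembles drawn exactly from the
finite-size scaling ansatz with a known exponent for recovery tests.

Positive quantities use lognormal families (only moments are observed;
positivity and right skew motivate the choice).  Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .transport import ConcentrationTrace

__all__ = [
    "SyntheticSpec",
    "synth_geometry_ensemble",
    "synth_scaling_distributions",
    "synth_concentration_trace",
]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


@dataclass(frozen=True)
class SyntheticSpec:
    """Targets for the synthetic ensembles (um-based lengths, SI rates)."""

    seed: int = 0
    socr_mean: float = 4.67e-17          # mol/s
    socr_cv: float = 0.69
    cell_count_mean: float = 3685.0
    cell_count_cv: float = 0.40
    volume_mean: float = 1.91e7          # um^3
    volume_cv: float = 0.33
    density_mean: float = 1.95e14        # cells/m^3
    density_cv: float = 0.26
    dim_means: tuple[float, float, float] = (243.8, 621.6, 124.7)  # um
    dim_cvs: tuple[float, float, float] = (0.05, 0.28, 0.95)
    trace_rate: float = 0.1              # 1/h
    trace_c0: float = 7.46               # nM

    def __post_init__(self) -> None:
        for name in ("socr_mean", "volume_mean", "density_mean", "trace_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.socr_cv, self.volume_cv, self.density_cv) < 0:
            raise ValueError("cvs must be non-negative")


def synth_geometry_ensemble(
    spec: SyntheticSpec,
    n: int,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Ensemble of tissue boxes with the observed volume/density moments.

    Volume and cell density are drawn lognormal at their observed (mean, cv)
    and the cell count derived as density*volume; per-axis shape factors with
    the observed per-axis cvs are rescaled isotropically to the drawn volume
    (the raw per-axis draws alone would imply a volume cv of ~1, inconsistent
    with the observed 0.33 - the real axes are correlated).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    vol = _lognormal(rng, spec.volume_mean, spec.volume_cv, n)          # um^3
    rho = _lognormal(rng, spec.density_mean, spec.density_cv, n)        # /m^3
    dims = np.column_stack([
        _lognormal(rng, m, cv, n) for m, cv in zip(spec.dim_means, spec.dim_cvs)
    ])
    # isotropic rescale so the box product matches the drawn volume exactly
    scale = (vol / dims.prod(axis=1)) ** (1.0 / 3.0)
    dims *= scale[:, None]
    count = rho * vol * 1e-18            # um^3 -> m^3
    return pd.DataFrame({
        "lx_um": dims[:, 0], "ly_um": dims[:, 1], "lz_um": dims[:, 2],
        "volume_um3": vol,
        "cell_count": count,
        "density_per_m3": rho,
    })


def synth_scaling_distributions(
    delta0: float,
    masses: Sequence[float],
    n: int,
    seed: int = 0,
    *,
    base: str = "lognormal",
    base_mean: float = 1.0,
    base_cv: float = 0.5,
) -> dict:
    """Per-mass samples obeying the scaling ansatz exactly: B = m^delta0 * X.

    ``base`` is the distribution of X ("lognormal" or "degenerate").  The
    ground-truth exponent is attached so recovery tests can assert against
    it.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size < 1 or np.unique(masses).size != masses.size:
        raise ValueError("masses must be distinct")
    rng = np.random.default_rng(seed)
    if base == "lognormal":
        x = _lognormal(rng, base_mean, base_cv, n)
    elif base == "degenerate":
        x = np.full(n, base_mean)
    else:
        raise ValueError(f"unknown base distribution {base!r}")
    out = {
        "samples": {float(m): m**delta0 * x for m in masses},
        "ground_truth": {
            "delta0": float(delta0), "base": base,
            "base_mean": base_mean, "base_cv": base_cv,
            "seed": seed, "n": n,
        },
    }
    return out


def synth_concentration_trace(
    k: float,
    c0: float,
    t_grid_h: np.ndarray,
    *,
    noise: float = 0.0,
    seed: int = 0,
    chamber_volume_m3: float = 3.19e-11,
    barrier_area_m2: float = 2.3e-9,
) -> tuple[ConcentrationTrace, dict]:
    """Exponential chamber-filling trace c(t) = c0 (1 - exp(-k t)).

    ``k`` in 1/h.  Returns the trace plus its ground truth: the closed-form
    permeability kV/A (cm/s) and equilibration times.  Optional Gaussian
    noise of standard deviation ``noise`` (fraction of c0) is added.
    """
    if k <= 0:
        raise ValueError("rate k must be positive")
    t = np.asarray(t_grid_h, dtype=float)
    frac = 1.0 - np.exp(-k * t)
    if noise > 0:
        rng = np.random.default_rng(seed)
        frac = np.clip(frac + rng.normal(0.0, noise, t.shape), 0.0, 1.0)
    trace = ConcentrationTrace(
        t_hours=t, c_frac=frac, c0=c0,
        chamber_volume=chamber_volume_m3, barrier_area=barrier_area_m2,
    )
    k_si = k / 3600.0                    # 1/s
    truth = {
        "rate_per_h": k,
        "permeability_cm_s": k_si * chamber_volume_m3 / barrier_area_m2 * 100.0,
        "t_eq_95_h": np.log(20.0) / k,
        "noise": noise,
        "seed": seed,
    }
    return trace, truth


def write_ensemble_csv(df: pd.DataFrame, path: Union[str, Path],
                       ground_truth: Optional[dict] = None) -> None:
    """CSV output with a JSON sidecar of ground-truth parameters."""
    path = Path(path)
    df.to_csv(path, index=False)
    if ground_truth is not None:
        path.with_suffix(".json").write_text(json.dumps(ground_truth, indent=2))
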