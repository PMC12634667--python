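"""Steady Michaelis-Menten oxygen reaction-diffusion in a box microtissue.

The tissue is a rectangular box of dense cardiac cells.  Oxygen obeys

    0 = div(D grad c) + R,    R = -sOCR * rho_c * c / (k_m + c)

with fixed concentration on the four side walls (medium-facing faces),
no-flux on the glass-facing bottom, and a Robin (gas-transfer) condition on
the PDMS-facing top: inward flux = k_pdms (c_amb - c).  The tissue oxygen
consumption rate B is the surface integral of inward diffusive flux over all
boundaries; at steady state it equals the volume-integrated consumption.

Discretisation: cell-centered finite differences on a structured grid, SI
units internally.  The Michaelis-Menten nonlinearity is handled by damped
Picard iteration on the linearised reaction coefficient sOCR*rho_c/(k_m+c),
with a Newton fallback; both leave the 7-point operator symmetric positive
definite, solved by conjugate gradients warm-started from the previous
iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueDomain",
    "OxygenParameters",
    "OxygenSolution",
    "solve_oxygen_steady",
    "tissue_ocr",
    "min_oxygen",
    "slab_min_concentration_zeroth_order",
]

_UM = 1e-6

#: face boundary-condition kinds: "dirichlet", "noflux", "robin"
_DEFAULT_BCS = {
    "x-": "dirichlet", "x+": "dirichlet",
    "y-": "dirichlet", "y+": "dirichlet",
    "z-": "noflux",    # glass bottom
    "z+": "robin",     # PDMS top
}


@dataclass(frozen=True)
class TissueDomain:
    """Tissue box (dimensions in um) with grid resolution and face BCs."""

    dims: tuple[float, float, float]          # (Lx, Ly, Lz) um
    shape: tuple[int, int, int] = (24, 60, 12)
    bcs: dict = field(default_factory=lambda: dict(_DEFAULT_BCS))
    name: str = "custom"

    def __post_init__(self) -> None:
        if any(L <= 0 for L in self.dims):
            raise ValueError("box dimensions must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid must have at least 2 cells per axis")
        missing = set(_DEFAULT_BCS) - set(self.bcs)
        if missing:
            raise ValueError(f"missing boundary conditions for faces {missing}")

    @property
    def volume(self) -> float:
        """Box volume in m^3."""
        return float(np.prod(self.dims)) * _UM**3

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Cell sizes (m)."""
        return tuple(L * _UM / n for L, n in zip(self.dims, self.shape))

    @classmethod
    def V1(cls, shape: tuple[int, int, int] = (20, 48, 10)) -> "TissueDomain":
        return cls(dims=(243.8, 621.6, 62.35), shape=shape, name="V1")

    @classmethod
    def V2(cls, shape: tuple[int, int, int] = (20, 48, 12)) -> "TissueDomain":
        return cls(dims=(243.8, 621.6, 124.7), shape=shape, name="V2")

    @classmethod
    def V3(cls, shape: tuple[int, int, int] = (24, 64, 12)) -> "TissueDomain":
        return cls(dims=(288.0, 950.0, 124.7), shape=shape, name="V3")


@dataclass(frozen=True)
class OxygenParameters:
    """Physical parameters of the oxygen model (SI).

    ``diffusivity`` is the oxygen diffusivity in tissue; it is not a measured
    device property and the model exposes it explicitly (typical cardiac
    tissue values span 1-3e-9 m2/s).  ``k_pdms`` defaults to
    D_PDMS/t_PDMS with D_PDMS = 3.4e-9 m2/s through a 2 mm slab.
    """

    diffusivity: float = 2.0e-9         # m2/s
    k_m: float = 6.9e-3                 # mol/m3, Michaelis constant
    socr: float = 4.67e-17              # mol/s per cell
    rho_c: float = 1.95e14              # cells/m3
    c_side: float = 0.21                # mol/m3, side-wall Dirichlet value
    c_critical: float = 0.04            # mol/m3, viability threshold
    k_pdms: float = 3.4e-9 / 2.0e-3     # m/s, PDMS transfer coefficient
    c_ambient: float = 0.21             # mol/m3 behind the PDMS

    def __post_init__(self) -> None:
        if self.diffusivity <= 0 or self.k_m <= 0 or self.rho_c <= 0:
            raise ValueError("diffusivity, k_m, rho_c must be positive")
        if self.socr < 0:
            raise ValueError("socr must be non-negative")
        if not self.k_m < self.c_side:
            raise ValueError("expected k_m < c_side for the oxygen model")


@dataclass
class OxygenSolution:
    """Converged steady oxygen field plus derived scalars."""

    c: np.ndarray                        # mol/m3, shape = domain.shape
    domain: TissueDomain
    params: OxygenParameters
    ocr: float                           # mol/s, surface-flux integral B
    volumetric_consumption: float        # mol/s, integral of |R| dV
    c_min: float
    c_max: float
    converged: bool
    residuals: np.ndarray                # nonlinear residual history

    @property
    def viable(self) -> bool:
        return self.c_min >= self.params.c_critical


class _Discretisation:
    """Assembled linear part of the steady problem (reused across solves)."""

    def __init__(self, domain: TissueDomain, params: OxygenParameters):
        nx, ny, nz = domain.shape
        dx, dy, dz = domain.spacing
        D = params.diffusivity
        n = nx * ny * nz
        idx = np.arange(n).reshape(nx, ny, nz)
        vol = dx * dy * dz

        diag = np.zeros(n)
        rows, cols, vals = [], [], []
        b = np.zeros(n)
        # per-face bookkeeping for the flux integral: (cell idx, conductance, c_ext)
        self.flux_faces: dict[str, tuple[np.ndarray, float, float]] = {}

        def interior(axis, d):
            # conductance per internal face
            areas = {0: dy * dz, 1: dx * dz, 2: dx * dy}
            g = D * areas[axis] / d
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            i = idx[tuple(sl_lo)].ravel()
            j = idx[tuple(sl_hi)].ravel()
            rows.extend([i, j])
            cols.extend([j, i])
            vals.extend([np.full(i.size, -g), np.full(i.size, -g)])
            np.add.at(diag, i, g)
            np.add.at(diag, j, g)

        for axis, d in enumerate((dx, dy, dz)):
            interior(axis, d)

        face_cells = {
            "x-": idx[0, :, :].ravel(), "x+": idx[-1, :, :].ravel(),
            "y-": idx[:, 0, :].ravel(), "y+": idx[:, -1, :].ravel(),
            "z-": idx[:, :, 0].ravel(), "z+": idx[:, :, -1].ravel(),
        }
        face_area = {"x-": dy * dz, "x+": dy * dz,
                     "y-": dx * dz, "y+": dx * dz,
                     "z-": dx * dy, "z+": dx * dy}
        face_d = {"x-": dx, "x+": dx, "y-": dy, "y+": dy, "z-": dz, "z+": dz}

        for face, cells in face_cells.items():
            bc = domain.bcs[face]
            A = face_area[face]
            if bc == "dirichlet":
                g = D * A / (face_d[face] / 2.0)  # half-cell to the wall value
                np.add.at(diag, cells, g)
                np.add.at(b, cells, g * params.c_side)
                self.flux_faces[face] = (cells, g, params.c_side)
            elif bc == "robin":
                # series conductance: half-cell diffusion + interfacial transfer
                g = A / (face_d[face] / (2.0 * D) + 1.0 / params.k_pdms)
                np.add.at(diag, cells, g)
                np.add.at(b, cells, g * params.c_ambient)
                self.flux_faces[face] = (cells, g, params.c_ambient)
            elif bc == "noflux":
                pass
            else:
                raise ValueError(f"unknown boundary condition {bc!r}")

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        self.L = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self.b = b
        self.vol = vol
        self.n = n
        self._prec = None

    def preconditioner(self, params: OxygenParameters) -> spla.LinearOperator:
        """Factorised (L + mean uptake) operator, reused across CG solves.

        The per-iteration operator differs from it only in the reaction
        diagonal, so it is an effective preconditioner for every solve of a
        population run on this geometry.
        """
        if self._prec is None:
            k0 = params.socr * params.rho_c * self.vol / (params.k_m + params.c_side)
            lu = spla.splu((self.L + sp.diags(np.full(self.n, k0))).tocsc())
            self._prec = spla.LinearOperator((self.n, self.n), matvec=lu.solve)
        return self._prec


def _nonlinear_residual(disc, params, c):
    """F(c) = L c + R0 V c/(km+c) - b (discrete steady-state residual)."""
    R0 = params.socr * params.rho_c
    return disc.L @ c + R0 * disc.vol * c / (params.k_m + c) - disc.b


def solve_oxygen_steady(
    domain: TissueDomain,
    params: OxygenParameters,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    damping: float = 0.7,
    c0: Optional[np.ndarray] = None,
    _disc: Optional[_Discretisation] = None,
) -> OxygenSolution:
    """Solve the steady Michaelis-Menten reaction-diffusion problem.

    Picard iteration with damping ``damping`` on the linearised uptake
    coefficient; if the relative nonlinear residual has not dropped below
    ``tol`` after ``max_iter`` iterations, switches to Newton.  Raises
    ``RuntimeError`` (with the residual history attached) on non-convergence.
    """
    disc = _disc if _disc is not None else _Discretisation(domain, params)
    R0 = params.socr * params.rho_c
    bnorm = np.linalg.norm(disc.b)
    if bnorm == 0.0:
        raise RuntimeError("all-Neumann problem with zero source is singular")

    c = np.full(disc.n, params.c_side) if c0 is None else c0.ravel().copy()
    residuals = []

    M = disc._prec  # populated for population runs; None for one-off solves

    def lin_solve(diag_add, rhs, x0):
        A = disc.L + sp.diags(diag_add)
        x, info = spla.cg(A, rhs, x0=x0, rtol=1e-12, atol=0.0, maxiter=20000, M=M)
        if info != 0:
            x = spla.spsolve(A.tocsc(), rhs)
        return x

    if M is not None:
        # population fast path: quasi-Newton with the frozen factorised
        # operator P = L + mean-uptake diagonal (the reaction diagonal is
        # small against the diffusion stencil, so P^-1 J stays near identity)
        for it in range(max_iter):
            F = _nonlinear_residual(disc, params, c)
            res = np.linalg.norm(F) / bnorm
            residuals.append(res)
            if res < tol:
                break
            c = c - M.matvec(F)
        residuals = np.asarray(residuals)
        if residuals[-1] >= tol:
            err = RuntimeError(
                f"oxygen solver (fast path) did not converge: residual "
                f"{residuals[-1]:.3e}"
            )
            err.residuals = residuals  # type: ignore[attr-defined]
            raise err
        return _package_solution(disc, domain, params, c, residuals)

    converged = False
    for it in range(max_iter):
        res = np.linalg.norm(_nonlinear_residual(disc, params, c)) / bnorm
        residuals.append(res)
        if res < tol:
            converged = True
            break
        if it < max_iter // 2:
            # Picard: freeze the uptake coefficient at the current iterate
            k = R0 * disc.vol / (params.k_m + np.maximum(c, 0.0))
            c_new = lin_solve(k, disc.b, c)
            c = damping * c_new + (1.0 - damping) * c
        else:
            # Newton on F(c); Jacobian adds R0 V km/(km+c)^2 on the diagonal
            cm = np.maximum(c, 0.0)
            jdiag = R0 * disc.vol * params.k_m / (params.k_m + cm) ** 2
            F = _nonlinear_residual(disc, params, c)
            dc = lin_solve(jdiag, -F, np.zeros_like(c))
            c = c + dc
    else:
        res = np.linalg.norm(_nonlinear_residual(disc, params, c)) / bnorm
        residuals.append(res)
        converged = res < tol

    residuals = np.asarray(residuals)
    if not converged:
        err = RuntimeError(
            f"oxygen solver did not converge: final residual {residuals[-1]:.3e}"
        )
        err.residuals = residuals  # type: ignore[attr-defined]
        raise err

    return _package_solution(disc, domain, params, c, residuals)


def _package_solution(disc, domain, params, c, residuals) -> OxygenSolution:
    R0 = params.socr * params.rho_c
    field3 = c.reshape(domain.shape)
    # inward surface flux integral B over all boundary faces
    B = 0.0
    for cells, g, c_ext in disc.flux_faces.values():
        B += float(np.sum(g * (c_ext - c[cells])))
    volumetric = float(np.sum(R0 * disc.vol * c / (params.k_m + c)))
    return OxygenSolution(
        c=field3,
        domain=domain,
        params=params,
        ocr=B,
        volumetric_consumption=volumetric,
        c_min=float(field3.min()),
        c_max=float(field3.max()),
        converged=True,
        residuals=np.asarray(residuals),
    )


def tissue_ocr(solution: OxygenSolution) -> float:
    """Tissue OCR B (mol/s): surface integral of inward oxygen flux.

    Computed during the solve with the discrete boundary fluxes of the same
    scheme, so at convergence it matches the volume-integrated consumption to
    the nonlinear tolerance (discrete divergence theorem).
    """
    if not solution.converged:
        raise ValueError("tissue_ocr requires a converged solution")
    return solution.ocr


def min_oxygen(solution: OxygenSolution) -> float:
    """Global minimum oxygen concentration (mol/m3) of the steady field."""
    return solution.c_min


def slab_min_concentration_zeroth_order(
    half_width_um: float, params: OxygenParameters
) -> float:
    """Closed-form midplane concentration of a 1D slab in the zeroth-order
    limit (c >> k_m): c_min = c_side - R0 a^2 / (2 D), with a the half-width
    and R0 = sOCR rho_c.  Independent-oracle for the PDE solver."""
    a = half_width_um * _UM
    R0 = params.socr * params.rho_c
    return params.c_side - R0 * a * a / (2.0 * params.diffusivity)
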