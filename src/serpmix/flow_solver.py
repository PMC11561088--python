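"""Steady 2D incompressible laminar flow and species transport on the chip mesh.

A collocated finite-volume solver on the body-fitted structured grid of
:mod:`serpmix.chip_geometry`.  Pressure-velocity coupling uses momentum-
interpolated (Rhie-Chow style) face velocities, which keeps the collocated
arrangement free of checkerboard pressure modes; the default algorithm
solves velocity and pressure as one monolithic banded system per outer
iteration (a segregated SIMPLE variant is also provided).  Convection is
discretized with first-order upwind plus a deferred second-order-upwind
correction; diffusion is central (the grid is orthogonal: Cartesian in
straights, polar in bends, so no cross-diffusion terms arise).  All linear
systems are banded in the streamwise-major ordering and are solved directly
with LU factorizations, so every solve is deterministic.

Equations solved (conservative form, per unit depth):

* continuity        div(rho v) = 0
* momentum          div(rho v v) = -grad p + div(mu grad v)
  (a "stokes" mode drops the convective term, reproducing the creeping-flow
  simplification grad p = mu lap v sometimes quoted for microfluidics)
* species           div(rho v Y) = div(rho D grad Y)

The species mass fraction Y tracks the solvent (ACN-PLGA) stream; the ACN
mass fraction is X_ACN = Y*(1 - w_PLGA), with w_PLGA the PLGA mass loading of
the solvent stream (7 mg/mL in ACN: w_PLGA = 7/797 ~ 0.88%).

The computational domain runs from the Y-junction to the outlet.  The
junction is modeled as a split co-flow inlet: by default uniform normal
velocity v_mean = TFR/(d*h) over the full width with Y = 1 on a band whose
width fraction equals the solvent flow fraction (faces straddling the split
carry exact flux-weighted values, so TFR and FRR are conserved to
round-off); see :class:`BoundaryConditions` for the merge-plane variant.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.linalg import solve_banded

from .chip_geometry import ChipSpec, StructuredMesh, ValidationError
from .lumped_model import (
    ACN_PLGA,
    TRIS,
    FluidProperties,
    OperatingPoint,
    dean,
    reynolds,
)

logger = logging.getLogger(__name__)

#: PLGA mass fraction of the solvent stream (7 mg/mL in ACN, stream density 797)
W_PLGA = 7.0 / 797.0


class SolverError(RuntimeError):
    """Numerical failure (divergence, NaN) during the solve."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


class ConvergenceError(SolverError):
    """Residual tolerance not reached within the iteration budget."""


# ---------------------------------------------------------------------------
# Settings / boundary conditions / mixture model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings.

    ``tol`` is the scaled-residual convergence criterion (1e-6 default,
    applied to momentum and continuity).  ``relax_u``/``relax_p`` are the
    SIMPLE under-relaxation factors (the pseudo-transient continuation
    knobs).  ``scheme`` selects the convection discretization for momentum
    and species; second-order upwind is applied as a deferred correction on
    top of the implicit first-order matrix.
    """

    scheme: Literal["second_order_upwind", "first_order"] = "second_order_upwind"
    algorithm: Literal["coupled", "simple"] = "coupled"
    tol: float = 1.0e-6
    max_outer: int = 2000
    relax_u: float = 0.7
    relax_p: float = 0.3
    momentum: Literal["navier_stokes", "stokes"] = "navier_stokes"
    property_coupling: Literal["constant", "coupled"] = "coupled"
    picard_max: int = 3
    picard_tol: float = 1.0e-4  # mean |dY| between property-coupling rounds
    species_max_iter: int = 60
    species_tol: float = 1.0e-9

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValidationError("tolerance must be positive")
        if not (0 < self.relax_u <= 1 and 0 < self.relax_p <= 1):
            raise ValidationError("relaxation factors must lie in (0, 1]")


def inlet_velocities(op: OperatingPoint, d: float, h: float) -> tuple[float, float]:
    """Uniform normal velocities (m/s) at the two physical inlet arms.

    Each arm has the full d x h cross-section (micrometres); for FRR a:b the
    solvent arm carries Q1 = TFR*a/(a+b) and the anti-solvent arm
    Q2 = TFR*b/(a+b), so v = Q/(d*h).
    """
    A = (d * 1e-6) * (h * 1e-6)
    if A <= 0:
        raise ValidationError("zero inlet cross-section")
    return op.q_solvent / A, op.q_antisolvent / A


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet/wall/outlet conditions for the junction-to-outlet domain.

    Two inlet representations of the merged stream are available:

    * ``developed`` (default): the streams enter side by side at their
      developed width fractions (= flow fractions) with uniform speed
      v_mean = TFR/(d h), i.e. the state a short distance downstream of the
      junction; the junction transition itself is not resolved.
    * ``merge``: each arm occupies half the merge-plane width with uniform
      normal speed v_i' = 2 Q_i/(d h) on its half, and the hydrodynamic
      squeeze of the weaker stream toward its wall develops inside the
      domain.  A sensitivity variant; both idealizations bracket the real
      angled-junction transition.

    ``v_inlet``/``y_inlet`` are the per-face normal speed and solvent mass
    fraction (faces straddling a split carry exact flux-weighted values, so
    TFR and FRR are conserved to round-off).  Walls are no-slip; the outlet
    is at zero gauge pressure.  ``v1``/``v2`` record the physical arm
    velocities for reporting.
    """

    v_mean: float
    solvent_fraction: float
    v_inlet: np.ndarray
    y_inlet: np.ndarray
    v1: float
    v2: float
    op: OperatingPoint
    inlet_model: str = "developed"

    @classmethod
    def from_operating_point(
        cls,
        op: OperatingPoint,
        spec: ChipSpec,
        mesh: StructuredMesh,
        inlet_model: str = "developed",
    ) -> "BoundaryConditions":
        v1, v2 = inlet_velocities(op, spec.d, spec.h)
        v_mean = op.q_total / spec.cross_section_m2
        alpha = op.solvent_fraction
        w = mesh.width
        lo, hi = mesh.t_edges[:-1], mesh.t_edges[1:]
        if inlet_model == "merge":
            split = 0.0  # arms meet at the channel mid-plane
            va, vb = 2.0 * alpha * v_mean, 2.0 * (1.0 - alpha) * v_mean
        elif inlet_model == "developed":
            split = -w / 2 + alpha * w
            va = vb = v_mean
        else:
            raise ValidationError(f"unknown inlet model {inlet_model!r}")
        # fraction of each inlet face lying on the solvent side of the split
        frac = np.clip(np.minimum(hi, split) - lo, 0.0, hi - lo) / (hi - lo)
        v_in = frac * va + (1.0 - frac) * vb
        with np.errstate(invalid="ignore"):
            y_in = np.where(v_in > 0, frac * va / np.maximum(v_in, 1e-300), 0.0)
        return cls(
            v_mean=v_mean,
            solvent_fraction=alpha,
            v_inlet=v_in,
            y_inlet=y_in,
            v1=v1,
            v2=v2,
            op=op,
            inlet_model=inlet_model,
        )


@dataclass(frozen=True)
class MixtureModel:
    """Blending law mapping local mass fraction Y to mixture rho and mu.

    Density follows the ideal-mixture inverse-specific-volume rule by
    default (mass-weighted specific volumes); viscosity is linear in Y.
    ``rho(0)``/``mu(0)`` equal the anti-solvent values, ``rho(1)``/``mu(1)``
    the solvent-stream values.
    """

    solvent: FluidProperties = ACN_PLGA
    antisolvent: FluidProperties = TRIS
    density_rule: Literal["inverse_volume", "linear"] = "inverse_volume"

    @property
    def D(self) -> float:
        if self.solvent.D is None:
            raise ValidationError("solvent stream has no diffusion coefficient")
        return self.solvent.D

    def rho(self, Y):
        Y = np.asarray(Y, dtype=float)
        if self.density_rule == "inverse_volume":
            return 1.0 / (Y / self.solvent.rho + (1.0 - Y) / self.antisolvent.rho)
        return Y * self.solvent.rho + (1.0 - Y) * self.antisolvent.rho

    def mu(self, Y):
        Y = np.asarray(Y, dtype=float)
        return Y * self.solvent.mu + (1.0 - Y) * self.antisolvent.mu


# ---------------------------------------------------------------------------
# Fields
# ---------------------------------------------------------------------------


@dataclass
class FlowField:
    """Converged velocity/pressure field with face mass fluxes.

    ``u``/``v`` are Cartesian velocity components at cell centroids
    (n_s, n_t); ``m_s``/``m_t`` face mass fluxes per unit depth (kg/(m s))
    oriented along +s / +t.  ``dp_inlet`` is the mean inlet-adjacent cell
    pressure (outlet gauge 0), the solver's inlet-to-outlet drop estimate.
    ``reynolds`` is the bulk value on the 2D channel-width scale
    (rho_mean * v_mean * w / mu_mean).
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    m_s: np.ndarray
    m_t: np.ndarray
    residual_history: list
    n_iterations: int
    converged: bool
    reynolds: float
    dean_max: float
    dp_inlet: float
    mass_balance_error: float

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.u, self.v, self.p, self.m_s, self.m_t):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


@dataclass
class SpeciesField:
    """Solvent-stream mass fraction Y and derived ACN mass fraction."""

    Y: np.ndarray
    w_plga: float = W_PLGA
    conservation_error: float = 0.0
    clip_excursion: float = 0.0
    n_iterations: int = 0

    @property
    def X_acn(self) -> np.ndarray:
        return self.Y * (1.0 - self.w_plga)

    def content_hash(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.Y).tobytes()).hexdigest()


# ---------------------------------------------------------------------------
# Geometry cache
# ---------------------------------------------------------------------------


class _FVGeom:
    """Precomputed face geometry for the finite-volume discretization."""

    def __init__(self, mesh: StructuredMesh):
        self.mesh = mesh
        n_s, n_t = mesh.shape
        c = mesh.centroid

        # station-face centroids (n_s+1, n_t, 2)
        self.fc_s = (
            mesh.point_station[:, None, :]
            + mesh.t_centers[None, :, None] * mesh.normal_station[:, None, :]
        )
        # transverse-face centroids (n_s, n_t+1, 2)
        self.fc_t = (
            mesh.point_col[:, None, :]
            + mesh.t_edges[None, :, None] * mesh.normal_col[:, None, :]
        )

        self.dist_s = np.empty((n_s + 1, n_t))
        self.dist_s[1:-1] = np.linalg.norm(c[1:] - c[:-1], axis=2)
        self.dist_s[0] = np.linalg.norm(c[0] - self.fc_s[0], axis=1)
        self.dist_s[-1] = np.linalg.norm(c[-1] - self.fc_s[-1], axis=1)

        self.dist_t = np.empty((n_s, n_t + 1))
        self.dist_t[:, 1:-1] = np.linalg.norm(c[:, 1:] - c[:, :-1], axis=2)
        self.dist_t[:, 0] = np.linalg.norm(c[:, 0] - self.fc_t[:, 0], axis=1)
        self.dist_t[:, -1] = np.linalg.norm(c[:, -1] - self.fc_t[:, -1], axis=1)

        self.V = mesh.area
        self.sfA = mesh.sface_area  # scalar: station faces all have length dt
        self.tfA = mesh.tface_area
        self.Ts = mesh.tangent_station  # (n_s+1, 2)
        self.Nc = mesh.normal_col  # (n_s, 2)


def _face_mean_s(phi: np.ndarray) -> np.ndarray:
    """Arithmetic mean on interior station faces, (n_s-1, n_t)."""
    return 0.5 * (phi[:-1] + phi[1:])


def _face_mean_t(phi: np.ndarray) -> np.ndarray:
    """Arithmetic mean on interior transverse faces, (n_s, n_t-1)."""
    return 0.5 * (phi[:, :-1] + phi[:, 1:])


def _green_gauss(
    geom: _FVGeom,
    phi: np.ndarray,
    inlet: np.ndarray | float | None,
    wall: float | None,
    outlet: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Green-Gauss cell gradient (gx, gy).

    Boundary face values: ``inlet``/``wall``/``outlet`` give Dirichlet values;
    ``None`` means zero normal gradient (face value = cell value).
    """
    n_s, n_t = phi.shape
    phif_s = np.empty((n_s + 1, n_t))
    phif_s[1:-1] = _face_mean_s(phi)
    phif_s[0] = phi[0] if inlet is None else inlet
    phif_s[-1] = phi[-1] if outlet is None else outlet

    phif_t = np.empty((n_s, n_t + 1))
    phif_t[:, 1:-1] = _face_mean_t(phi)
    phif_t[:, 0] = phi[:, 0] if wall is None else wall
    phif_t[:, -1] = phi[:, -1] if wall is None else wall

    # station faces: outward normal of east face = +Ts[j+1], west = -Ts[j]
    w_s = phif_s[:, :, None] * geom.sfA * geom.Ts[:, None, :]  # (n_s+1, n_t, 2)
    flux = w_s[1:] - w_s[:-1]
    w_t = (phif_t * geom.tfA)[:, :, None] * geom.Nc[:, None, :]  # (n_s, n_t+1, 2)
    flux += w_t[:, 1:] - w_t[:, :-1]
    g = flux / geom.V[:, :, None]
    return g[:, :, 0], g[:, :, 1]


def _sou_correction(
    geom: _FVGeom,
    phi: np.ndarray,
    m_s: np.ndarray,
    m_t: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    limit: bool = False,
) -> np.ndarray:
    """Deferred second-order-upwind correction source (added to the RHS).

    For each interior face the convected value is linearly reconstructed from
    the upwind cell: phi_f = phi_U + grad_U . (x_f - x_U); the correction is
    m_f * (phi_f - phi_U_firstorder) distributed to both adjacent cells.
    With ``limit`` the reconstructed face value is bounded between the two
    adjacent cell values (keeps a transported scalar monotone at fronts).
    """
    n_s, n_t = phi.shape
    c = geom.mesh.centroid
    b = np.zeros_like(phi)

    # station faces j = 1 .. n_s-1
    up = m_s[1:-1] >= 0  # upwind cell is j-1 where flux is positive
    dxU = np.where(up[..., None], geom.fc_s[1:-1] - c[:-1], geom.fc_s[1:-1] - c[1:])
    gxU = np.where(up, gx[:-1], gx[1:])
    gyU = np.where(up, gy[:-1], gy[1:])
    phiU = np.where(up, phi[:-1], phi[1:])
    dphi = gxU * dxU[..., 0] + gyU * dxU[..., 1]
    if limit:
        lo = np.minimum(phi[:-1], phi[1:])
        hi = np.maximum(phi[:-1], phi[1:])
        dphi = np.clip(phiU + dphi, lo, hi) - phiU
    corr = m_s[1:-1] * dphi
    b[:-1] -= corr
    b[1:] += corr

    # transverse faces i = 1 .. n_t-1
    up = m_t[:, 1:-1] >= 0
    dxU = np.where(
        up[..., None], geom.fc_t[:, 1:-1] - c[:, :-1], geom.fc_t[:, 1:-1] - c[:, 1:]
    )
    gxU = np.where(up, gx[:, :-1], gx[:, 1:])
    gyU = np.where(up, gy[:, :-1], gy[:, 1:])
    phiU = np.where(up, phi[:, :-1], phi[:, 1:])
    dphi = gxU * dxU[..., 0] + gyU * dxU[..., 1]
    if limit:
        lo = np.minimum(phi[:, :-1], phi[:, 1:])
        hi = np.maximum(phi[:, :-1], phi[:, 1:])
        dphi = np.clip(phiU + dphi, lo, hi) - phiU
    corr = m_t[:, 1:-1] * dphi
    b[:, :-1] -= corr
    b[:, 1:] += corr
    return b


def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 0.5 * (np.sign(a) + np.sign(b)) * np.minimum(np.abs(a), np.abs(b))


def _muscl_correction(
    phi: np.ndarray,
    m_s: np.ndarray,
    m_t: np.ndarray,
    inlet: np.ndarray,
) -> np.ndarray:
    """Deferred bounded second-order (minmod MUSCL) correction for a scalar.

    Dimension-by-dimension reconstruction along the structured grid lines:
    phi_f = phi_U + minmod(D_loc, D_up)/2.  TVD per direction, so the
    converged scheme keeps a transported scalar monotone at sharp fronts
    (no over/undershoot beyond round-off).  Falls back to first order at
    boundaries (inlet value used as the far-upwind state of the first face;
    walls/outlet replicate the edge cell).
    """
    n_s, n_t = phi.shape
    b = np.zeros_like(phi)

    # streamwise faces k = 1..n_s-1 between cells k-1 and k
    pad = np.vstack([inlet[None, :], phi, phi[-1:][:]])  # (n_s+2, n_t)
    dloc = phi[1:] - phi[:-1]  # (n_s-1, n_t)
    up = m_s[1:-1] >= 0
    # up-flow: U = k-1, far-up = pad[k-1] = cell k-2 (or inlet)
    dup_pos = phi[:-1] - pad[:-3]
    # down-flow: U = k, far-up = pad[k+2] = cell k+1 (or outlet copy)
    dup_neg = phi[1:] - pad[3:]
    dphi = np.where(
        up, 0.5 * _minmod(dloc, dup_pos), 0.5 * _minmod(-dloc, dup_neg)
    )
    corr = m_s[1:-1] * dphi
    b[:-1] -= corr
    b[1:] += corr

    # transverse faces i = 1..n_t-1 (walls replicate: first order at walls)
    padt = np.hstack([phi[:, :1], phi, phi[:, -1:]])
    dloc = phi[:, 1:] - phi[:, :-1]
    up = m_t[:, 1:-1] >= 0
    dup_pos = phi[:, :-1] - padt[:, :-3]
    dup_neg = phi[:, 1:] - padt[:, 3:]
    dphi = np.where(
        up, 0.5 * _minmod(dloc, dup_pos), 0.5 * _minmod(-dloc, dup_neg)
    )
    corr = m_t[:, 1:-1] * dphi
    b[:, :-1] -= corr
    b[:, 1:] += corr
    return b


def _assemble(
    geom: _FVGeom,
    m_s: np.ndarray,
    m_t: np.ndarray,
    gam_s: np.ndarray,
    gam_t: np.ndarray,
    convection: bool,
    wall_dirichlet: bool,
):
    """First-order upwind + central-diffusion coefficients.

    Returns (aP, aW, aE, aS, aN, bc_in) with neighbour links zeroed on the
    domain boundary.  ``bc_in`` is the coefficient multiplying the Dirichlet
    inlet value in the RHS.  Walls: Dirichlet (momentum) or zero-flux
    (species).  Outlet: zero diffusion, upwind convective outflow.
    """
    n_s, n_t = geom.V.shape
    D_s = gam_s * geom.sfA / geom.dist_s  # (n_s+1, n_t)
    D_t = gam_t * geom.tfA / geom.dist_t  # (n_s, n_t+1)

    if convection:
        ms_p = np.maximum(m_s, 0.0)
        ms_m = np.maximum(-m_s, 0.0)
        mt_p = np.maximum(m_t, 0.0)
        mt_m = np.maximum(-m_t, 0.0)
    else:
        ms_p = ms_m = np.zeros_like(m_s)
        mt_p = mt_m = np.zeros_like(m_t)

    aW = D_s[:-1] + ms_p[:-1]
    aE = D_s[1:] + ms_m[1:]
    aS = D_t[:, :-1] + mt_p[:, :-1]
    aN = D_t[:, 1:] + mt_m[:, 1:]

    aP = (
        D_s[:-1] + ms_m[:-1]
        + D_s[1:] + ms_p[1:]
        + D_t[:, :-1] + mt_m[:, :-1]
        + D_t[:, 1:] + mt_p[:, 1:]
    )

    # inlet (west of j=0): Dirichlet face; the generic sum already put
    # D_s[0] + max(-m_in, 0) = D_s[0] on the diagonal, which is what a
    # Dirichlet inflow face needs.  The value enters the RHS with D + m_in.
    bc_in = D_s[0] + ms_p[0]
    aW[0] = 0.0

    # outlet (east of j=n_s-1): no diffusion, upwind convective outflow only
    aE[-1] = 0.0
    aP[-1] -= D_s[-1]

    # walls
    aS[:, 0] = 0.0
    aN[:, -1] = 0.0
    if not wall_dirichlet:
        aP[:, 0] -= D_t[:, 0]
        aP[:, -1] -= D_t[:, -1]
    # (convection through walls is zero: m_t[:,0] = m_t[:,-1] = 0)

    return aP, aW, aE, aS, aN, bc_in


def _solve_penta(aP, aW, aE, aS, aN, rhs_cols):
    """Direct banded solve of the pentadiagonal system (streamwise-major)."""
    n_s, n_t = aP.shape
    n = n_s * n_t
    bw = n_t
    ab = np.zeros((2 * bw + 1, n))
    ab[bw] = aP.ravel()
    aNf = aN.ravel()
    aSf = aS.ravel()
    aEf = aE.ravel()
    aWf = aW.ravel()
    ab[bw - 1, 1:] = -aNf[:-1]
    ab[bw + 1, :-1] = -aSf[1:]
    ab[0, bw:] = -aEf[:-bw]
    ab[2 * bw, :-bw] = -aWf[bw:]
    b = np.stack([r.ravel() for r in rhs_cols], axis=1)
    x = solve_banded((bw, bw), ab, b, overwrite_ab=True, overwrite_b=True, check_finite=False)
    return [x[:, k].reshape(n_s, n_t) for k in range(len(rhs_cols))]


def _apply_stencil(aP, aW, aE, aS, aN, phi):
    """A @ phi for the pentadiagonal operator (for residual evaluation)."""
    out = aP * phi
    out[1:] -= aW[1:] * phi[:-1]
    out[:-1] -= aE[:-1] * phi[1:]
    out[:, 1:] -= aS[:, 1:] * phi[:, :-1]
    out[:, :-1] -= aN[:, :-1] * phi[:, 1:]
    return out


# ---------------------------------------------------------------------------
# Flow solve (SIMPLE)
# ---------------------------------------------------------------------------


def _face_props(phi_c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Face values of a cell property (arithmetic mean, boundary = cell)."""
    n_s, n_t = phi_c.shape
    fs = np.empty((n_s + 1, n_t))
    fs[1:-1] = _face_mean_s(phi_c)
    fs[0], fs[-1] = phi_c[0], phi_c[-1]
    ft = np.empty((n_s, n_t + 1))
    ft[:, 1:-1] = _face_mean_t(phi_c)
    ft[:, 0], ft[:, -1] = phi_c[:, 0], phi_c[:, -1]
    return fs, ft


def _init_fields(mesh, bc, rho_fs, geom, init, m_in):
    if init is not None:
        return init.u.copy(), init.v.copy(), init.p.copy(), init.m_s.copy(), init.m_t.copy()
    # developed-parabola initial guess along the local tangent (exact in
    # the straights away from bends, so startup transients are local)
    n_s, n_t = mesh.shape
    prof = 1.5 * bc.v_mean * (1.0 - (2.0 * mesh.t_centers / mesh.width) ** 2)
    u = mesh.tangent_col[:, 0][:, None] * prof[None, :]
    v = mesh.tangent_col[:, 1][:, None] * prof[None, :]
    p = np.zeros((n_s, n_t))
    m_s = np.empty((n_s + 1, n_t))
    m_s[:] = rho_fs * geom.sfA * prof[None, :]
    m_s[0] = m_in
    m_t = np.zeros((n_s, n_t + 1))
    return u, v, p, m_s, m_t


def _finalize(mesh, bc, rho_c, mu_c, u, v, p, m_s, m_t, history, converged, mdot_in):
    n_s, n_t = mesh.shape
    Dh = mesh.width  # plane-channel reference scale of the 2D domain
    Re = reynolds(float(rho_c.mean()), bc.v_mean, Dh, float(mu_c.mean()))
    finite_R = mesh.radius_col[np.isfinite(mesh.radius_col)]
    Dn = dean(Re, Dh, float(finite_R.min())) if finite_R.size else 0.0
    if Re > 100.0:
        logger.warning("Re = %.3g outside the strongly laminar regime", Re)
    if Dn > 110.0:
        logger.warning("Dean number %.3g outside the no-secondary-flow regime", Dn)
    mass_err = float(np.abs(m_s[-1].sum() - mdot_in) / mdot_in)
    return FlowField(
        u=u, v=v, p=p, m_s=m_s, m_t=m_t,
        residual_history=history, n_iterations=len(history), converged=converged,
        reynolds=Re, dean_max=Dn, dp_inlet=float(p[0].mean()), mass_balance_error=mass_err,
    )


def solve_flow(
    mesh: StructuredMesh,
    bc: BoundaryConditions,
    rho,
    mu,
    settings: SolverSettings = SolverSettings(),
    init: FlowField | None = None,
) -> FlowField:
    """Converge the steady laminar velocity/pressure field.

    ``rho``/``mu`` may be scalars (constant properties) or (n_s, n_t) cell
    arrays (Y-coupled mixture properties).  Two pressure-velocity coupling
    algorithms are provided: a monolithic ``coupled`` solve (default; each
    outer iteration solves velocity and pressure together with Rhie-Chow
    stabilized continuity, so only the convection/momentum-interpolation lag
    iterates) and segregated ``simple``.  Deterministic: fields are
    parabola-initialized (or warm-started from ``init``), no randomness.
    """
    if settings.algorithm == "coupled":
        return _solve_flow_coupled(mesh, bc, rho, mu, settings, init)
    return _solve_flow_simple(mesh, bc, rho, mu, settings, init)


def _solve_flow_simple(
    mesh: StructuredMesh,
    bc: BoundaryConditions,
    rho,
    mu,
    settings: SolverSettings,
    init: FlowField | None = None,
) -> FlowField:
    geom = _FVGeom(mesh)
    n_s, n_t = mesh.shape
    rho_c = np.broadcast_to(np.asarray(rho, dtype=float), (n_s, n_t)).copy()
    mu_c = np.broadcast_to(np.asarray(mu, dtype=float), (n_s, n_t)).copy()
    rho_fs, rho_ft = _face_props(rho_c)
    mu_fs, mu_ft = _face_props(mu_c)

    # inlet boundary values
    u_in_x = bc.v_inlet * geom.Ts[0, 0]  # inlet face velocity components (n_t,)
    u_in_y = bc.v_inlet * geom.Ts[0, 1]
    m_in = rho_fs[0] * geom.sfA * bc.v_inlet  # fixed inlet mass flux (n_t,)
    mdot_in = float(m_in.sum())
    v_ref = bc.v_mean

    u, v, p, m_s, m_t = _init_fields(mesh, bc, rho_fs, geom, init, m_in)

    alpha_u = settings.relax_u
    alpha_p = settings.relax_p
    convection = settings.momentum == "navier_stokes"
    second_order = settings.scheme == "second_order_upwind"

    history: list[tuple[float, float, float]] = []
    converged = False
    aPu_rel = None

    for it in range(settings.max_outer):
        aP, aW, aE, aS, aN, bc_in = _assemble(
            geom, m_s, m_t, mu_fs, mu_ft, convection, wall_dirichlet=True
        )

        gpx, gpy = _green_gauss(geom, p, inlet=None, wall=None, outlet=0.0)
        bu = -gpx * geom.V
        bv = -gpy * geom.V
        bu[0] += bc_in * u_in_x
        bv[0] += bc_in * u_in_y

        if second_order and convection:
            gux, guy = _green_gauss(geom, u, inlet=u_in_x, wall=0.0, outlet=None)
            gvx, gvy = _green_gauss(geom, v, inlet=u_in_y, wall=0.0, outlet=None)
            bu += _sou_correction(geom, u, m_s, m_t, gux, guy)
            bv += _sou_correction(geom, v, m_s, m_t, gvx, gvy)

        # unrelaxed scaled residuals (before the solve)
        ru = bu - _apply_stencil(aP, aW, aE, aS, aN, u)
        rv = bv - _apply_stencil(aP, aW, aE, aS, aN, v)
        res_u = float(np.abs(ru).sum()) / (mdot_in * v_ref)
        res_v = float(np.abs(rv).sum()) / (mdot_in * v_ref)
        imb = (m_s[:-1] - m_s[1:]) + (m_t[:, :-1] - m_t[:, 1:])
        res_m = float(np.abs(imb).sum()) / mdot_in

        history.append((res_u, res_v, res_m))
        if not np.isfinite(res_u + res_v + res_m):
            raise SolverError("flow solve diverged (non-finite residual)", history)
        if it >= 2 and max(res_u, res_v, res_m) < settings.tol:
            converged = True
            break

        # implicit under-relaxation
        aPu_rel = aP / alpha_u
        bu += (1.0 - alpha_u) * aPu_rel * u
        bv += (1.0 - alpha_u) * aPu_rel * v
        u, v = _solve_penta(aPu_rel, aW, aE, aS, aN, [bu, bv])

        # Rhie-Chow face velocities -> provisional mass fluxes
        # (gpx/gpy still hold the gradient of the current p)
        dV = geom.V / aPu_rel

        # interior station faces
        Tsx = geom.Ts[1:-1, 0][:, None]
        Tsy = geom.Ts[1:-1, 1][:, None]
        ubar = _face_mean_s(u) * Tsx + _face_mean_s(v) * Tsy
        dcoef = _face_mean_s(dV)
        gbar = _face_mean_s(gpx) * Tsx + _face_mean_s(gpy) * Tsy
        vn = ubar - dcoef * ((p[1:] - p[:-1]) / geom.dist_s[1:-1] - gbar)
        m_s[1:-1] = rho_fs[1:-1] * geom.sfA * vn

        # interior transverse faces
        Ncx = geom.Nc[:, 0][:, None]
        Ncy = geom.Nc[:, 1][:, None]
        vbar = _face_mean_t(u) * Ncx + _face_mean_t(v) * Ncy
        dcoef_t = _face_mean_t(dV)
        gbar_t = _face_mean_t(gpx) * Ncx + _face_mean_t(gpy) * Ncy
        vn_t = vbar - dcoef_t * ((p[:, 1:] - p[:, :-1]) / geom.dist_t[:, 1:-1] - gbar_t)
        m_t[:, 1:-1] = rho_ft[:, 1:-1] * geom.tfA[:, 1:-1] * vn_t

        # boundaries: inlet fixed, walls zero, outlet extrapolated + scaled
        m_s[0] = m_in
        m_t[:, 0] = 0.0
        m_t[:, -1] = 0.0
        un_out = u[-1] * geom.Ts[-1, 0] + v[-1] * geom.Ts[-1, 1]
        m_out = rho_fs[-1] * geom.sfA * un_out
        tot_out = float(m_out.sum())
        if tot_out > 0.1 * mdot_in:
            m_out *= mdot_in / tot_out
        else:  # startup guard: distribute the inflow uniformly
            m_out = np.full(n_t, mdot_in / n_t)
        m_s[-1] = m_out

        # pressure correction (SIMPLE)
        cs = np.zeros((n_s + 1, n_t))
        cs[1:-1] = rho_fs[1:-1] * geom.sfA * _face_mean_s(dV) / geom.dist_s[1:-1]
        c_out = rho_fs[-1] * geom.sfA * dV[-1] / geom.dist_s[-1]
        ct = np.zeros((n_s, n_t + 1))
        ct[:, 1:-1] = rho_ft[:, 1:-1] * geom.tfA[:, 1:-1] * _face_mean_t(dV) / geom.dist_t[:, 1:-1]

        apP = cs[:-1] + cs[1:] + ct[:, :-1] + ct[:, 1:]
        apP[-1] += c_out
        rhs_p = (m_s[:-1] - m_s[1:]) + (m_t[:, :-1] - m_t[:, 1:])
        (pc,) = _solve_penta(apP, cs[:-1], cs[1:], ct[:, :-1], ct[:, 1:], [rhs_p])

        # corrections
        m_s[1:-1] -= cs[1:-1] * (pc[1:] - pc[:-1])
        m_t[:, 1:-1] -= ct[:, 1:-1] * (pc[:, 1:] - pc[:, :-1])
        m_s[-1] += c_out * pc[-1]
        gcx, gcy = _green_gauss(geom, pc, inlet=None, wall=None, outlet=0.0)
        u -= dV * gcx
        v -= dV * gcy
        p += alpha_p * pc

    else:
        raise ConvergenceError(
            f"flow solve did not reach tol={settings.tol} in {settings.max_outer} "
            f"iterations (last residuals {history[-1]})",
            history,
        )

    return _finalize(mesh, bc, rho_c, mu_c, u, v, p, m_s, m_t, history, converged, mdot_in)


def _solve_flow_coupled(
    mesh: StructuredMesh,
    bc: BoundaryConditions,
    rho,
    mu,
    settings: SolverSettings,
    init: FlowField | None = None,
) -> FlowField:
    """Monolithic velocity-pressure solve.

    Each outer iteration assembles the linearized momentum equations
    (first-order upwind convection at lagged mass fluxes, deferred
    second-order correction in the RHS, Green-Gauss pressure gradient
    implicit in p) together with the continuity equations written on
    momentum-interpolated face velocities (Rhie-Chow: the face pressure-
    difference term is implicit, the mean-gradient counterpart lagged),
    and solves the resulting banded block system directly.  Only the
    convection/interpolation lag iterates, so convergence takes an order of
    ten iterations instead of the hundreds a segregated scheme needs on this
    long domain.  Bandwidth is 3*n_t + 2 in the streamwise-major interleaved
    (u, v, p) ordering.
    """
    from scipy.linalg import lapack

    geom = _FVGeom(mesh)
    n_s, n_t = mesh.shape
    rho_c = np.broadcast_to(np.asarray(rho, dtype=float), (n_s, n_t)).copy()
    mu_c = np.broadcast_to(np.asarray(mu, dtype=float), (n_s, n_t)).copy()
    rho_fs, rho_ft = _face_props(rho_c)
    mu_fs, mu_ft = _face_props(mu_c)

    u_in_x = bc.v_inlet * geom.Ts[0, 0]
    u_in_y = bc.v_inlet * geom.Ts[0, 1]
    m_in = rho_fs[0] * geom.sfA * bc.v_inlet
    mdot_in = float(m_in.sum())
    v_ref = bc.v_mean

    u, v, p, m_s, m_t = _init_fields(mesh, bc, rho_fs, geom, init, m_in)

    convection = settings.momentum == "navier_stokes"
    second_order = settings.scheme == "second_order_upwind"

    ncell = n_s * n_t
    n3 = 3 * ncell
    kl = ku = 3 * n_t + 2
    ldab = 2 * kl + ku + 1
    abT = np.zeros((n3, ldab))  # .T is the F-ordered LAPACK band array
    rhs3 = np.empty(n3)

    def put(ca: int, cb: int, d: int, coef: np.ndarray) -> None:
        """Coefficient of unknown (cell k+d, comp cb) in row (cell k, comp ca)."""
        row = kl + ku - 3 * d + ca - cb
        cf = coef.ravel()
        if d >= 0:
            abT[3 * d + cb :: 3, row][: ncell - d] = cf[: ncell - d]
        else:
            abT[cb::3, row][: ncell + d] = cf[-d:]

    # geometry shorthands
    Tsx_f = geom.Ts[:, 0][:, None]  # (n_s+1, 1)
    Tsy_f = geom.Ts[:, 1][:, None]
    Ncx = geom.Nc[:, 0][:, None]  # (n_s, 1)
    Ncy = geom.Nc[:, 1][:, None]
    A_s = geom.sfA  # scalar station-face length
    A_t = geom.tfA  # (n_s, n_t+1)

    history: list[tuple[float, float, float]] = []
    converged = False

    for it in range(settings.max_outer):
        aP, aW, aE, aS, aN, bc_in = _assemble(
            geom, m_s, m_t, mu_fs, mu_ft, convection, wall_dirichlet=True
        )
        gpx, gpy = _green_gauss(geom, p, inlet=None, wall=None, outlet=0.0)

        bu = np.zeros((n_s, n_t))
        bv = np.zeros((n_s, n_t))
        bu[0] += bc_in * u_in_x
        bv[0] += bc_in * u_in_y
        if second_order and convection:
            gux, guy = _green_gauss(geom, u, inlet=u_in_x, wall=0.0, outlet=None)
            gvx, gvy = _green_gauss(geom, v, inlet=u_in_y, wall=0.0, outlet=None)
            bu += _sou_correction(geom, u, m_s, m_t, gux, guy)
            bv += _sou_correction(geom, v, m_s, m_t, gvx, gvy)

        # residuals of the current iterate (momentum includes the pressure term)
        ru = bu - gpx * geom.V - _apply_stencil(aP, aW, aE, aS, aN, u)
        rv = bv - gpy * geom.V - _apply_stencil(aP, aW, aE, aS, aN, v)
        res_u = float(np.abs(ru).sum()) / (mdot_in * v_ref)
        res_v = float(np.abs(rv).sum()) / (mdot_in * v_ref)
        imb = (m_s[:-1] - m_s[1:]) + (m_t[:, :-1] - m_t[:, 1:])
        res_m = float(np.abs(imb).sum()) / mdot_in
        history.append((res_u, res_v, res_m))
        if not np.isfinite(res_u + res_v + res_m):
            raise SolverError("flow solve diverged (non-finite residual)", history)
        if it >= 1 and max(res_u, res_v, res_m) < settings.tol:
            converged = True
            break

        abT.fill(0.0)

        # ---- momentum rows (comp 0 = u, comp 1 = v) ----
        for comp, b_m in ((0, bu), (1, bv)):
            put(comp, comp, 0, aP)
            put(comp, comp, -n_t, -aW)
            put(comp, comp, n_t, -aE)
            put(comp, comp, -1, -aS)
            put(comp, comp, 1, -aN)
            # pressure: + sum_f p_f A_f n_f (x or y component)
            nx_st = Tsx_f if comp == 0 else Tsy_f  # (n_s+1,1)
            nx_tc = Ncx if comp == 0 else Ncy  # (n_s,1)
            cP = np.zeros((n_s, n_t))
            # east faces: interior 0.5(pP+pE), outlet p=0 (no coefficient)
            ce = np.zeros((n_s, n_t))
            ce[:-1] = 0.5 * A_s * nx_st[1:-1]
            cP[:-1] += 0.5 * A_s * nx_st[1:-1]
            # west faces: interior 0.5(pW+pP), inlet p_f = pP
            cw = np.zeros((n_s, n_t))
            cw[1:] = -0.5 * A_s * nx_st[1:-1]
            cP[1:] += -0.5 * A_s * nx_st[1:-1]
            cP[0] += -A_s * nx_st[0]
            # north/south faces: interior mean, walls p_f = pP
            cn = np.zeros((n_s, n_t))
            cn[:, :-1] = 0.5 * A_t[:, 1:-1] * nx_tc
            cP[:, :-1] += 0.5 * A_t[:, 1:-1] * nx_tc
            cP[:, -1] += A_t[:, -1] * nx_tc[:, 0]
            cs_ = np.zeros((n_s, n_t))
            cs_[:, 1:] = -0.5 * A_t[:, 1:-1] * nx_tc
            cP[:, 1:] += -0.5 * A_t[:, 1:-1] * nx_tc
            cP[:, 0] += -A_t[:, 0] * nx_tc[:, 0]
            put(comp, 2, 0, cP)
            put(comp, 2, n_t, ce)
            put(comp, 2, -n_t, cw)
            put(comp, 2, 1, cn)
            put(comp, 2, -1, cs_)
            rhs3[comp::3] = b_m.ravel()

        # ---- continuity rows (comp 2) ----
        dV = geom.V / aP  # Rhie-Chow dissipation scale (unrelaxed diagonal)
        d_s = np.zeros((n_s + 1, n_t))
        d_s[1:-1] = _face_mean_s(dV)
        d_s[-1] = dV[-1]
        d_t = np.zeros((n_s, n_t + 1))
        d_t[:, 1:-1] = _face_mean_t(dV)
        # face pressure-Laplacian coefficients
        cps = np.zeros((n_s + 1, n_t))
        cps[1:-1] = rho_fs[1:-1] * A_s * d_s[1:-1] / geom.dist_s[1:-1]
        cps[-1] = rho_fs[-1] * A_s * d_s[-1] / geom.dist_s[-1]
        cpt = np.zeros((n_s, n_t + 1))
        cpt[:, 1:-1] = rho_ft[:, 1:-1] * A_t[:, 1:-1] * d_t[:, 1:-1] / geom.dist_t[:, 1:-1]
        # lagged mean-gradient terms
        gbs = np.zeros((n_s + 1, n_t))
        gbs[1:-1] = _face_mean_s(gpx) * Tsx_f[1:-1] + _face_mean_s(gpy) * Tsy_f[1:-1]
        gbs[-1] = gpx[-1] * Tsx_f[-1] + gpy[-1] * Tsy_f[-1]
        gbt = np.zeros((n_s, n_t + 1))
        gbt[:, 1:-1] = _face_mean_t(gpx) * Ncx + _face_mean_t(gpy) * Ncy

        # velocity coefficients: out-flux sum over faces
        half_e = np.zeros((n_s, n_t))
        half_e[:-1] = 0.5 * rho_fs[1:-1] * A_s
        half_w = np.zeros((n_s, n_t))
        half_w[1:] = 0.5 * rho_fs[1:-1] * A_s
        half_n = np.zeros((n_s, n_t))
        half_n[:, :-1] = 0.5 * rho_ft[:, 1:-1] * A_t[:, 1:-1]
        half_s = np.zeros((n_s, n_t))
        half_s[:, 1:] = 0.5 * rho_ft[:, 1:-1] * A_t[:, 1:-1]
        out_e = np.zeros((n_s, n_t))  # full outlet-face coefficient on P
        out_e[-1] = rho_fs[-1] * A_s

        for comp, nst, ntc in ((0, Tsx_f, Ncx), (1, Tsy_f, Ncy)):
            cP = (
                half_e * nst[1:]
                - half_w * nst[:-1]
                + half_n * ntc
                - half_s * ntc
                + out_e * nst[-1:]
            )
            put(2, comp, 0, cP)
            ce = np.zeros((n_s, n_t))
            ce[:-1] = half_e[:-1] * nst[1:-1]
            put(2, comp, n_t, ce)
            cw = np.zeros((n_s, n_t))
            cw[1:] = -half_w[1:] * nst[1:-1]
            put(2, comp, -n_t, cw)
            cn = np.zeros((n_s, n_t))
            cn[:, :-1] = half_n[:, :-1] * ntc
            put(2, comp, 1, cn)
            cs_ = np.zeros((n_s, n_t))
            cs_[:, 1:] = -half_s[:, 1:] * ntc
            put(2, comp, -1, cs_)

        # pressure (Rhie-Chow Laplacian); outlet face has p_b = 0, and the
        # out-of-range neighbour entries at the outlet row are dropped by put
        pP = cps[:-1] + cps[1:] + cpt[:, :-1] + cpt[:, 1:]
        put(2, 2, 0, pP)
        put(2, 2, n_t, -cps[1:])
        put(2, 2, -n_t, -cps[:-1])
        put(2, 2, 1, -cpt[:, 1:])
        put(2, 2, -1, -cpt[:, :-1])

        b_c = np.zeros((n_s, n_t))
        b_c[0] += m_in  # fixed inflow
        # lagged mean-gradient contributions (out-flux sign convention)
        lag_e = rho_fs[1:] * A_s * d_s[1:] * gbs[1:]
        lag_w = rho_fs[:-1] * A_s * d_s[:-1] * gbs[:-1]
        lag_n = rho_ft[:, 1:] * A_t[:, 1:] * d_t[:, 1:] * gbt[:, 1:]
        lag_s = rho_ft[:, :-1] * A_t[:, :-1] * d_t[:, :-1] * gbt[:, :-1]
        b_c -= lag_e - lag_w + lag_n - lag_s
        rhs3[2::3] = b_c.ravel()

        lub, piv, x, info = lapack.dgbsv(kl, ku, abT.T, rhs3, overwrite_ab=1, overwrite_b=1)
        if info != 0:
            raise SolverError(f"coupled banded solve failed (info={info})", history)
        u = x[0::3].reshape(n_s, n_t).copy()
        v = x[1::3].reshape(n_s, n_t).copy()
        p = x[2::3].reshape(n_s, n_t).copy()

        # momentum-interpolated face fluxes from the new state
        gpx, gpy = _green_gauss(geom, p, inlet=None, wall=None, outlet=0.0)
        ubar = _face_mean_s(u) * Tsx_f[1:-1] + _face_mean_s(v) * Tsy_f[1:-1]
        gb = _face_mean_s(gpx) * Tsx_f[1:-1] + _face_mean_s(gpy) * Tsy_f[1:-1]
        m_s[1:-1] = rho_fs[1:-1] * A_s * (
            ubar - d_s[1:-1] * ((p[1:] - p[:-1]) / geom.dist_s[1:-1] - gb)
        )
        vbar = _face_mean_t(u) * Ncx + _face_mean_t(v) * Ncy
        gb_t = _face_mean_t(gpx) * Ncx + _face_mean_t(gpy) * Ncy
        m_t[:, 1:-1] = rho_ft[:, 1:-1] * A_t[:, 1:-1] * (
            vbar - d_t[:, 1:-1] * ((p[:, 1:] - p[:, :-1]) / geom.dist_t[:, 1:-1] - gb_t)
        )
        m_s[0] = m_in
        m_t[:, 0] = 0.0
        m_t[:, -1] = 0.0
        un_out = u[-1] * geom.Ts[-1, 0] + v[-1] * geom.Ts[-1, 1]
        gb_out = gpx[-1] * geom.Ts[-1, 0] + gpy[-1] * geom.Ts[-1, 1]
        m_s[-1] = rho_fs[-1] * A_s * (
            un_out - d_s[-1] * ((0.0 - p[-1]) / geom.dist_s[-1] - gb_out)
        )
    else:
        raise ConvergenceError(
            f"flow solve did not reach tol={settings.tol} in {settings.max_outer} "
            f"iterations (last residuals {history[-1]})",
            history,
        )

    # exact global balance for the downstream species solve
    tot_out = float(m_s[-1].sum())
    if tot_out > 0:
        m_s[-1] *= mdot_in / tot_out
    return _finalize(mesh, bc, rho_c, mu_c, u, v, p, m_s, m_t, history, converged, mdot_in)


# ---------------------------------------------------------------------------
# Species solve
# ---------------------------------------------------------------------------


def solve_species(
    mesh: StructuredMesh,
    flow: FlowField,
    D: float,
    bc: BoundaryConditions,
    settings: SolverSettings = SolverSettings(),
    rho=None,
) -> SpeciesField:
    """Converge the solvent mass-fraction field on a frozen flow field.

    Conservative convection-diffusion with the flow's face mass fluxes;
    walls are impermeable, the outlet is purely convective, the inlet is the
    split co-flow Dirichlet profile.  The implicit matrix is first-order
    upwind; the second-order-upwind correction is applied deferred and
    iterated to ``species_tol``.  Y is clipped to [0, 1] afterwards (the
    excursion is recorded; deferred corrections can overshoot marginally).
    """
    if D <= 0:
        raise ValidationError("diffusion coefficient must be positive")
    geom = _FVGeom(mesh)
    n_s, n_t = mesh.shape
    rho_c = np.broadcast_to(
        np.asarray(rho if rho is not None else 1000.0, dtype=float), (n_s, n_t)
    )
    rho_fs = np.empty((n_s + 1, n_t))
    rho_fs[1:-1] = _face_mean_s(rho_c)
    rho_fs[0], rho_fs[-1] = rho_c[0], rho_c[-1]
    rho_ft = np.empty((n_s, n_t + 1))
    rho_ft[:, 1:-1] = _face_mean_t(rho_c)
    rho_ft[:, 0], rho_ft[:, -1] = rho_c[:, 0], rho_c[:, -1]

    aP, aW, aE, aS, aN, bc_in = _assemble(
        geom, flow.m_s, flow.m_t, rho_fs * D, rho_ft * D, True, wall_dirichlet=False
    )
    b0 = np.zeros((n_s, n_t))
    b0[0] = bc_in * bc.y_inlet

    (Y,) = _solve_penta(aP, aW, aE, aS, aN, [b0])
    n_iter = 1
    if settings.scheme == "second_order_upwind":
        beta = 0.7  # under-relaxation of the deferred correction (limiter cycles)
        for k in range(settings.species_max_iter):
            b = b0 + _muscl_correction(Y, flow.m_s, flow.m_t, bc.y_inlet)
            (Y_new,) = _solve_penta(aP, aW, aE, aS, aN, [b])
            delta = float(np.abs(Y_new - Y).max())
            Y = Y + beta * (Y_new - Y)
            n_iter += 1
            if not np.isfinite(delta):
                raise SolverError("species solve diverged")
            if delta < settings.species_tol:
                break

    excursion = float(max(0.0 - Y.min(), Y.max() - 1.0, 0.0))
    if excursion > 5e-2:
        logger.warning("species boundedness excursion %.3g before clipping", excursion)
    Y = np.clip(Y, 0.0, 1.0)

    # flow-weighted outlet mean vs inlet mixture ratio
    mdot_in = float(flow.m_s[0].sum())
    y_in_mean = float((flow.m_s[0] * bc.y_inlet).sum() / mdot_in)
    y_out_mean = float((flow.m_s[-1] * Y[-1]).sum() / flow.m_s[-1].sum())
    cons = abs(y_out_mean - y_in_mean)
    return SpeciesField(
        Y=Y, conservation_error=cons, clip_excursion=excursion, n_iterations=n_iter
    )


# ---------------------------------------------------------------------------
# Coupled solve
# ---------------------------------------------------------------------------


def solve_coupled(
    mesh: StructuredMesh,
    bc: BoundaryConditions,
    mixture: MixtureModel = MixtureModel(),
    settings: SolverSettings = SolverSettings(),
) -> tuple[FlowField, SpeciesField]:
    """Flow + species with optional Y-dependent mixture properties.

    ``constant`` coupling evaluates rho/mu at the blended state
    Y = solvent_fraction and solves flow then species once (one-way).
    ``coupled`` alternates flow and species (Picard) with cell-wise rho(Y),
    mu(Y) until the Y field settles to ``picard_tol`` (max-norm) or
    ``picard_max`` rounds.
    """
    if settings.property_coupling == "constant":
        rho0 = float(mixture.rho(bc.solvent_fraction))
        mu0 = float(mixture.mu(bc.solvent_fraction))
        flow = solve_flow(mesh, bc, rho0, mu0, settings)
        species = solve_species(mesh, flow, mixture.D, bc, settings, rho=rho0)
        return flow, species

    n_s, n_t = mesh.shape
    Y = np.full((n_s, n_t), bc.solvent_fraction)
    flow = None
    species = None
    # inexact Picard: intermediate rounds converge the flow and species to
    # relaxed tolerances (the property field they feed is itself
    # provisional); the final round below polishes at the full settings.
    loose = replace(
        settings,
        tol=min(max(100.0 * settings.tol, settings.tol), 1e-4),
        species_max_iter=min(settings.species_max_iter, 20),
    )
    for k in range(settings.picard_max):
        rho_c = mixture.rho(Y)
        mu_c = mixture.mu(Y)
        flow = solve_flow(mesh, bc, rho_c, mu_c, loose, init=flow)
        species = solve_species(mesh, flow, mixture.D, bc, loose, rho=rho_c)
        delta = float(np.abs(species.Y - Y).mean())
        Y = species.Y
        logger.info("picard round %d: mean |dY| = %.3g", k + 1, delta)
        if delta < settings.picard_tol:
            break
    rho_c = mixture.rho(Y)
    mu_c = mixture.mu(Y)
    flow = solve_flow(mesh, bc, rho_c, mu_c, settings, init=flow)
    species = solve_species(mesh, flow, mixture.D, bc, settings, rho=rho_c)
    assert flow is not None and species is not None
    return flow, species
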