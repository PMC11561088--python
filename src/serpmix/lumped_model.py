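"""0D lumped-parameter hydraulic network of the serpentine chip.

Each channel portion is a hydraulic resistance in series: straight runs follow
the Hagen-Poiseuille drop 32*mu*L*v/Dh^2, bends add a concentrated loss
K*rho*v^2/2 with K approximated from the low-Reynolds bend-loss diagram of
Ghia et al. as K = 32*R*(0.026*Dn*e^0.661 + 1)*theta / (Dh*Re).  Compliance
and inertance are neglected (glass chip, creeping velocities), as is the
concentrated loss of the Y-junction itself.  The model answers one practical
question: what total flow rate drives the inlet-to-outlet drop to the
cartridge burst pressure (800 mbar)?

The bend-loss correlation admits a second reading of the printed exponent,
``0.026*Dn**0.661 + 1`` (a power law on the log-log diagram); both variants
are exposed through ``k_variant``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .chip_geometry import ChipSpec, ValidationError

MBAR = 100.0  # Pa per mbar
ML_PER_MIN = 1e-6 / 60.0  # m^3/s per ml/min

KVariant = Literal["literal", "power"]


class SingularRegimeError(ValueError):
    """Correlation not defined (e.g. creeping-flow limit Re = 0)."""


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Density (kg/m^3), dynamic viscosity (Pa s), and diffusion coefficient
    of the species into the anti-solvent (m^2/s, None if not applicable)."""

    rho: float
    mu: float
    D: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValidationError("rho and mu must be strictly positive")
        if self.D is not None and self.D <= 0:
            raise ValidationError("D must be strictly positive when given")


#: Reference solutions (rheometer-characterized at 298 K)
TRIS = FluidProperties(rho=1000.0, mu=1.0e-3, D=None, name="TRIS")
WATER = FluidProperties(rho=1000.0, mu=1.0e-3, D=None, name="water")
ACN = FluidProperties(rho=790.0, mu=4.0e-4, D=3.5e-9, name="ACN")
ACN_PLGA = FluidProperties(rho=797.0, mu=5.0e-4, D=3.5e-9, name="ACN-PLGA")

FLUIDS = {f.name: f for f in (TRIS, WATER, ACN, ACN_PLGA)}


@dataclass(frozen=True)
class OperatingPoint:
    """Total flow rate (ml/min) and flow-rate ratio solvent:anti-solvent (a, b)."""

    tfr_ml_min: float
    frr: tuple[float, float] = (1, 1)

    def __post_init__(self) -> None:
        # TFR = 0 is admitted as the no-flow limit (zero drop); negative is not.
        if self.tfr_ml_min < 0:
            raise ValidationError("TFR must be non-negative")
        a, b = self.frr
        if a <= 0 or b <= 0:
            raise ValidationError("FRR parts must be positive")

    @property
    def q_total(self) -> float:
        """Total volumetric flow (m^3/s)."""
        return self.tfr_ml_min * ML_PER_MIN

    @property
    def solvent_fraction(self) -> float:
        """Q_solvent / Q_total = a/(a+b) for FRR a:b."""
        a, b = self.frr
        return a / (a + b)

    @property
    def q_solvent(self) -> float:
        return self.q_total * self.solvent_fraction

    @property
    def q_antisolvent(self) -> float:
        return self.q_total * (1.0 - self.solvent_fraction)

    @property
    def frr_label(self) -> str:
        a, b = self.frr
        fmt = lambda x: str(int(x)) if float(x).is_integer() else f"{x:g}"  # noqa: E731
        return f"{fmt(a)}:{fmt(b)}"

    @property
    def dilution_ratio(self) -> float:
        """Anti-solvent:solvent numeric ratio n for FRR 1:n (b/a in general)."""
        a, b = self.frr
        return b / a


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------


def straight_drop(L: float, v: float, mu: float, Dh: float) -> float:
    """Hagen-Poiseuille pressure drop 32*mu*L*v/Dh^2 (Pa); SI inputs."""
    if Dh <= 0:
        raise ValidationError("hydraulic diameter must be positive")
    if L < 0 or v < 0 or mu < 0:
        raise ValidationError("L, v, mu must be non-negative")
    return 32.0 * mu * L * v / Dh**2


def reynolds(rho: float, v: float, Dh: float, mu: float) -> float:
    """Re = rho*v*Dh/mu."""
    if rho <= 0 or Dh <= 0 or mu <= 0 or v < 0:
        raise ValidationError("invalid Reynolds inputs")
    return rho * v * Dh / mu


def dean(Re: float, Dh: float, R: float) -> float:
    """Dean number Dn = Re*sqrt(Dh/(2R)) of a bend of centerline radius R."""
    if Re < 0 or Dh <= 0 or R <= 0:
        raise ValidationError("invalid Dean inputs")
    return Re * math.sqrt(Dh / (2.0 * R))


def bend_loss_coeff(
    Re: float,
    Dn: float,
    R: float,
    theta: float,
    Dh: float,
    variant: KVariant = "literal",
) -> float:
    """Bend loss coefficient K such that the bend drop is K*rho*v^2/2.

    K = 32*R*(0.026*Dn*e^0.661 + 1)*theta / (Dh*Re) in the default "literal"
    reading of the printed correlation; the "power" variant replaces the
    factor with 0.026*Dn**0.661 + 1.  Linear in theta; K -> 32*R*theta/(Dh*Re)
    as Dn -> 0.
    """
    if Re <= 0:
        raise SingularRegimeError("bend-loss correlation undefined at Re = 0")
    if Dn < 0 or R <= 0 or theta < 0 or Dh <= 0:
        raise ValidationError("invalid bend-loss inputs")
    if variant == "literal":
        f = 0.026 * Dn * math.exp(0.661) + 1.0
    elif variant == "power":
        f = 0.026 * Dn**0.661 + 1.0
    else:
        raise ValidationError(f"unknown K variant {variant!r}")
    return 32.0 * R * f * theta / (Dh * Re)


def bend_drop(K: float, rho: float, v: float) -> float:
    """Concentrated bend loss K*rho*v^2/2 (Pa)."""
    if K < 0 or rho < 0:
        raise ValidationError("K and rho must be non-negative")
    return 0.5 * K * rho * v**2


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class HydraulicState:
    """Per-segment drops and the network total for one operating point."""

    segments: pd.DataFrame  # kind, L/R/theta, v, Re, Dn, K, dp
    inlet_drops: tuple[float, float]  # (solvent arm, anti-solvent arm), Pa
    governing_inlet_drop: float  # Pa
    main_drop: float  # Pa
    total_drop: float  # Pa
    operating_point: OperatingPoint
    fluid: FluidProperties

    @property
    def total_drop_mbar(self) -> float:
        return self.total_drop / MBAR

    def to_csv(self, path) -> None:
        self.segments.to_csv(path, index=False)


def network_drop(
    spec: ChipSpec,
    fluid: FluidProperties = WATER,
    op: OperatingPoint | None = None,
    k_variant: KVariant = "literal",
    return_state: bool = False,
) -> float | HydraulicState:
    """Inlet-to-outlet pressure drop (Pa) of the lumped network.

    The two inlet arms are parallel branches carrying Q_solvent and
    Q_antisolvent; the branch with the larger drop governs (common outlet
    pressure; the pump limit is set by the worse branch).  The main channel
    (all straights and bends in series) carries the full TFR.  The junction's
    own concentrated loss is excluded.  A single fluid (water by default)
    characterizes the whole network.
    """
    if op is None:
        op = OperatingPoint(tfr_ml_min=0.2)
    segs = spec.segments
    if not segs:
        raise ValidationError("empty network")

    Dh = spec.hydraulic_diameter_m
    A = spec.cross_section_m2
    v_main = op.q_total / A
    if op.q_total == 0.0:  # no-flow limit: every drop vanishes
        if not return_state:
            return 0.0
        return HydraulicState(
            segments=pd.DataFrame([]),
            inlet_drops=(0.0, 0.0),
            governing_inlet_drop=0.0,
            main_drop=0.0,
            total_drop=0.0,
            operating_point=op,
            fluid=fluid,
        )

    rows = []
    # inlet arms (straight, length = physical L1, full cross-section each)
    L_in = spec.L1 * 1e-6
    inlet_drops = []
    for label, q in (("inlet1 (solvent)", op.q_solvent), ("inlet2 (anti-solvent)", op.q_antisolvent)):
        v = q / A
        dp = straight_drop(L_in, v, fluid.mu, Dh)
        inlet_drops.append(dp)
        rows.append(
            dict(kind=label, L_m=L_in, R_m=np.nan, theta_rad=np.nan, v_m_s=v,
                 Re=reynolds(fluid.rho, v, Dh, fluid.mu), Dn=np.nan, K=np.nan, dp_Pa=dp)
        )

    Re = reynolds(fluid.rho, v_main, Dh, fluid.mu)
    main = 0.0
    for seg in segs:
        if seg.kind == "straight":
            L = seg.length * 1e-6  # type: ignore[operator]
            dp = straight_drop(L, v_main, fluid.mu, Dh)
            rows.append(
                dict(kind="straight", L_m=L, R_m=np.nan, theta_rad=np.nan, v_m_s=v_main,
                     Re=Re, Dn=np.nan, K=np.nan, dp_Pa=dp)
            )
        else:
            R = seg.radius * 1e-6  # type: ignore[operator]
            Dn = dean(Re, Dh, R)
            K = bend_loss_coeff(Re, Dn, R, seg.angle, Dh, variant=k_variant)  # type: ignore[arg-type]
            dp = bend_drop(K, fluid.rho, v_main)
            rows.append(
                dict(kind="bend", L_m=np.nan, R_m=R, theta_rad=seg.angle, v_m_s=v_main,
                     Re=Re, Dn=Dn, K=K, dp_Pa=dp)
            )
        main += dp

    governing = max(inlet_drops)
    total = governing + main
    if not return_state:
        return total
    return HydraulicState(
        segments=pd.DataFrame(rows),
        inlet_drops=(inlet_drops[0], inlet_drops[1]),
        governing_inlet_drop=governing,
        main_drop=main,
        total_drop=total,
        operating_point=op,
        fluid=fluid,
    )


def limit_tfr(
    spec: ChipSpec,
    fluid: FluidProperties = WATER,
    burst_pressure_mbar: float = 800.0,
    frr: tuple[float, float] = (1, 1),
    k_variant: KVariant = "literal",
    rtol: float = 1e-9,
) -> float:
    """TFR (ml/min) at which the network drop reaches the burst pressure.

    The drop is strictly monotone in TFR, so the root is unique; a bracket
    [~0, hi] is grown by doubling and resolved with Brent's method.
    """
    if burst_pressure_mbar <= 0:
        raise ValidationError("burst pressure must be positive")
    target = burst_pressure_mbar * MBAR

    def f(tfr: float) -> float:
        return float(network_drop(spec, fluid, OperatingPoint(tfr, frr), k_variant)) - target

    hi = 0.1
    for _ in range(60):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise SolverError("could not bracket the burst pressure (drop not increasing?)")
    lo = hi / 2.0 if f(hi / 2.0) < 0 else 1e-12
    root = brentq(f, lo, hi, rtol=rtol, maxiter=200)
    return float(root)


@dataclass(frozen=True)
class PressurePoint:
    """A pressure drop computed for a given operating point and fluid."""

    op: OperatingPoint
    fluid_name: str
    dp: float  # Pa
    source: str = ""  # "0d" / "cfd"


def compare_0d_cfd(lumped: PressurePoint, solver: PressurePoint) -> float:
    """Signed relative difference (lumped - solver)/solver between the 0D
    network drop and the field-solver drop at the same operating point."""
    if (
        not math.isclose(lumped.op.tfr_ml_min, solver.op.tfr_ml_min, rel_tol=1e-12)
        or lumped.op.frr != solver.op.frr
    ):
        raise ValidationError("operating points do not match")
    if solver.dp == 0:
        if lumped.dp == 0:
            return 0.0
        raise ValidationError("solver drop is zero, relative difference undefined")
    return (lumped.dp - solver.dp) / solver.dp
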