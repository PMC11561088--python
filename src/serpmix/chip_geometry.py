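"""Parametric serpentine-chip geometry, structured meshing, and section location.

The mixing cartridge is a planar channel of constant width ``d`` (200 um in the
reference chip) and depth ``h`` (100 um) laid out as two inlet arms joined at a
Y-junction, followed by a serpentine body of straight runs connected by 90- and
180-degree circular bends.  Because the flow is strongly laminar and the duct
has no depth-wise structure, the fluid dynamics is treated as a 2D problem on
the channel mid-plane; the geometry here is therefore a planform: a centerline
path plus a constant-width band around it.

Units: the public ``ChipSpec`` is expressed in micrometres, matching how chip
drawings are dimensioned; everything derived (paths, meshes) is in metres.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import yaml
from shapely.geometry import LineString, Polygon

logger = logging.getLogger(__name__)

UM = 1e-6  # micrometre, in metres


class ValidationError(ValueError):
    """A chip/mesh specification violates its invariants."""


class GeometryError(ValueError):
    """A specification is dimensionally valid but geometrically degenerate."""


class RefinementError(ValueError):
    """Requested mesh resolution cannot discretize the channel width."""


class ConfigurationError(ValueError):
    """A request is inconsistent with the chip layout (e.g. section count)."""


def hydraulic_diameter(d: float, h: float) -> float:
    """Hydraulic diameter 4A/P = 2dh/(d+h) of a rectangular duct.

    Arguments and result share whatever length unit is passed in (the chip
    tables use micrometres).  Symmetric in ``d`` and ``h``.
    """
    if d <= 0 or h <= 0:
        raise ValidationError(f"duct sides must be positive, got d={d}, h={h}")
    return 2.0 * d * h / (d + h)


# ---------------------------------------------------------------------------
# Segment / chip specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentSpec:
    """One piece of the serpentine body: a straight run or a circular bend.

    ``length`` (straights) and ``radius`` (bends) are in micrometres; ``angle``
    is the bend angle in radians and must be 90 or 180 degrees; ``turn`` is the
    bend direction (+1 = left/counter-clockwise, -1 = right/clockwise).
    """

    kind: Literal["straight", "bend"]
    length: float | None = None
    radius: float | None = None
    angle: float | None = None
    turn: int = 1

    def __post_init__(self) -> None:
        if self.kind == "straight":
            if self.length is None or self.length <= 0:
                raise ValidationError("straight segment needs length > 0")
            if self.radius is not None or self.angle is not None:
                raise ValidationError("straight segment takes no radius/angle")
        elif self.kind == "bend":
            if self.radius is None or self.radius <= 0:
                raise GeometryError("bend needs radius > 0")
            if self.angle is None or not any(
                math.isclose(self.angle, a, rel_tol=1e-9) for a in (math.pi / 2, math.pi)
            ):
                raise ValidationError("bend angle must be 90 or 180 degrees (pi/2 or pi)")
            if self.turn not in (-1, 1):
                raise ValidationError("bend turn must be +1 (left) or -1 (right)")
        else:
            raise ValidationError(f"unknown segment kind {self.kind!r}")

    @property
    def arc_length_um(self) -> float:
        if self.kind == "straight":
            return float(self.length)  # type: ignore[arg-type]
        return float(self.radius) * float(self.angle)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind}
        if self.kind == "straight":
            out["length"] = self.length
        else:
            out.update(radius=self.radius, angle=self.angle, turn=self.turn)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SegmentSpec":
        return cls(**data)


def straight(length_um: float) -> SegmentSpec:
    return SegmentSpec(kind="straight", length=length_um)


def bend(radius_um: float, angle_rad: float, turn: int = 1) -> SegmentSpec:
    return SegmentSpec(kind="bend", radius=radius_um, angle=angle_rad, turn=turn)


def default_segment_sequence(
    L2: float, L3: float, L4: float, R1: float, R2: float, n_straight: int = 15
) -> tuple[SegmentSpec, ...]:
    """Default serpentine layout.

    Straight #1 (length L2, horizontal, carries the unmixed reference
    section), a 90-degree bend of radius R2, straight #2 (L3), then
    ``n_straight - 2`` straights of length L4 joined by 180-degree U-bends of
    radius R1 with alternating handedness.
    """
    if n_straight < 1:
        raise ValidationError("n_straight must be >= 1")
    segs: list[SegmentSpec] = [straight(L2)]
    if n_straight >= 2:
        segs.append(bend(R2, math.pi / 2, turn=+1))
        segs.append(straight(L3))
    turn = -1
    for _ in range(n_straight - 2):
        segs.append(bend(R1, math.pi, turn=turn))
        segs.append(straight(L4))
        turn = -turn
    return tuple(segs)


@dataclass(frozen=True)
class ChipSpec:
    """Geometric description of the serpentine mixing chip (micrometres).

    Defaults are the reference glass chip: L1=1500, L2=2500, L3=5600,
    L4=13000, R1=R2=800, d=200 (channel width w), h=100 (depth).
    """

    L1: float = 1500.0
    L2: float = 2500.0
    L3: float = 5600.0
    L4: float = 13000.0
    R1: float = 800.0
    R2: float = 800.0
    d: float = 200.0
    h: float = 100.0
    n_straight: int = 15
    segment_sequence: tuple[SegmentSpec, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "L3", "L4", "R1", "R2", "d", "h"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.n_straight < 1:
            raise ValidationError("n_straight must be >= 1")

    @property
    def segments(self) -> tuple[SegmentSpec, ...]:
        if self.segment_sequence is not None:
            return self.segment_sequence
        return default_segment_sequence(
            self.L2, self.L3, self.L4, self.R1, self.R2, self.n_straight
        )

    @property
    def width_m(self) -> float:
        return self.d * UM

    @property
    def depth_m(self) -> float:
        return self.h * UM

    @property
    def hydraulic_diameter_m(self) -> float:
        return hydraulic_diameter(self.d, self.h) * UM

    @property
    def cross_section_m2(self) -> float:
        return self.width_m * self.depth_m

    def inlet_length_m(self, dh_multiples: float = 20.0) -> float:
        """In-silico inlet arm length guaranteeing developed flow.

        max(L1, ``dh_multiples`` hydraulic diameters); the physical arm is L1.
        """
        return max(self.L1 * UM, dh_multiples * self.hydraulic_diameter_m)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {
            name: getattr(self, name)
            for name in ("L1", "L2", "L3", "L4", "R1", "R2", "d", "h", "n_straight")
        }
        if self.segment_sequence is not None:
            out["segment_sequence"] = [s.to_dict() for s in self.segment_sequence]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ChipSpec":
        data = dict(data)
        seq = data.pop("segment_sequence", None)
        if seq is not None:
            data["segment_sequence"] = tuple(SegmentSpec.from_dict(s) for s in seq)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ChipSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Centerline path
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinePrimitive:
    p0: np.ndarray  # start point (m)
    direction: np.ndarray  # unit tangent
    length: float  # m

    def point(self, ds: float) -> np.ndarray:
        return self.p0 + ds * self.direction

    def tangent(self, ds: float) -> np.ndarray:
        return self.direction


@dataclass(frozen=True)
class ArcPrimitive:
    center: np.ndarray  # m
    radius: float  # centerline radius (m)
    theta0: float  # angle of start point about center
    dtheta: float  # signed sweep (+ = ccw)

    @property
    def length(self) -> float:
        return self.radius * abs(self.dtheta)

    def point(self, ds: float) -> np.ndarray:
        th = self.theta0 + math.copysign(ds / self.radius, self.dtheta)
        return self.center + self.radius * np.array([math.cos(th), math.sin(th)])

    def tangent(self, ds: float) -> np.ndarray:
        th = self.theta0 + math.copysign(ds / self.radius, self.dtheta)
        sgn = 1.0 if self.dtheta >= 0 else -1.0
        return sgn * np.array([-math.sin(th), math.cos(th)])


@dataclass(frozen=True)
class CenterlinePath:
    """Ordered line/arc primitives from the junction (s=0) to the outlet."""

    primitives: tuple[LinePrimitive | ArcPrimitive, ...]

    @property
    def cumulative_lengths(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([p.length for p in self.primitives])])

    @property
    def total_length(self) -> float:
        return float(sum(p.length for p in self.primitives))

    def _locate(self, s: float) -> tuple[LinePrimitive | ArcPrimitive, float]:
        if not -1e-12 <= s <= self.total_length + 1e-12:
            raise ValidationError(f"arc length {s} outside [0, {self.total_length}]")
        s = min(max(s, 0.0), self.total_length)
        cum = self.cumulative_lengths
        idx = int(np.searchsorted(cum, s, side="right") - 1)
        idx = min(idx, len(self.primitives) - 1)
        return self.primitives[idx], s - cum[idx]

    def point(self, s: float) -> np.ndarray:
        prim, ds = self._locate(s)
        return prim.point(ds)

    def tangent(self, s: float) -> np.ndarray:
        prim, ds = self._locate(s)
        return prim.tangent(ds)

    def normal(self, s: float) -> np.ndarray:
        tx, ty = self.tangent(s)
        return np.array([-ty, tx])  # left normal

    def arc_length_to_outlet(self, s: float) -> float:
        return self.total_length - s

    def polyline(self, max_seg: float = 2e-5) -> np.ndarray:
        """Densified (n,2) polyline for plotting / shapely."""
        pts = []
        for prim in self.primitives:
            n = max(2, int(math.ceil(prim.length / max_seg)) + 1)
            for ds in np.linspace(0.0, prim.length, n, endpoint=False):
                pts.append(prim.point(ds))
        pts.append(self.primitives[-1].point(self.primitives[-1].length))
        return np.asarray(pts)


# ---------------------------------------------------------------------------
# Chip builder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chip:
    """Built chip: spec, main-channel centerline, planar outline, inlet arms."""

    spec: ChipSpec
    path: CenterlinePath
    outline: Polygon  # main channel planform (junction -> outlet)
    inlet_arms: tuple[LineString, LineString]  # centerlines of the two arms

    @property
    def n_body_straights(self) -> int:
        return sum(1 for p in self.path.primitives if isinstance(p, LinePrimitive))

    @property
    def planform_area(self) -> float:
        """Exact main-channel planform area d * S_total (tangent-continuous band)."""
        return self.spec.width_m * self.path.total_length


def build_chip(spec: ChipSpec) -> Chip:
    """Build the centerline path and constant-width planar outline.

    Raises :class:`GeometryError` when a bend radius is below d/2 (the inner
    wall would self-intersect).
    """
    w = spec.width_m
    segs = spec.segments
    if not segs:
        raise ValidationError("empty segment sequence")
    for seg in segs:
        if seg.kind == "bend" and seg.radius * UM < w / 2:  # type: ignore[operator]
            raise GeometryError(
                f"bend radius {seg.radius} um < d/2 = {spec.d / 2} um: inner wall self-intersects"
            )

    prims: list[LinePrimitive | ArcPrimitive] = []
    p = np.zeros(2)
    phi = 0.0  # heading; first straight along +x (horizontal)
    for seg in segs:
        t = np.array([math.cos(phi), math.sin(phi)])
        if seg.kind == "straight":
            L = seg.length * UM  # type: ignore[operator]
            prims.append(LinePrimitive(p0=p.copy(), direction=t, length=L))
            p = p + L * t
        else:
            R = seg.radius * UM  # type: ignore[operator]
            n_left = np.array([-math.sin(phi), math.cos(phi)])
            center = p + seg.turn * R * n_left
            v0 = p - center
            theta0 = math.atan2(v0[1], v0[0])
            dtheta = seg.turn * seg.angle  # type: ignore[operator]
            prims.append(ArcPrimitive(center=center, radius=R, theta0=theta0, dtheta=dtheta))
            phi += dtheta
            th1 = theta0 + dtheta
            p = center + R * np.array([math.cos(th1), math.sin(th1)])

    path = CenterlinePath(primitives=tuple(prims))

    # planar outline via buffered centerline (shapely; arcs densified)
    line = LineString(path.polyline(max_seg=min(w / 4, 2e-5)))
    outline = line.buffer(w / 2, cap_style="flat", join_style="round", quad_segs=32)

    # inlet arms: straight channels of length max(L1, 20 Dh) meeting the
    # junction at +/-45 degrees to the first straight (mirror-symmetric).
    Lin = spec.inlet_length_m()
    arm_dirs = [
        np.array([-math.cos(math.pi / 4), math.sin(math.pi / 4)]),
        np.array([-math.cos(math.pi / 4), -math.sin(math.pi / 4)]),
    ]
    arms = tuple(LineString([Lin * d_, np.zeros(2)]) for d_ in arm_dirs)
    return Chip(spec=spec, path=path, outline=outline, inlet_arms=arms)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Structured mesh
# ---------------------------------------------------------------------------


@dataclass
class StructuredMesh:
    """Body-fitted structured quadrilateral mesh of the main channel.

    Logical shape ``(n_s, n_t)``: streamwise column index j (junction ->
    outlet) by transverse index i (wall at t=-w/2 -> wall at t=+w/2, where t is
    the signed offset along the left normal of the centerline).

    Cells in straight columns are rectangles; cells in bend columns are
    annular sectors.  The grid is orthogonal everywhere, so faces fall into two
    families: *station faces* (normal along the flow, ``n_s + 1`` stations) and
    *transverse faces* (normal across the flow, ``n_t + 1`` rows, the outermost
    two being the walls).  All geometric quantities are in metres (areas m^2,
    per-unit-depth face "areas" are lengths in m).
    """

    cell_size: float  # characteristic size (m)
    width: float  # channel width (m)
    n_s: int
    n_t: int
    dt: float  # transverse spacing (m)
    t_edges: np.ndarray  # (n_t+1,)
    t_centers: np.ndarray  # (n_t,)
    ds_col: np.ndarray  # (n_s,) centerline length of each column
    s_col: np.ndarray  # (n_s,) centerline station of column midpoint
    curv_col: np.ndarray  # (n_s,) signed curvature turn (0 straight, +-1 bend)
    radius_col: np.ndarray  # (n_s,) bend centerline radius (inf for straights)
    tangent_col: np.ndarray  # (n_s, 2) unit tangent at column midpoint
    normal_col: np.ndarray  # (n_s, 2) left normal at column midpoint
    tangent_station: np.ndarray  # (n_s+1, 2) unit tangent at stations
    normal_station: np.ndarray  # (n_s+1, 2)
    point_station: np.ndarray  # (n_s+1, 2) centerline point at stations
    point_col: np.ndarray  # (n_s, 2) centerline point at column midpoints
    centroid: np.ndarray  # (n_s, n_t, 2)
    area: np.ndarray  # (n_s, n_t)
    sface_area: float  # station-face length (= dt, uniform)
    tface_area: np.ndarray  # (n_s, n_t+1) transverse-face lengths
    total_path_length: float

    # -- derived ------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_s, self.n_t)

    @property
    def n_cells(self) -> int:
        return self.n_s * self.n_t

    @property
    def cells_across_width(self) -> int:
        return self.n_t

    def total_area(self) -> float:
        return float(self.area.sum())

    @property
    def s_cell(self) -> np.ndarray:
        """(n_s, n_t) streamwise station of each cell (column midpoint)."""
        return np.broadcast_to(self.s_col[:, None], (self.n_s, self.n_t))

    @property
    def arc_length_to_outlet(self) -> np.ndarray:
        """(n_s, n_t) centerline distance from each cell to the outlet."""
        return self.total_path_length - self.s_cell

    def boundary_tags(self) -> dict[str, list[tuple[str, int, int]]]:
        """Boundary faces, each carrying exactly one tag.

        Station-0 faces split into ``inlet1`` (t < 0 half) and ``inlet2``;
        the last station is ``outlet``; transverse rows 0 and n_t are ``wall``.
        Faces are identified as (family, j, i).
        """
        half = self.n_t // 2
        tags: dict[str, list[tuple[str, int, int]]] = {
            "inlet1": [("s", 0, i) for i in range(half)],
            "inlet2": [("s", 0, i) for i in range(half, self.n_t)],
            "outlet": [("s", self.n_s, i) for i in range(self.n_t)],
            "wall": [("t", j, i) for j in range(self.n_s) for i in (0, self.n_t)],
        }
        return tags

    def vertices(self) -> tuple[np.ndarray, np.ndarray]:
        """(points, quads) for export: corner nodes of every cell.

        Nodes are shared between neighbouring cells: grid of station x
        transverse edge positions.
        """
        # corner at (station j, t edge i): station point + t * station normal
        pts = (
            self.point_station[:, None, :]
            + self.t_edges[None, :, None] * self.normal_station[:, None, :]
        )  # (n_s+1, n_t+1, 2)
        npts_t = self.n_t + 1
        idx = lambda j, i: j * npts_t + i  # noqa: E731
        j = np.repeat(np.arange(self.n_s), self.n_t)
        i = np.tile(np.arange(self.n_t), self.n_s)
        quads = np.stack(
            [idx(j, i), idx(j + 1, i), idx(j + 1, i + 1), idx(j, i + 1)], axis=1
        )
        return pts.reshape(-1, 2), quads


def generate_mesh(chip: Chip, cell_size: float = 10.0) -> StructuredMesh:
    """Discretize the main channel with a structured quadrangular grid.

    ``cell_size`` is the characteristic size in micrometres (10 um default,
    the mesh-sensitivity-validated resolution).  If it does not divide the
    width evenly the nearest divisor is used (logged).
    """
    spec = chip.spec
    w = spec.width_m
    hcell = cell_size * UM
    if hcell >= w:
        raise RefinementError(f"cell size {cell_size} um >= channel width {spec.d} um")
    n_t = max(2, int(round(w / hcell)))
    dt = w / n_t
    if not math.isclose(dt, hcell, rel_tol=1e-9):
        logger.info(
            "cell size %.4g um does not divide width %.4g um; using %.4g um (%d cells)",
            cell_size,
            spec.d,
            dt / UM,
            n_t,
        )

    t_edges = np.linspace(-w / 2, w / 2, n_t + 1)
    t_centers = 0.5 * (t_edges[:-1] + t_edges[1:])

    ds_parts, s_parts, curv_parts, rad_parts = [], [], [], []
    s0 = 0.0
    for prim in chip.path.primitives:
        n_cols = max(1, int(round(prim.length / hcell)))
        ds = prim.length / n_cols
        mids = s0 + (np.arange(n_cols) + 0.5) * ds
        ds_parts.append(np.full(n_cols, ds))
        s_parts.append(mids)
        if isinstance(prim, ArcPrimitive):
            curv_parts.append(np.full(n_cols, 1.0 if prim.dtheta > 0 else -1.0))
            rad_parts.append(np.full(n_cols, prim.radius))
        else:
            curv_parts.append(np.zeros(n_cols))
            rad_parts.append(np.full(n_cols, np.inf))
        s0 += prim.length

    ds_col = np.concatenate(ds_parts)
    s_col = np.concatenate(s_parts)
    curv_col = np.concatenate(curv_parts)
    radius_col = np.concatenate(rad_parts)
    n_s = len(ds_col)

    s_stations = np.concatenate([[0.0], np.cumsum(ds_col)])
    # guard against accumulation drift at the outlet
    s_stations[-1] = chip.path.total_length

    pt_st = np.array([chip.path.point(s) for s in s_stations])
    tg_st = np.array([chip.path.tangent(s) for s in s_stations])
    nm_st = np.stack([-tg_st[:, 1], tg_st[:, 0]], axis=1)
    pt_col = np.array([chip.path.point(s) for s in s_col])
    tg_col = np.array([chip.path.tangent(s) for s in s_col])
    nm_col = np.stack([-tg_col[:, 1], tg_col[:, 0]], axis=1)

    area = np.empty((n_s, n_t))
    tfA = np.empty((n_s, n_t + 1))
    centroid = np.empty((n_s, n_t, 2))

    is_bend = curv_col != 0
    # straights: rectangles
    if np.any(~is_bend):
        js = np.where(~is_bend)[0]
        area[js] = ds_col[js, None] * dt
        tfA[js] = ds_col[js, None]
        centroid[js] = pt_col[js, None, :] + t_centers[None, :, None] * nm_col[js, None, :]
    # bends: annular sectors; radius of edge at offset t is R - turn * t
    if np.any(is_bend):
        jb = np.where(is_bend)[0]
        R = radius_col[jb][:, None]
        sgn = curv_col[jb][:, None]
        dth = (ds_col[jb] / radius_col[jb])[:, None]
        r_edge = R - sgn * t_edges[None, :]  # (nb, n_t+1)
        r_lo = np.minimum(r_edge[:, :-1], r_edge[:, 1:])
        r_hi = np.maximum(r_edge[:, :-1], r_edge[:, 1:])
        area[jb] = 0.5 * dth * (r_hi**2 - r_lo**2)
        tfA[jb] = dth * r_edge
        r_c = (2.0 / 3.0) * (r_hi**3 - r_lo**3) / (r_hi**2 - r_lo**2)
        t_c = sgn * (R - r_c)  # signed transverse offset of the area centroid
        centroid[jb] = pt_col[jb, None, :] + t_c[:, :, None] * nm_col[jb, None, :]

    mesh = StructuredMesh(
        cell_size=dt,
        width=w,
        n_s=n_s,
        n_t=n_t,
        dt=dt,
        t_edges=t_edges,
        t_centers=t_centers,
        ds_col=ds_col,
        s_col=s_col,
        curv_col=curv_col,
        radius_col=radius_col,
        tangent_col=tg_col,
        normal_col=nm_col,
        tangent_station=tg_st,
        normal_station=nm_st,
        point_station=pt_st,
        point_col=pt_col,
        centroid=centroid,
        area=area,
        sface_area=dt,
        tface_area=tfA,
        total_path_length=chip.path.total_length,
    )

    planform = chip.planform_area
    rel = abs(mesh.total_area() - planform) / planform
    if rel > 5e-3:
        logger.warning("mesh area deviates from outline area by %.3g%%", 100 * rel)
    return mesh


# ---------------------------------------------------------------------------
# Measurement sections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionLocator:
    """Transverse sample lines at the midpoint of each straight run.

    ``stations`` are arc-length positions (m, increasing), ``columns`` the
    corresponding streamwise cell-column indices; each section samples the
    ``n_t`` cells across the width.
    """

    stations: np.ndarray  # (n_sections,)
    columns: np.ndarray  # (n_sections,) int
    t_centers: np.ndarray  # (n_t,)

    @property
    def n_sections(self) -> int:
        return len(self.stations)

    @property
    def samples_per_section(self) -> int:
        return len(self.t_centers)


def locate_sections(chip: Chip, mesh: StructuredMesh, n: int = 15) -> SectionLocator:
    """Locate the ``n`` measurement cross-sections (one per straight run)."""
    straights = [
        (cum, prim)
        for cum, prim in zip(chip.path.cumulative_lengths, chip.path.primitives)
        if isinstance(prim, LinePrimitive)
    ]
    if len(straights) < n:
        raise ConfigurationError(
            f"chip has {len(straights)} straight runs, cannot place {n} sections"
        )
    stations = np.array([cum + prim.length / 2 for cum, prim in straights[:n]])
    columns = np.array([int(np.argmin(np.abs(mesh.s_col - s))) for s in stations])
    return SectionLocator(stations=stations, columns=columns, t_centers=mesh.t_centers)


def sections_to_csv(locator: SectionLocator, path) -> None:
    """CSV export: one row per (section, sample)."""
    import pandas as pd

    rows = []
    for k in range(locator.n_sections):
        for i, t in enumerate(locator.t_centers):
            rows.append(
                {
                    "section": k + 1,
                    "station_m": locator.stations[k],
                    "column": int(locator.columns[k]),
                    "sample": i,
                    "transverse_m": t,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
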