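"""Mixing and nanoprecipitation metrics for the serpentine micromixer.

Five quantities characterize a run:

* **Mixing index** MI_j = (1 - sqrt(Var_j / Var_ref)) * 100, the section-wise
  homogeneity of the solvent mass fraction relative to the unmixed state at
  the first straight run (0 = unmixed, 100 = fully mixed).
* **Mixing efficiency** ME = (1 - N_unmixed/N_tot) * 100, the fraction of grid
  cells no longer holding essentially pure solvent (Y > 0.95), i.e. without
  unreacted polymer.
* **Area of precipitation** AoP% = area(0.7 < X_ACN < 0.95) / total area * 100,
  the solvent-concentration window in which the polymer can nucleate.
* **Mixing time** tau_mix = w^2 / (9 D (1 + 1/FRR)^2), the diffusion-limited
  time for transverse homogenization under hydrodynamic focusing (FRR is the
  anti-solvent:solvent numeric ratio n for a 1:n run, so stronger dilution
  focuses the stream and shortens tau_mix).
* **Residence time** tau_res,i = L_i / v_i per AoP cell, with L_i the
  centerline distance from the cell's streamwise station to the outlet and
  v_i the velocity magnitude at its centroid; values below tau_mix are
  discarded (too short for nuclei to form).

Percentiles are computed with the inclusive linear-interpolation estimator
(numpy's default), so interquartile ranges are bit-for-bit reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chip_geometry import SectionLocator, StructuredMesh, ValidationError
from .flow_solver import FlowField, SpeciesField
from .lumped_model import OperatingPoint

logger = logging.getLogger(__name__)

AOP_LOWER = 0.7
AOP_UPPER = 0.95
UNMIXED_THRESHOLD = 0.95


class DegenerateReferenceError(ValueError):
    """The unmixed reference section has zero variance."""


# ---------------------------------------------------------------------------
# Section profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionProfile:
    """Mass-fraction samples across one measurement cross-section."""

    index: int  # 1-based section number
    station: float  # arc length (m)
    t: np.ndarray  # transverse sample coordinates (m)
    x: np.ndarray  # mass-fraction samples

    def __post_init__(self) -> None:
        if len(self.x) < 2:
            raise ValidationError("a section needs at least two samples")
        if np.any(self.x < -1e-9) or np.any(self.x > 1 + 1e-9):
            raise ValidationError("mass-fraction samples must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def mean(self) -> float:
        return float(self.x.mean())

    @property
    def variance(self) -> float:
        """Population variance (1/N convention)."""
        return float(np.mean((self.x - self.x.mean()) ** 2))


def extract_section_profiles(
    mesh: StructuredMesh, locator: SectionLocator, values: np.ndarray
) -> list[SectionProfile]:
    """Sample a cell field (n_s, n_t) across each located section."""
    profiles = []
    for k in range(locator.n_sections):
        j = int(locator.columns[k])
        profiles.append(
            SectionProfile(
                index=k + 1,
                station=float(locator.stations[k]),
                t=locator.t_centers.copy(),
                x=np.asarray(values[j], dtype=float).copy(),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Classical metrics
# ---------------------------------------------------------------------------


def mixing_index(profile: SectionProfile, reference: SectionProfile) -> float:
    """MI (%) of a section against the unmixed reference section.

    The denominator is the variance of the reference-section samples about
    the reference mean; the result is clamped to [0, 100].
    """
    if profile.n != reference.n:
        raise ValidationError("profile and reference must have equal sample counts")
    var_ref = reference.variance
    if var_ref == 0.0:
        raise DegenerateReferenceError("reference section is already uniform")
    mi = (1.0 - np.sqrt(profile.variance / var_ref)) * 100.0
    return float(np.clip(mi, 0.0, 100.0))


def mixing_index_curve(profiles: Sequence[SectionProfile]) -> pd.DataFrame:
    """MI for sections j = 2..n against section 1 (the unmixed reference)."""
    ref = profiles[0]
    rows = [
        {"section": p.index, "MI_pct": mixing_index(p, ref)} for p in profiles[1:]
    ]
    return pd.DataFrame(rows)


def mixing_efficiency(
    y: np.ndarray,
    mesh: StructuredMesh,
    upto_column: int | None = None,
    threshold: float = UNMIXED_THRESHOLD,
) -> float:
    """ME (%) over the region from the junction up to ``upto_column``.

    Cells with Y > threshold still hold essentially pure solvent (unreacted
    polymer).  ``upto_column=None`` uses the whole channel.
    """
    region = y if upto_column is None else y[: upto_column + 1]
    if region.size == 0:
        raise ValidationError("empty region")
    n_unmixed = int((region > threshold).sum())
    return (1.0 - n_unmixed / region.size) * 100.0


def mixing_efficiency_curve(
    y: np.ndarray,
    mesh: StructuredMesh,
    locator: SectionLocator,
    threshold: float = UNMIXED_THRESHOLD,
    cumulative: bool = True,
) -> pd.DataFrame:
    """ME evaluated at each section.

    By default over the cumulative upstream region ending at each section
    (the evolution along the chip); ``cumulative=False`` restricts to each
    section's own cell column.
    """
    rows = []
    for k in range(locator.n_sections):
        j = int(locator.columns[k])
        if cumulative:
            me = mixing_efficiency(y, mesh, upto_column=j, threshold=threshold)
        else:
            me = mixing_efficiency(y[j : j + 1], mesh, threshold=threshold)
        rows.append({"section": k + 1, "ME_pct": me})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Precipitation-oriented metrics
# ---------------------------------------------------------------------------


def area_of_precipitation(
    x_acn: np.ndarray,
    mesh: StructuredMesh,
    lower: float = AOP_LOWER,
    upper: float = AOP_UPPER,
) -> tuple[float, np.ndarray]:
    """AoP%% and the boolean AoP cell mask (strict bounds lower < X < upper)."""
    mask = (x_acn > lower) & (x_acn < upper)
    a_aop = float(mesh.area[mask].sum())
    a_tot = mesh.total_area()
    return 100.0 * a_aop / a_tot, mask


def mixing_time(w: float, D: float, frr) -> float:
    """tau_mix = w^2 / (9 D (1 + 1/n)^2) in seconds.

    ``w`` is the channel width (m), ``D`` the solvent/anti-solvent diffusion
    coefficient (m^2/s) and ``frr`` either the numeric anti-solvent:solvent
    ratio n (for a 1:n run) or an :class:`OperatingPoint`.
    """
    if w <= 0 or D <= 0:
        raise ValidationError("w and D must be strictly positive")
    n = frr.dilution_ratio if isinstance(frr, OperatingPoint) else float(frr)
    if n <= 0:
        raise ValidationError("FRR ratio must be strictly positive")
    return w**2 / (9.0 * D * (1.0 + 1.0 / n) ** 2)


@dataclass
class ResidenceTimes:
    """tau_res distribution over the AoP, before/after the tau_mix filter."""

    raw: np.ndarray  # all finite tau values over the AoP (s)
    filtered: np.ndarray  # surviving values (tau >= tau_mix)
    tau_mix: float
    n_stagnant: int  # AoP cells excluded for |v| = 0

    @property
    def median(self) -> float:
        return float(np.median(self.filtered)) if self.filtered.size else float("nan")

    def percentiles(self, q=(25, 50, 75)) -> np.ndarray:
        if not self.filtered.size:
            return np.full(len(q), np.nan)
        return np.percentile(self.filtered, q)


def residence_times(
    aop_mask: np.ndarray,
    flow: FlowField,
    mesh: StructuredMesh,
    tau_mix_s: float,
) -> ResidenceTimes:
    """Per-AoP-cell residence time L_i / v_i, tau_mix-filtered.

    L_i is measured along the centerline (streamwise station to outlet), not
    as a Euclidean distance — inside a serpentine only the along-channel
    distance is meaningful.  Stagnant cells (|v| = 0) are excluded with a
    warning.
    """
    speed = flow.speed[aop_mask]
    L = mesh.arc_length_to_outlet[aop_mask]
    stagnant = speed == 0.0
    n_stag = int(stagnant.sum())
    if n_stag:
        logger.warning("%d stagnant AoP cells excluded from tau_res", n_stag)
    tau = L[~stagnant] / speed[~stagnant]
    return ResidenceTimes(
        raw=tau,
        filtered=tau[tau >= tau_mix_s],
        tau_mix=tau_mix_s,
        n_stagnant=n_stag,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """All metrics of one operating point (one Table-4-style row + curves)."""

    op: OperatingPoint
    aop_pct: float
    aop_area_m2: float
    total_area_m2: float
    tau_mix_s: float
    tau_res_median: float
    tau_res_p25: float
    tau_res_p75: float
    v_median: float
    v_p25: float
    v_p75: float
    n_aop_cells: int
    n_cells: int
    mi_by_section: pd.DataFrame
    me_by_section: pd.DataFrame
    empty_aop: bool = False

    @property
    def final_mi(self) -> float:
        return float(self.mi_by_section["MI_pct"].iloc[-1])

    def row(self) -> dict:
        return {
            "FRR": self.op.frr_label,
            "AoP_pct": self.aop_pct,
            "tau_res_median_s": self.tau_res_median,
            "tau_res_p25_s": self.tau_res_p25,
            "tau_res_p75_s": self.tau_res_p75,
            "v_median_m_s": self.v_median,
            "v_p25_m_s": self.v_p25,
            "v_p75_m_s": self.v_p75,
            "tau_mix_s": self.tau_mix_s,
            "MI_final_pct": self.final_mi,
        }


def compute_metrics(
    mesh: StructuredMesh,
    locator: SectionLocator,
    flow: FlowField,
    species: SpeciesField,
    op: OperatingPoint,
    D: float,
) -> MetricsReport:
    """Evaluate MI/ME curves, AoP, tau_mix and the in-AoP distributions.

    The in-AoP velocity statistics are taken over the same tau_mix-filtered
    cell set as the residence times.
    """
    profiles = extract_section_profiles(mesh, locator, species.Y)
    mi = mixing_index_curve(profiles)
    me = mixing_efficiency_curve(species.Y, mesh, locator)

    aop_pct, mask = area_of_precipitation(species.X_acn, mesh)
    tmix = mixing_time(mesh.width, D, op)

    speed = flow.speed
    if mask.any():
        rt = residence_times(mask, flow, mesh, tmix)
        # velocities over the cells that survive the tau_mix filter
        sp = speed[mask]
        L = mesh.arc_length_to_outlet[mask]
        ok = sp > 0.0
        keep = np.zeros_like(sp, dtype=bool)
        keep[ok] = (L[ok] / sp[ok]) >= tmix
        v_stats = (
            np.percentile(sp[keep], [25, 50, 75]) if keep.any() else np.full(3, np.nan)
        )
        t_stats = rt.percentiles()
        empty = not keep.any()
    else:
        logger.warning("empty AoP for FRR %s: tau_res undefined", op.frr_label)
        v_stats = np.full(3, np.nan)
        t_stats = np.full(3, np.nan)
        empty = True

    return MetricsReport(
        op=op,
        aop_pct=aop_pct,
        aop_area_m2=float(mesh.area[mask].sum()),
        total_area_m2=mesh.total_area(),
        tau_mix_s=tmix,
        tau_res_median=float(t_stats[1]),
        tau_res_p25=float(t_stats[0]),
        tau_res_p75=float(t_stats[2]),
        v_median=float(v_stats[1]),
        v_p25=float(v_stats[0]),
        v_p75=float(v_stats[2]),
        n_aop_cells=int(mask.sum()),
        n_cells=mesh.n_cells,
        mi_by_section=mi,
        me_by_section=me,
        empty_aop=empty,
    )


def summarize(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """One row per operating point (AoP%%, tau_res and velocity median/IQR)."""
    return pd.DataFrame([r.row() for r in reports])


def mi_me_table(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Long-format (FRR, section, MI, ME) table across operating points."""
    frames = []
    for r in reports:
        df = pd.merge(r.me_by_section, r.mi_by_section, on="section", how="left")
        df.insert(0, "FRR", r.op.frr_label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
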