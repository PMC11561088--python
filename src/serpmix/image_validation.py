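"""Image-based validation of simulated mixing profiles.

The experimental protocol photographs the channel at the midpoint of each
straight run (15 RGB micrographs, channel horizontal in-frame, pre-aligned).
Validation proceeds per section:

1. a rectangular ROI drawn on the first image is reused for the stack;
2. the two dark channel borders are detected as grayscale row minima;
3. the RGB profile along the transverse line at the ROI's horizontal center
   is extracted, discarding the first/last 10 pixels next to the borders
   (border shadow);
4. the simulated mass-fraction profile is rendered through a two-endpoint
   colormap (the measured RGB of the two unmixed solutions), resampled onto
   the same pixel grid, and the per-channel percentage difference
   eps_ij = 100 * (I_exp - I_num) / I_num is reported for the interior
   sections (inlet/outlet excluded) together with a grayscale variant.

A deterministic synthetic-micrograph generator stands in for the microscope,
so the whole pipeline is exercised end to end without instrument data.
Grayscale uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .chip_geometry import ValidationError

logger = logging.getLogger(__name__)

EDGE_EXCLUSION = 10  # px dropped at each border (shadow)
BT601 = np.array([0.299, 0.587, 0.114])


class BorderDetectionError(RuntimeError):
    """Fewer than two distinct border lines found."""


def grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB image (float)."""
    return np.asarray(image, dtype=float) @ BT601


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorMapSpec:
    """Linear two-endpoint colormap: mass fraction Y -> 8-bit RGB.

    ``c0`` is the color of the pure anti-solvent (Y = 0; rhodamine-dyed TRIS
    by default), ``c1`` the pure solvent stream (Y = 1; near-transparent
    ACN-PLGA).  Rendering quantizes to 8-bit, as a contour-plot screenshot
    would.
    """

    c0: tuple[float, float, float] = (236.0, 64.0, 122.0)
    c1: tuple[float, float, float] = (232.0, 232.0, 232.0)

    def __post_init__(self) -> None:
        for c in (self.c0, self.c1):
            if any(not 0 <= v <= 255 for v in c):
                raise ValidationError("colormap endpoints must lie in [0, 255]^3")

    def map(self, y) -> np.ndarray:
        """(..., 3) uint8 colors for mass fractions in [0, 1]."""
        y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
        c0 = np.asarray(self.c0)
        c1 = np.asarray(self.c1)
        rgb = c0 + y[..., None] * (c1 - c0)
        return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class ROISpec:
    """Rectangle (0-based pixels, top-left origin) covering the channel width."""

    x: int
    y: int
    w: int
    h: int

    def validate(self, image: np.ndarray) -> None:
        H, W = image.shape[:2]
        if not (0 <= self.x < self.x + self.w <= W and 0 <= self.y < self.y + self.h <= H):
            raise ValidationError(f"ROI {self} outside image bounds {(H, W)}")


@dataclass(frozen=True)
class ChannelBorders:
    """Row indices of the two dark border lines (top < bottom)."""

    top: int
    bottom: int

    @property
    def interior(self) -> int:
        """Pixel rows strictly between the borders (the 'border separation')."""
        return self.bottom - self.top - 1


@dataclass
class RGBProfile:
    """Edge-trimmed transverse intensity profile of one section."""

    section: int
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    @property
    def channels(self) -> np.ndarray:
        return np.stack([self.r, self.g, self.b])

    @property
    def means(self) -> np.ndarray:
        """Mean intensity per channel (Ī_j, j = R, G, B)."""
        return self.channels.mean(axis=1)

    @property
    def mean_gray(self) -> float:
        return float(BT601 @ self.means)

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class MicrographStack:
    """Per-section RGB images (8-bit), equal dimensions, channel horizontal."""

    images: list[np.ndarray]
    sections: list[int]

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValidationError(f"stack images differ in shape: {shapes}")

    @classmethod
    def from_directory(cls, directory, pattern: str = "section_{i:02d}.png", n: int = 15):
        directory = Path(directory)
        images, sections = [], []
        for i in range(1, n + 1):
            f = directory / pattern.format(i=i)
            if not f.exists():
                raise FileNotFoundError(f)
            images.append(np.asarray(iio.imread(f))[..., :3])
            sections.append(i)
        return cls(images=images, sections=sections)

    def save(self, directory, pattern: str = "section_{i:02d}.png") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for im, i in zip(self.images, self.sections):
            iio.imwrite(directory / pattern.format(i=i), im)


@dataclass
class ComparisonReport:
    """Per-section per-channel percentage differences (and grayscale)."""

    sections: np.ndarray  # (n,)
    eps: np.ndarray  # (n, 3) %, channels R, G, B
    eps_gray: np.ndarray  # (n,)

    @property
    def grand_mean(self) -> np.ndarray:
        return self.eps.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "section": self.sections,
                "eps_R_pct": self.eps[:, 0],
                "eps_G_pct": self.eps[:, 1],
                "eps_B_pct": self.eps[:, 2],
                "eps_gray_pct": self.eps_gray,
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None):
        """Grouped bar plot of eps per section and channel (+ grayscale)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4))
        width = 0.2
        xs = np.arange(len(self.sections))
        for k, (label, color) in enumerate(
            zip(("R", "G", "B"), ("tab:red", "tab:green", "tab:blue"))
        ):
            ax.bar(xs + (k - 1.5) * width, self.eps[:, k], width, label=label, color=color)
        ax.bar(xs + 1.5 * width, self.eps_gray, width, label="gray", color="0.5")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xticks(xs, [str(s) for s in self.sections])
        ax.set_xlabel("section")
        ax.set_ylabel("percentage difference (%)")
        ax.legend(ncols=4)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def detect_borders(image: np.ndarray, roi: ROISpec, min_separation: int = 5) -> ChannelBorders:
    """Locate the two dark border rows inside the ROI.

    Grayscale is averaged over the central 50% of the ROI's columns; the
    global minimum row is taken first, then the best minimum at least
    ``min_separation`` rows away on the opposite side of the ROI midline.
    """
    roi.validate(image)
    gray = grayscale(image[roi.y : roi.y + roi.h, roi.x : roi.x + roi.w])
    c0 = roi.w // 4
    c1 = roi.w - roi.w // 4
    rows = gray[:, c0:c1].mean(axis=1)
    if np.ptp(rows) < 1.0:
        raise BorderDetectionError("no distinct grayscale minima (uniform ROI)")
    first = int(np.argmin(rows))
    mid = roi.h / 2.0
    # candidate rows on the opposite side of the midline, far enough away
    idx = np.arange(roi.h)
    opposite = (idx - mid) * (first - mid) < 0 if first != mid else idx != first
    candidates = opposite & (np.abs(idx - first) >= min_separation)
    if not candidates.any():
        raise BorderDetectionError("no second border candidate on the opposite side")
    second = int(idx[candidates][np.argmin(rows[candidates])])
    if abs(rows[second] - rows.min()) > 0.5 * np.ptp(rows):
        raise BorderDetectionError("second minimum not distinct enough")
    top, bottom = sorted((first, second))

    # a border line can be more than one pixel thick: slide each detected row
    # inward while the neighbouring row is part of the same dark band, so the
    # returned rows are the ones adjacent to the channel interior
    def _inward(row: int, step: int) -> int:
        while 0 <= row + step < roi.h and rows[row + step] <= rows[row] * 1.02 + 1.0:
            row += step
        return row

    top = _inward(top, +1)
    bottom = _inward(bottom, -1)
    if bottom - top < min_separation:
        raise BorderDetectionError("borders collapsed onto one dark band")
    return ChannelBorders(top=top + roi.y, bottom=bottom + roi.y)


def extract_profile(
    image: np.ndarray,
    borders: ChannelBorders,
    roi: ROISpec,
    section: int = 0,
    edge_exclusion: int = EDGE_EXCLUSION,
) -> RGBProfile:
    """RGB intensities along the transverse line at the ROI's horizontal
    center, between the borders, trimmed by ``edge_exclusion`` px per side."""
    interior = borders.interior
    if interior < 2 * edge_exclusion + 1:
        raise ValidationError(
            f"channel interior ({interior} px) narrower than twice the edge "
            f"exclusion ({edge_exclusion} px) plus one"
        )
    col = roi.x + roi.w // 2
    r0 = borders.top + 1 + edge_exclusion
    r1 = borders.bottom - edge_exclusion  # exclusive
    line = np.asarray(image[r0:r1, col, :3], dtype=float)
    return RGBProfile(section=section, r=line[:, 0], g=line[:, 1], b=line[:, 2])


def render_numeric_profile(
    y_profile: np.ndarray,
    cmap: ColorMapSpec,
    n_pixels: int,
    section: int = 0,
    edge_exclusion: int = EDGE_EXCLUSION,
) -> RGBProfile:
    """Simulated counterpart of :func:`extract_profile`.

    The transverse mass-fraction profile (sampled at cell centers) is
    resampled onto ``n_pixels`` pixel rows spanning the channel interior,
    mapped through the colormap (8-bit quantized, like the rendered contour
    plot), then trimmed like the experimental profile.
    """
    y_px = _resample_to_pixels(y_profile, n_pixels)
    rgb = cmap.map(y_px).astype(float)
    sl = slice(edge_exclusion, n_pixels - edge_exclusion)
    return RGBProfile(section=section, r=rgb[sl, 0], g=rgb[sl, 1], b=rgb[sl, 2])


def _resample_to_pixels(y_profile: np.ndarray, n_pixels: int) -> np.ndarray:
    """Linear resampling from cell-center samples onto pixel-center rows."""
    y_profile = np.asarray(y_profile, dtype=float)
    n = len(y_profile)
    src = (np.arange(n) + 0.5) / n
    dst = (np.arange(n_pixels) + 0.5) / n_pixels
    return np.interp(dst, src, y_profile)


def percent_difference(
    exp: Sequence[RGBProfile],
    num: Sequence[RGBProfile],
    sections: Sequence[int] | None = None,
) -> ComparisonReport:
    """eps_ij = 100 (Ī_exp,ij - Ī_num,ij)/Ī_num,ij per section i and channel j.

    By default the interior sections i = 1..14 are compared (inlet/outlet
    excluded).  Zero numerical mean intensity makes eps undefined (flagged as
    NaN with a warning).
    """
    by_sec_exp = {p.section: p for p in exp}
    by_sec_num = {p.section: p for p in num}
    if sections is None:
        common = sorted(set(by_sec_exp) & set(by_sec_num))
        sections = [s for s in common if s <= 14] or common
    eps = np.empty((len(sections), 3))
    eps_gray = np.empty(len(sections))
    for k, s in enumerate(sections):
        if s not in by_sec_exp or s not in by_sec_num:
            raise ValidationError(f"section {s} missing from one of the stacks")
        ie = by_sec_exp[s].means
        in_ = by_sec_num[s].means
        with np.errstate(divide="ignore", invalid="ignore"):
            eps[k] = np.where(in_ > 0, 100.0 * (ie - in_) / in_, np.nan)
        if np.any(in_ == 0):
            logger.warning("section %d: zero numerical mean intensity, eps undefined", s)
        ge, gn = by_sec_exp[s].mean_gray, by_sec_num[s].mean_gray
        eps_gray[k] = 100.0 * (ge - gn) / gn if gn > 0 else np.nan
    return ComparisonReport(sections=np.asarray(sections), eps=eps, eps_gray=eps_gray)


def synth_micrograph(
    y_profile: np.ndarray,
    cmap: ColorMapSpec,
    *,
    image_size: tuple[int, int] = (240, 320),
    channel_px: int = 140,
    border_px: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: int = 205,
    border_value: int = 12,
) -> np.ndarray:
    """Deterministic synthetic channel micrograph (uint8 RGB).

    A horizontal channel band of ``channel_px`` interior rows, centered
    vertically, colored row-wise by ``cmap(Y)`` (the first profile sample maps
    to the top interior row); dark border lines of ``border_px`` rows above
    and below; flat background; optional additive Gaussian noise (clipped).
    """
    H, W = image_size
    if channel_px + 2 * border_px > H:
        raise ValidationError("channel does not fit in the image")
    img = np.full((H, W, 3), background, dtype=float)
    top = (H - channel_px) // 2 - border_px  # first border row
    img[top : top + border_px, :, :] = border_value
    r0 = top + border_px
    colors = cmap.map(_resample_to_pixels(y_profile, channel_px)).astype(float)
    img[r0 : r0 + channel_px, :, :] = colors[:, None, :]
    img[r0 + channel_px : r0 + channel_px + border_px, :, :] = border_value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def synth_stack(
    y_profiles: Sequence[np.ndarray],
    cmap: ColorMapSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> MicrographStack:
    """Synthetic stack (one image per section profile), seeded per section."""
    images = [
        synth_micrograph(y, cmap, noise_sd=noise_sd, seed=seed + k, **kwargs)
        for k, y in enumerate(y_profiles)
    ]
    return MicrographStack(images=images, sections=list(range(1, len(images) + 1)))


def default_roi(image: np.ndarray, margin: int = 10) -> ROISpec:
    """A centered ROI covering the full channel width with vertical margin."""
    H, W = image.shape[:2]
    return ROISpec(x=W // 4, y=margin, w=W // 2, h=H - 2 * margin)


def validate_stack(
    stack: MicrographStack,
    y_profiles: Sequence[np.ndarray],
    cmap: ColorMapSpec,
    roi: ROISpec | None = None,
    edge_exclusion: int = EDGE_EXCLUSION,
    sections: Sequence[int] | None = None,
) -> ComparisonReport:
    """Full validation pipeline: detect, extract, render, compare."""
    if len(stack.images) != len(y_profiles):
        raise ValidationError("stack and profile counts differ")
    if roi is None:
        roi = default_roi(stack.images[0])
    # the first image's borders/ROI are reused across the stack (pre-aligned)
    borders = detect_borders(stack.images[0], roi)
    exp, num = [], []
    for im, sec, y in zip(stack.images, stack.sections, y_profiles):
        prof = extract_profile(im, borders, roi, section=sec, edge_exclusion=edge_exclusion)
        exp.append(prof)
        num.append(
            render_numeric_profile(
                y, cmap, borders.interior, section=sec, edge_exclusion=edge_exclusion
            )
        )
    return percent_difference(exp, num, sections=sections)
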