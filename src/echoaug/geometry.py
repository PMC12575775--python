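"""Sector-scan geometry: rendering and detection of the fan-shaped support.

Coordinates are 0-based ``(row, col)`` with row 0 at the top.  The sector
axis angle is measured in degrees from straight down, positive toward
increasing columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from skimage import measure

from .errors import DetectionError, InvalidArgumentError

__all__ = ["SectorGeometry", "sector_support", "detect_sector"]


@dataclass(frozen=True)
class SectorGeometry:
    """Apex position, opening angle, depth extent and axis direction."""

    apex: tuple  # (row, col), pixels; may lie above the frame (row < 0)
    opening_angle: float  # degrees, in (0, 180)
    radius: float  # pixels
    axis_angle: float = 0.0  # degrees from straight down, + toward +col

    def __post_init__(self):
        if not 0.0 < self.opening_angle < 180.0:
            raise InvalidArgumentError(
                f"opening_angle must be in (0, 180), got {self.opening_angle}"
            )
        if self.radius <= 0:
            raise InvalidArgumentError(f"radius must be positive, got {self.radius}")

    @property
    def axis_vector(self):
        """Unit (d_row, d_col); (1, 0) points straight down."""
        a = math.radians(self.axis_angle)
        return (math.cos(a), math.sin(a))

    def with_(self, **kwargs):
        return replace(self, **kwargs)


def sector_support(geometry: SectorGeometry, shape) -> np.ndarray:
    """Boolean grid of pixels inside the sector fan."""
    H, W = shape
    if geometry.apex[0] > H:
        raise InvalidArgumentError("apex must lie inside or above the frame")
    rr, cc = np.mgrid[0:H, 0:W]
    dr = rr - geometry.apex[0]
    dc = cc - geometry.apex[1]
    d = np.hypot(dr, dc)
    ar, ac = geometry.axis_vector
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(d > 0, (dr * ar + dc * ac) / np.maximum(d, 1e-12), 1.0)
    half = math.radians(geometry.opening_angle / 2.0)
    return (d <= geometry.radius) & (cosang >= math.cos(half))


def _largest_component(binary):
    lbl = measure.label(binary, connectivity=2)
    if lbl.max() == 0:
        raise DetectionError("no foreground above threshold")
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    return lbl == counts.argmax()


def detect_sector(image, intensity_threshold: float = 0.02):
    """Estimate sector geometry from a B-mode-like image.

    The support is the largest connected component above the threshold; the
    apex is the intersection of straight lines fit to the two lateral edges
    of the support (fitted on the middle rows, away from the rounded apex and
    the bottom arc).

    Returns ``(SectorGeometry, support)``; raises :class:`DetectionError`
    when no foreground exists or the lateral edges are (near) parallel.
    """
    image = np.asarray(image, dtype=np.float64)
    fg = image > intensity_threshold
    if not fg.any():
        raise DetectionError("no pixels above the intensity threshold")
    support = _largest_component(fg)

    rows = np.flatnonzero(support.any(axis=1))
    r0, r1 = rows[0], rows[-1]
    extent = r1 - r0
    lo = r0 + max(2, int(0.12 * extent))
    hi = r0 + int(0.70 * extent)
    W = support.shape[1]

    def usable(r):
        # rows clipped by the frame have vertical (frame) edges, not sector edges
        cols = np.flatnonzero(support[r])
        return cols.size > 0 and cols[0] > 0 and cols[-1] < W - 1

    fit_rows = [r for r in range(lo, hi + 1) if usable(r)]
    if len(fit_rows) < 4:
        fit_rows = [r for r in rows if usable(r)]
    if len(fit_rows) < 4:
        raise DetectionError("too few unclipped rows to fit the sector edges")
    fit_rows = np.asarray(fit_rows)
    left = np.array([np.flatnonzero(support[r])[0] for r in fit_rows], dtype=float)
    right = np.array([np.flatnonzero(support[r])[-1] for r in fit_rows], dtype=float)

    al, bl = np.polyfit(fit_rows, left, 1)
    ar_, br = np.polyfit(fit_rows, right, 1)
    if abs(al - ar_) < 1e-3:
        raise DetectionError("lateral edges are parallel; apex undefined")
    apex_r = (br - bl) / (al - ar_)
    apex_c = al * apex_r + bl
    ang_l = math.degrees(math.atan(al))
    ang_r = math.degrees(math.atan(ar_))
    opening = ang_r - ang_l
    if not 0.0 < opening < 180.0:
        raise DetectionError(f"implausible opening angle {opening:.1f} degrees")
    axis_angle = 0.5 * (ang_l + ang_r)

    sr, sc = np.nonzero(support)
    radius = float(np.hypot(sr - apex_r, sc - apex_c).max())
    geom = SectorGeometry(
        apex=(float(apex_r), float(apex_c)),
        opening_angle=float(opening),
        radius=radius,
        axis_angle=float(axis_angle),
    )
    return geom, support
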