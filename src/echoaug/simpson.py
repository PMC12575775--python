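"""Biplane method-of-discs volumes and ejection fraction from LV masks.

Disc construction: per view the LV long axis is the principal axis of the
labeled pixel set, apex/base are the extreme projections, the long-axis
length is the mean of the two views' lengths, and the diameter of each of
``n_discs`` equal slabs is the perpendicular extent (max - min projection)
of the LV pixels in that slab, in mm.  Discs are paired between views from
the wider end (the base) so orientation is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, PipelineFailureError, UndefinedMetricError

__all__ = [
    "DiscStack",
    "extract_disc_stack",
    "simpson_biplane_volume",
    "ef",
    "biplane_ef_from_masks",
]

LV_LABEL = 1


@dataclass(frozen=True)
class DiscStack:
    """Long-axis length plus per-disc diameters from two orthogonal views."""

    L: float  # mm
    a: np.ndarray  # mm, view-1 diameters, base (index 0) to apex
    b: np.ndarray  # mm, view-2 diameters

    def __post_init__(self):
        a = np.asarray(self.a, dtype=np.float64)
        b = np.asarray(self.b, dtype=np.float64)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if self.L <= 0:
            raise InvalidArgumentError(f"long-axis length must be positive, got {self.L}")
        if a.shape != b.shape or a.ndim != 1:
            raise InvalidArgumentError("diameter sequences must be 1-D and equal length")
        if np.any(a < 0) or np.any(b < 0):
            raise InvalidArgumentError("diameters must be non-negative")

    @property
    def n_discs(self) -> int:
        return int(self.a.size)


def _view_profile(mask, spacing, n_discs):
    """(length_mm, per-disc diameters base->apex) of the LV in one view."""
    sel = np.asarray(mask) == LV_LABEL
    if not sel.any():
        raise UndefinedMetricError("LV label absent from mask")
    coords = np.argwhere(sel).astype(np.float64)
    coords[:, 0] *= spacing[0]
    coords[:, 1] *= spacing[1]
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    p = centered @ axis
    q = centered @ np.array([-axis[1], axis[0]])
    p -= p.min()
    length = float(p.max())
    if length <= 0:
        raise UndefinedMetricError("degenerate LV (zero long-axis extent)")
    edges = np.linspace(0.0, length, n_discs + 1)
    diam = np.zeros(n_discs)
    slab = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_discs - 1)
    for i in range(n_discs):
        qi = q[slab == i]
        if qi.size:
            diam[i] = float(qi.max() - qi.min())
    if diam[0] < diam[-1]:  # orient base (wider end) first
        diam = diam[::-1].copy()
    return length, diam


def extract_disc_stack(mask_view1, mask_view2, spacing1, spacing2, n_discs: int = 20) -> DiscStack:
    """Per-disc diameters from two orthogonal views of the same LV."""
    if n_discs < 1:
        raise InvalidArgumentError("n_discs must be >= 1")
    l1, a = _view_profile(mask_view1, spacing1, n_discs)
    l2, b = _view_profile(mask_view2, spacing2, n_discs)
    return DiscStack(L=0.5 * (l1 + l2), a=a, b=b)


def simpson_biplane_volume(stack: DiscStack) -> float:
    """V = (pi/4) (L/n) sum_i a_i b_i, converted mm^3 -> ml."""
    v_mm3 = math.pi / 4.0 * (stack.L / stack.n_discs) * float(np.sum(stack.a * stack.b))
    return v_mm3 / 1000.0


def ef(edv: float, esv: float) -> float:
    """Ejection fraction (EDV - ESV) / EDV."""
    if edv <= 0:
        raise InvalidArgumentError(f"EDV must be positive, got {edv}")
    if not 0 <= esv <= edv:
        raise InvalidArgumentError(f"ESV must be in [0, EDV], got {esv}")
    return (edv - esv) / edv


def biplane_ef_from_masks(a2c_cycles, a4c_cycles, spacing_a2c, spacing_a4c, n_discs: int = 20):
    """EF estimate averaged over every (A2C cycle, A4C cycle) pair.

    Each cycle is an ``(ed_mask, es_mask)`` pair.  Pairs whose disc
    extraction fails are skipped; when every pair fails the exam is flagged
    via :class:`PipelineFailureError`.
    """
    if len(a2c_cycles) < 1 or len(a4c_cycles) < 1:
        raise InvalidArgumentError("at least one cycle per view is required")
    values = []
    for ed2, es2 in a2c_cycles:
        for ed4, es4 in a4c_cycles:
            try:
                edv = simpson_biplane_volume(
                    extract_disc_stack(ed2, ed4, spacing_a2c, spacing_a4c, n_discs)
                )
                esv = simpson_biplane_volume(
                    extract_disc_stack(es2, es4, spacing_a2c, spacing_a4c, n_discs)
                )
                values.append(ef(edv, min(esv, edv)))
            except UndefinedMetricError:
                continue
    if not values:
        raise PipelineFailureError("EF could not be computed for any cycle pair")
    return float(np.mean(values))
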