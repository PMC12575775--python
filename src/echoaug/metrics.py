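"""Segmentation overlap/boundary metrics and SSIM retrieval."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .errors import InvalidArgumentError, UndefinedMetricError

__all__ = ["dice", "hausdorff_mm", "ssim", "rank_by_ssim"]


def dice(mask_a, mask_b, label=1) -> float:
    """2|A n B| / (|A| + |B|) for the given label; 1 when both sets empty."""
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch {a.shape} vs {b.shape}")
    A = a == label
    B = b == label
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((A & B).sum()) / denom


def _boundary(binary):
    return binary & ~ndimage.binary_erosion(binary, border_value=0)


def _boundary_coords_mm(mask, label, spacing):
    sel = np.asarray(mask) == label
    if not sel.any():
        raise UndefinedMetricError(f"label {label} absent from mask")
    coords = np.argwhere(_boundary(sel)).astype(np.float64)
    coords[:, 0] *= spacing[0]
    coords[:, 1] *= spacing[1]
    return coords


def hausdorff_mm(mask_a, mask_b, label=1, spacing=(1.0, 1.0), percentile=None) -> float:
    """Symmetric Hausdorff distance between boundary pixel sets, in mm.

    Per-axis mm scaling is applied before distances.  ``percentile=95``
    gives the HD95 variant (the max of the two directed 95th percentiles);
    the default is the classical maximum.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch {a.shape} vs {b.shape}")
    ca = _boundary_coords_mm(a, label, spacing)
    cb = _boundary_coords_mm(b, label, spacing)
    d_ab, _ = cKDTree(cb).query(ca)
    d_ba, _ = cKDTree(ca).query(cb)
    if percentile is None:
        return float(max(d_ab.max(), d_ba.max()))
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def ssim(image_a, image_b) -> float:
    """Mean local SSIM with an 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03 and dynamic range 1."""
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidArgumentError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )


def rank_by_ssim(query, candidates):
    """Candidate indices ordered by decreasing SSIM to the query; ties broken
    by candidate index.  Returns ``(indices, scores_in_that_order)``."""
    if len(candidates) == 0:
        raise InvalidArgumentError("candidate set must be non-empty")
    scores = np.array([ssim(query, c) for c in candidates])
    order = np.argsort(-scores, kind="stable")
    return order, scores[order]
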