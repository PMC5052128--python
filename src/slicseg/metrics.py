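"""Segmentation evaluation: Dice overlap, average symmetric surface
distance (ASSD, in mm), and Fleiss' kappa multi-rater agreement.

Surface voxels are mask voxels with at least one face-adjacent (6-connected)
background neighbor; voxels on the image border count as surface.  Distances
between surface voxel centres are exact Euclidean distances in mm, computed
with a spacing-aware distance transform (equivalent to all-pairs search).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import LabelVolume

__all__ = ["dice", "assd", "fleiss_kappa", "surface_voxels", "evaluate"]


def _as_mask(x) -> np.ndarray:
    data = x.data if isinstance(x, LabelVolume) else np.asarray(x)
    if not np.all(np.isin(np.unique(data), (0, 1))):
        raise ValueError("masks must be binary")
    return data.astype(bool)


def dice(seg, truth) -> float:
    """Dice overlap ``2|A ∩ B| / (|A| + |B|)``; both-empty is an error."""
    a, b = _as_mask(seg), _as_mask(truth)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2.0 * int((a & b).sum()) / denom


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array marking mask voxels with a face-adjacent background
    neighbor (image border counts as background)."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def assd(seg, truth, spacing) -> float:
    """Average symmetric surface distance in mm.

    Averages, over both surfaces, each surface voxel's shortest Euclidean
    distance to the other surface.
    """
    a, b = _as_mask(seg), _as_mask(truth)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    if not a.any() or not b.any():
        raise ValueError("ASSD undefined for an empty mask")
    spacing = tuple(float(s) for s in spacing)
    sa, sb = surface_voxels(a), surface_voxels(b)
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    total = dist_to_b[sa].sum() + dist_to_a[sb].sum()
    return float(total / (sa.sum() + sb.sum()))


def fleiss_kappa(segmentations) -> float:
    """Fleiss' kappa over >= 2 binary segmentations of one grid.

    Each voxel is a subject rated into {0, 1} by ``n`` raters: the observed
    agreement is the mean pairwise agreement per voxel, the chance agreement
    the sum of squared overall category proportions, and
    ``kappa = (Pa - Pe) / (1 - Pe)``.
    """
    masks = [_as_mask(s) for s in segmentations]
    if len(masks) < 2:
        raise ValueError("Fleiss' kappa needs at least 2 raters")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all raters must segment the same grid")
    n = len(masks)
    pos = np.sum([m.astype(np.int64) for m in masks], axis=0).ravel()
    neg = n - pos
    pa = np.mean((pos * (pos - 1) + neg * (neg - 1)) / (n * (n - 1)))
    p1 = pos.sum() / (n * pos.size)
    pe = p1 ** 2 + (1 - p1) ** 2
    if pe >= 1.0:
        raise ValueError("kappa undefined: all raters unanimous on one class")
    return float((pa - pe) / (1 - pe))


def evaluate(seg: LabelVolume, truth: LabelVolume) -> dict:
    """Dice, ASSD and per-slice Dice of one segmentation against a reference."""
    per_slice = []
    for s in range(seg.data.shape[0]):
        if seg.data[s].sum() + truth.data[s].sum() == 0:
            per_slice.append(float("nan"))
        else:
            per_slice.append(dice(seg.data[s], truth.data[s]))
    return {
        "dice": dice(seg, truth),
        "assd_mm": assd(seg, truth, truth.spacing),
        "per_slice_dice": per_slice,
    }
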