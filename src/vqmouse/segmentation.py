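"""Threshold-limited region-growing lung segmentation from CT.

The lung label is built in four steps on the HU-calibrated, smoothed CT:

1. ``grow_airspace`` — connected region growing from a seed, keeping voxels
   with HU <= -50 (the airspace: parenchyma + conducting airways).
2. ``grow_volume`` — a bounded dilation (default 2 one-voxel iterations)
   that admits neighbouring voxels below +100 HU, pulling in denser
   parenchyma while the +100 HU gate excludes chest wall and bone.
3. ``fill_holes`` — 3-D hole filling, so enclosed soft-tissue structures
   (major vessels) belong to the lung.
4. ``remove_trachea`` — removal of the trachea / main bronchi above a cut
   plane (or within a user mask); applied to the ventilation label only.

All steps are deterministic; ``segment_lung`` composes them and pools the
result onto the half-resolution analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CT, LungLabel, Volume, downsample_mask_half

__all__ = [
    "SegmentationParams",
    "grow_airspace",
    "grow_volume",
    "fill_holes",
    "remove_trachea",
    "segment_lung",
    "default_seed",
    "qc_metrics",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationParams:
    """Tunable thresholds of the lung-label recipe.

    ``airspace_threshold_hu`` (inclusive, <=) defines the airspace;
    ``exclusion_threshold_hu`` (strict, <) gates the volume-growing step.
    """

    airspace_threshold_hu: float = -50.0
    exclusion_threshold_hu: float = 100.0
    growth_iterations: int = 2
    connectivity: int = 6
    remove_trachea: bool = False
    trachea_cut_index: int | None = None   # axial (axis-2) plane index
    trachea_mask: np.ndarray | None = None
    apex_high: bool = True                 # apex at high axial index

    def __post_init__(self) -> None:
        if self.airspace_threshold_hu >= self.exclusion_threshold_hu:
            raise ValueError("airspace threshold must be below exclusion threshold")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        if self.growth_iterations < 0:
            raise ValueError("growth_iterations must be >= 0")

    @property
    def structure(self) -> np.ndarray:
        return _STRUCTS[self.connectivity]


def default_seed(ct: Volume, slab_fraction: float = 0.4) -> tuple[int, int, int]:
    """Default seed: the minimum-HU voxel within the central slab.

    The central ``slab_fraction`` of each axis nearly always contains
    airway or lung air in a thorax scan, making the choice reproducible
    without user input.
    """
    lo = [int(s * (1 - slab_fraction) / 2) for s in ct.shape]
    hi = [s - l for s, l in zip(ct.shape, lo)]
    sub = ct.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    flat = int(np.argmin(sub))
    idx = np.unravel_index(flat, sub.shape)
    return tuple(int(i + l) for i, l in zip(idx, lo))


def grow_airspace(
    ct: Volume,
    seed_point: tuple[int, int, int],
    params: SegmentationParams | None = None,
) -> LungLabel:
    """Connected component of HU <= threshold voxels reachable from the seed."""
    params = params or SegmentationParams()
    seed = tuple(int(i) for i in seed_point)
    hu = np.asarray(ct.data, float)
    if hu[seed] > params.airspace_threshold_hu:
        raise ValueError(
            f"seed voxel HU {hu[seed]:.1f} is above the airspace threshold "
            f"{params.airspace_threshold_hu:.1f}"
        )
    below = hu <= params.airspace_threshold_hu
    comp, _ = ndimage.label(below, structure=params.structure)
    mask = comp == comp[seed]
    if not mask.any():
        raise ValueError("airspace growing produced an empty label")
    return LungLabel(mask=mask, spacing_mm=ct.spacing_mm, origin_mm=ct.origin_mm)


def grow_volume(
    label: LungLabel, ct: Volume, params: SegmentationParams | None = None
) -> LungLabel:
    """Iterative one-voxel dilation accepting neighbours below +100 HU.

    Monotone (output is a superset of the input); the exclusion threshold
    is a strict upper gate so bone/chest-wall voxels are never admitted.
    """
    params = params or SegmentationParams()
    if label.voxel_count == 0:
        raise ValueError("cannot grow an empty label")
    allowed = np.asarray(ct.data, float) < params.exclusion_threshold_hu
    mask = label.mask.copy()
    for _ in range(params.growth_iterations):
        grown = ndimage.binary_dilation(mask, structure=params.structure)
        mask = mask | (grown & allowed)
    return label.with_mask(mask)


def fill_holes(label: LungLabel) -> LungLabel:
    """Add background components not connected to the volume border (3-D)."""
    if label.voxel_count == 0:
        raise ValueError("cannot fill holes of an empty label")
    return label.with_mask(ndimage.binary_fill_holes(label.mask))


def remove_trachea(
    label: LungLabel, params: SegmentationParams
) -> LungLabel:
    """Remove airway voxels above the cut plane (or inside a user mask).

    With a cut plane, the labelled voxels strictly above it (towards the
    apex per orientation) that belong to a connected component touching
    the plane's airway are removed; used for the ventilation label.
    """
    if params.trachea_mask is not None:
        out = label.mask & ~params.trachea_mask.astype(bool)
        if not out.any():
            raise ValueError("trachea removal emptied the label")
        return label.with_mask(out)
    if params.trachea_cut_index is None:
        raise ValueError("trachea_cut_index or trachea_mask required")
    cut = int(params.trachea_cut_index)
    nz = label.mask.shape[2]
    above = np.zeros_like(label.mask)
    if params.apex_high:
        if cut + 1 < nz:
            above[:, :, cut + 1:] = True
    else:
        if cut > 0:
            above[:, :, :cut] = True
    region = label.mask & above
    if not region.any():
        return label.with_mask(label.mask.copy())
    # above the carina the trachea is a separate midline tube while the
    # lung apices sit laterally: remove only the component nearest the
    # label's transverse centroid
    comp, n = ndimage.label(region, structure=params.structure)
    cx, cy = np.argwhere(label.mask).mean(axis=0)[:2]
    best, best_d = 0, np.inf
    for c in range(1, n + 1):
        idx = np.argwhere(comp == c)
        d = np.hypot(idx[:, 0] - cx, idx[:, 1] - cy).min()
        if d < best_d:
            best, best_d = c, d
    out = label.mask & ~(comp == best)
    if not out.any():
        raise ValueError("trachea removal emptied the label")
    return label.with_mask(out)


def segment_lung(
    ct: Volume,
    seed: tuple[int, int, int] | None = None,
    params: SegmentationParams | None = None,
    downsample: bool = True,
) -> LungLabel:
    """Full recipe: grow, dilate, fill holes, (optionally) cut trachea,
    then pool the mask onto the half-resolution analysis grid.
    """
    if ct.modality != CT:
        raise ValueError("lung segmentation runs on CT volumes")
    params = params or SegmentationParams()
    if seed is None:
        seed = default_seed(ct)
    label = grow_airspace(ct, seed, params)
    label = grow_volume(label, ct, params)
    label = fill_holes(label)
    if params.remove_trachea:
        label = remove_trachea(label, params)
    if label.voxel_count == 0:
        raise ValueError("empty label")
    if downsample:
        label = downsample_mask_half(label)
        if label.voxel_count == 0:
            raise ValueError("empty label after downsampling")
    return label


def qc_metrics(label: LungLabel) -> dict:
    """Automated QC in place of the manual inspection step: connected
    component count and labelled volume, to be range-checked per study."""
    comp, n = ndimage.label(label.mask, structure=_STRUCTS[6])
    sizes = np.bincount(comp.ravel())[1:] if n else np.array([])
    return {
        "n_components": int(n),
        "largest_component_fraction": float(sizes.max() / sizes.sum()) if n else 0.0,
        "voxel_count": label.voxel_count,
        "volume_mL": label.volume_mL,
    }
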