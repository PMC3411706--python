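"""CT densitometry and air-volume quantitation.

Air content is estimated from an HU histogram (default 25 HU/bin) over a
thoracic region of interest: each bin contributes voxel count x air
coefficient x voxel volume, where the air coefficient is the fraction of
air in a voxel of that density — linear from 1 at -1000 HU (pure air) to
0 at 0 HU (water/tissue), clamped outside.  Functional residual capacity
(FRC) is the air volume of the end-expiratory gated CT; tidal volume (TV)
is the inspiratory-minus-expiratory difference.

Bin edges are aligned so a bin centre falls exactly on -500 HU, making
the canonical worked example (air coefficient 0.5 at -500 HU) exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CT, LungLabel, Volume

__all__ = [
    "AirHistogram",
    "air_coefficient",
    "hu_histogram",
    "air_volume",
    "frc_tv",
    "dilated_roi",
]

DEFAULT_BIN_WIDTH_HU = 25.0


def air_coefficient(hu):
    """Fraction of air in a voxel of the given HU: clamp(-HU/1000, 0, 1)."""
    return np.clip(-np.asarray(hu, float) / 1000.0, 0.0, 1.0)


@dataclass
class AirHistogram:
    bin_width_hu: float
    bin_centers: np.ndarray
    voxel_counts: np.ndarray
    air_coefficients: np.ndarray
    voxel_volume_mL: float

    @property
    def total_air_mL(self) -> float:
        return float(
            (self.voxel_counts * self.air_coefficients).sum() * self.voxel_volume_mL
        )

    @property
    def total_voxels(self) -> int:
        return int(self.voxel_counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center_hu": self.bin_centers,
            "count": self.voxel_counts,
            "air_coefficient": self.air_coefficients,
            "air_mL": self.voxel_counts * self.air_coefficients
                      * self.voxel_volume_mL,
        })


def hu_histogram(
    ct: Volume, roi: LungLabel, bin_width: float = DEFAULT_BIN_WIDTH_HU
) -> AirHistogram:
    """Density histogram over the ROI with a bin centred at -500 HU."""
    if ct.modality != CT:
        raise ValueError("densitometry runs on CT volumes")
    if roi.mask.shape != ct.shape:
        raise ValueError("ROI and CT live on different grids")
    if roi.voxel_count == 0:
        raise ValueError("empty ROI")
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    hu = np.asarray(ct.data, float)[roi.mask]
    # edges at -500 - bin/2 + k*bin  ->  one centre exactly at -500
    anchor = -500.0 - bin_width / 2.0
    lo = anchor + np.floor((hu.min() - anchor) / bin_width) * bin_width
    hi = anchor + np.ceil((hu.max() - anchor) / bin_width + 1e-9) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    counts, _ = np.histogram(hu, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return AirHistogram(
        bin_width_hu=float(bin_width),
        bin_centers=centers,
        voxel_counts=counts,
        air_coefficients=air_coefficient(centers),
        voxel_volume_mL=roi.voxel_volume_mL,
    )


def air_volume(h: AirHistogram) -> float:
    """Air volume in mL: sum of count x air coefficient x voxel volume."""
    return h.total_air_mL


def frc_tv(
    exp_ct: Volume,
    insp_ct: Volume,
    roi: LungLabel,
    bin_width: float = DEFAULT_BIN_WIDTH_HU,
) -> tuple[float, float]:
    """FRC from the expiratory image; TV = inspiratory - expiratory air.

    A negative TV is returned as-is with a warning: it signals a gating or
    ROI problem, not a physiological state.
    """
    if exp_ct.shape != insp_ct.shape or exp_ct.spacing_mm != insp_ct.spacing_mm:
        raise ValueError("expiratory and inspiratory CTs live on different grids")
    frc = air_volume(hu_histogram(exp_ct, roi, bin_width))
    insp = air_volume(hu_histogram(insp_ct, roi, bin_width))
    tv = insp - frc
    if frc < roi.voxel_volume_mL:
        warnings.warn("ROI contains essentially no air; check the ROI",
                      stacklevel=2)
    if tv < 0:
        warnings.warn("negative tidal volume; check gating and ROI",
                      stacklevel=2)
    return frc, tv


def dilated_roi(label: LungLabel, dilate_voxels: int = 2) -> LungLabel:
    """Convenience thoracic ROI: the lung label dilated a few voxels.

    The source protocol drew the thoracic cavity manually; a dilated lung
    label is a reproducible stand-in (tissue voxels contribute ~0 air, so
    modest over-inclusion is harmless).
    """
    if dilate_voxels < 0:
        raise ValueError("dilation must be >= 0")
    if dilate_voxels == 0:
        return label
    mask = ndimage.binary_dilation(
        label.mask, structure=ndimage.generate_binary_structure(3, 1),
        iterations=dilate_voxels,
    )
    return label.with_mask(mask)
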