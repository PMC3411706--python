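"""Core volume data model and grid operations.

Everything downstream (segmentation, registration, per-voxel V/Q
quantitation, densitometry) runs on the :class:`Volume` carrier: a 3-D
scalar grid with isotropic voxel spacing, a world origin, and a modality
tag.  CT volumes are expressed in Hounsfield units after calibration
(air = -1000, water = 0); SPECT volumes carry reconstructed counts.

Conventions
-----------
* axis 2 of the array is the axial (cranio-caudal) direction; by default
  the lung apex sits at the high index (configurable per call where it
  matters, see :mod:`vqmouse.regions`).
* voxel centres, 0-based indices; world coordinate of voxel ``i`` is
  ``origin_mm + i * spacing_mm``.  All interface distances are mm.
* rigid transforms map points from the *moving* frame into the *fixed*
  frame; resampling a moving volume onto a fixed grid therefore pulls
  samples through the inverse map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LungLabel",
    "HUCalibration",
    "RigidTransform",
    "Grid",
    "read_volume",
    "write_volume",
    "read_label",
    "write_label",
    "calibrate_hu",
    "gaussian_smooth",
    "downsample_half",
    "downsample_mask_half",
    "resample",
    "sample_at_points",
]

# Module-wide defaults (the spec'd "config" knobs live here).
DEFAULT_FILL = 0.0          # out-of-field value for resampling
CT_FILL = -1000.0           # sensible fill for CT (air)
SPACING_ATOL = 1e-4         # isotropy tolerance, mm
MM3_PER_ML = 1000.0

CT = "CT"
SPECT = "SPECT"


@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel lattice: shape, isotropic spacing and origin."""

    shape: tuple[int, int, int]
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (possibly fractional) voxel indices."""
        return np.asarray(self.origin_mm) + np.asarray(idx, float) * self.spacing_mm

    @property
    def voxel_volume_mL(self) -> float:
        return self.spacing_mm**3 / MM3_PER_ML


@dataclass
class Volume:
    """A 3-D scalar image with isotropic spacing and a modality tag."""

    data: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = CT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D data")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("each grid dimension must be >= 2")
        if not np.isfinite(self.spacing_mm) or self.spacing_mm <= 0:
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if self.modality not in (CT, SPECT):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.origin_mm = tuple(float(x) for x in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, float(self.spacing_mm), self.origin_mm)

    @property
    def voxel_volume_mL(self) -> float:
        return self.spacing_mm**3 / MM3_PER_ML

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class LungLabel:
    """Binary lung mask on a volume's grid; its voxel count is the TLV."""

    mask: np.ndarray
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("label mask must be 3D")
        if self.spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        self.origin_mm = tuple(float(x) for x in self.origin_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mL(self) -> float:
        return self.spacing_mm**3 / MM3_PER_ML

    @property
    def volume_mL(self) -> float:
        return self.voxel_count * self.voxel_volume_mL

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.mask.shape), float(self.spacing_mm), self.origin_mm)

    def centroid_mm(self) -> np.ndarray:
        if self.voxel_count == 0:
            raise ValueError("empty label has no centroid")
        idx = np.argwhere(self.mask).mean(axis=0)
        return np.asarray(self.origin_mm) + idx * self.spacing_mm

    def with_mask(self, mask: np.ndarray) -> "LungLabel":
        return replace(self, mask=mask)


@dataclass
class HUCalibration:
    """Raw-intensity anchors for the linear HU calibration.

    ``air_mean`` and ``water_mean`` are mean raw intensities sampled from an
    empty-airspace ROI and a water tube in the field of view; the ROI choice
    is the caller's (scanner protocols differ), only the two means enter.
    """

    air_mean: float
    water_mean: float

    def __post_init__(self) -> None:
        if self.air_mean == self.water_mean:
            raise ValueError("air and water anchors must differ")

    @classmethod
    def from_json(cls, path: str | Path) -> "HUCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(air_mean=float(d["air_mean"]), water_mean=float(d["water_mean"]))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"air_mean": self.air_mean, "water_mean": self.water_mean}, fh)


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class RigidTransform:
    """6-DOF rigid body motion: 3 translations (mm), 3 rotations (deg).

    The map is ``y = R (x - c) + c + t`` with ``R`` the intrinsic X-then-
    Y-then-Z rotation (``R = Rx @ Ry @ Rz``) about the centre ``c``
    (typically the lung-label centroid).  ``from_frame``/``to_frame`` are
    optional tags used by the registration pipeline to make transform
    composition order violations impossible.
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    from_frame: str | None = None
    to_frame: str | None = None

    # -- parameter vector helpers (order: tx ty tz rx ry rz) --------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], float)

    def with_params(self, p: Sequence[float]) -> "RigidTransform":
        tx, ty, tz, rx, ry, rz = (float(v) for v in p)
        return replace(self, tx=tx, ty=ty, tz=tz, rx=rx, ry=ry, rz=rz)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz], float)

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = np.deg2rad([self.rx, self.ry, self.rz])
        return _rot_x(rx) @ _rot_y(ry) @ _rot_z(rz)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate map (mm)."""
        R = self.rotation_matrix()
        c = np.asarray(self.center_mm, float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + self.translation - R @ c
        return M

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of world points."""
        R = self.rotation_matrix()
        c = np.asarray(self.center_mm, float)
        return (np.asarray(pts, float) - c) @ R.T + c + self.translation

    def inverse(self) -> "RigidTransform":
        Minv = np.linalg.inv(self.matrix())
        return RigidTransform.from_matrix(
            Minv, center_mm=self.center_mm,
            from_frame=self.to_frame, to_frame=self.from_frame,
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``.

        Frame tags must chain (``other.to_frame == self.from_frame``) when
        both are present.
        """
        if (
            self.from_frame is not None
            and other.to_frame is not None
            and self.from_frame != other.to_frame
        ):
            raise ValueError(
                f"cannot compose: inner transform maps to frame "
                f"{other.to_frame!r} but outer expects {self.from_frame!r}"
            )
        M = self.matrix() @ other.matrix()
        return RigidTransform.from_matrix(
            M, center_mm=self.center_mm,
            from_frame=other.from_frame, to_frame=self.to_frame,
        )

    @classmethod
    def from_matrix(
        cls,
        M: np.ndarray,
        center_mm: Sequence[float] = (0.0, 0.0, 0.0),
        from_frame: str | None = None,
        to_frame: str | None = None,
    ) -> "RigidTransform":
        """Recover (t, intrinsic XYZ angles) from a homogeneous rigid map."""
        M = np.asarray(M, float)
        R = M[:3, :3]
        # R = Rx @ Ry @ Rz  =>  R[0,2] = sin(ry)
        ry = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
        if abs(R[0, 2]) < 1.0 - 1e-12:
            rx = np.arctan2(-R[1, 2], R[2, 2])
            rz = np.arctan2(-R[0, 1], R[0, 0])
        else:  # gimbal lock: fold everything into rx
            rx = np.arctan2(R[2, 1], R[1, 1])
            rz = 0.0
        c = np.asarray(center_mm, float)
        t = M[:3, 3] - c + R @ c
        return cls(
            tx=float(t[0]), ty=float(t[1]), tz=float(t[2]),
            rx=float(np.rad2deg(rx)), ry=float(np.rad2deg(ry)),
            rz=float(np.rad2deg(rz)),
            center_mm=tuple(float(x) for x in c),
            from_frame=from_frame, to_frame=to_frame,
        )

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.params, 0.0, atol=atol))

    def to_dict(self) -> dict:
        return {
            "tx_mm": self.tx, "ty_mm": self.ty, "tz_mm": self.tz,
            "rx_deg": self.rx, "ry_deg": self.ry, "rz_deg": self.rz,
            "center_mm": list(self.center_mm),
            "convention": "intrinsic XYZ about center, then translation",
            "from_frame": self.from_frame, "to_frame": self.to_frame,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tx=d["tx_mm"], ty=d["ty_mm"], tz=d["tz_mm"],
            rx=d["rx_deg"], ry=d["ry_deg"], rz=d["rz_deg"],
            center_mm=tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
            from_frame=d.get("from_frame"), to_frame=d.get("to_frame"),
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_for(spacing: float, origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path, modality: str = CT) -> Volume:
    """Read a 3-D NIfTI volume; spacing comes from the header.

    Anisotropic spacing is rejected (every grid in this pipeline is
    isotropic); resample externally first if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    if max(zooms) - min(zooms) > SPACING_ATOL:
        raise ValueError(
            f"anisotropic voxel spacing {zooms} in {path}; "
            "resample to isotropic spacing first"
        )
    origin = img.affine[:3, 3]
    return Volume(
        data=np.asarray(data),
        spacing_mm=float(zooms[0]),
        origin_mm=tuple(float(x) for x in origin),
        modality=modality,
    )


def write_volume(vol: Volume, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_for(vol.spacing_mm, vol.origin_mm))
    img.header.set_zooms((vol.spacing_mm,) * 3)
    nib.save(img, str(path))


def read_label(path: str | Path) -> LungLabel:
    v = read_volume(path, modality=CT)
    return LungLabel(mask=v.data > 0, spacing_mm=v.spacing_mm, origin_mm=v.origin_mm)


def write_label(label: LungLabel, path: str | Path) -> None:
    img = nib.Nifti1Image(
        label.mask.astype(np.uint8), _affine_for(label.spacing_mm, label.origin_mm)
    )
    img.header.set_zooms((label.spacing_mm,) * 3)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Intensity and grid operations
# ---------------------------------------------------------------------------

def calibrate_hu(raw: Volume, cal: HUCalibration) -> Volume:
    """Linear HU calibration sending air_mean -> -1000 and water_mean -> 0."""
    if raw.modality != CT:
        raise ValueError("HU calibration applies to CT volumes only")
    scale = 1000.0 / (cal.water_mean - cal.air_mean)
    data = (np.asarray(raw.data, float) - cal.water_mean) * scale
    return raw.with_data(data)


def gaussian_smooth(v: Volume, sigma_vox: float) -> Volume:
    """Isotropic Gaussian filter; sigma in voxel units (sigma 0 = identity)."""
    if sigma_vox < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_vox == 0:
        return v.with_data(v.data.copy())
    return v.with_data(ndimage.gaussian_filter(np.asarray(v.data, float), sigma_vox))


def downsample_half(v: Volume) -> Volume:
    """2x2x2 block-mean pooling; doubles the spacing, conserves the mean.

    The origin moves by half the old spacing so that new voxel centres sit
    at the centroid of each 2x2x2 block.
    """
    shape = v.shape
    if any(s % 2 for s in shape):
        raise ValueError(f"all dimensions must be even for 2x pooling, got {shape}")
    d = np.asarray(v.data, float)
    pooled = d.reshape(
        shape[0] // 2, 2, shape[1] // 2, 2, shape[2] // 2, 2
    ).mean(axis=(1, 3, 5))
    new_origin = tuple(o + v.spacing_mm / 2.0 for o in v.origin_mm)
    return Volume(
        data=pooled,
        spacing_mm=v.spacing_mm * 2.0,
        origin_mm=new_origin,
        modality=v.modality,
    )


def downsample_mask_half(label: LungLabel, threshold: float = 0.5) -> LungLabel:
    """Block-mean pool a binary mask; keep voxels with block mean >= threshold."""
    as_vol = Volume(
        data=label.mask.astype(float), spacing_mm=label.spacing_mm,
        origin_mm=label.origin_mm, modality=CT,
    )
    pooled = downsample_half(as_vol)
    return LungLabel(
        mask=pooled.data >= threshold,
        spacing_mm=pooled.spacing_mm,
        origin_mm=pooled.origin_mm,
    )


def _conserve_counts(v: Volume) -> bool:
    return v.modality == SPECT


def resample(
    v: Volume,
    t: RigidTransform | None,
    target: Grid | Volume | LungLabel,
    fill: float | None = None,
    conserve_counts: bool | None = None,
) -> Volume:
    """Trilinearly resample ``v`` under rigid map ``t`` onto ``target``'s grid.

    ``t`` maps moving (``v``) world coordinates into the target frame; each
    target voxel pulls its value from ``v`` at ``t^{-1}(x)``.  For SPECT
    count volumes (or ``conserve_counts=True``) values are treated as count
    densities: the interpolated value is scaled by the voxel-volume ratio so
    total activity is approximately conserved across grid changes.
    """
    grid = target.grid if not isinstance(target, Grid) else target
    if any(s < 2 for s in grid.shape):
        raise ValueError("degenerate target grid")
    if fill is None:
        fill = DEFAULT_FILL
    if conserve_counts is None:
        conserve_counts = _conserve_counts(v)
    t = t if t is not None else RigidTransform()

    Minv = np.linalg.inv(t.matrix())
    R, off = Minv[:3, :3], Minv[:3, 3]
    o_t = np.asarray(grid.origin_mm, float)
    o_m = np.asarray(v.origin_mm, float)
    # moving index = (R @ (o_t + s_t * i) + off - o_m) / s_m
    mat = R * (grid.spacing_mm / v.spacing_mm)
    offset = (R @ o_t + off - o_m) / v.spacing_mm
    out = ndimage.affine_transform(
        np.asarray(v.data, float), mat, offset=offset,
        output_shape=grid.shape, order=1, mode="constant", cval=float(fill),
    )
    if conserve_counts:
        out = out * (grid.spacing_mm / v.spacing_mm) ** 3
    return Volume(
        data=out, spacing_mm=grid.spacing_mm,
        origin_mm=grid.origin_mm, modality=v.modality,
    )


def sample_at_points(
    v: Volume, pts_world: np.ndarray, fill: float = np.nan
) -> np.ndarray:
    """Trilinear samples of ``v`` at (N, 3) world points; outside -> fill."""
    idx = (np.asarray(pts_world, float) - np.asarray(v.origin_mm)) / v.spacing_mm
    return ndimage.map_coordinates(
        np.asarray(v.data, float), idx.T, order=1, mode="constant", cval=fill
    )
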