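"""Digital mouse-thorax phantom with known ground truth.

Generates CT and coupled ventilation/perfusion SPECT volumes for an
idealised mouse thorax so that every pipeline stage (segmentation,
registration, per-voxel log(V/Q), regionalization, densitometry) can be
tested against known truth without scanner data.

Geometry
--------
A soft-tissue body ellipsoid (~+40 HU) inside air (-1000 HU) contains two
elongated lung ellipsoids joined by a stylised main-bronchi channel and a
trachea that ends inside the body (the animal is intubated; the airway is
not connected to outside air, which keeps region growing confined).  A
thin dense shell (~+150 HU, chest wall / pleura) surrounds the airspace —
it is this dense boundary that makes the +100 HU exclusion gate of the
segmentation recipe effective.

CT densitometry
---------------
Lung voxels draw HU from a bimodal mixture: smooth parenchyma centred on
``hu_air_peak`` and interior vessel-like blobs centred on
``hu_tissue_peak``.  The tissue weight follows from consistency between
the target FRC and the lung volume, and a final exact shift is solved so
the per-voxel air-fraction sum over the thoracic ROI equals ``frc_mL``
(expiratory) or ``frc_mL + tv_mL`` (inspiratory).

V/Q fields
----------
Perfusion is log-normal in a smooth Gaussian field G; the log10(V/Q)
field is ``sigma * X`` with ``X = rho*G + sqrt(1-rho^2)*H`` (H smooth,
independent), and V = Q * 10^(sigma X).  Because both fields are later
normalized to relative frequencies, the *mean* of finite log(V/Q) is not
a free location parameter — global scalings of V or Q cancel — but is
fixed by the distribution shape and its correlation with Q.  The
generator therefore solves (perfusion heterogeneity ``a``, coupling
``rho``) numerically so that the realized normalized mean and the
per-voxel V-Q Pearson correlation equal the requested values.  Zero-V and
zero-Q defects are placed as contiguous patches at the label periphery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .core import (
    CT,
    SPECT,
    Grid,
    LungLabel,
    RigidTransform,
    Volume,
    resample,
    write_label,
    write_volume,
)
from .densitometry import air_coefficient

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomBundle",
    "build_geometry",
    "generate_ct",
    "generate_vq",
    "misalign",
    "generate_phantom",
    "generate_study",
    "write_phantom",
]


@dataclass
class PhantomSpec:
    """Generator parameters; defaults reproduce a healthy 12-week-old
    mouse study condition (lung ~0.56 mL / ~46k analysis voxels, FRC
    0.124 mL, TV 0.048 mL, log(V/Q) mean -0.071 / SD 0.361, 3.23 % TLV
    unventilated, per-voxel V-Q correlation 0.58, perfusion:ventilation
    total-activity ratio 24.2)."""

    # grid
    shape: tuple[int, int, int] = (88, 88, 128)
    spacing_mm: float = 0.23
    # geometry (mm, relative to the body centre at world origin)
    body_semi_mm: tuple[float, float, float] = (7.6, 7.6, 14.0)
    lung_semi_mm: tuple[float, float, float] = (1.9, 3.3, 10.6)
    lung_offset_mm: tuple[float, float, float] = (3.1, 0.0, 0.0)
    trachea_radius_mm: float = 0.55
    bronchi_radius_mm: float = 0.8
    hilum_z_mm: float = 5.5          # bronchi height above body centre
    trachea_top_mm: float = 11.5     # trachea end (inside the body)
    shell_hu: float = 150.0
    shell_thickness_vox: int = 2
    body_hu: float = 40.0
    # CT densitometry
    hu_air_peak: float = -325.0
    hu_air_sd: float = 70.0
    hu_tissue_peak: float = -25.0
    hu_tissue_sd: float = 70.0
    ct_noise_hu: float = 10.0
    # respiratory states
    frc_mL: float = 0.124
    tv_mL: float = 0.048
    # V/Q distribution
    logvq_mean: float = -0.071
    logvq_sd: float = 0.361
    logvq_skew: float = 0.0          # 0 -> normal log-ratio field
    frac_v_zero: float = 0.0323
    frac_q_zero: float = 0.000012
    vq_pearson_r: float = 0.58
    qv_ratio: float = 24.2
    total_v_counts: float = 1.96e5
    smoothness_vox: float = 2.0
    ct_coupling: float = 0.9         # shared-field weight between CT and Q
    vessel_q_factor: float = 0.12    # activity suppression inside vessels
    spect_blur_vox: float = 1.0      # PSF-like blur applied to study SPECTs
    poisson_noise: bool = False
    # misalignments to be recovered by registration
    spect_misalignment: RigidTransform = field(
        default_factory=lambda: RigidTransform(tx=0.8, ty=-0.5, tz=0.3,
                                               rx=2.0, ry=-1.0, rz=1.5)
    )
    ct_misalignment: RigidTransform = field(
        default_factory=lambda: RigidTransform(tx=-0.4, ty=0.3, tz=-0.2,
                                               rx=-1.0, ry=0.5, rz=-0.8)
    )
    misalignment_bound_mm: float = 2.0
    misalignment_bound_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_v_zero < 1 and 0 <= self.frac_q_zero < 1):
            raise ValueError("defect fractions must lie in [0, 1)")
        if self.frac_v_zero + self.frac_q_zero >= 1:
            raise ValueError("defect fractions must sum below 1")
        if not self.frc_mL > 0:
            raise ValueError("frc_mL must be positive")
        if self.tv_mL < 0:
            raise ValueError("tv_mL must be non-negative")
        for i in range(3):
            if (abs(self.lung_offset_mm[i]) + self.lung_semi_mm[i]
                    > self.body_semi_mm[i]):
                raise ValueError("lungs must fit inside the body ellipsoid")
        if not self.logvq_sd >= 0:
            raise ValueError("logvq_sd must be non-negative")

    @property
    def grid(self) -> Grid:
        origin = tuple(-(s - 1) / 2.0 * self.spacing_mm for s in self.shape)
        return Grid(self.shape, self.spacing_mm, origin)

    @property
    def total_q_counts(self) -> float:
        return self.qv_ratio * self.total_v_counts


@dataclass
class PhantomTruth:
    """Ground truth *measured from the generated voxel data*."""

    label: LungLabel
    thorax_roi: LungLabel
    carina_index: int
    trachea_voxels_above_carina: int
    air_volume_exp_mL: float | None = None
    air_volume_insp_mL: float | None = None
    finite_logvq_mean: float | None = None
    finite_logvq_sd: float | None = None
    finite_logvq_skew: float | None = None
    pct_neg_inf: float | None = None
    pct_pos_inf: float | None = None
    pct_both_zero: float | None = None
    vq_pearson_r: float | None = None
    spect_misalignment: RigidTransform | None = None
    ct_misalignment: RigidTransform | None = None
    solved_perfusion_heterogeneity: float | None = None
    solved_coupling_rho: float | None = None

    def to_json_dict(self) -> dict:
        d = {
            "label_voxel_count": self.label.voxel_count,
            "label_volume_mL": self.label.volume_mL,
            "carina_index": self.carina_index,
            "air_volume_exp_mL": self.air_volume_exp_mL,
            "air_volume_insp_mL": self.air_volume_insp_mL,
            "finite_logvq_mean": self.finite_logvq_mean,
            "finite_logvq_sd": self.finite_logvq_sd,
            "finite_logvq_skew": self.finite_logvq_skew,
            "pct_neg_inf": self.pct_neg_inf,
            "pct_pos_inf": self.pct_pos_inf,
            "pct_both_zero": self.pct_both_zero,
            "vq_pearson_r": self.vq_pearson_r,
        }
        if self.spect_misalignment is not None:
            d["spect_misalignment"] = self.spect_misalignment.to_dict()
        if self.ct_misalignment is not None:
            d["ct_misalignment"] = self.ct_misalignment.to_dict()
        return d


@dataclass
class PhantomBundle:
    """Aligned phantom volumes plus truth (see :func:`generate_phantom`)."""

    ct_exp: Volume
    ct_insp: Volume
    vent: Volume
    perf: Volume
    label: LungLabel
    truth: PhantomTruth


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _world_coords(grid: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [grid.origin_mm[i] + np.arange(grid.shape[i]) * grid.spacing_mm
            for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xyz, center, semi) -> np.ndarray:
    x, y, z = xyz
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def build_geometry(spec: PhantomSpec) -> dict:
    """Boolean masks for every anatomical compartment on the phantom grid."""
    grid = spec.grid
    xyz = _world_coords(grid)
    x, y, z = xyz
    body = _ellipsoid(xyz, (0, 0, 0), spec.body_semi_mm)
    dx, dy, dz = spec.lung_offset_mm
    lung_r = _ellipsoid(xyz, (dx, dy, dz), spec.lung_semi_mm)
    lung_l = _ellipsoid(xyz, (-dx, dy, dz), spec.lung_semi_mm)
    lungs = lung_r | lung_l
    # stylised main bronchi: a horizontal channel joining the lungs
    bronchi = (
        (np.hypot(y, z - spec.hilum_z_mm) <= spec.bronchi_radius_mm)
        & (np.abs(x) <= abs(dx))
        & ~lungs
    )
    trachea = (
        (np.hypot(x, y) <= spec.trachea_radius_mm)
        & (z > spec.hilum_z_mm)
        & (z <= spec.trachea_top_mm)
    )
    label_mask = lungs | bronchi
    airspace = label_mask | trachea
    # the airspace (plus its dense shell) must sit strictly inside the
    # body, otherwise region growing would leak into outside air
    clearance = ndimage.binary_dilation(
        airspace, ndimage.generate_binary_structure(3, 1),
        iterations=spec.shell_thickness_vox + 1,
    )
    if (clearance & ~body).any():
        raise ValueError("lungs/airways too close to the body surface")
    shell = (
        ndimage.binary_dilation(
            airspace, ndimage.generate_binary_structure(3, 1),
            iterations=spec.shell_thickness_vox,
        )
        & ~airspace
    )
    carina_z = spec.hilum_z_mm + spec.bronchi_radius_mm
    carina_index = int(round((carina_z - grid.origin_mm[2]) / grid.spacing_mm))
    thorax = ndimage.binary_dilation(
        airspace, ndimage.generate_binary_structure(3, 1), iterations=2
    )
    nz = grid.shape[2]
    above = np.zeros_like(trachea)
    above[:, :, min(carina_index + 1, nz):] = True
    return {
        "grid": grid,
        "body": body,
        "lungs": lungs,
        "bronchi": bronchi,
        "trachea": trachea,
        "label": label_mask,
        "airspace": airspace,
        "shell": shell,
        "thorax": thorax,
        "carina_index": carina_index,
        "trachea_above_carina": int((trachea & above).sum()),
    }


def _smooth_standard_field(
    shape, smoothness_vox: float, rng: np.random.Generator,
    norm_mask: np.ndarray,
) -> np.ndarray:
    """Gaussian-filtered white noise, standardized over ``norm_mask``."""
    f = rng.standard_normal(shape)
    if smoothness_vox > 0:
        f = ndimage.gaussian_filter(f, smoothness_vox)
    mu = f[norm_mask].mean()
    sd = f[norm_mask].std()
    return (f - mu) / sd


# ---------------------------------------------------------------------------
# CT generation
# ---------------------------------------------------------------------------

def _exact_air_mL(hu: np.ndarray, roi: np.ndarray, voxel_mL: float) -> float:
    return float(air_coefficient(hu[roi]).sum() * voxel_mL)


def draw_vessels(
    spec: PhantomSpec, geo: dict, rng: np.random.Generator
) -> np.ndarray:
    """Interior vessel-like tissue blobs.

    Their total volume share follows from FRC / lung-volume consistency at
    the stated expiratory density peaks, and each blob keeps a 2-voxel
    clearance from the lung surface so hole filling recovers it, as it
    does for real vessels.  Vessels are a fixed anatomical structure: the
    same mask serves both respiratory states and the V/Q generator.
    """
    grid = geo["grid"]
    lung = geo["label"]
    n_lung = int(lung.sum())
    voxel_mL = grid.voxel_volume_mL
    trachea_air = spec.trachea_radius_mm  # placeholder, replaced below
    # expiratory target defines the anatomy
    hu_trachea = np.full(int(geo["trachea"].sum()), -980.0)
    trachea_air = float(air_coefficient(hu_trachea).sum() * voxel_mL)
    mean_airfrac = (spec.frc_mL - trachea_air) / (n_lung * voxel_mL)
    frac_air_peak = air_coefficient(spec.hu_air_peak)
    frac_tis_peak = air_coefficient(spec.hu_tissue_peak)
    if not (frac_tis_peak < mean_airfrac < frac_air_peak):
        raise ValueError(
            f"FRC {spec.frc_mL} mL requires a mean lung air fraction of "
            f"{mean_airfrac:.3f}, outside the density-peak range"
        )
    w_tissue = (frac_air_peak - mean_airfrac) / (frac_air_peak - frac_tis_peak)

    interior = ndimage.binary_erosion(
        lung, ndimage.generate_binary_structure(3, 1), iterations=1
    )
    dt = ndimage.distance_transform_cdt(lung, metric="taxicab")
    tissue = np.zeros(grid.shape, bool)
    target_tissue = int(round(w_tissue * n_lung))
    cand = np.argwhere(interior & (dt >= 4))
    order = rng.permutation(len(cand))
    gx, gy, gz = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
    k = 0
    while tissue.sum() < target_tissue and k < len(order):
        c = cand[order[k]]
        r = min(rng.uniform(2.0, 5.0), float(dt[tuple(c)]) - 2.0)
        ball = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) <= r * r
        tissue |= ball & interior
        k += 1
    excess = int(tissue.sum()) - target_tissue
    if excess > 0:
        idx = np.argwhere(tissue)
        drop = idx[rng.permutation(len(idx))[:excess]]
        tissue[tuple(drop.T)] = False
    return tissue


def generate_ct(
    spec: PhantomSpec,
    state: str = "expiratory",
    rng: np.random.Generator | None = None,
    geometry: dict | None = None,
    texture_field: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
) -> tuple[Volume, PhantomTruth]:
    """Synthesize a CT for one respiratory state.

    Lung HU draw from the bimodal parenchyma/vessel mixture, then a global
    shift on lung voxels is solved so the exact per-voxel air-fraction sum
    over the thoracic ROI equals ``frc_mL`` (expiratory) or
    ``frc_mL + tv_mL`` (inspiratory).  The returned truth records the
    realized air volume measured from the final voxel values.
    """
    if state not in ("expiratory", "inspiratory"):
        raise ValueError("state must be 'expiratory' or 'inspiratory'")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    geo = geometry if geometry is not None else build_geometry(spec)
    grid = geo["grid"]
    voxel_mL = grid.voxel_volume_mL
    lung = geo["label"]

    target_air = spec.frc_mL + (spec.tv_mL if state == "inspiratory" else 0.0)

    hu = np.full(grid.shape, -1000.0)
    hu[geo["body"]] = spec.body_hu
    hu[geo["shell"]] = spec.shell_hu
    hu[geo["trachea"]] = -980.0

    tissue = vessel_mask if vessel_mask is not None else \
        draw_vessels(spec, geo, rng)
    parenchyma = lung & ~tissue
    if texture_field is None:
        texture_field = _smooth_standard_field(
            grid.shape, spec.smoothness_vox, rng, lung
        )
    # each component mixes the shared smooth texture with white noise in a
    # unit-variance combination so the stated spread is the component SD
    white = rng.standard_normal(grid.shape)
    hu[parenchyma] = (
        spec.hu_air_peak
        + spec.hu_air_sd * (0.85 * texture_field[parenchyma]
                            + 0.53 * white[parenchyma])
    )
    hu[tissue] = (
        spec.hu_tissue_peak
        + spec.hu_tissue_sd * (0.85 * texture_field[tissue]
                               + 0.53 * white[tissue])
    )
    if spec.ct_noise_hu > 0:
        hu[lung] += spec.ct_noise_hu * rng.standard_normal(int(lung.sum()))

    # exact air-volume shift on lung voxels (monotone in the shift)
    roi = geo["thorax"]

    def air_err(shift: float) -> float:
        trial = hu.copy()
        trial[lung] = hu[lung] + shift
        return _exact_air_mL(trial, roi, voxel_mL) - target_air

    lo, hi = -900.0, 900.0
    if air_err(lo) * air_err(hi) > 0:
        raise ValueError("target air volume infeasible for this geometry")
    shift = brentq(air_err, lo, hi, xtol=1e-6)
    hu[lung] += shift
    if not (-1000.0 < spec.hu_air_peak + shift < 0.0):
        raise ValueError("required mean lung HU outside (-1000, 0)")

    vol = Volume(data=hu, spacing_mm=grid.spacing_mm,
                 origin_mm=grid.origin_mm, modality=CT)
    truth = PhantomTruth(
        label=LungLabel(geo["label"], grid.spacing_mm, grid.origin_mm),
        thorax_roi=LungLabel(roi, grid.spacing_mm, grid.origin_mm),
        carina_index=geo["carina_index"],
        trachea_voxels_above_carina=geo["trachea_above_carina"],
    )
    realized = _exact_air_mL(hu, roi, voxel_mL)
    if state == "expiratory":
        truth.air_volume_exp_mL = realized
    else:
        truth.air_volume_insp_mL = realized
    return vol, truth


# ---------------------------------------------------------------------------
# V/Q generation
# ---------------------------------------------------------------------------

def _skewed_component(
    base: np.ndarray, skew_target: float
) -> np.ndarray:
    """Map a standard-normal field to a standardized reversed-lognormal one
    with (approximately) the requested negative skewness."""
    if skew_target == 0:
        return base
    if skew_target > 0:
        raise ValueError("only zero or negative skew targets are supported")
    # lognormal skew: (w + 2) sqrt(w - 1), w = exp(s^2); solve for w
    g = abs(skew_target)
    w = brentq(lambda w: (w + 2) * np.sqrt(w - 1) - g, 1.0 + 1e-9, 20.0)
    s = np.sqrt(np.log(w))
    y = np.exp(s * base)
    y = -(y - y.mean()) / y.std()
    return y


def generate_vq(
    spec: PhantomSpec,
    label: LungLabel,
    rng: np.random.Generator | None = None,
    ct_texture_field: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
) -> tuple[Volume, Volume, PhantomTruth]:
    """Coupled ventilation/perfusion count fields over the label.

    Solves the perfusion heterogeneity ``a`` and the coupling ``rho`` so
    that the *normalized* finite log(V/Q) mean equals ``logvq_mean`` and
    the per-voxel Pearson correlation equals ``vq_pearson_r`` (see module
    docstring for why the mean is shape-determined).  The realized
    statistics are recorded in the returned truth from the generated voxel
    data.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    m = label.mask
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty label")
    n_v0 = int(round(spec.frac_v_zero * n))
    n_q0 = int(round(spec.frac_q_zero * n))
    if n_v0 + n_q0 >= n - 2:
        raise ValueError("label too small for the requested defect fractions")

    shape = m.shape
    G0 = _smooth_standard_field(shape, spec.smoothness_vox, rng, m)
    H0 = _smooth_standard_field(shape, spec.smoothness_vox, rng, m)
    defect_noise = _smooth_standard_field(shape, spec.smoothness_vox, rng, m)
    if ct_texture_field is None:
        ct_texture_field = _smooth_standard_field(
            shape, spec.smoothness_vox, rng, m
        )
    beta = spec.ct_coupling
    G = beta * ct_texture_field + np.sqrt(1 - beta**2) * G0
    G = (G - G[m].mean()) / G[m].std()

    # peripheral defect placement: lowest (depth + noise) score first
    dt = ndimage.distance_transform_cdt(m, metric="taxicab").astype(float)
    score = dt[m] + 0.8 * defect_noise[m]
    order = np.argsort(score, kind="stable")
    flat_v0 = order[:n_v0]
    flat_q0 = order[n_v0:n_v0 + n_q0]
    is_v0 = np.zeros(n, bool)
    is_v0[flat_v0] = True
    is_q0 = np.zeros(n, bool)
    is_q0[flat_q0] = True
    finite = ~(is_v0 | is_q0)

    g = G[m]
    h = _skewed_component(H0[m], spec.logvq_skew)
    h = (h - h[finite].mean()) / h[finite].std()
    sigma = spec.logvq_sd
    # vessels carry neither alveoli nor trapped tracer: both V and Q are
    # suppressed there by the same factor, which leaves log(V/Q) untouched
    vess = vessel_mask[m] if vessel_mask is not None else np.zeros(n, bool)

    def build(a: float, rho: float):
        q = np.exp(a * g)
        q[vess] *= spec.vessel_q_factor
        x = rho * g + np.sqrt(max(1 - rho**2, 0.0)) * h
        x = (x - x[finite].mean()) / x[finite].std() if sigma > 0 else x * 0
        lf = sigma * x
        v = q * np.power(10.0, lf)
        v[is_v0] = 0.0
        if n_q0:
            v[is_q0] = np.median(v[finite])
        qd = q.copy()
        qd[is_q0] = 0.0
        return v, qd, lf

    def normalized_mean(a: float, rho: float) -> float:
        v, qd, lf = build(a, rho)
        # mean over finite voxels of log10(v_rel/q_rel)
        return float(
            lf[finite].mean() + np.log10(qd.sum()) - np.log10(v.sum())
        )

    def pearson(a: float, rho: float) -> float:
        v, qd, _ = build(a, rho)
        return float(np.corrcoef(v, qd)[0, 1])

    if sigma == 0:
        a_sol, rho_sol = 0.5, 0.0
    else:
        def solve_rho(a: float) -> float:
            f = lambda r: normalized_mean(a, r) - spec.logvq_mean
            lo, hi = -0.99, 0.99
            if f(lo) * f(hi) > 0:
                # mean target unreachable at this heterogeneity; return the
                # nearer bound so the outer solve moves a away from here
                return lo if abs(f(lo)) < abs(f(hi)) else hi
            return brentq(f, lo, hi, xtol=1e-6)

        def r_err(a: float) -> float:
            return pearson(a, solve_rho(a)) - spec.vq_pearson_r

        # coarse scan then bisection on the leftmost crossing: R(a) is
        # close to monotone but noisy at extreme heterogeneity, so a wide
        # blind bracket can latch onto spurious far roots
        grid_a = np.arange(0.3, 2.41, 0.15)
        errs = [r_err(a) for a in grid_a]
        a_sol = None
        for k in range(len(grid_a) - 1):
            if errs[k] == 0 or errs[k] * errs[k + 1] < 0:
                a_sol = brentq(r_err, grid_a[k], grid_a[k + 1], xtol=1e-5)
                break
        if a_sol is None:
            k = int(np.argmin(np.abs(errs)))
            if abs(errs[k]) > 0.02:
                raise ValueError(
                    "requested log(V/Q) mean/SD and V-Q correlation are "
                    "jointly infeasible for this label"
                )
            a_sol = float(grid_a[k])
        rho_sol = solve_rho(a_sol)

    v, qd, lf = build(a_sol, rho_sol)
    v = v * (spec.total_v_counts / v.sum())
    qd = qd * (spec.total_q_counts / qd.sum())

    # realized truth, measured from the generated (pre-noise) voxel data
    v_rel = v / v.sum()
    q_rel = qd / qd.sum()
    fin = (v_rel > 0) & (q_rel > 0)
    lv = np.log10(v_rel[fin] / q_rel[fin])
    d = lv - lv.mean()
    truth = PhantomTruth(
        label=label,
        thorax_roi=label,
        carina_index=-1,
        trachea_voxels_above_carina=0,
        finite_logvq_mean=float(lv.mean()),
        finite_logvq_sd=float(lv.std()),
        finite_logvq_skew=float((d**3).mean() / lv.std() ** 3),
        pct_neg_inf=100.0 * float(((v_rel == 0) & (q_rel > 0)).sum()) / n,
        pct_pos_inf=100.0 * float(((q_rel == 0) & (v_rel > 0)).sum()) / n,
        pct_both_zero=100.0 * float(((q_rel == 0) & (v_rel == 0)).sum()) / n,
        vq_pearson_r=float(np.corrcoef(v, qd)[0, 1]),
        solved_perfusion_heterogeneity=float(a_sol),
        solved_coupling_rho=float(rho_sol),
    )

    if spec.poisson_noise:
        v = rng.poisson(v).astype(float)
        qd = rng.poisson(qd).astype(float)

    V = np.zeros(shape)
    Q = np.zeros(shape)
    V[m] = v
    Q[m] = qd
    mk = lambda d: Volume(data=d, spacing_mm=label.spacing_mm,
                          origin_mm=label.origin_mm, modality=SPECT)
    return mk(V), mk(Q), truth


# ---------------------------------------------------------------------------
# misalignment and study assembly
# ---------------------------------------------------------------------------

def misalign(
    v: Volume,
    transform: RigidTransform,
    spec: PhantomSpec | None = None,
    fill: float | None = None,
) -> Volume:
    """Resample a volume under a known rigid motion (ground truth for the
    registration recovery tests)."""
    bound_t = spec.misalignment_bound_mm if spec else 2.0
    bound_r = spec.misalignment_bound_deg if spec else 10.0
    p = transform.params
    if np.any(np.abs(p[:3]) > bound_t) or np.any(np.abs(p[3:]) > bound_r):
        raise ValueError(
            f"misalignment {p} exceeds bounds "
            f"(|t| <= {bound_t} mm, |theta| <= {bound_r} deg)"
        )
    if transform.is_identity():
        return v.with_data(v.data.copy())
    if fill is None:
        fill = -1000.0 if v.modality == CT else 0.0
    return resample(v, transform, v, fill=fill)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Aligned phantom: expiratory/inspiratory CT, V and Q, label, truth."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    geo = build_geometry(spec)
    grid = geo["grid"]
    texture = _smooth_standard_field(
        grid.shape, spec.smoothness_vox, rng, geo["label"]
    )
    vessels = draw_vessels(spec, geo, rng)
    ct_exp, truth = generate_ct(spec, "expiratory", rng, geo, texture, vessels)
    ct_insp, truth_i = generate_ct(spec, "inspiratory", rng, geo, texture,
                                   vessels)
    truth.air_volume_insp_mL = truth_i.air_volume_insp_mL
    vent, perf, truth_vq = generate_vq(spec, truth.label, rng, texture,
                                       vessels)
    for f in ("finite_logvq_mean", "finite_logvq_sd", "finite_logvq_skew",
              "pct_neg_inf", "pct_pos_inf", "pct_both_zero", "vq_pearson_r",
              "solved_perfusion_heterogeneity", "solved_coupling_rho"):
        setattr(truth, f, getattr(truth_vq, f))
    truth.spect_misalignment = spec.spect_misalignment
    truth.ct_misalignment = spec.ct_misalignment
    return PhantomBundle(ct_exp=ct_exp, ct_insp=ct_insp, vent=vent,
                         perf=perf, label=truth.label, truth=truth)


def generate_study(spec: PhantomSpec | None = None) -> dict:
    """Misaligned four-volume study for end-to-end registration tests.

    The ventilation CT defines the anatomy frame.  Both SPECT scans are
    offset from their CT by ``spect_misalignment`` (the animal does not
    move between a SPECT scan and the adjacent CT); the perfusion pair is
    additionally offset by ``ct_misalignment``.
    """
    spec = spec or PhantomSpec()
    bundle = generate_phantom(spec)
    t_s = spec.spect_misalignment
    t_c = spec.ct_misalignment
    t_cs = t_c.compose(t_s)

    def blur(v: Volume) -> Volume:
        # reconstructed SPECT is PSF-limited: activity decays smoothly
        # across the lung boundary instead of stopping at the label edge
        if spec.spect_blur_vox <= 0:
            return v
        return v.with_data(ndimage.gaussian_filter(v.data, spec.spect_blur_vox))

    vent_s = blur(bundle.vent)
    perf_s = blur(bundle.perf)
    return {
        "vent_ct": bundle.ct_exp,
        "perf_ct": misalign(bundle.ct_exp, t_c, spec, fill=-1000.0),
        "vent_spect": misalign(vent_s, t_s, spec, fill=0.0),
        "perf_spect": misalign(perf_s, t_cs, spec, fill=0.0),
        "vent_spect_aligned": vent_s,
        "perf_spect_aligned": perf_s,
        "bundle": bundle,
        "truth": bundle.truth,
    }


def write_study(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write a misaligned four-volume study (plus gated CTs, label and
    truth) ready for the end-to-end pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = generate_study(spec)
    b = study["bundle"]
    paths = {}
    for name, vol in [("vent_ct", study["vent_ct"]),
                      ("perf_ct", study["perf_ct"]),
                      ("vent_spect", study["vent_spect"]),
                      ("perf_spect", study["perf_spect"]),
                      ("exp_ct", b.ct_exp), ("insp_ct", b.ct_insp)]:
        p = out / f"{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = str(p)
    p = out / "label.nii.gz"
    write_label(b.label, p)
    paths["label"] = str(p)
    tp = out / "truth.json"
    with open(tp, "w") as fh:
        json.dump(b.truth.to_json_dict(), fh, indent=2)
    paths["truth"] = str(tp)
    return paths


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write ct_exp/ct_insp/vent/perf/label NIfTI files plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = generate_phantom(spec)
    paths = {}
    for name, vol in [("ct_exp", b.ct_exp), ("ct_insp", b.ct_insp),
                      ("vent", b.vent), ("perf", b.perf)]:
        p = out / f"{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = str(p)
    p = out / "label.nii.gz"
    write_label(b.label, p)
    paths["label"] = str(p)
    tp = out / "truth.json"
    with open(tp, "w") as fh:
        json.dump(b.truth.to_json_dict(), fh, indent=2)
    paths["truth"] = str(tp)
    return paths
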