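"""Study-level orchestration: manifest-driven end-to-end runs.

A study manifest (YAML or dict) lists one subject's four reconstructed
volumes (ventilation/perfusion CT and SPECT), optional respiratory-gated
CTs, calibration, parameters and an output directory.  ``run_study``
executes segment -> register -> log(V/Q) -> regions -> air volumes and
writes a reproducible report bundle; ``aggregate`` combines per-subject
summaries into a cohort table (mean +/- SEM), honouring an explicit
exclusion list.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    HUCalibration,
    LungLabel,
    Volume,
    calibrate_hu,
    downsample_half,
    gaussian_smooth,
    read_label,
    read_volume,
    write_label,
    write_volume,
)
from .densitometry import dilated_roi, frc_tv, hu_histogram
from .regions import axial_thirds, inner_outer, regional_summary
from .registration import MIConfig, transfer_and_coregister
from .segmentation import SegmentationParams, qc_metrics, segment_lung
from .vqstats import (
    ReferenceStats,
    compute_log_vq,
    histogram,
    normalize_activity,
    summarize,
)

__all__ = ["StudyManifest", "run_study", "aggregate"]

log = logging.getLogger("vqmouse")

_REQUIRED = ("vent_ct", "perf_ct", "vent_spect", "perf_spect")


@dataclass
class StudyManifest:
    """One subject's inputs and processing options."""

    vent_ct: str
    perf_ct: str
    vent_spect: str
    perf_spect: str
    out_dir: str
    exp_ct: str | None = None
    insp_ct: str | None = None
    calibration: str | None = None        # JSON with air_mean/water_mean
    reference_stats: str | None = None    # JSON with ref_mean/ref_sd
    roi: str | None = None                # thoracic ROI for air volumes
    presmooth_sigma_vox: float = 0.8
    downsample_ct: bool = False           # full-resolution CT -> half grid
    seg: dict = field(default_factory=dict)
    mi: dict = field(default_factory=dict)
    hist_bin_width: float = 0.05
    hu_bin_width: float = 25.0
    roi_dilate_voxels: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        missing = [k for k in (*_REQUIRED, "out_dir") if k not in d]
        if missing:
            raise ValueError(f"manifest missing required fields: {missing}")
        return cls(**d)

    def validate(self) -> None:
        for k in _REQUIRED:
            p = getattr(self, k)
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest field {k!r}: {p} not found")


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"[{name}] {e}") from e
        return wrapper
    return deco


def run_study(manifest: StudyManifest | str | Path) -> dict:
    """Execute the full pipeline for one subject; returns the report dict.

    Outputs in ``out_dir``: summary.json, regions.tsv, hist.tsv,
    airvol.json (when gated CTs are given), transforms.json, label.nii.gz,
    qc.json and run.log.  Any stage failure aborts with a stage-tagged
    error; outputs written before the failure are retained.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = StudyManifest.from_yaml(manifest)
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        return _run_study_inner(manifest, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_study_inner(manifest: StudyManifest, out: Path) -> dict:
    log.info("vqmouse %s on %s; seed=%d", __version__,
             platform.platform(), manifest.seed)

    @_stage("load")
    def load():
        cal = (HUCalibration.from_json(manifest.calibration)
               if manifest.calibration else None)

        def load_ct(p):
            v = read_volume(p, modality="CT")
            if cal is not None:
                v = calibrate_hu(v, cal)
            return v

        vols = {
            "vent_ct": load_ct(manifest.vent_ct),
            "perf_ct": load_ct(manifest.perf_ct),
            "vent_spect": read_volume(manifest.vent_spect, modality="SPECT"),
            "perf_spect": read_volume(manifest.perf_spect, modality="SPECT"),
        }
        if manifest.exp_ct and manifest.insp_ct:
            vols["exp_ct"] = load_ct(manifest.exp_ct)
            vols["insp_ct"] = load_ct(manifest.insp_ct)
        return vols

    vols = load()

    @_stage("preprocess")
    def preprocess():
        for k in ("vent_ct", "perf_ct"):
            v = gaussian_smooth(vols[k], manifest.presmooth_sigma_vox)
            if manifest.downsample_ct:
                v = downsample_half(v)
            vols[k] = v

    preprocess()

    @_stage("segment")
    def segment():
        params = SegmentationParams(**manifest.seg) if manifest.seg \
            else SegmentationParams()
        label = segment_lung(vols["vent_ct"], params=params,
                             downsample=manifest.downsample_ct)
        qc = qc_metrics(label)
        log.info("segmentation QC: %s", qc)
        with open(out / "qc.json", "w") as f:
            json.dump(qc, f, indent=2)
        write_label(label, out / "label.nii.gz")
        return label

    label = segment()
    if manifest.downsample_ct:
        # the label was pooled to the analysis grid inside segment_lung;
        # the CTs must follow for the registration stage
        vols["vent_ct"] = downsample_half(vols["vent_ct"])
        vols["perf_ct"] = downsample_half(vols["perf_ct"])

    @_stage("register")
    def register():
        cfg = MIConfig(**manifest.mi) if manifest.mi else MIConfig()
        res = transfer_and_coregister(
            vols["vent_ct"], vols["perf_ct"],
            vols["vent_spect"], vols["perf_spect"], label, cfg=cfg,
        )
        with open(out / "transforms.json", "w") as f:
            json.dump({
                "spect_to_ct": res["t_spect"].to_dict(),
                "perf_ct_to_vent_ct": res["t_ct"].to_dict(),
                "perf_spect_composed": res["t_perf_composed"].to_dict(),
                "converged": res["converged"],
                "mi_traces": res["mi_traces"],
            }, f, indent=2)
        return res

    reg = register()

    @_stage("vqstats")
    def vq_stats():
        v_raw, q_raw = reg["V"], reg["Q"]
        v_rel = normalize_activity(v_raw, label)
        q_rel = normalize_activity(q_raw, label)
        res = compute_log_vq(
            v_rel, q_rel, label,
            v_raw_total=float(v_raw.data[label.mask].sum()),
            q_raw_total=float(q_raw.data[label.mask].sum()),
        )
        ref = None
        if manifest.reference_stats:
            with open(manifest.reference_stats) as f:
                d = json.load(f)
            ref = ReferenceStats(ref_mean=d["ref_mean"], ref_sd=d["ref_sd"])
        summ = summarize(res, ref)
        d = summ.to_dict()
        d["Q:V Ratio"] = res.qv_total_ratio
        histogram(res, manifest.hist_bin_width).to_csv(
            out / "hist.tsv", sep="\t", index=False
        )
        return res, summ, d, ref

    res, summ, summary_dict, ref = vq_stats()

    @_stage("regions")
    def regions():
        frames = []
        for name, part in [("thirds", axial_thirds(label)),
                           ("shells", inner_outer(label))]:
            df = regional_summary(res, part, ref)
            df.insert(0, "partition", name)
            frames.append(df)
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(out / "regions.tsv", sep="\t", index=False)
        return table

    regions()

    airvol = None
    if "exp_ct" in vols:
        @_stage("airvol")
        def air():
            roi = (read_label(manifest.roi) if manifest.roi
                   else dilated_roi(label, manifest.roi_dilate_voxels))
            frc, tv = frc_tv(vols["exp_ct"], vols["insp_ct"], roi,
                             manifest.hu_bin_width)
            d = {"FRC_mL": frc, "TV_mL": tv,
                 "bin_width_hu": manifest.hu_bin_width}
            h = hu_histogram(vols["exp_ct"], roi, manifest.hu_bin_width)
            h.to_frame().to_csv(out / "airvol_hist.tsv", sep="\t",
                                index=False)
            with open(out / "airvol.json", "w") as f:
                json.dump(d, f, indent=2)
            return d

        airvol = air()
        summary_dict["Functional Residual Capacity (mL)"] = airvol["FRC_mL"]
        summary_dict["Tidal Volume (mL)"] = airvol["TV_mL"]

    summary_dict["provenance"] = {
        "vqmouse_version": __version__,
        "seed": manifest.seed,
        "manifest": {k: v for k, v in vars(manifest).items()},
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary_dict, f, indent=2, sort_keys=True)
    log.info("study complete: %s", out / "summary.json")
    return summary_dict


def aggregate(
    summaries: list[dict | str | Path],
    exclude: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Cohort table: mean and SEM per numeric metric across subjects.

    ``exclude`` maps subject indices (into ``summaries``) to a stated
    reason; exclusions are logged, never automatic.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    loaded = []
    for s in summaries:
        if not isinstance(s, dict):
            with open(s) as f:
                s = json.load(f)
        loaded.append(s)
    exclude = exclude or {}
    for idx, reason in exclude.items():
        log.info("excluding subject %d: %s", idx, reason)
    kept = [s for i, s in enumerate(loaded) if i not in exclude]
    if not kept:
        raise ValueError("all subjects excluded")
    keys = [k for k, v in kept[0].items() if isinstance(v, (int, float))
            and v is not None]
    for s in kept[1:]:
        miss = [k for k in keys if not isinstance(s.get(k), (int, float))]
        if miss:
            raise ValueError(f"inconsistent metric sets across subjects: {miss}")
    rows = []
    for k in keys:
        vals = np.array([float(s[k]) for s in kept])
        n = len(vals)
        rows.append({
            "metric": k,
            "n": n,
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        })
    return pd.DataFrame(rows)
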