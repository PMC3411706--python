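"""Per-voxel log(V/Q) quantitation.

Ventilation and perfusion counts are converted to relative frequencies
(percent of total activity within the lung label), so every result is
invariant to the absolute injected/inhaled activity — in the source data
perfusion totals exceed ventilation totals by a factor of ~24 and this
must not matter.  The per-voxel ratio is reported as log10(V/Q):

* both activities positive      -> finite log10(v_rel / q_rel)
* V = 0, Q > 0                  -> category -inf (unventilated)
* Q = 0, V > 0                  -> category +inf (unperfused)
* both zero                     -> category both_zero, display value 0

Distribution moments (mean, SD, skewness, excess kurtosis) are computed
over finite voxels only; mismatch is the percentage of total lung volume
(TLV) beyond +/- 2 reference standard deviations from the reference mean,
with the corresponding infinity category added for the "total" figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import LungLabel, Volume

__all__ = [
    "Category",
    "LogVQResult",
    "ReferenceStats",
    "VQSummary",
    "normalize_activity",
    "compute_log_vq",
    "summarize",
    "histogram",
    "voxel_correlation",
]


class Category(IntEnum):
    OUTSIDE = -1
    FINITE = 0
    NEG_INF = 1   # V = 0, Q > 0
    POS_INF = 2   # Q = 0, V > 0
    BOTH_ZERO = 3


@dataclass
class ReferenceStats:
    """Reference ("averaged") mean/SD defining the mismatch thresholds.

    In a cohort analysis these come from the group average (e.g. the young
    cohort), so that an aged or diseased subject is judged against healthy
    thresholds; self-referenced thresholds are the fallback.
    """

    ref_mean: float
    ref_sd: float

    def __post_init__(self) -> None:
        if not self.ref_sd > 0:
            raise ValueError("reference SD must be positive")

    @property
    def low_threshold(self) -> float:
        return self.ref_mean - 2.0 * self.ref_sd

    @property
    def high_threshold(self) -> float:
        return self.ref_mean + 2.0 * self.ref_sd


@dataclass
class LogVQResult:
    """Per-voxel log10(V/Q) field with category map and normalized inputs."""

    logvq: np.ndarray          # finite values; 0 stored for special voxels
    category: np.ndarray       # Category codes; OUTSIDE off-label
    v_rel: np.ndarray          # % of total V activity per voxel (0 off-label)
    q_rel: np.ndarray
    label: LungLabel
    qv_total_ratio: float      # raw total Q / total V inside the label

    @property
    def finite_mask(self) -> np.ndarray:
        return self.category == Category.FINITE

    @property
    def finite_values(self) -> np.ndarray:
        return self.logvq[self.finite_mask]

    def category_percent(self, cat: Category) -> float:
        n = self.label.voxel_count
        return 100.0 * float((self.category == cat).sum()) / n


@dataclass
class VQSummary:
    mean: float | None
    sd: float | None
    skewness: float | None
    excess_kurtosis: float | None
    mean_vq_ratio: float | None      # 10**mean, the back-transformed ratio
    pct_low: float                   # finite voxels below ref_mean - 2 ref_sd
    pct_high: float
    pct_neg_inf: float
    pct_pos_inf: float
    pct_both_zero: float
    pct_low_total: float             # pct_low + pct_neg_inf
    pct_high_total: float
    pearson_r: float | None
    n_voxels: int
    n_finite: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """Summary keyed like the cohort characteristics table."""
        return {
            "Q:V Ratio": None,  # filled by callers that know raw totals
            "Log(V/Q) Mean": self.mean,
            "Log(V/Q) Standard Deviation": self.sd,
            "Log(V/Q) Skewness": self.skewness,
            "Log(V/Q) Excess Kurtosis": self.excess_kurtosis,
            "Mean V/Q Ratio": self.mean_vq_ratio,
            "Log(V/Q) -Inf values (%TLV)": self.pct_neg_inf,
            "Log(V/Q) +Inf values (%TLV)": self.pct_pos_inf,
            "Log(V/Q) Both-zero values (%TLV)": self.pct_both_zero,
            "Log(V/Q) Low values (%TLV)": self.pct_low,
            "Log(V/Q) High values (%TLV)": self.pct_high,
            "Log(V/Q) Low total incl -Inf (%TLV)": self.pct_low_total,
            "Log(V/Q) High total incl +Inf (%TLV)": self.pct_high_total,
            "Per-voxel V-Q Pearson R": self.pearson_r,
            "TLV voxels": self.n_voxels,
            "Finite voxels": self.n_finite,
            "warnings": self.warnings,
        }


def normalize_activity(spect: Volume | np.ndarray, label: LungLabel) -> np.ndarray:
    """Relative-frequency field: voxel activity / total label activity x 100.

    Off-label voxels are zeroed; the result sums to 100 over the label and
    is invariant to any global positive rescaling of the input.
    """
    data = spect.data if isinstance(spect, Volume) else spect
    data = np.asarray(data, float)
    if data.shape != label.mask.shape:
        raise ValueError("activity field and label live on different grids")
    if np.any(data[label.mask] < 0):
        raise ValueError("negative activity inside the label")
    total = data[label.mask].sum()
    if not total > 0:
        raise ValueError("zero total activity inside the label")
    out = np.zeros_like(data)
    out[label.mask] = data[label.mask] * (100.0 / total)
    return out


def compute_log_vq(
    v_rel: np.ndarray, q_rel: np.ndarray, label: LungLabel,
    v_raw_total: float | None = None, q_raw_total: float | None = None,
) -> LogVQResult:
    """Per-voxel log10(V/Q) with the zero-activity category conventions."""
    v_rel = np.asarray(v_rel, float)
    q_rel = np.asarray(q_rel, float)
    m = label.mask
    if v_rel.shape != m.shape or q_rel.shape != m.shape:
        raise ValueError("fields and label live on different grids")
    if np.any(v_rel[m] < 0) or np.any(q_rel[m] < 0):
        raise ValueError("negative activity")

    category = np.full(m.shape, int(Category.OUTSIDE), dtype=np.int8)
    vpos = v_rel > 0
    qpos = q_rel > 0
    category[m & vpos & qpos] = Category.FINITE
    category[m & ~vpos & qpos] = Category.NEG_INF
    category[m & vpos & ~qpos] = Category.POS_INF
    category[m & ~vpos & ~qpos] = Category.BOTH_ZERO

    logvq = np.zeros(m.shape, float)
    fin = category == Category.FINITE
    logvq[fin] = np.log10(v_rel[fin] / q_rel[fin])

    if v_raw_total and q_raw_total:
        ratio = float(q_raw_total) / float(v_raw_total)
    else:
        ratio = float("nan")
    return LogVQResult(
        logvq=logvq, category=category, v_rel=v_rel, q_rel=q_rel,
        label=label, qv_total_ratio=ratio,
    )


def summarize(
    res: LogVQResult,
    ref: ReferenceStats | None = None,
    include_both_zero_in_moments: bool = False,
) -> VQSummary:
    """Distribution moments and mismatch percentages.

    Moments use population (biased) estimators — at tens of thousands of
    voxels the bias is immaterial.  ``both_zero`` voxels are excluded from
    the moments by default: their stored value of 0 is a display
    convention, not a measured ratio (a toggle is provided).
    """
    vals = res.finite_values
    if include_both_zero_in_moments:
        vals = np.concatenate(
            [vals, np.zeros(int((res.category == Category.BOTH_ZERO).sum()))]
        )
    n = res.label.voxel_count
    warn: list[str] = []
    if vals.size < 2:
        raise ValueError("need at least 2 finite voxels to summarize")

    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd > 0:
        skew = float(sstats.skew(vals, bias=True))
        kurt = float(sstats.kurtosis(vals, fisher=True, bias=True))
    else:
        skew = None
        kurt = None
        warn.append("all finite voxels identical: skewness/kurtosis undefined")

    if ref is None:
        if sd == 0:
            warn.append("degenerate field: self-referenced thresholds undefined")
            ref_use = None
        else:
            ref_use = ReferenceStats(ref_mean=mean, ref_sd=sd)
            warn.append("self-referenced thresholds (no reference cohort supplied)")
    else:
        ref_use = ref

    if ref_use is not None:
        # strict inequality: a voxel exactly on the threshold counts as matched
        pct_low = 100.0 * float((vals < ref_use.low_threshold).sum()) / n
        pct_high = 100.0 * float((vals > ref_use.high_threshold).sum()) / n
    else:
        pct_low = pct_high = 0.0

    pct_neg = res.category_percent(Category.NEG_INF)
    pct_pos = res.category_percent(Category.POS_INF)
    pct_bz = res.category_percent(Category.BOTH_ZERO)

    try:
        r = voxel_correlation(res.v_rel, res.q_rel, res.label)
    except ValueError:
        r = None
        warn.append("per-voxel correlation undefined (zero variance)")

    return VQSummary(
        mean=mean, sd=sd, skewness=skew, excess_kurtosis=kurt,
        mean_vq_ratio=float(10.0**mean),
        pct_low=pct_low, pct_high=pct_high,
        pct_neg_inf=pct_neg, pct_pos_inf=pct_pos, pct_both_zero=pct_bz,
        pct_low_total=pct_low + pct_neg, pct_high_total=pct_high + pct_pos,
        pearson_r=r, n_voxels=n, n_finite=int(res.finite_mask.sum()),
        warnings=warn,
    )


def histogram(res: LogVQResult, bin_width: float = 0.05) -> pd.DataFrame:
    """Volume-standardized log(V/Q) distribution: % TLV per bin.

    Finite voxels fall in regular bins of ``bin_width`` (edges aligned to
    multiples of the width); the special categories appear as named rows so
    the percentages always total 100 % TLV.
    """
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    vals = res.finite_values
    n = res.label.voxel_count
    rows = []
    if vals.size:
        lo = np.floor(vals.min() / bin_width)
        hi = np.ceil(vals.max() / bin_width)
        if hi == lo:
            hi = lo + 1
        edges = np.arange(lo, hi + 1) * bin_width
        counts, _ = np.histogram(vals, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2
        for c, k in zip(centers, counts):
            rows.append({"bin": f"{c:.6g}", "bin_center": float(c),
                         "pct_tlv": 100.0 * k / n})
    for name, cat in [("-inf", Category.NEG_INF), ("+inf", Category.POS_INF),
                      ("both_zero", Category.BOTH_ZERO)]:
        rows.append({"bin": name, "bin_center": np.nan,
                     "pct_tlv": res.category_percent(cat)})
    return pd.DataFrame(rows)


def voxel_correlation(
    v_rel: np.ndarray, q_rel: np.ndarray, label: LungLabel
) -> float:
    """Pearson correlation of V and Q over all labelled voxels."""
    m = label.mask
    v = np.asarray(v_rel, float)[m]
    q = np.asarray(q_rel, float)[m]
    if v.size < 3:
        raise ValueError("need at least 3 voxels")
    if v.std() == 0 or q.std() == 0:
        raise ValueError("zero variance in one of the fields")
    return float(np.corrcoef(v, q)[0, 1])
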