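"""Regionalization of the lung label and per-region V/Q statistics.

Two partitions are supported:

* apex / middle / base — axial slabs split at the slices whose cumulative
  labelled-voxel fraction is closest to 33 % and 66 % of total lung
  volume;
* inner / outer — the label eroded ``depth`` times (default 3) with the
  six-neighbour structuring element gives the inner core; the outer shell
  is the set difference.

Both partitions are exact: regions are disjoint and their union is the
original label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LungLabel
from .vqstats import Category, LogVQResult, ReferenceStats

__all__ = ["RegionPartition", "axial_thirds", "inner_outer", "regional_summary"]

_SIX = ndimage.generate_binary_structure(3, 1)


@dataclass
class RegionPartition:
    """Named disjoint sub-labels whose union is the whole label."""

    masks: dict[str, np.ndarray]
    label: LungLabel
    boundaries: tuple[int, int] | None = None   # axial indices (thirds mode)
    erosion_depth: int | None = None            # voxels (shells mode)

    def __post_init__(self) -> None:
        union = np.zeros_like(self.label.mask)
        for name, m in self.masks.items():
            if (union & m).any():
                raise ValueError(f"region {name!r} overlaps another region")
            union |= m
        if not np.array_equal(union, self.label.mask):
            raise ValueError("regions do not cover the label exactly")

    def volumes_pct_tlv(self) -> dict[str, float]:
        n = self.label.voxel_count
        return {k: 100.0 * float(m.sum()) / n for k, m in self.masks.items()}


def axial_thirds(label: LungLabel, apex_high: bool = True) -> RegionPartition:
    """Split into apex/middle/base at the 33 % / 66 % volume percentiles.

    The cumulative count runs base-to-apex; each boundary is the slice
    whose cumulative fraction is nearest the target (lower index on ties),
    and the boundary slice belongs to the lower slab.
    """
    mask = label.mask
    per_slice = mask.sum(axis=(0, 1)).astype(float)
    occupied = np.nonzero(per_slice)[0]
    if occupied.size < 3:
        raise ValueError("label spans fewer than 3 axial slices")
    total = per_slice.sum()
    cum = np.cumsum(per_slice) / total  # fraction up to and including slice k

    def nearest(target: float) -> int:
        d = np.abs(cum - target)
        return int(np.argmin(d))  # argmin takes the lower index on ties

    b1 = nearest(1.0 / 3.0)
    b2 = nearest(2.0 / 3.0)
    if not b1 < b2:
        raise ValueError("degenerate axial split (label too thin or lopsided)")

    nz = mask.shape[2]
    zone = np.zeros(nz, dtype=int)          # 0 low, 1 mid, 2 high
    zone[b1 + 1: b2 + 1] = 1
    zone[b2 + 1:] = 2
    names_low_to_high = ["base", "middle", "apex"] if apex_high else \
                        ["apex", "middle", "base"]
    masks = {}
    for z, name in enumerate(names_low_to_high):
        sel = np.zeros(nz, bool)
        sel[zone == z] = True
        masks[name] = mask & sel[None, None, :]
    masks = {k: masks[k] for k in ("apex", "middle", "base")}
    return RegionPartition(masks=masks, label=label, boundaries=(b1, b2))


def inner_outer(label: LungLabel, depth: int = 3) -> RegionPartition:
    """Erode the label ``depth`` times with the 6-neighbour element: the
    survivor is the inner region, the removed rind the outer region."""
    if depth < 1:
        raise ValueError("erosion depth must be >= 1")
    inner = ndimage.binary_erosion(
        label.mask, structure=_SIX, iterations=depth, border_value=0
    )
    if not inner.any():
        raise ValueError(
            f"erosion by {depth} voxels empties the label; lower the depth"
        )
    outer = label.mask & ~inner
    return RegionPartition(
        masks={"inner": inner, "outer": outer}, label=label, erosion_depth=depth
    )


def regional_summary(
    res: LogVQResult,
    part: RegionPartition,
    ref: ReferenceStats | None = None,
) -> pd.DataFrame:
    """Per-region table: finite-voxel mean/SD, share of total V and Q
    activity, and category percentages, plus a whole-lung row."""
    if part.label.mask.shape != res.label.mask.shape:
        raise ValueError("partition and result live on different grids")
    tot_v = res.v_rel[res.label.mask].sum()
    tot_q = res.q_rel[res.label.mask].sum()
    n_tlv = res.label.voxel_count

    def one(name: str, m: np.ndarray) -> dict:
        fin = m & (res.category == Category.FINITE)
        vals = res.logvq[fin]
        row: dict = {
            "region": name,
            "n_voxels": int(m.sum()),
            "pct_tlv": 100.0 * float(m.sum()) / n_tlv,
            "pct_v_counts": 100.0 * float(res.v_rel[m].sum()) / tot_v,
            "pct_q_counts": 100.0 * float(res.q_rel[m].sum()) / tot_q,
        }
        if vals.size >= 2:
            row["mean"] = float(vals.mean())
            row["sd"] = float(vals.std(ddof=0))
        else:
            row["mean"] = row["sd"] = np.nan
            row["warning"] = "fewer than 2 finite voxels"
        for label_, cat in [("pct_neg_inf", Category.NEG_INF),
                            ("pct_pos_inf", Category.POS_INF),
                            ("pct_both_zero", Category.BOTH_ZERO)]:
            row[label_] = 100.0 * float((m & (res.category == cat)).sum()) / n_tlv
        if ref is not None and vals.size:
            row["pct_low"] = 100.0 * float((vals < ref.low_threshold).sum()) / n_tlv
            row["pct_high"] = 100.0 * float((vals > ref.high_threshold).sum()) / n_tlv
        return row

    rows = [one(name, m) for name, m in part.masks.items()]
    rows.append(one("whole_lung", res.label.mask.copy()))
    return pd.DataFrame(rows)
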