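"""Depth-resolved nuclear density, sectional occupancy, phase composition.

Horizontal (en face) virtual sections of a 3D nuclear field, every 2 μm:

* counts of nuclear centroids per slab, normalized to 100×100 μm;
* fraction of the sectional area covered by the union of nuclear
  cross-section disks (overlaps counted once), by rasterization;
* G1-like vs S/G2-like composition per slab.

Counting is centroid-in-slab with half-open [lo, hi) bins, so summing all
slabs gives the total nucleus count exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import NuclearField, PHASE_G1, PHASE_SG2, ValidationError

__all__ = [
    "section_counts",
    "section_occupancy",
    "phase_composition",
    "depth_profile",
    "PhaseComposition",
]

DEFAULT_SLAB = 2.0  # μm
DEFAULT_RESOLUTION = 0.1  # μm/pixel


def _check_depth(field: NuclearField, depth: float) -> None:
    if not (0.0 <= depth <= field.box[2]):
        raise ValidationError(
            f"depth {depth} μm outside box [0, {field.box[2]}]"
        )


def section_counts(
    field: NuclearField, depth: float, slab: float = DEFAULT_SLAB
) -> float:
    """Centroid count in the slab [depth−slab/2, depth+slab/2), per
    100×100 μm of sectional area."""
    _check_depth(field, depth)
    if slab <= 0:
        raise ValidationError("slab thickness must be positive")
    lo, hi = depth - slab / 2, depth + slab / 2
    d = field.nuclei["depth_um"]
    count = int(((d >= lo) & (d < hi)).sum())
    return count * 1.0e4 / field.section_area_um2


def section_occupancy(
    field: NuclearField,
    depth: float,
    resolution: float = DEFAULT_RESOLUTION,
) -> float:
    """Fraction of the horizontal section covered by nuclear cross-sections.

    Every nucleus whose sphere intersects the plane contributes a disk of
    radius sqrt(r² − dz²); the union is rasterized on a grid of
    ``resolution`` μm/pixel (pixel-center test), so overlaps count once.
    """
    _check_depth(field, depth)
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    lx, ly, _ = field.box
    nx = int(round(lx / resolution))
    ny = int(round(ly / resolution))
    mask = np.zeros((ny, nx), dtype=bool)

    n = field.nuclei
    if len(n):
        dz = n["depth_um"].to_numpy() - depth
        r = n["radius_um"].to_numpy()
        hit = np.abs(dz) < r
        rc = np.sqrt(r[hit] ** 2 - dz[hit] ** 2)
        cx = n["x_um"].to_numpy()[hit]
        cy = n["y_um"].to_numpy()[hit]
        for x0, y0, rad in zip(cx, cy, rc):
            # paint only the disk's bounding box
            i_lo = max(int((y0 - rad) / resolution) - 1, 0)
            i_hi = min(int((y0 + rad) / resolution) + 2, ny)
            j_lo = max(int((x0 - rad) / resolution) - 1, 0)
            j_hi = min(int((x0 + rad) / resolution) + 2, nx)
            if i_lo >= i_hi or j_lo >= j_hi:
                continue
            yy = (np.arange(i_lo, i_hi) + 0.5) * resolution - y0
            xx = (np.arange(j_lo, j_hi) + 0.5) * resolution - x0
            local = yy[:, None] ** 2 + xx[None, :] ** 2 <= rad * rad
            mask[i_lo:i_hi, j_lo:j_hi] |= local
    return float(mask.mean())


@dataclass
class PhaseComposition:
    count_g1: int
    count_sg2: int
    proportion_g1: Optional[float]  # None when the slab is empty

    @property
    def total(self) -> int:
        return self.count_g1 + self.count_sg2


def phase_composition(
    field: NuclearField, depth: float, slab: float = DEFAULT_SLAB
) -> PhaseComposition:
    """G1-like / S-G2-like counts and G1 proportion in one slab.

    The proportion is explicitly undefined (None) for an empty slab.
    """
    _check_depth(field, depth)
    n = field.nuclei
    if len(n) and (n["phase"].isna() | (n["phase"] == "")).any():
        raise ValidationError("field contains nuclei without phase labels")
    lo, hi = depth - slab / 2, depth + slab / 2
    in_slab = n[(n["depth_um"] >= lo) & (n["depth_um"] < hi)]
    g1 = int((in_slab["phase"] == PHASE_G1).sum())
    sg2 = int((in_slab["phase"] == PHASE_SG2).sum())
    total = g1 + sg2
    return PhaseComposition(g1, sg2, g1 / total if total else None)


def depth_profile(
    field: NuclearField,
    slab: float = DEFAULT_SLAB,
    max_depth: Optional[float] = None,
    with_occupancy: bool = False,
    resolution: float = DEFAULT_RESOLUTION,
) -> pd.DataFrame:
    """Full profile over slabs [0, slab), [slab, 2·slab), ...

    Columns: depth_bin_lo/hi, count_per_100um2, g1_count, sg2_count and,
    when requested, occupancy_pct at the slab center.
    """
    dmax = field.box[2] if max_depth is None else max_depth
    edges = np.arange(0.0, dmax + slab / 2, slab)
    rows = []
    for lo in edges[:-1]:
        center = lo + slab / 2
        comp = phase_composition(field, center, slab)
        row = {
            "depth_bin_lo_um": lo,
            "depth_bin_hi_um": lo + slab,
            "count_per_100um2": section_counts(field, center, slab),
            "g1_count": comp.count_g1,
            "sg2_count": comp.count_sg2,
        }
        if with_occupancy:
            row["occupancy_pct"] = 100.0 * section_occupancy(
                field, center, resolution
            )
        rows.append(row)
    return pd.DataFrame(rows)
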