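"""Pulse-chase depth-distribution analysis.

A thymidine-analogue pulse labels S-phase nuclei; after a short chase the
labeled cohort contains both nuclei still in S phase (basal half of the
neuroepithelium) and G2-phase nuclei already migrating apically.  The
cohort is summarized as a depth histogram in 10-μm bins (percent of total)
and two cohorts are compared per bin with a 2×2 χ² test (in-bin vs
out-of-bin × group), continuity-uncorrected, on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .core import LabeledCohort, ValidationError
from .stats import chi_square

__all__ = ["DepthHistogram", "brdu_histogram", "compare_bins"]

DEFAULT_BIN_WIDTH = 10.0  # μm


@dataclass
class DepthHistogram:
    bin_edges: np.ndarray  # μm, 10-μm steps from 0
    counts: np.ndarray
    percentages: np.ndarray  # % of total per bin
    mean_depth: float
    sd_depth: float
    group: str

    @property
    def n_cells(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "count": self.counts,
                "percent": self.percentages,
            }
        )


def brdu_histogram(
    cohort: LabeledCohort, bin_width: float = DEFAULT_BIN_WIDTH
) -> DepthHistogram:
    """Half-open depth bins [k·w, (k+1)·w) covering the whole epithelium."""
    if cohort.n_cells == 0:
        raise ValidationError(f"group {cohort.group!r}: empty cohort")
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    n_bins = max(int(np.ceil(cohort.ne_thickness / bin_width)), 1)
    # a depth exactly at the basal boundary falls in the last bin
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((cohort.depths / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return DepthHistogram(
        bin_edges=edges,
        counts=counts,
        percentages=100.0 * counts / counts.sum(),
        mean_depth=float(cohort.depths.mean()),
        sd_depth=float(cohort.depths.std(ddof=1)) if cohort.n_cells > 1 else 0.0,
        group=cohort.group,
    )


def compare_bins(
    h1: DepthHistogram,
    h2: DepthHistogram,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-bin 2×2 χ² comparison of two depth histograms.

    Each bin forms the table [[in₁, out₁], [in₂, out₂]]; the enrichment
    direction reports which group is over-represented in the bin.  Bins
    empty in both groups carry no information and get χ²=0, p=1.  By
    default the raw per-bin p-values are reported; ``bonferroni=True``
    multiplies them by the number of bins (capped at 1).
    """
    n_lo = min(h1.bin_edges.size, h2.bin_edges.size) - 1
    if not np.allclose(h1.bin_edges[: n_lo + 1], h2.bin_edges[: n_lo + 1]):
        raise ValidationError("histograms are on different bin grids")
    # pad the shorter histogram with empty bins so the grids align
    n_bins = max(h1.counts.size, h2.counts.size)
    c1 = np.pad(h1.counts, (0, n_bins - h1.counts.size))
    c2 = np.pad(h2.counts, (0, n_bins - h2.counts.size))
    width = h1.bin_edges[1] - h1.bin_edges[0]
    n1, n2 = c1.sum(), c2.sum()

    rows = []
    for k in range(n_bins):
        a, b = int(c1[k]), int(c2[k])
        if a + b == 0 or (n1 - a) + (n2 - b) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = chi_square(np.array([[a, n1 - a], [b, n2 - b]]))
        if bonferroni:
            p = min(p * n_bins, 1.0)
        p1, p2 = a / n1 * 100.0, b / n2 * 100.0
        if p1 == p2:
            direction = "none"
        else:
            direction = h1.group if p1 > p2 else h2.group
        rows.append(
            {
                "bin_lo_um": k * width,
                "bin_hi_um": (k + 1) * width,
                f"count_{h1.group}": a,
                f"count_{h2.group}": b,
                f"percent_{h1.group}": p1,
                f"percent_{h2.group}": p2,
                "chi2": stat,
                "p_value": p,
                "enriched_in": direction,
            }
        )
    return pd.DataFrame(rows)
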