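"""Kinetochore geometry consistency.

Compares two distance distributions measured on very different instruments:
inter-kinetochore cluster distances from fluorescence microscopy (center of
one kinetochore focus to the center of the other on a pre-anaphase spindle)
and end-to-end doublet-kinetochore lengths from cryo-electron tomography.
If doublet particles are sister kinetochores that stayed linked through
purification, the doublet lengths should sit inside the spread of the
in-vivo inter-kinetochore distances and close to its median.

All distances are handled in nanometers; the I/O layer converts micrometer
inputs on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["DistanceSample", "ConsistencyReport", "distance_summary", "consistency_report"]


@dataclass(frozen=True)
class DistanceSample:
    """A sample of positive distances (nm) of one kind."""

    values: np.ndarray
    kind: str = "inter_kt"  # "inter_kt" | "doublet_length"
    replicate: np.ndarray | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size == 0:
            raise ValidationError("DistanceSample requires at least one value")
        if not np.all(vals > 0):
            raise ValidationError("distances must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ConsistencyReport:
    median_inter_kt: float
    median_doublet: float
    fraction_within_range: float
    fraction_within_tol: float
    tol: float
    bin_edges: np.ndarray
    hist_doublet: np.ndarray
    hist_inter_kt: np.ndarray


def distance_summary(sample: DistanceSample) -> tuple[float, tuple[float, float], int]:
    """(median, (Q1, Q3), n) as exact order statistics."""
    vals = sample.values
    median = float(np.median(vals))
    q1, q3 = (float(q) for q in np.percentile(vals, [25, 75]))
    return median, (q1, q3), sample.n


def consistency_report(
    doublets: DistanceSample,
    inter_kt: DistanceSample,
    tol: float = 100.0,
    bin_width: float = 50.0,
) -> ConsistencyReport:
    """How well do doublet lengths fit inside the inter-kinetochore spread?

    ``fraction_within_range`` is the fraction of doublet lengths inside
    [min, max] of the inter-kinetochore sample; ``fraction_within_tol`` the
    fraction within ``tol`` nm of its median. Shared-bin histograms (default
    50 nm bins) are emitted for an overlay plot.
    """
    if tol < 0:
        raise ParameterError("tol must be >= 0")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    d = doublets.values
    k = inter_kt.values
    med_k = float(np.median(k))
    lo, hi = float(k.min()), float(k.max())
    within_range = float(np.mean((d >= lo) & (d <= hi)))
    within_tol = float(np.mean(np.abs(d - med_k) <= tol))
    both_lo = min(d.min(), k.min())
    both_hi = max(d.max(), k.max())
    first = np.floor(both_lo / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((both_hi - first) / bin_width)))
    edges = first + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= both_hi:  # right edge must include the max
        edges = np.append(edges, edges[-1] + bin_width)
    hist_d, _ = np.histogram(d, bins=edges)
    hist_k, _ = np.histogram(k, bins=edges)
    return ConsistencyReport(
        median_inter_kt=med_k,
        median_doublet=float(np.median(d)),
        fraction_within_range=within_range,
        fraction_within_tol=within_tol,
        tol=float(tol),
        bin_edges=edges,
        hist_doublet=hist_d,
        hist_inter_kt=hist_k,
    )
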