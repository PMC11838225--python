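"""Footprint calling: segment each fiber's m6A pattern into protected runs.

A footprint is a stretch of methylatable sites that stayed unmethylated
because a protein (here, a nucleosome) occluded the methyltransferase. The
caller is a run-length rule over the fiber's methylatable sites, ordered by
site index (not genomic distance):

* boundaries are placed at every run of ``split_run`` or more consecutive
  methylated sites — in accessible DNA, where most sites are methylated,
  such runs occur every few bases, so accessible linkers reliably terminate
  footprints;
* isolated methylated sites (runs shorter than ``split_run``) are tolerated
  inside a footprint, absorbing the low background methylation that leaks
  into genuinely protected DNA; setting ``split_run=1`` recovers a strict
  caller that splits on every methylated site;
* each candidate segment is trimmed to its outermost unmethylated sites and
  emitted if it contains at least ``min_sites`` unmethylated sites and spans
  at least ``min_len`` bp.

Footprints truncated by the fiber ends are flagged boundary-censored but
still emitted; the size filter the analyses need (>400 bp) is applied
downstream, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .fibers import Fiber

__all__ = ["Footprint", "CallingParams", "call_footprints", "call_footprints_all", "footprint_frame"]

FOOTPRINT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "fiber_id",
    "n_unmethylated_sites",
    "size_class",
    "boundary_censored",
]


@dataclass(frozen=True)
class CallingParams:
    """Thresholds for the run-length footprint caller.

    ``nucleosomal_range`` classifies spans: below the low edge is
    subnucleosomal, inside is nucleosomal, above is oversize. Defaults keep
    canonical nucleosomes (147 bp) and wide centromeric footprints (up to
    ~230 bp with extra wrapped DNA) in separate, recoverable classes.
    """

    min_len: int = 80
    min_sites: int = 5
    nucleosomal_range: tuple[int, int] = (80, 200)
    split_run: int = 2

    def __post_init__(self):
        if self.min_len < 1:
            raise ParameterError("min_len must be >= 1")
        if self.min_sites < 1:
            raise ParameterError("min_sites must be >= 1")
        lo, hi = self.nucleosomal_range
        if not lo < hi:
            raise ParameterError("nucleosomal_range must satisfy low < high")
        if self.split_run < 1:
            raise ParameterError("split_run must be >= 1")

    def classify(self, span: int) -> str:
        lo, hi = self.nucleosomal_range
        if span < lo:
            return "subnucleosomal"
        if span <= hi:
            return "nucleosomal"
        return "oversize"


@dataclass(frozen=True)
class Footprint:
    """A protected interval called on one fiber."""

    fiber_id: str
    chrom: str
    start: int
    end: int
    n_unmethylated_sites: int
    size_class: str
    boundary_censored: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


def call_footprints(fiber: Fiber, params: CallingParams = CallingParams()) -> list[Footprint]:
    """Call footprints on one fiber. See the module docstring for the rule."""
    sites = fiber.methylatable_sites
    if sites.size == 0:
        return []
    meth = fiber.methylation_mask()

    # run-length encode the methylation mask
    change = np.flatnonzero(np.diff(meth.astype(np.int8)) != 0) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [meth.size]])
    run_meth = meth[run_starts]
    run_lens = run_ends - run_starts

    # hard boundaries: methylated runs of length >= split_run
    hard = run_meth & (run_lens >= params.split_run)
    footprints: list[Footprint] = []
    seg_start_run = 0
    boundary_runs = list(np.flatnonzero(hard)) + [len(run_starts)]
    for b in boundary_runs:
        if b > seg_start_run:
            i0 = run_starts[seg_start_run]
            i1 = run_ends[b - 1]
            fp = _emit_segment(fiber, sites, meth, i0, i1, params)
            if fp is not None:
                footprints.append(fp)
        seg_start_run = b + 1
    return footprints


def _emit_segment(fiber, sites, meth, i0, i1, params) -> Footprint | None:
    unmeth_idx = np.flatnonzero(~meth[i0:i1]) + i0
    if unmeth_idx.size < params.min_sites:
        return None
    first, last = unmeth_idx[0], unmeth_idx[-1]
    start = int(sites[first])
    end = int(sites[last]) + 1
    span = end - start
    if span < params.min_len:
        return None
    censored = first == 0 or last == sites.size - 1
    return Footprint(
        fiber_id=fiber.fiber_id,
        chrom=fiber.chrom,
        start=start,
        end=end,
        n_unmethylated_sites=int(unmeth_idx.size),
        size_class=params.classify(span),
        boundary_censored=bool(censored),
    )


def footprint_frame(footprints) -> pd.DataFrame:
    """Collect Footprint records into the standard table, sorted by position."""
    df = pd.DataFrame(
        [
            {
                "chrom": fp.chrom,
                "start": fp.start,
                "end": fp.end,
                "fiber_id": fp.fiber_id,
                "n_unmethylated_sites": fp.n_unmethylated_sites,
                "size_class": fp.size_class,
                "boundary_censored": fp.boundary_censored,
            }
            for fp in footprints
        ],
        columns=FOOTPRINT_COLUMNS,
    )
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def call_footprints_all(fibers, params: CallingParams = CallingParams()) -> pd.DataFrame:
    """Call footprints on every fiber; returns the sorted footprint table."""
    seen: set[str] = set()
    all_fps: list[Footprint] = []
    for fiber in fibers:
        if fiber.fiber_id in seen:
            raise ValidationError(f"duplicate fiber_id {fiber.fiber_id!r}")
        seen.add(fiber.fiber_id)
        all_fps.extend(call_footprints(fiber, params))
    return footprint_frame(all_fps)
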