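"""The Fiber record: one sequenced chromatin molecule.

A fiber is a reference interval plus two sorted coordinate sets: the positions
that the methyltransferase could have methylated (methylatable sites, the
strand-collapsed adenine positions) and the subset it actually methylated.
Protein-occupied DNA shows up as stretches of methylatable-but-unmethylated
sites; everything downstream works off these two arrays.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["Fiber"]


def _as_sorted_unique(x, label: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.int64)
    if arr.ndim != 1:
        raise ValidationError(f"{label} must be one-dimensional")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{label} must be strictly increasing")
    return arr


@dataclass(frozen=True)
class Fiber:
    """One chromatin molecule with per-site m6A calls in reference coordinates."""

    fiber_id: str
    chrom: str
    start: int
    end: int
    methylated_sites: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    methylatable_sites: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"fiber {self.fiber_id}: end ({self.end}) must exceed start ({self.start})"
            )
        able = _as_sorted_unique(self.methylatable_sites, "methylatable_sites")
        meth = _as_sorted_unique(self.methylated_sites, "methylated_sites")
        for label, arr in (("methylatable", able), ("methylated", meth)):
            if arr.size and (arr[0] < self.start or arr[-1] >= self.end):
                raise ValidationError(
                    f"fiber {self.fiber_id}: {label} sites outside [{self.start}, {self.end})"
                )
        if meth.size:
            idx = np.searchsorted(able, meth)
            ok = bool(np.all(idx < able.size)) and np.array_equal(able[np.minimum(idx, able.size - 1)], meth)
            if not ok:
                raise ValidationError(
                    f"fiber {self.fiber_id}: methylated sites must be a subset of methylatable sites"
                )
        object.__setattr__(self, "methylatable_sites", able)
        object.__setattr__(self, "methylated_sites", meth)

    @property
    def length(self) -> int:
        return self.end - self.start

    def methylation_mask(self) -> np.ndarray:
        """Boolean mask over methylatable_sites: True where methylated."""
        mask = np.zeros(self.methylatable_sites.size, dtype=bool)
        if self.methylated_sites.size:
            mask[np.searchsorted(self.methylatable_sites, self.methylated_sites)] = True
        return mask

    def overlaps(self, start: int, end: int, chrom: str | None = None) -> bool:
        """Half-open interval intersection of length >= 1 bp."""
        if chrom is not None and self.chrom != chrom:
            return False
        return self.start < end and self.end > start

    def spans(self, start: int, end: int, chrom: str | None = None) -> bool:
        if chrom is not None and self.chrom != chrom:
            return False
        return self.start <= start and self.end >= end
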