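"""Synthetic data generators.

This module builds everything the downstream analyses consume, with the
statistical structure the real experiments produce:

* a toy genome of one or more chromosomes carrying point centromeres whose
  protected region is either a single block (single centromeric nucleosome)
  or two blocks separated by accessible linker DNA (double-nucleosome model);
* a bulk chromatin layout tiling each chromosome with nucleosome-protected
  intervals separated by short linkers;
* long chromatin fibers with per-site m6A calls — accessible DNA methylated
  with high probability, protected DNA with low probability;
* optical-trap rupture-force event lists with right-censored "escape" events;
* inter-kinetochore distance and doublet-length measurement samples.

Every generator takes a single integer seed and is bit-reproducible for a
fixed seed. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import CoordinateError, LayoutError, ParameterError
from .fibers import Fiber
from .survival import RuptureEvent

__all__ = [
    "CentromereModel",
    "GenomeModel",
    "NucleosomeLayout",
    "MethylationParams",
    "RuptureGenParams",
    "DistanceGenParams",
    "build_genome",
    "layout_chromatin",
    "simulate_fibers",
    "simulate_rupture_events",
    "simulate_distances",
    "mixture_cdf",
    "mixture_median",
    "shift_mixture_to_median",
]

DEFAULT_NUC_LEN = 147
#: CDEI / CDEII / CDEIII lengths (bp) used when none are given. CDEII is the
#: AT-rich element carrying the centromeric nucleosome: 165 bp in K. marxianus,
#: roughly half that in S. cerevisiae.
DEFAULT_CDE_LENGTHS = (8, 165, 25)


@dataclass(frozen=True)
class CentromereModel:
    """A point centromere and the protected-region architecture to emulate.

    ``model`` selects between one protected block covering the centromere
    (``"single"``) and two blocks separated by an accessible linker
    (``"double"``). ``protected_width`` is an int for single, or a
    ``(width1, linker, width2)`` triple for double. Blocks are centered on the
    centromere midpoint and may extend past the annotated centromere by at
    most one nucleosome length.
    """

    chrom: str
    start: int
    end: int
    model: str = "single"
    protected_width: int | tuple[int, int, int] = 227
    cde_lengths: tuple[int, int, int] = DEFAULT_CDE_LENGTHS

    def __post_init__(self):
        if self.end <= self.start:
            raise CoordinateError(f"centromere on {self.chrom}: end <= start")
        if self.model not in ("single", "double"):
            raise ParameterError(f"unknown centromere model {self.model!r}")
        if self.model == "single":
            if not isinstance(self.protected_width, (int, np.integer)) or self.protected_width < 1:
                raise ParameterError("single model requires a positive integer protected_width")
        else:
            try:
                w1, linker, w2 = self.protected_width
            except (TypeError, ValueError) as exc:
                raise ParameterError(
                    "double model requires a (width1, linker, width2) triple"
                ) from exc
            if w1 < 1 or w2 < 1:
                raise ParameterError("protected widths must be >= 1 bp")
            if linker < 1:
                raise ParameterError("double model requires linker >= 1 bp")
        if len(self.cde_lengths) != 3 or any(v < 0 for v in self.cde_lengths):
            raise ParameterError("cde_lengths must be three non-negative lengths")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def protected_intervals(self, nuc_len: int = DEFAULT_NUC_LEN) -> list[tuple[int, int]]:
        """Protected block(s), centered on the centromere midpoint."""
        c = self.center
        if self.model == "single":
            w = int(self.protected_width)
            s = c - w // 2
            blocks = [(s, s + w)]
        else:
            w1, linker, w2 = (int(v) for v in self.protected_width)
            total = w1 + linker + w2
            s = c - total // 2
            blocks = [(s, s + w1), (s + w1 + linker, s + total)]
        lo, hi = self.start - nuc_len, self.end + nuc_len
        for bs, be in blocks:
            if bs < lo or be > hi:
                raise LayoutError(
                    f"centromere on {self.chrom}: protected block [{bs},{be}) extends "
                    f"more than one nucleosome beyond the centromere [{self.start},{self.end})"
                )
        return blocks


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: chromosome sizes, centromeres, and methylatable positions.

    ``site_positions[chrom]`` is the sorted array of strand-collapsed
    m6A-methylatable coordinates (the A/T positions of a real genome),
    drawn independently per base with probability ``at_fraction``.
    """

    chromosomes: list[tuple[str, int]]
    at_fraction: float
    centromeres: list[CentromereModel]
    site_positions: dict[str, np.ndarray]

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise CoordinateError(f"unknown chromosome {chrom!r}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass(frozen=True)
class NucleosomeLayout:
    """Disjoint protected intervals per chromosome, bulk plus centromeric."""

    intervals: dict[str, np.ndarray]  # (n, 2) int arrays, sorted, disjoint
    centromeric: dict[str, np.ndarray]  # subset of the above, per chromosome
    nuc_len: int = DEFAULT_NUC_LEN

    def protected_mask(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """True for each position lying inside a protected interval."""
        iv = self.intervals.get(chrom)
        if iv is None or iv.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], positions, side="right") - 1
        inside = idx >= 0
        inside[inside] &= positions[inside] < iv[idx[inside], 1]
        return inside


@dataclass(frozen=True)
class MethylationParams:
    """Per-site methylation probabilities for accessible vs protected DNA.

    Accessible DNA is methylated efficiently but not completely
    (``p_meth_accessible``); protected DNA picks up a low background rate
    (``p_meth_protected``) standing in for incomplete protection and miscalls.
    """

    p_meth_accessible: float = 0.8
    p_meth_protected: float = 0.02

    def __post_init__(self):
        for name in ("p_meth_accessible", "p_meth_protected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.p_meth_protected >= self.p_meth_accessible:
            raise ParameterError("p_meth_protected must be < p_meth_accessible")


@dataclass(frozen=True)
class RuptureGenParams:
    """Truncated-Gaussian-mixture rupture forces with escape censoring."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mean pN, sd pN)
    censor_fraction: float = 0.0
    n_events: int = 0
    seed: int = 0
    condition: str = "sim"

    def __post_init__(self):
        comps = tuple(tuple(float(v) for v in c) for c in self.components)
        if not comps:
            raise ParameterError("mixture must have at least one component")
        if any(len(c) != 3 for c in comps):
            raise ParameterError("each component is (weight, mean, sd)")
        w = sum(c[0] for c in comps)
        if not math.isclose(w, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ParameterError(f"component weights must sum to 1, got {w}")
        if any(c[2] <= 0 for c in comps):
            raise ParameterError("component sds must be > 0")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ParameterError("censor_fraction must lie in [0, 1]")
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        object.__setattr__(self, "components", comps)


@dataclass(frozen=True)
class DistanceGenParams:
    """Log-normal distance sample parameterized by its true median (nm)."""

    true_median: float
    log_sd: float = 0.3
    n: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.true_median <= 0:
            raise ParameterError("true_median must be > 0")
        if self.log_sd < 0:
            raise ParameterError("log_sd must be >= 0")
        if self.n < 1:
            raise ParameterError("n must be >= 1")


# ---------------------------------------------------------------------------
# genome & chromatin


def build_genome(
    n_chrom: int,
    chrom_length: int,
    at_fraction: float,
    cen_specs: list[CentromereModel],
    seed: int,
) -> GenomeModel:
    """Draw a toy genome with iid methylatable sites and the given centromeres.

    Chromosomes are named ``chr1 .. chrN`` with identical lengths; each
    ``CentromereModel`` must name one of them and fit inside it.
    """
    if n_chrom < 1 or chrom_length < 1:
        raise ParameterError("n_chrom and chrom_length must be >= 1")
    if not 0.0 < at_fraction <= 1.0:
        raise ParameterError(f"at_fraction must lie in (0, 1], got {at_fraction}")
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chrom)]
    names = {name for name, _ in chromosomes}
    for cen in cen_specs:
        if cen.chrom not in names:
            raise CoordinateError(f"centromere chromosome {cen.chrom!r} not in genome")
        if cen.start < 0 or cen.end > chrom_length:
            raise CoordinateError(
                f"centromere [{cen.start},{cen.end}) outside {cen.chrom} of length {chrom_length}"
            )
    rng = np.random.default_rng(seed)
    sites = {
        name: np.flatnonzero(rng.random(length) < at_fraction).astype(np.int64)
        for name, length in chromosomes
    }
    return GenomeModel(chromosomes, float(at_fraction), list(cen_specs), sites)


def layout_chromatin(
    genome: GenomeModel,
    nuc_len: int = DEFAULT_NUC_LEN,
    linker_dist: tuple[float, float] = (20.0, 10.0),
    seed: int = 0,
) -> NucleosomeLayout:
    """Tile each chromosome with nucleosomes, then stamp in centromeric blocks.

    Bulk chromatin is ``nuc_len``-bp protected intervals separated by integer
    linkers drawn from a normal distribution truncated at 0. Within one
    nucleosome length of each centromere the bulk tiling is erased and replaced
    by the centromere's protected block(s).
    """
    if nuc_len < 1:
        raise ParameterError("nuc_len must be >= 1")
    mean, sd = linker_dist
    if mean < 0:
        raise ParameterError("linker mean must be >= 0")
    rng = np.random.default_rng(seed)
    cens_by_chrom: dict[str, list[CentromereModel]] = {}
    for cen in genome.centromeres:
        cens_by_chrom.setdefault(cen.chrom, []).append(cen)

    intervals: dict[str, np.ndarray] = {}
    centromeric: dict[str, np.ndarray] = {}
    for name, length in genome.chromosomes:
        bulk: list[tuple[int, int]] = []
        pos = 0
        while pos + nuc_len <= length:
            bulk.append((pos, pos + nuc_len))
            linker = max(0, int(round(rng.normal(mean, sd)))) if sd > 0 or mean > 0 else 0
            pos += nuc_len + linker
        cen_blocks: list[tuple[int, int]] = []
        for cen in cens_by_chrom.get(name, ()):
            blocks = cen.protected_intervals(nuc_len)
            if blocks[0][0] < 0 or blocks[-1][1] > length:
                raise LayoutError(
                    f"centromeric protected blocks on {name} exceed the chromosome"
                )
            lo, hi = cen.start - nuc_len, cen.end + nuc_len
            bulk = [(s, e) for s, e in bulk if e <= lo or s >= hi]
            cen_blocks.extend(blocks)
        merged = sorted(bulk + cen_blocks)
        for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
            if s2 < e1:
                raise LayoutError(
                    f"layout collision on {name}: [{s1},{e1}) overlaps [{s2},{e2})"
                )
        intervals[name] = np.array(merged, dtype=np.int64).reshape(-1, 2)
        centromeric[name] = np.array(sorted(cen_blocks), dtype=np.int64).reshape(-1, 2)
    return NucleosomeLayout(intervals, centromeric, nuc_len)


def _fiber_bulk_mask(
    rng,
    fsites: np.ndarray,
    lo: int,
    hi: int,
    nuc_len: int,
    linker_dist: tuple[float, float],
    zones: list[tuple[int, int]],
    cen_blocks: np.ndarray,
) -> np.ndarray:
    """Protected mask for one fiber with its own bulk nucleosome phasing.

    Bulk nucleosomes are tiled from a random phase offset across [lo, hi);
    any bulk nucleosome touching a centromere exclusion zone is dropped and
    the fixed centromeric blocks are kept instead.
    """
    mean, sd = linker_dist
    pitch = nuc_len + max(0, int(round(mean)))
    pos = lo - int(rng.integers(0, pitch))
    protected = np.zeros(fsites.size, dtype=bool)
    while pos < hi:
        e = pos + nuc_len
        in_zone = any(pos < zhi and e > zlo for zlo, zhi in zones)
        if not in_zone:
            i0, i1 = np.searchsorted(fsites, [pos, e])
            protected[i0:i1] = True
        linker = max(0, int(round(rng.normal(mean, sd)))) if (sd > 0 or mean > 0) else 0
        pos = e + linker
    for s, e in cen_blocks:
        i0, i1 = np.searchsorted(fsites, [s, e])
        protected[i0:i1] = True
    return protected


def simulate_fibers(
    genome: GenomeModel,
    layout: NucleosomeLayout,
    n_fibers: int,
    fiber_len_dist: tuple[float, float] = (15_000.0, 3_000.0),
    meth: MethylationParams = MethylationParams(),
    seed: int = 0,
    min_len: int = 1_000,
    bulk_phasing: str = "genome",
    linker_dist: tuple[float, float] = (20.0, 10.0),
) -> list[Fiber]:
    """Sample long fibers uniformly over the genome and methylate their sites.

    Fiber starts are uniform over concatenated chromosome coordinates; lengths
    are normal (default mean 15 kb, sd 3 kb) clipped to at least ``min_len``
    and to the chromosome end. Each methylatable site on a fiber is methylated
    independently with ``p_meth_accessible`` outside protected intervals and
    ``p_meth_protected`` inside them.

    ``bulk_phasing`` controls whether every fiber shares the genome-wide
    nucleosome layout ("genome", the default — useful when tests compare
    against the layout as ground truth) or re-draws its own bulk nucleosome
    positions ("fiber"), emulating cell-to-cell positioning variability: real
    fibers come from different cells, so only strongly positioned features
    (the centromeric block, which stays fixed) line up across molecules.
    """
    if n_fibers < 0:
        raise ParameterError("n_fibers must be >= 0")
    if bulk_phasing not in ("genome", "fiber"):
        raise ParameterError(f"bulk_phasing must be 'genome' or 'fiber', got {bulk_phasing!r}")
    zones_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for cen in genome.centromeres:
        zones_by_chrom.setdefault(cen.chrom, []).append(
            (cen.start - layout.nuc_len, cen.end + layout.nuc_len)
        )
    rng = np.random.default_rng(seed)
    fibers: list[Fiber] = []
    if n_fibers == 0:
        return fibers
    names = [name for name, _ in genome.chromosomes]
    lengths = np.array([length for _, length in genome.chromosomes], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    mean_len, sd_len = fiber_len_dist
    if mean_len < 1:
        raise ParameterError("fiber length mean must be >= 1")
    starts_global = rng.integers(0, offsets[-1], size=n_fibers)
    drawn_lengths = np.maximum(min_len, np.round(rng.normal(mean_len, sd_len, size=n_fibers))).astype(np.int64)
    for i in range(n_fibers):
        ci = int(np.searchsorted(offsets, starts_global[i], side="right") - 1)
        chrom = names[ci]
        start = int(starts_global[i] - offsets[ci])
        end = int(min(start + drawn_lengths[i], lengths[ci]))
        sites = genome.site_positions[chrom]
        lo, hi = np.searchsorted(sites, [start, end])
        fsites = sites[lo:hi]
        if bulk_phasing == "genome":
            protected = layout.protected_mask(chrom, fsites)
        else:
            protected = _fiber_bulk_mask(
                rng,
                fsites,
                start,
                end,
                layout.nuc_len,
                linker_dist,
                zones_by_chrom.get(chrom, []),
                layout.centromeric.get(chrom, np.empty((0, 2), np.int64)),
            )
        p = np.where(protected, meth.p_meth_protected, meth.p_meth_accessible)
        methylated = fsites[rng.random(fsites.size) < p]
        fibers.append(
            Fiber(
                fiber_id=f"fiber{i:06d}",
                chrom=chrom,
                start=start,
                end=end,
                methylated_sites=methylated,
                methylatable_sites=fsites,
            )
        )
    return fibers


# ---------------------------------------------------------------------------
# rupture forces


def mixture_cdf(x, components) -> np.ndarray:
    """CDF of a Gaussian mixture (untruncated; truncation at 0 is negligible
    for the pN-scale parameters used here and is handled by resampling in the
    generator)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x, dtype=float)
    for w, mu, sd in components:
        out = out + w * stats.norm.cdf(x, loc=mu, scale=sd)
    return out


def mixture_median(components) -> float:
    """Median of a Gaussian mixture, by bracketed root finding on the CDF."""
    mus = [mu for _, mu, _ in components]
    sds = [sd for _, _, sd in components]
    lo = min(m - 10 * s for m, s in zip(mus, sds))
    hi = max(m + 10 * s for m, s in zip(mus, sds))
    return float(optimize.brentq(lambda x: mixture_cdf(x, components) - 0.5, lo, hi))


def shift_mixture_to_median(components, target_median: float):
    """Shift all component means by a common offset so the mixture median
    equals ``target_median``; the shape (spacing, weights, sds) is unchanged."""
    shift = target_median - mixture_median(components)
    return tuple((w, mu + shift, sd) for w, mu, sd in components)


def simulate_rupture_events(params: RuptureGenParams) -> list[RuptureEvent]:
    """Draw rupture forces from the truncated mixture and censor a subset.

    Escapes are events where the bead detached from the trap (or the assay
    ended) before rupture: each censored event records a force drawn uniformly
    between 0 and its latent rupture force, and is flagged ``"escape"``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_events
    weights = np.array([c[0] for c in params.components])
    means = np.array([c[1] for c in params.components])
    sds = np.array([c[2] for c in params.components])
    comp = rng.choice(len(weights), size=n, p=weights)
    forces = rng.normal(means[comp], sds[comp])
    # truncate at 0 by redrawing within the same component
    bad = np.flatnonzero(forces <= 0)
    while bad.size:
        forces[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = bad[forces[bad] <= 0]
    escape = rng.random(n) < params.censor_fraction
    recorded = np.where(escape, rng.uniform(0.0, 1.0, size=n) * forces, forces)
    return [
        RuptureEvent(
            force=float(recorded[i]),
            outcome="escape" if escape[i] else "rupture",
            condition=params.condition,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# distances


def simulate_distances(params: DistanceGenParams) -> np.ndarray:
    """Log-normal distances (nm) whose population median is ``true_median``."""
    rng = np.random.default_rng(params.seed)
    if params.log_sd == 0:
        return np.full(params.n, float(params.true_median))
    return rng.lognormal(mean=math.log(params.true_median), sigma=params.log_sd, size=params.n)
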