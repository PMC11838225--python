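"""Readers and writers for the package's tabular formats.

All genomic records use 0-based half-open coordinates (BED conventions).
Formats:

* fiber table — TSV: fiber_id, chrom, start, end, comma-separated methylated
  positions, comma-separated methylatable positions ("." for empty);
* BED6 for centromeres and protected-interval truth;
* BED6+2 for footprints (name=fiber_id, score=n_unmethylated_sites, extra
  columns size_class and boundary_censored);
* bedGraph for density profiles (NaN rows omitted);
* CSV for rupture events (force_pN, outcome, condition) and distance
  measurements (value, unit, kind, replicate; um converted to nm on read);
* an adapter turning MM/ML-tagged aligned long reads (SAM/BAM) into Fiber
  records.

Parsers raise :class:`~cenfiber.errors.FormatError` with the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .fibers import Fiber
from .footprints import FOOTPRINT_COLUMNS, Footprint

__all__ = [
    "write_fiber_table",
    "read_fiber_table",
    "write_bed6",
    "read_bed6",
    "write_footprint_bed",
    "read_footprint_bed",
    "footprints_from_frame",
    "write_bedgraph",
    "write_events_csv",
    "read_events_csv",
    "write_distances_csv",
    "read_distances_csv",
    "fibers_from_alignments",
]


def _fmt_positions(arr) -> str:
    arr = np.asarray(arr)
    return ",".join(str(int(x)) for x in arr) if arr.size else "."


def _parse_positions(text: str, path, line_no) -> np.ndarray:
    if text == "." or text == "":
        return np.empty(0, dtype=np.int64)
    try:
        return np.array([int(t) for t in text.split(",")], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"bad position list {text[:40]!r}", str(path), line_no) from exc


def write_fiber_table(fibers, path) -> None:
    with open(path, "w") as fh:
        fh.write("fiber_id\tchrom\tstart\tend\tmethylated\tmethylatable\n")
        for f in fibers:
            fh.write(
                f"{f.fiber_id}\t{f.chrom}\t{f.start}\t{f.end}\t"
                f"{_fmt_positions(f.methylated_sites)}\t{_fmt_positions(f.methylatable_sites)}\n"
            )


def read_fiber_table(path) -> list[Fiber]:
    fibers = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("fiber_id\t"):
            raise FormatError("missing fiber-table header", str(path), 1)
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"expected 6 columns, got {len(parts)}", str(path), line_no)
            try:
                start, end = int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise FormatError("non-integer coordinates", str(path), line_no) from exc
            try:
                fibers.append(
                    Fiber(
                        fiber_id=parts[0],
                        chrom=parts[1],
                        start=start,
                        end=end,
                        methylated_sites=_parse_positions(parts[4], path, line_no),
                        methylatable_sites=_parse_positions(parts[5], path, line_no),
                    )
                )
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), line_no) from exc
    return fibers


def write_bed6(records, path) -> None:
    """records: iterable of (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path) -> list[tuple[str, int, int, str, str, str]]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED needs at least 3 columns", str(path), line_no)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError("non-integer BED coordinates", str(path), line_no) from exc
            if end <= start:
                raise FormatError(f"BED end ({end}) <= start ({start})", str(path), line_no)
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append((parts[0], start, end, name, score, strand))
    return out


def write_footprint_bed(footprints: pd.DataFrame, path) -> None:
    """BED6+2: chrom start end fiber_id n_unmethylated_sites . size_class censored."""
    with open(path, "w") as fh:
        for row in footprints.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.fiber_id}\t"
                f"{row.n_unmethylated_sites}\t.\t{row.size_class}\t{int(row.boundary_censored)}\n"
            )


def read_footprint_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(f"expected 8 columns, got {len(parts)}", str(path), line_no)
            try:
                start, end = int(parts[1]), int(parts[2])
                score = int(parts[4])
                censored = bool(int(parts[7]))
            except ValueError as exc:
                raise FormatError("malformed footprint record", str(path), line_no) from exc
            if end <= start:
                raise FormatError(f"end ({end}) <= start ({start})", str(path), line_no)
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "fiber_id": parts[3],
                    "n_unmethylated_sites": score,
                    "size_class": parts[6],
                    "boundary_censored": censored,
                }
            )
    return pd.DataFrame(rows, columns=FOOTPRINT_COLUMNS)


def footprints_from_frame(df: pd.DataFrame) -> list[Footprint]:
    """Rehydrate Footprint records from the footprint table."""
    return [
        Footprint(
            fiber_id=row.fiber_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            n_unmethylated_sites=int(row.n_unmethylated_sites),
            size_class=row.size_class,
            boundary_censored=bool(row.boundary_censored),
        )
        for row in df.itertuples(index=False)
    ]


def write_bedgraph(profile, path) -> None:
    """Density profile as bedGraph; undefined (NaN) bases are omitted.

    Consecutive equal-valued bases are merged into one record.
    """
    chrom = profile.window.chrom
    pos = profile.positions()
    dens = profile.density
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        for p, v in zip(pos, dens):
            if np.isnan(v):
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{p}\t{run_val:.6g}\n")
                    run_start = None
                continue
            if run_start is None:
                run_start, run_val = p, v
            elif v != run_val:
                fh.write(f"{chrom}\t{run_start}\t{p}\t{run_val:.6g}\n")
                run_start, run_val = p, v
        if run_start is not None:
            fh.write(f"{chrom}\t{run_start}\t{pos[-1] + 1}\t{run_val:.6g}\n")


def write_events_csv(events, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["force_pN", "outcome", "condition"])
        for e in events:
            writer.writerow([repr(e.force), e.outcome, e.condition])


def read_events_csv(path):
    from .survival import RuptureEvent

    events = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return events
        if [h.strip() for h in header[:2]] != ["force_pN", "outcome"]:
            raise FormatError("expected header force_pN,outcome[,condition]", str(path), 1)
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                force = float(row[0])
            except ValueError as exc:
                raise FormatError(f"bad force {row[0]!r}", str(path), line_no) from exc
            outcome = row[1].strip()
            condition = row[2].strip() if len(row) > 2 else ""
            try:
                events.append(RuptureEvent(force=force, outcome=outcome, condition=condition))
            except ValidationError as exc:
                raise FormatError(str(exc), str(path), line_no) from exc
    return events


_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "μm": 1000.0, "micron": 1000.0}


def write_distances_csv(samples, path) -> None:
    """samples: iterable of DistanceSample; values written in nm."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["value", "unit", "kind", "replicate"])
        for sample in samples:
            reps = sample.replicate
            for i, v in enumerate(sample.values):
                rep = "" if reps is None else reps[i]
                writer.writerow([repr(float(v)), "nm", sample.kind, rep])


def read_distances_csv(path):
    """Returns {kind: DistanceSample} with all values converted to nm."""
    from .geometry import DistanceSample

    values: dict[str, list[float]] = {}
    reps: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            return {}
        if [h.strip() for h in header[:3]] != ["value", "unit", "kind"]:
            raise FormatError("expected header value,unit,kind[,replicate]", str(path), 1)
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            unit = row[1].strip().lower()
            if unit not in _UNIT_TO_NM:
                raise FormatError(f"unknown unit {row[1]!r}", str(path), line_no)
            try:
                v = float(row[0]) * _UNIT_TO_NM[unit]
            except ValueError as exc:
                raise FormatError(f"bad value {row[0]!r}", str(path), line_no) from exc
            kind = row[2].strip()
            values.setdefault(kind, []).append(v)
            reps.setdefault(kind, []).append(row[3].strip() if len(row) > 3 else "")
    return {
        kind: DistanceSample(
            values=np.array(vals), kind=kind, replicate=np.array(reps[kind], dtype=object)
        )
        for kind, vals in values.items()
    }


def fibers_from_alignments(path, min_ml: int = 128, mode: str | None = None) -> list[Fiber]:
    """Fiber records from MM/ML-tagged aligned long reads (SAM/BAM).

    Methylatable sites are the reference positions of aligned read bases that
    are A or T (the strand-collapsed adenine positions); methylated sites are
    the subset carrying an m6A call ('a' modification on either strand) with
    likelihood >= ``min_ml`` (of 255). Unmapped and secondary/supplementary
    records are skipped.
    """
    import pysam

    fibers = []
    with pysam.AlignmentFile(str(path), mode) as bam:  # mode inferred if None
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            pairs = rec.get_aligned_pairs(matches_only=True)
            read2ref = dict(pairs)
            methylatable = sorted(
                ref for read, ref in pairs if seq[read].upper() in ("A", "T")
            )
            meth_reads = set()
            modified = rec.modified_bases or {}
            for (base, _strand, mod), calls in modified.items():
                if mod != "a":
                    continue
                for read_pos, qual in calls:
                    if qual == -1 or qual >= min_ml:
                        meth_reads.add(read_pos)
            methylated = sorted(
                read2ref[rp] for rp in meth_reads if rp in read2ref
            )
            if not methylatable:
                continue
            fibers.append(
                Fiber(
                    fiber_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    methylated_sites=np.array(methylated, dtype=np.int64),
                    methylatable_sites=np.array(methylatable, dtype=np.int64),
                )
            )
    return fibers
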