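"""Readers and writers for the formats the pipeline touches.

PAF (minimap2's pairwise mapping format, mandatory 12 columns), FASTA
assemblies, BED3 repeat annotations, and the TSV/JSON report files.  All
coordinates are kept 0-based half-open internally — the PAF and BED native
convention — and converted only at report boundaries.

Soft-masked (lowercase) bases are treated as ordinary bases; repeat status
comes exclusively from the repeat track, never from masking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentBlock",
    "SequenceRecord",
    "AssemblyCatalog",
    "RepeatTrack",
    "PAFParseError",
    "read_paf",
    "write_paf",
    "read_fasta",
    "write_fasta",
    "build_catalog",
    "catalog_from_sequences",
    "find_gap_runs",
    "read_repeat_track",
    "merge_intervals",
    "write_report",
    "write_circos_links",
    "read_report_json",
    "CHROMOSOME",
    "UNPLACED_DEBRIS",
    "DEFAULT_MIN_GAP_RUN",
    "DEFAULT_MIN_CHROMOSOME_LEN",
]

CHROMOSOME = "chromosome"
UNPLACED_DEBRIS = "unplaced_debris"

#: shortest run of N/n counted as an assembly gap (scaffold gaps are
#: "typically 10-100" N; shorter runs are treated as ambiguous base calls)
DEFAULT_MIN_GAP_RUN = 10

#: fallback rule when no explicit chromosome list is given: sequences at
#: least this long are chromosome-scale, the rest unplaced debris
DEFAULT_MIN_CHROMOSOME_LEN = 10_000_000


class PAFParseError(ValueError):
    """A PAF line that cannot be mapped onto the mandatory 12 columns."""


@dataclass(frozen=True)
class AlignmentBlock:
    """One PAF record: a contiguous aligned segment between two assemblies.

    Coordinates are 0-based half-open on both sides.  ``strand`` is ``"+"``
    when the query aligns in the same direction as the target, ``"-"``
    otherwise.  ``residue_matches`` and ``block_len`` are PAF columns 10 and
    11; ``mapq`` is the phred-scaled mapping quality (column 12).
    """

    query_name: str
    query_seq_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_seq_len: int
    target_start: int
    target_end: int
    residue_matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_seq_len):
            raise ValueError(
                f"query interval [{self.query_start}, {self.query_end}) out of "
                f"bounds for {self.query_name!r} (len {self.query_seq_len})"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_seq_len):
            raise ValueError(
                f"target interval [{self.target_start}, {self.target_end}) out "
                f"of bounds for {self.target_name!r} (len {self.target_seq_len})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.residue_matches > self.block_len:
            raise ValueError("residue_matches exceeds block_len")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0, 255]")

    @property
    def query_span(self) -> int:
        """Aligned query bp — the unit summed into category tallies."""
        return self.query_end - self.query_start

    @property
    def match_fraction(self) -> float:
        """Identity proxy: residue matches over alignment block length."""
        return self.residue_matches / self.block_len


@dataclass(frozen=True)
class SequenceRecord:
    name: str
    length: int
    status: str = CHROMOSOME  # CHROMOSOME or UNPLACED_DEBRIS
    is_x: bool = False


@dataclass
class AssemblyCatalog:
    """Per-assembly registry: sequence lengths, gap runs, placement status.

    ``gap_intervals`` maps sequence name to sorted, non-overlapping
    (start, end) runs of N of length >= ``min_gap_run``.
    """

    sequences: dict[str, SequenceRecord]
    gap_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    min_gap_run: int = DEFAULT_MIN_GAP_RUN

    def __post_init__(self) -> None:
        for name, ivs in self.gap_intervals.items():
            if name not in self.sequences:
                raise ValueError(f"gap intervals on unknown sequence {name!r}")
            length = self.sequences[name].length
            prev_end = -1
            for start, end in ivs:
                if not (0 <= start < end <= length):
                    raise ValueError(f"gap ({start}, {end}) out of bounds on {name!r}")
                if start <= prev_end:
                    raise ValueError(f"gap intervals overlap/unsorted on {name!r}")
                prev_end = end

    @property
    def total_length(self) -> int:
        return sum(rec.length for rec in self.sequences.values())

    @property
    def chromosomes(self) -> list[SequenceRecord]:
        return [r for r in self.sequences.values() if r.status == CHROMOSOME]

    @property
    def debris(self) -> list[SequenceRecord]:
        return [r for r in self.sequences.values() if r.status == UNPLACED_DEBRIS]

    def status_of(self, name: str) -> str:
        try:
            return self.sequences[name].status
        except KeyError:
            raise KeyError(f"sequence {name!r} not in catalog") from None

    def gap_bp(self, name: str | None = None) -> int:
        if name is not None:
            return sum(e - s for s, e in self.gap_intervals.get(name, []))
        return sum(self.gap_bp(n) for n in self.sequences)


@dataclass
class RepeatTrack:
    """Merged repeat-element intervals per sequence (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    skipped: int = 0  # intervals dropped because their sequence was unknown

    def repeat_bp(self, name: str) -> int:
        return sum(e - s for s, e in self.intervals.get(name, []))

    def density_pct(self, name: str, length: int) -> float:
        return 100.0 * self.repeat_bp(name) / length if length else 0.0


# ---------------------------------------------------------------------------
# PAF


def _parse_paf_line(line: str, lineno: int) -> AlignmentBlock:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise PAFParseError(f"line {lineno}: expected >= 12 fields, got {len(fields)}")
    try:
        return AlignmentBlock(
            query_name=fields[0],
            query_seq_len=int(fields[1]),
            query_start=int(fields[2]),
            query_end=int(fields[3]),
            strand=fields[4],
            target_name=fields[5],
            target_seq_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            residue_matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
        )
    except ValueError as exc:
        raise PAFParseError(f"line {lineno}: {exc}") from exc


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read the mandatory 12 PAF columns; optional SAM-like tags are ignored.

    An empty file yields an empty list.  Malformed lines raise
    :class:`PAFParseError` naming the 1-based line number.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            blocks.append(_parse_paf_line(line, lineno))
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as handle:
        for b in blocks:
            handle.write(
                f"{b.query_name}\t{b.query_seq_len}\t{b.query_start}\t"
                f"{b.query_end}\t{b.strand}\t{b.target_name}\t{b.target_seq_len}\t"
                f"{b.target_start}\t{b.target_end}\t{b.residue_matches}\t"
                f"{b.block_len}\t{b.mapq}\n"
            )


# ---------------------------------------------------------------------------
# FASTA and catalogs


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {name: sequence} mapping."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no sequences in FASTA {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def find_gap_runs(seq: str, min_gap_run: int = DEFAULT_MIN_GAP_RUN) -> list[tuple[int, int]]:
    """Maximal runs of N/n of length >= ``min_gap_run``, as (start, end).

    Run boundaries are located with a vectorised scan over the byte array
    rather than pattern matching, so the regex scan stays available as an
    independent check.
    """
    if not seq:
        return []
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    if not is_n.any():
        return []
    padded = np.concatenate(([False], is_n, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[0::2], edges[1::2]
    keep = (ends - starts) >= min_gap_run
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def catalog_from_sequences(
    seqs: Mapping[str, str],
    chromosomes: Sequence[str] | None = None,
    min_chromosome_len: int = DEFAULT_MIN_CHROMOSOME_LEN,
    x_name: str | None = None,
    min_gap_run: int = DEFAULT_MIN_GAP_RUN,
) -> AssemblyCatalog:
    """Build a catalog from in-memory sequences.

    Chromosome status comes from ``chromosomes`` (explicit name list) when
    given, otherwise from the ``min_chromosome_len`` threshold.  ``x_name``
    flags the X chromosome for the repeat-density regression.
    """
    records: dict[str, SequenceRecord] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    chrom_set = set(chromosomes) if chromosomes is not None else None
    for name, seq in seqs.items():
        if chrom_set is not None:
            status = CHROMOSOME if name in chrom_set else UNPLACED_DEBRIS
        else:
            status = CHROMOSOME if len(seq) >= min_chromosome_len else UNPLACED_DEBRIS
        records[name] = SequenceRecord(
            name=name, length=len(seq), status=status, is_x=(name == x_name)
        )
        runs = find_gap_runs(seq, min_gap_run)
        if runs:
            gaps[name] = runs
    return AssemblyCatalog(sequences=records, gap_intervals=gaps, min_gap_run=min_gap_run)


def build_catalog(
    fasta: str | Path,
    chromosomes: Sequence[str] | None = None,
    min_chromosome_len: int = DEFAULT_MIN_CHROMOSOME_LEN,
    x_name: str | None = None,
    min_gap_run: int = DEFAULT_MIN_GAP_RUN,
) -> AssemblyCatalog:
    """Read a FASTA and build its :class:`AssemblyCatalog`."""
    return catalog_from_sequences(
        read_fasta(fasta),
        chromosomes=chromosomes,
        min_chromosome_len=min_chromosome_len,
        x_name=x_name,
        min_gap_run=min_gap_run,
    )


# ---------------------------------------------------------------------------
# Repeat tracks (BED3)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ordered = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for start, end in ordered:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def read_repeat_track(bed: str | Path, catalog: AssemblyCatalog) -> RepeatTrack:
    """Parse a BED3+ repeat annotation against a catalog.

    Intervals are clipped to sequence bounds and merged.  Intervals on
    sequences absent from the catalog are skipped with a warning (counted in
    ``RepeatTrack.skipped``); a start >= end is an error.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    with open(bed) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed}: line {lineno}: BED needs >= 3 columns")
            name, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{bed}: line {lineno}: start {start} >= end {end}")
            if name not in catalog.sequences:
                skipped += 1
                continue
            length = catalog.sequences[name].length
            start, end = max(0, start), min(end, length)
            if start < end:
                raw.setdefault(name, []).append((start, end))
    if skipped:
        warnings.warn(f"{bed}: skipped {skipped} intervals on unknown sequences")
    return RepeatTrack(
        intervals={name: merge_intervals(ivs) for name, ivs in raw.items()},
        skipped=skipped,
    )


def write_repeat_bed(track: RepeatTrack, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, ivs in track.intervals.items():
            for start, end in ivs:
                handle.write(f"{name}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Reports


def write_report(table, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a discrepancy table as ``<prefix>.tsv`` (printed precision)
    and ``<prefix>.json`` (full precision).  Returns both paths."""
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    with open(tsv_path, "w") as handle:
        handle.write("comparison\tcategory\tbp\tpercent\n")
        for category in table.CATEGORIES:
            handle.write(
                f"{table.comparison}\t{category}\t{table.bp[category]}\t"
                f"{table.formatted_pct(category)}\n"
            )
        handle.write(
            f"{table.comparison}\ttotal_evaluated\t{table.evaluated_total}\t100.0\n"
        )
    with open(json_path, "w") as handle:
        json.dump(table.to_dict(), handle, indent=2)
        handle.write("\n")
    return tsv_path, json_path


def read_report_json(path: str | Path):
    from .summarize import DiscrepancyTable

    with open(path) as handle:
        payload = json.load(handle)
    return DiscrepancyTable.from_dict(payload)


def write_circos_links(labeled, path: str | Path) -> Path:
    """Export labeled blocks as a circos-style link table.

    One row per block: query sequence and span, target sequence and span,
    strand and category — 1-based inclusive coordinates, the convention of
    circos-style plotting tools.
    """
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(
            "query\tquery_start\tquery_end\ttarget\ttarget_start\ttarget_end\t"
            "strand\tcategory\n"
        )
        for lb in labeled:
            b = lb.block
            handle.write(
                f"{b.query_name}\t{b.query_start + 1}\t{b.query_end}\t"
                f"{b.target_name}\t{b.target_start + 1}\t{b.target_end}\t"
                f"{b.strand}\t{lb.label.value}\n"
            )
    return path
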