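"""Contiguity statistics: N50/L50, counts, maxima, gap percentage.

Scaffold metrics are computed over full catalog sequences; contig metrics
over the pieces obtained by splitting scaffolds at gap runs (runs of N at
least ``min_gap_run`` long — shorter runs neither split contigs nor count
as gap bp).  N50 is the length of the sequence at which the
descending-length cumulative sum first reaches half the total (inclusive
crossing: a cumulative sum exactly equal to total/2 counts); L50 is how
many sequences that takes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AssemblyCatalog

__all__ = ["AssemblyStats", "nx_lx", "compute_stats", "compare_stats"]


def nx_lx(lengths: list[int], fraction: float = 0.5) -> tuple[int, int]:
    """(Nx, Lx) of a set of sequence lengths, inclusive crossing rule."""
    if not lengths:
        raise ValueError("no sequences")
    total = sum(lengths)
    threshold = fraction * total
    cum = 0
    for i, length in enumerate(sorted(lengths, reverse=True), start=1):
        cum += length
        if cum >= threshold:
            return length, i
    raise AssertionError("unreachable: cumulative sum must reach threshold")


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_scaffolds: int
    n_contigs: int
    gap_pct: float
    max_scaffold_len: int
    max_contig_len: int
    scaffold_n50: int
    contig_n50: int
    scaffold_l50: int
    contig_l50: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def contig_lengths(catalog: AssemblyCatalog) -> list[int]:
    """Lengths of scaffold pieces split at qualifying gap runs."""
    pieces: list[int] = []
    for rec in catalog.sequences.values():
        pos = 0
        for gap_start, gap_end in catalog.gap_intervals.get(rec.name, []):
            if gap_start > pos:
                pieces.append(gap_start - pos)
            pos = gap_end
        if rec.length > pos:
            pieces.append(rec.length - pos)
    return pieces


def compute_stats(catalog: AssemblyCatalog) -> AssemblyStats:
    if not catalog.sequences:
        raise ValueError("empty catalog")
    scaffolds = [rec.length for rec in catalog.sequences.values()]
    contigs = contig_lengths(catalog)
    total = sum(scaffolds)
    gap_bp = catalog.gap_bp()
    scaffold_n50, scaffold_l50 = nx_lx(scaffolds)
    contig_n50, contig_l50 = nx_lx(contigs)
    return AssemblyStats(
        total_length=total,
        n_scaffolds=len(scaffolds),
        n_contigs=len(contigs),
        gap_pct=100.0 * gap_bp / total,
        max_scaffold_len=max(scaffolds),
        max_contig_len=max(contigs),
        scaffold_n50=scaffold_n50,
        contig_n50=contig_n50,
        scaffold_l50=scaffold_l50,
        contig_l50=contig_l50,
    )


def compare_stats(a: AssemblyStats, b: AssemblyStats) -> dict[str, dict]:
    """Per-metric comparison of two assemblies' statistics.

    For each metric: both values, the ratio b/a, the percent change of b
    relative to a (negative = reduction), and a direction label.  Metrics
    with a zero baseline are reported as undefined.
    """
    report: dict[str, dict] = {}
    for metric, va in a.to_dict().items():
        vb = getattr(b, metric)
        entry: dict = {"a": va, "b": vb}
        if va == 0:
            entry.update(ratio=None, pct_change=None, direction="undefined")
        else:
            ratio = vb / va
            entry["ratio"] = ratio
            entry["pct_change"] = 100.0 * (vb - va) / va
            entry["direction"] = (
                "unchanged" if vb == va else ("increased" if vb > va else "reduced")
            )
        report[metric] = entry
    return report
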