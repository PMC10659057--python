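"""Seeded synthetic assembly pairs with ground-truthed discrepancies.

A multi-chromosome truth genome (the "reference") is generated with a
repeat track whose density is elevated on an X-like chromosome, then a
derived assembly (the "query") is produced by implanting structural edits
— inversions (reverse-complemented in place), translocations (segments
moved to another chromosome), relocations (segments moved out of order
within a chromosome) and debris (segments excised into small standalone
scaffolds) — with optional runs of N at the new junctions.

The derived assembly is represented internally as a list of truth-genome
segments, so idealized PAF alignment blocks (correct coordinates and
strands, matches = block length, mapQ 60) can be emitted exactly from the
edit history, optionally fragmented at random breakpoints without
changing covered bp.  Every output is a pure function of the
configuration, including its seed.

Inversion sizes follow a log-normal whose mode sits at 20 kbp with about
15-20% of draws above 100 kbp, mirroring the size spectrum reported for
real chromosome-scale assembly comparisons; debris fragments are at least
15 kbp, the usual Hi-C scaffolding inclusion threshold, so they are
distinguishable from filter-discarded noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    CHROMOSOME,
    UNPLACED_DEBRIS,
    AlignmentBlock,
    AssemblyCatalog,
    RepeatTrack,
    SequenceRecord,
    merge_intervals,
)
from .summarize import ChromosomeProfile

__all__ = [
    "SimulationConfig",
    "TruthEvent",
    "TruthEventSet",
    "Segment",
    "SimulationResult",
    "generate_truth",
    "implant_events",
    "emit_ideal_paf",
    "simulate",
    "score_recovery",
    "planted_regression_profiles",
    "x_only_signal_profiles",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: log-normal sigma giving P(size > 100 kbp) ~= 0.175 when the mode is 20 kbp
_INVERSION_SIGMA = 0.885


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic assembly pair.

    Defaults describe a 10 Mbp, 5-chromosome toy genome (4 autosome-like
    sequences plus one repeat-enriched X-like sequence) carrying 10
    inversions, 5 translocations, 5 relocations and 5 debris fragments.
    """

    seed: int = 0
    chromosome_lengths: tuple[int, ...] = (2_000_000,) * 5
    x_index: int = 4  # which chromosome is the X-like sequence
    n_inversions: int = 10
    n_translocations: int = 5
    n_relocations: int = 5
    n_debris: int = 5
    inversion_size_mode: int = 20_000
    inversion_sigma: float = _INVERSION_SIGMA
    min_event_size: int = 5_000
    max_event_size: int = 400_000
    segment_size_range: tuple[int, int] = (20_000, 80_000)  # transloc/reloc
    debris_size_range: tuple[int, int] = (15_000, 100_000)
    gap_run_len: int = 100
    insert_gaps: bool = True
    repeat_densities: tuple[float, ...] = (25.0, 30.0, 22.0, 28.0, 55.0)  # %
    repeat_element_range: tuple[int, int] = (500, 3_000)
    repeat_motif_len: int = 6
    fragmentation_rate: float = 2e-5  # breakpoints per bp of alignment

    def __post_init__(self) -> None:
        if len(self.repeat_densities) != len(self.chromosome_lengths):
            raise ValueError("one repeat density per chromosome required")
        if not 0 <= self.x_index < len(self.chromosome_lengths):
            raise ValueError("x_index out of range")
        if any(d < 0 or d > 100 for d in self.repeat_densities):
            raise ValueError("repeat densities must be in [0, 100]")
        if self.min_event_size <= 0:
            raise ValueError("event sizes must be positive")

    @property
    def chromosome_names(self) -> list[str]:
        return [
            "chrX" if i == self.x_index else f"chr{i + 1}"
            for i in range(len(self.chromosome_lengths))
        ]

    @property
    def x_name(self) -> str:
        return "chrX"


@dataclass(frozen=True)
class Segment:
    """One derived-assembly piece: a truth interval, or a gap run."""

    source_chrom: str | None  # None marks an inserted run of Ns
    start: int
    end: int
    strand: str = "+"
    event_id: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # inversion | translocation | relocation | debris
    truth_chrom: str
    truth_start: int
    truth_end: int
    derived_chrom: str
    derived_start: int
    derived_end: int

    @property
    def length(self) -> int:
        return self.truth_end - self.truth_start


@dataclass
class TruthEventSet:
    events: list[TruthEvent] = field(default_factory=list)

    def bp_by_kind(self) -> dict[str, int]:
        out = {"inversion": 0, "translocation": 0, "relocation": 0, "debris": 0}
        for ev in self.events:
            out[ev.kind] += ev.length
        return out

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class SimulationResult:
    config: SimulationConfig
    truth_seqs: dict[str, str]
    derived_seqs: dict[str, str]
    ref_catalog: AssemblyCatalog
    query_catalog: AssemblyCatalog
    repeat_track: RepeatTrack
    events: TruthEventSet
    segments: dict[str, list[Segment]]
    blocks: list[AlignmentBlock]


# ---------------------------------------------------------------------------
# Truth genome


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_truth(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], AssemblyCatalog, RepeatTrack]:
    """Seeded truth genome with a repeat track hitting target densities.

    Repeats are realized as tandem duplications of short random motifs —
    genuinely repetitive sequence, not just annotated intervals — placed
    without overlap until each chromosome reaches its target density.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seqs: dict[str, str] = {}
    track: dict[str, list[tuple[int, int]]] = {}
    for name, length, density in zip(
        cfg.chromosome_names, cfg.chromosome_lengths, cfg.repeat_densities
    ):
        arr = _random_sequence(rng, length)
        target_bp = density / 100.0 * length
        placed: list[tuple[int, int]] = []
        covered = 0
        lo, hi = cfg.repeat_element_range
        attempts = 0
        while covered < target_bp:
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, length - size)))
            interval = (start, start + size)
            if any(s < interval[1] and interval[0] < e for s, e in placed):
                attempts += 1
                if attempts > 100_000:
                    raise ValueError(
                        f"cannot reach repeat density {density}% on {name}"
                    )
                continue
            placed.append(interval)
            covered += size
            motif = _random_sequence(rng, cfg.repeat_motif_len)
            reps = math.ceil(size / cfg.repeat_motif_len)
            arr[start : start + size] = np.tile(motif, reps)[:size]
        seqs[name] = arr.tobytes().decode("ascii")
        if placed:
            track[name] = merge_intervals(placed)
    catalog = AssemblyCatalog(
        sequences={
            name: SequenceRecord(
                name=name, length=len(seq), status=CHROMOSOME, is_x=(name == cfg.x_name)
            )
            for name, seq in seqs.items()
        },
        gap_intervals={},
    )
    return seqs, catalog, RepeatTrack(intervals=track)


# ---------------------------------------------------------------------------
# Event implantation


def _draw_inversion_size(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    mu = math.log(cfg.inversion_size_mode) + cfg.inversion_sigma**2
    size = int(rng.lognormal(mean=mu, sigma=cfg.inversion_sigma))
    return max(cfg.min_event_size, min(cfg.max_event_size, size))


def _sample_windows(
    cfg: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, str, int, int]]:
    """Non-overlapping (kind, chromosome, start, end) truth windows."""
    kinds = (
        ["inversion"] * cfg.n_inversions
        + ["translocation"] * cfg.n_translocations
        + ["relocation"] * cfg.n_relocations
        + ["debris"] * cfg.n_debris
    )
    lengths = dict(zip(cfg.chromosome_names, cfg.chromosome_lengths))
    names = cfg.chromosome_names
    weights = np.array(cfg.chromosome_lengths, dtype=float)
    weights /= weights.sum()
    taken: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    margin = 1_000  # keep events apart and off chromosome ends
    windows: list[tuple[str, str, int, int]] = []
    for kind in kinds:
        for _ in range(10_000):
            if kind == "inversion":
                size = _draw_inversion_size(cfg, rng)
            elif kind == "debris":
                size = int(rng.integers(*cfg.debris_size_range))
            else:
                size = int(rng.integers(*cfg.segment_size_range))
            chrom = names[int(rng.choice(len(names), p=weights))]
            space = lengths[chrom] - size - 2 * margin
            if space <= 0:
                continue
            start = margin + int(rng.integers(0, space))
            end = start + size
            if any(s - margin < end and start < e + margin for s, e in taken[chrom]):
                continue
            taken[chrom].append((start, end))
            windows.append((kind, chrom, start, end))
            break
        else:
            raise ValueError(
                f"could not place a {kind} event; chromosomes too small for the "
                "requested event load"
            )
    return windows


def implant_events(
    truth_seqs: dict[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, list[Segment]], TruthEventSet]:
    """Derive the query assembly by applying the sampled edits.

    Returns the derived sequences, the per-derived-sequence segment lists
    (the exact edit history), and the ground-truth event set with
    coordinates in both assemblies.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    windows = _sample_windows(cfg, rng)

    # cut each chromosome at event boundaries
    cuts: dict[str, list[tuple[int, int, int | None]]] = {}
    for name in cfg.chromosome_names:
        events_here = sorted(
            (start, end, i) for i, (_, chrom, start, end) in enumerate(windows) if chrom == name
        )
        pieces: list[tuple[int, int, int | None]] = []
        pos = 0
        for start, end, i in events_here:
            if start > pos:
                pieces.append((pos, start, None))
            pieces.append((start, end, i))
            pos = end
        length = len(truth_seqs[name])
        if pos < length:
            pieces.append((pos, length, None))
        cuts[name] = pieces

    lists: dict[str, list[Segment]] = {}
    debris_lists: dict[str, list[Segment]] = {}
    pending_moves: list[tuple[int, Segment, str]] = []  # (event_id, segment, dest chrom)
    n_debris = 0
    for name in cfg.chromosome_names:
        segs: list[Segment] = []
        for start, end, ev in cuts[name]:
            kind = windows[ev][0] if ev is not None else None
            if kind == "inversion":
                segs.append(Segment(name, start, end, "-", ev))
            elif kind == "debris":
                n_debris += 1
                debris_lists[f"debris_{n_debris}"] = [Segment(name, start, end, "+", ev)]
            elif kind in ("translocation", "relocation"):
                if kind == "translocation":
                    others = [n for n in cfg.chromosome_names if n != name]
                    dest = others[int(rng.choice(len(others)))]
                else:
                    dest = name
                pending_moves.append((ev, Segment(name, start, end, "+", ev), dest))
            else:
                segs.append(Segment(name, start, end, "+", ev))
        lists[name] = segs

    # reinsert moved segments at positions that break collinearity
    for ev, seg, dest in pending_moves:
        host = lists[dest]
        slots = list(range(len(host) + 1))
        if dest == seg.source_chrom:
            # slots adjacent to the original neighbours would restore order
            origin = [
                i for i in slots
                if (i > 0 and host[i - 1].source_chrom == dest and host[i - 1].end == seg.start)
                or (i < len(host) and host[i].source_chrom == dest and host[i].start == seg.end)
            ]
            f = origin[0] if origin else 0

            # an implanted relocation is only unambiguous when the in-place
            # material it jumps over outweighs it; otherwise the collinear
            # backbone legitimately keeps the moved segment and calls the
            # lighter displaced piece relocated instead
            def displaced_weight(s: int) -> int:
                lo, hi = (f, s) if s >= f else (s, f)
                return sum(
                    h.length for h in host[lo:hi]
                    if h.source_chrom == dest and h.strand == "+" and h.event_id is None
                )

            qualified = [
                s for s in slots
                if s not in origin and displaced_weight(s) > 2 * seg.length
            ]
            slots = qualified or [max(slots, key=displaced_weight)]
        slot = slots[int(rng.choice(len(slots)))]
        host.insert(slot, seg)

    lists.update(debris_lists)

    # insert gap runs at every junction that is not truth-contiguous
    if cfg.insert_gaps and cfg.gap_run_len > 0:
        for name, segs in lists.items():
            with_gaps: list[Segment] = []
            for seg in segs:
                if with_gaps:
                    prev = with_gaps[-1]
                    contiguous = (
                        prev.source_chrom == seg.source_chrom
                        and prev.strand == "+" == seg.strand
                        and prev.end == seg.start
                    )
                    if not contiguous:
                        with_gaps.append(Segment(None, 0, cfg.gap_run_len))
                with_gaps.append(seg)
            lists[name] = with_gaps

    derived_seqs: dict[str, str] = {}
    derived_pos: dict[int, tuple[str, int, int]] = {}
    for name, segs in lists.items():
        parts: list[str] = []
        pos = 0
        for seg in segs:
            if seg.source_chrom is None:
                parts.append("N" * seg.length)
            else:
                piece = truth_seqs[seg.source_chrom][seg.start : seg.end]
                if seg.strand == "-":
                    piece = _revcomp(piece)
                parts.append(piece)
                if seg.event_id is not None:
                    derived_pos[seg.event_id] = (name, pos, pos + seg.length)
            pos += seg.length
        derived_seqs[name] = "".join(parts)

    events = TruthEventSet(
        events=[
            TruthEvent(
                kind=kind,
                truth_chrom=chrom,
                truth_start=start,
                truth_end=end,
                derived_chrom=derived_pos[i][0],
                derived_start=derived_pos[i][1],
                derived_end=derived_pos[i][2],
            )
            for i, (kind, chrom, start, end) in enumerate(windows)
        ]
    )
    return derived_seqs, lists, events


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Idealized alignments


def emit_ideal_paf(
    truth_seqs: dict[str, str],
    derived_seqs: dict[str, str],
    segments: dict[str, list[Segment]],
    fragmentation_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[AlignmentBlock]:
    """Exact alignment blocks from the edit history (query = derived).

    With ``fragmentation_rate`` > 0, each block is split at a Poisson
    number of uniform breakpoints, leaving covered bp unchanged — a stand-
    in for real aligners breaking long alignments into pieces.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    blocks: list[AlignmentBlock] = []
    for qname, segs in segments.items():
        qlen = len(derived_seqs[qname])
        qpos = 0
        for seg in segs:
            if seg.source_chrom is None:
                qpos += seg.length
                continue
            tlen = len(truth_seqs[seg.source_chrom])
            offsets = [0, seg.length]
            if fragmentation_rate > 0 and seg.length > 1:
                k = int(rng.poisson(fragmentation_rate * seg.length))
                if k:
                    breakpoints = rng.integers(1, seg.length, size=k)
                    offsets = sorted({0, seg.length, *breakpoints.tolist()})
            for a, b in zip(offsets[:-1], offsets[1:]):
                if seg.strand == "+":
                    tstart, tend = seg.start + a, seg.start + b
                else:
                    tstart, tend = seg.end - b, seg.end - a
                blocks.append(
                    AlignmentBlock(
                        query_name=qname,
                        query_seq_len=qlen,
                        query_start=qpos + a,
                        query_end=qpos + b,
                        strand=seg.strand,
                        target_name=seg.source_chrom,
                        target_seq_len=tlen,
                        target_start=tstart,
                        target_end=tend,
                        residue_matches=b - a,
                        block_len=b - a,
                        mapq=60,
                    )
                )
            qpos += seg.length
    return blocks


def simulate(cfg: SimulationConfig, with_noise: bool | None = None) -> SimulationResult:
    """Run the full generator: truth, derived assembly, repeats, ideal PAF.

    ``with_noise`` overrides whether alignment fragmentation is applied
    (default: apply the configured rate).
    """
    rng = np.random.default_rng(cfg.seed)
    truth_seqs, ref_catalog, track = generate_truth(cfg, rng)
    derived_seqs, segments, events = implant_events(truth_seqs, cfg, rng)
    rate = cfg.fragmentation_rate
    if with_noise is False:
        rate = 0.0
    blocks = emit_ideal_paf(truth_seqs, derived_seqs, segments, fragmentation_rate=rate, rng=rng)
    query_catalog = AssemblyCatalog(
        sequences={
            name: SequenceRecord(
                name=name,
                length=len(seq),
                status=UNPLACED_DEBRIS if name.startswith("debris_") else CHROMOSOME,
                is_x=(name == cfg.x_name),
            )
            for name, seq in derived_seqs.items()
        },
        gap_intervals={
            name: _gap_intervals_from_segments(segs)
            for name, segs in segments.items()
            if any(s.source_chrom is None for s in segs)
        },
        min_gap_run=min(cfg.gap_run_len, 10) if cfg.gap_run_len else 10,
    )
    return SimulationResult(
        config=cfg,
        truth_seqs=truth_seqs,
        derived_seqs=derived_seqs,
        ref_catalog=ref_catalog,
        query_catalog=query_catalog,
        repeat_track=track,
        events=events,
        segments=segments,
        blocks=blocks,
    )


def _gap_intervals_from_segments(segs: list[Segment]) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for seg in segs:
        if seg.source_chrom is None:
            out.append((pos, pos + seg.length))
        pos += seg.length
    return out


def score_recovery(events: TruthEventSet, labeled) -> dict[str, tuple[float, float]]:
    """bp-level (precision, recall) per event kind, in derived coordinates.

    Predicted intervals are the query spans of blocks carrying each
    discrepancy label; truth intervals come from the event set.  A kind
    with no predictions scores precision 1.0; with no truth, recall 1.0.
    """
    kinds = ("inversion", "translocation", "relocation", "debris")
    truth_iv: dict[str, dict[str, list[tuple[int, int]]]] = {k: {} for k in kinds}
    for ev in events:
        truth_iv[ev.kind].setdefault(ev.derived_chrom, []).append(
            (ev.derived_start, ev.derived_end)
        )
    pred_iv: dict[str, dict[str, list[tuple[int, int]]]] = {k: {} for k in kinds}
    for lb in labeled:
        kind = lb.label.value
        if kind in pred_iv:
            pred_iv[kind].setdefault(lb.block.query_name, []).append(
                (lb.block.query_start, lb.block.query_end)
            )

    def _bp(ivmap: dict[str, list[tuple[int, int]]]) -> int:
        return sum(e - s for ivs in ivmap.values() for s, e in merge_intervals(ivs))

    def _overlap(a: dict, b: dict) -> int:
        total = 0
        for chrom in a.keys() & b.keys():
            ia, ib = merge_intervals(a[chrom]), merge_intervals(b[chrom])
            i = j = 0
            while i < len(ia) and j < len(ib):
                lo = max(ia[i][0], ib[j][0])
                hi = min(ia[i][1], ib[j][1])
                if lo < hi:
                    total += hi - lo
                if ia[i][1] <= ib[j][1]:
                    i += 1
                else:
                    j += 1
        return total

    scores = {}
    for kind in kinds:
        tp = _overlap(truth_iv[kind], pred_iv[kind])
        pred_bp = _bp(pred_iv[kind])
        truth_bp = _bp(truth_iv[kind])
        precision = tp / pred_bp if pred_bp else 1.0
        recall = tp / truth_bp if truth_bp else 1.0
        scores[kind] = (precision, recall)
    return scores


# ---------------------------------------------------------------------------
# Planted regressions (chromosome-level discrepancy vs repeat density)


def planted_regression_profiles(
    rng: np.random.Generator,
    n_chromosomes: int = 22,
    slope: float = 0.15,
    intercept: float = 1.0,
    noise_sd: float = 0.5,
    repeat_range: tuple[float, float] = (25.0, 45.0),
    x_repeat_pct: float = 60.0,
    chromosome_length: int = 1_000_000,
) -> list[ChromosomeProfile]:
    """Profiles with a planted linear discrepancy-vs-repeat dependence.

    One repeat-enriched X-like chromosome sits at ``x_repeat_pct``; the
    rest draw repeat densities uniformly from ``repeat_range``.
    """
    profiles = []
    for i in range(n_chromosomes):
        is_x = i == n_chromosomes - 1
        x = x_repeat_pct if is_x else float(rng.uniform(*repeat_range))
        y = max(0.0, intercept + slope * x + float(rng.normal(0.0, noise_sd)))
        profiles.append(
            ChromosomeProfile(
                name="chrX" if is_x else f"chr{i + 1}",
                length=chromosome_length,
                discrepancy_bp=int(round(y / 100.0 * chromosome_length)),
                repeat_bp=int(round(x / 100.0 * chromosome_length)),
                is_x=is_x,
            )
        )
    return profiles


def x_only_signal_profiles(
    rng: np.random.Generator,
    n_chromosomes: int = 22,
    baseline: float = 1.0,
    noise_sd: float = 0.3,
    x_discrepancy_pct: float = 12.0,
    repeat_range: tuple[float, float] = (25.0, 45.0),
    x_repeat_pct: float = 60.0,
    chromosome_length: int = 1_000_000,
) -> list[ChromosomeProfile]:
    """Profiles where elevated discrepancy is confined to the X point."""
    profiles = []
    for i in range(n_chromosomes):
        is_x = i == n_chromosomes - 1
        x = x_repeat_pct if is_x else float(rng.uniform(*repeat_range))
        y = x_discrepancy_pct if is_x else max(
            0.0, baseline + float(rng.normal(0.0, noise_sd))
        )
        profiles.append(
            ChromosomeProfile(
                name="chrX" if is_x else f"chr{i + 1}",
                length=chromosome_length,
                discrepancy_bp=int(round(y / 100.0 * chromosome_length)),
                repeat_bp=int(round(x / 100.0 * chromosome_length)),
                is_x=is_x,
            )
        )
    return profiles
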