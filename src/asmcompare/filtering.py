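"""Alignment-block retention filters and stacked-block detection.

Blocks are filtered before any discrepancy screening: short query
sequences, short alignment blocks, low mapping quality and low identity
are all set aside as unassessed rather than being called discrepancies.
Comparisons are strict (<), so a value exactly at a threshold is retained.

"Stacked" blocks are query alignment blocks overlapping by more than half
of the shorter block's span; the shorter of each such pair is set aside as
unassessed so one query region is never counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io_formats import AlignmentBlock

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "DiscardReason",
    "filter_blocks",
    "detect_stacked",
    "apply_filters",
]


class DiscardReason:
    QUERY_TOO_SHORT = "query_too_short"
    BLOCK_TOO_SHORT = "block_too_short"
    LOW_MAPQ = "low_mapq"
    LOW_MATCH_FRACTION = "low_match_fraction"


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds.

    ``min_query_seq_len`` applies to the full query *sequence* length (PAF
    column 2), not the aligned span; ``min_block_len`` applies to the
    alignment block length (column 11).  ``fragmented_min_query_seq_len``
    is the extra 1 Mbp query-length filter used against highly fragmented
    assemblies; leave it ``None`` to disable.
    """

    min_query_seq_len: int = 3_000
    min_block_len: int = 500
    min_mapq: int = 30
    min_match_fraction: float = 0.8
    fragmented_min_query_seq_len: int | None = None
    stacked_overlap_fraction: float = 0.5

    FRAGMENTED_DEFAULT = 1_000_000

    def __post_init__(self) -> None:
        if min(self.min_query_seq_len, self.min_block_len, self.min_mapq) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.min_match_fraction <= 1.0:
            raise ValueError("min_match_fraction must be in [0, 1]")
        if not 0.0 <= self.stacked_overlap_fraction <= 1.0:
            raise ValueError("stacked_overlap_fraction must be in [0, 1]")

    def with_fragmented_mode(self) -> "FilterConfig":
        return replace(self, fragmented_min_query_seq_len=self.FRAGMENTED_DEFAULT)

    @property
    def effective_min_query_seq_len(self) -> int:
        if self.fragmented_min_query_seq_len is not None:
            return max(self.min_query_seq_len, self.fragmented_min_query_seq_len)
        return self.min_query_seq_len


@dataclass
class FilterOutcome:
    """Partition of input blocks into retained / discarded / stacked."""

    retained: list[AlignmentBlock] = field(default_factory=list)
    discarded: list[tuple[AlignmentBlock, str]] = field(default_factory=list)
    stacked: list[AlignmentBlock] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.discarded) + len(self.stacked)

    @property
    def discarded_bp(self) -> int:
        return sum(b.query_span for b, _ in self.discarded)

    @property
    def stacked_bp(self) -> int:
        return sum(b.query_span for b in self.stacked)

    @property
    def retained_bp(self) -> int:
        return sum(b.query_span for b in self.retained)


def discard_reason(block: AlignmentBlock, cfg: FilterConfig) -> str | None:
    """First failing criterion, or None if the block passes all four."""
    if block.query_seq_len < cfg.effective_min_query_seq_len:
        return DiscardReason.QUERY_TOO_SHORT
    if block.block_len < cfg.min_block_len:
        return DiscardReason.BLOCK_TOO_SHORT
    if block.mapq < cfg.min_mapq:
        return DiscardReason.LOW_MAPQ
    if block.residue_matches / block.block_len < cfg.min_match_fraction:
        return DiscardReason.LOW_MATCH_FRACTION
    return None


def filter_blocks(blocks: list[AlignmentBlock], cfg: FilterConfig | None = None) -> FilterOutcome:
    """Apply the four retention filters; stacked detection is separate."""
    cfg = cfg or FilterConfig()
    outcome = FilterOutcome()
    for block in blocks:
        reason = discard_reason(block, cfg)
        if reason is None:
            outcome.retained.append(block)
        else:
            outcome.discarded.append((block, reason))
    return outcome


def _query_overlap(a: AlignmentBlock, b: AlignmentBlock) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start)


def _stacking_loser(a: AlignmentBlock, b: AlignmentBlock) -> AlignmentBlock:
    """The block set aside from an overlapping pair: the shorter one.

    Length ties keep the block with more residue matches, then the
    lexicographically smaller (target_name, target_start, query_start).
    """
    if a.query_span != b.query_span:
        return a if a.query_span < b.query_span else b
    if a.residue_matches != b.residue_matches:
        return a if a.residue_matches < b.residue_matches else b
    ka = (a.target_name, a.target_start, a.query_start)
    kb = (b.target_name, b.target_start, b.query_start)
    return b if ka <= kb else a


def _sort_key(b: AlignmentBlock) -> tuple:
    return (
        b.query_name, b.query_start, b.query_end,
        b.target_name, b.target_start, b.strand,
    )


def detect_stacked(blocks: list[AlignmentBlock], cfg: FilterConfig | None = None) -> FilterOutcome:
    """Move stacked blocks out of the retained set.

    Within each query sequence: while any two surviving blocks overlap (in
    query coordinates) by more than ``stacked_overlap_fraction`` of the
    shorter block's span, mark one block per round — the globally shortest
    losing block among all offending pairs (deterministic tie-breaks) — and
    re-examine.  The result is independent of input order.
    """
    cfg = cfg or FilterConfig()
    by_query: dict[str, list[AlignmentBlock]] = {}
    for block in blocks:
        by_query.setdefault(block.query_name, []).append(block)

    stacked: list[AlignmentBlock] = []
    kept: list[AlignmentBlock] = []
    for group in by_query.values():
        alive = sorted(group, key=_sort_key)
        while True:
            losers = []
            for i in range(len(alive)):
                for j in range(i + 1, len(alive)):
                    a, b = alive[i], alive[j]
                    overlap = _query_overlap(a, b)
                    shorter = min(a.query_span, b.query_span)
                    if overlap > cfg.stacked_overlap_fraction * shorter:
                        losers.append(_stacking_loser(a, b))
            if not losers:
                break
            # one removal per round keeps the rule canonical under ties
            victim = min(losers, key=lambda x: (x.query_span, x.residue_matches, _sort_key(x)))
            alive.remove(victim)
            stacked.append(victim)
        kept.extend(alive)

    order = {id(b): i for i, b in enumerate(blocks)}
    kept.sort(key=lambda b: order[id(b)])
    return FilterOutcome(retained=kept, stacked=sorted(stacked, key=_sort_key))


def apply_filters(blocks: list[AlignmentBlock], cfg: FilterConfig | None = None) -> FilterOutcome:
    """Retention filters followed by stacked detection, as one partition."""
    cfg = cfg or FilterConfig()
    first = filter_blocks(blocks, cfg)
    second = detect_stacked(first.retained, cfg)
    return FilterOutcome(
        retained=second.retained,
        discarded=first.discarded,
        stacked=second.stacked,
    )
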