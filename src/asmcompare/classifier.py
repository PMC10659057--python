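"""Structural discrepancy classification of retained alignment blocks.

Each retained block receives exactly one label, assigned in a fixed
precedence order so that nested discrepancies are never stacked:

1. **debris** — the block's query sequence is an unplaced scrap in the
   query assembly while its target is chromosome-assigned in the
   reference (small sequences assimilated in one assembly but not the
   other).
2. **translocation** — the query sequence is a chromosome but the block
   aligns to a reference chromosome other than the dominant homolog of
   its query chromosome.
3. **inversion** — the block's strand opposes the dominant mapping
   direction of its reference sequence.
4. **relocation** — the block falls outside the collinear backbone of its
   reference sequence: it aligns to the right chromosome in the right
   orientation but out of order.
5. **congruent** — everything else.

Dominant targets and strands are argmaxes of summed aligned bp over the
blocks still unlabeled at that precedence step.  The collinear backbone is
the bp-weight-maximal subset of blocks whose reference positions increase
along the query — a weighted longest-increasing-subsequence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .io_formats import (
    CHROMOSOME,
    UNPLACED_DEBRIS,
    AlignmentBlock,
    AssemblyCatalog,
)

__all__ = [
    "Label",
    "LabeledBlock",
    "HomologyMap",
    "UndefinedHomologError",
    "dominant_target",
    "dominant_strand",
    "backbone",
    "classify_blocks",
    "DISCREPANCY_LABELS",
]


class Label(str, enum.Enum):
    CONGRUENT = "congruent"
    DEBRIS = "debris"
    TRANSLOCATION = "translocation"
    INVERSION = "inversion"
    RELOCATION = "relocation"
    UNASSESSED_DISCARDED = "unassessed_discarded"
    UNASSESSED_STACKED = "unassessed_stacked"
    UNASSESSED_UNALIGNED = "unassessed_unaligned"


DISCREPANCY_LABELS = (
    Label.DEBRIS,
    Label.TRANSLOCATION,
    Label.INVERSION,
    Label.RELOCATION,
)


@dataclass(frozen=True)
class LabeledBlock:
    block: AlignmentBlock
    label: Label
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.label in DISCREPANCY_LABELS and not self.evidence:
            raise ValueError(f"{self.label.value} label requires evidence")


@dataclass
class HomologyMap:
    """Dominant homologs resolved during classification.

    ``query_to_target`` maps each query chromosome to its dominant
    reference sequence and the aligned bp supporting it;
    ``target_strand`` maps each reference sequence to its dominant strand
    and supporting bp.
    """

    query_to_target: dict[str, tuple[str, int]]
    target_strand: dict[str, tuple[str, int]]


class UndefinedHomologError(ValueError):
    """No retained blocks from the named query sequence."""


def dominant_target(blocks: list[AlignmentBlock], query_chr: str) -> tuple[str, int]:
    """Reference sequence receiving the most aligned bp from ``query_chr``.

    Ties go to the larger support, then the lexicographically smaller
    target name.
    """
    support: dict[str, int] = {}
    for b in blocks:
        if b.query_name == query_chr:
            support[b.target_name] = support.get(b.target_name, 0) + b.query_span
    if not support:
        raise UndefinedHomologError(f"no retained blocks from query {query_chr!r}")
    best = min(support.items(), key=lambda kv: (-kv[1], kv[0]))
    return best


def dominant_strand(blocks: list[AlignmentBlock], target_seq: str) -> str:
    """Strand with the most aligned bp on ``target_seq``; ties -> forward."""
    fwd = sum(b.query_span for b in blocks if b.target_name == target_seq and b.strand == "+")
    rev = sum(b.query_span for b in blocks if b.target_name == target_seq and b.strand == "-")
    if fwd == 0 and rev == 0:
        raise ValueError(f"no blocks on target {target_seq!r}")
    return "+" if fwd >= rev else "-"


def backbone(blocks: list[AlignmentBlock], dominant: str = "+") -> set[int]:
    """Indices of the collinear backbone of same-target blocks.

    Blocks are ordered along the query — (query_name, query_start), with
    within-query order reversed when the dominant strand is reverse — and
    the backbone is the subset of maximal total query bp whose
    target_start values are strictly increasing in that order, found by
    weighted longest-increasing-subsequence DP (O(n^2)).  Non-members are
    relocation candidates.
    """
    n = len(blocks)
    if n == 0:
        return set()
    sign = 1 if dominant == "+" else -1
    order = sorted(range(n), key=lambda i: (blocks[i].query_name, sign * blocks[i].query_start))
    starts = [blocks[i].target_start for i in order]
    weights = [blocks[i].query_span for i in order]

    best = list(weights)  # best[i]: max weight of an increasing chain ending at i
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if starts[j] < starts[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    # deterministic argmax: highest weight, then earliest end position
    end = min(range(n), key=lambda i: (-best[i], i))
    members: set[int] = set()
    while end != -1:
        members.add(order[end])
        end = prev[end]
    return members


def classify_blocks(
    retained: list[AlignmentBlock],
    query_catalog: AssemblyCatalog,
    ref_catalog: AssemblyCatalog,
    debris_side: str = "query",
) -> tuple[list[LabeledBlock], HomologyMap]:
    """Assign one precedence-ordered label to every retained block.

    ``debris_side`` selects which assembly's unplaced scraps count as
    debris: ``"query"`` (default — small query sequences aligning into
    reference chromosomes), ``"reference"`` (query chromosomes aligning
    into unplaced reference sequences), or ``"both"``.
    """
    if debris_side not in ("query", "reference", "both"):
        raise ValueError(f"debris_side must be query|reference|both, got {debris_side!r}")
    for b in retained:
        if b.query_name not in query_catalog.sequences:
            raise KeyError(f"query sequence {b.query_name!r} missing from query catalog")
        if b.target_name not in ref_catalog.sequences:
            raise KeyError(f"target sequence {b.target_name!r} missing from reference catalog")

    labels: dict[int, LabeledBlock] = {}

    # (1) debris
    survivors: list[tuple[int, AlignmentBlock]] = []
    for i, b in enumerate(retained):
        q_debris = query_catalog.status_of(b.query_name) == UNPLACED_DEBRIS
        t_chrom = ref_catalog.status_of(b.target_name) == CHROMOSOME
        q_chrom = query_catalog.status_of(b.query_name) == CHROMOSOME
        t_debris = ref_catalog.status_of(b.target_name) == UNPLACED_DEBRIS
        is_debris = False
        if debris_side in ("query", "both") and q_debris and t_chrom:
            is_debris = True
            side = "query"
        if debris_side in ("reference", "both") and q_chrom and t_debris:
            is_debris = True
            side = "reference"
        if is_debris:
            labels[i] = LabeledBlock(b, Label.DEBRIS, evidence=f"unplaced on {side} side")
        else:
            survivors.append((i, b))

    # (2) translocation: dominant target per query chromosome over blocks
    # surviving the debris step
    surviving_blocks = [b for _, b in survivors]
    query_to_target: dict[str, tuple[str, int]] = {}
    for name in {b.query_name for b in surviving_blocks}:
        if query_catalog.status_of(name) == CHROMOSOME:
            query_to_target[name] = dominant_target(surviving_blocks, name)
    next_survivors: list[tuple[int, AlignmentBlock]] = []
    for i, b in survivors:
        dom = query_to_target.get(b.query_name)
        if dom is not None and b.target_name != dom[0]:
            labels[i] = LabeledBlock(
                b,
                Label.TRANSLOCATION,
                evidence=f"dominant target of {b.query_name} is {dom[0]} ({dom[1]} bp)",
            )
        else:
            next_survivors.append((i, b))
    survivors = next_survivors

    # (3) inversion: dominant strand per reference sequence over blocks
    # surviving earlier steps
    surviving_blocks = [b for _, b in survivors]
    target_strand: dict[str, tuple[str, int]] = {}
    for name in {b.target_name for b in surviving_blocks}:
        strand = dominant_strand(surviving_blocks, name)
        support = sum(
            b.query_span for b in surviving_blocks
            if b.target_name == name and b.strand == strand
        )
        target_strand[name] = (strand, support)
    next_survivors = []
    for i, b in survivors:
        strand, support = target_strand[b.target_name]
        if b.strand != strand:
            labels[i] = LabeledBlock(
                b,
                Label.INVERSION,
                evidence=f"dominant strand of {b.target_name} is {strand} ({support} bp)",
            )
        else:
            next_survivors.append((i, b))
    survivors = next_survivors

    # (4) relocation: backbone per reference sequence
    by_target: dict[str, list[tuple[int, AlignmentBlock]]] = {}
    for i, b in survivors:
        by_target.setdefault(b.target_name, []).append((i, b))
    for name, group in by_target.items():
        strand = target_strand[name][0]
        members = backbone([b for _, b in group], dominant=strand)
        for k, (i, b) in enumerate(group):
            if k in members:
                labels[i] = LabeledBlock(b, Label.CONGRUENT, evidence="backbone")
            else:
                labels[i] = LabeledBlock(
                    b, Label.RELOCATION, evidence=f"outside backbone of {name}"
                )

    homology = HomologyMap(query_to_target=query_to_target, target_strand=target_strand)
    return [labels[i] for i in range(len(retained))], homology
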