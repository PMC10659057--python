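"""Per-category tallies, per-chromosome profiles, and the repeat regression.

Category bp are summed query-block lengths.  Percentages are taken of the
total evaluated reference — by default the sum of all category bp, so the
six categories always partition the total exactly; a reference-assembly
denominator is available as an alternative reading, in which case the
unaligned remainder of the reference is folded into "unassessed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

from .classifier import DISCREPANCY_LABELS, Label, LabeledBlock
from .filtering import FilterOutcome
from .io_formats import AssemblyCatalog, RepeatTrack

__all__ = [
    "DiscrepancyTable",
    "ChromosomeProfile",
    "RegressionResult",
    "round_half_up",
    "tally",
    "table_from_bp",
    "total_discrepancy",
    "chromosome_profiles",
    "regress",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class DiscrepancyTable:
    """Per-category bp and percentages for one genome comparison.

    ``bp`` maps each of the six categories to its summed query-block bp;
    ``evaluated_total`` is the denominator.  Percentages are exposed at
    full precision (:meth:`pct`) and at printed precision
    (:meth:`formatted_pct`: half-up, two decimals below 10%, one above).
    """

    CATEGORIES = (
        "debris",
        "translocation",
        "inversion",
        "relocation",
        "unassessed",
        "congruent",
    )

    bp: dict[str, int]
    evaluated_total: int
    comparison: str = ""

    def __post_init__(self) -> None:
        if self.evaluated_total <= 0:
            raise ValueError("evaluated_total must be positive")
        for category in self.CATEGORIES:
            self.bp.setdefault(category, 0)

    def pct(self, category: str) -> float:
        return 100.0 * self.bp[category] / self.evaluated_total

    def formatted_pct(self, category: str) -> float:
        p = self.pct(category)
        return round_half_up(p, 2 if p < 10 else 1)

    @property
    def percentages(self) -> dict[str, float]:
        return {c: self.pct(c) for c in self.CATEGORIES}

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "evaluated_total": self.evaluated_total,
            "bp": {c: self.bp[c] for c in self.CATEGORIES},
            "pct": self.percentages,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DiscrepancyTable":
        return cls(
            bp=dict(payload["bp"]),
            evaluated_total=payload["evaluated_total"],
            comparison=payload.get("comparison", ""),
        )


_LABEL_TO_CATEGORY = {
    Label.DEBRIS: "debris",
    Label.TRANSLOCATION: "translocation",
    Label.INVERSION: "inversion",
    Label.RELOCATION: "relocation",
    Label.CONGRUENT: "congruent",
}


def tally(
    labeled: list[LabeledBlock],
    outcome: FilterOutcome,
    ref_catalog: AssemblyCatalog,
    denominator: str = "evaluated",
    comparison: str = "",
) -> DiscrepancyTable:
    """Sum labeled query-block bp into the six-category table.

    Unassessed bp = discarded bp + stacked bp; with
    ``denominator="assembly"`` the reference assembly length is the
    denominator and its unaligned remainder is also counted unassessed,
    with ``denominator="evaluated"`` (default) the denominator is the sum
    of all category bp.  Either way the categories partition the total.
    """
    if denominator not in ("evaluated", "assembly"):
        raise ValueError(f"denominator must be evaluated|assembly, got {denominator!r}")
    bp = {c: 0 for c in DiscrepancyTable.CATEGORIES}
    for lb in labeled:
        bp[_LABEL_TO_CATEGORY[lb.label]] += lb.block.query_span
    bp["unassessed"] = outcome.discarded_bp + outcome.stacked_bp
    if denominator == "assembly":
        evaluated_total = ref_catalog.total_length
        remainder = evaluated_total - sum(bp.values())
        if remainder < 0:
            raise ValueError(
                "aligned bp exceed the reference assembly length; use the "
                "evaluated denominator for this comparison"
            )
        bp["unassessed"] += remainder
    else:
        evaluated_total = sum(bp.values())
    if evaluated_total == 0:
        raise ValueError("nothing to tally: evaluated total is zero")
    return DiscrepancyTable(bp=bp, evaluated_total=evaluated_total, comparison=comparison)


def table_from_bp(
    bp: dict[str, int], evaluated_total: int | None = None, comparison: str = ""
) -> DiscrepancyTable:
    """Build a table directly from per-category bp counts.

    The entry point for re-deriving percentages from a published
    comparison's bp counts; the default denominator is their sum.
    """
    counts = {c: int(bp.get(c, 0)) for c in DiscrepancyTable.CATEGORIES}
    total = evaluated_total if evaluated_total is not None else sum(counts.values())
    return DiscrepancyTable(bp=counts, evaluated_total=total, comparison=comparison)


def total_discrepancy(table_or_percentages) -> float:
    """Headline total: the four discrepancy percentages summed, 1 decimal.

    Accepts a :class:`DiscrepancyTable` (full-precision percentages) or a
    mapping of already-printed per-category percentages.
    """
    if isinstance(table_or_percentages, DiscrepancyTable):
        pcts = {c: table_or_percentages.pct(c) for c in ("debris", "translocation", "inversion", "relocation")}
    else:
        pcts = table_or_percentages
    total = sum(pcts[c] for c in ("debris", "translocation", "inversion", "relocation"))
    return round_half_up(total, 1)


@dataclass(frozen=True)
class ChromosomeProfile:
    name: str
    length: int
    discrepancy_bp: int
    repeat_bp: int
    is_x: bool = False

    @property
    def discrepancy_pct(self) -> float:
        return 100.0 * self.discrepancy_bp / self.length

    @property
    def repeat_pct(self) -> float:
        return 100.0 * self.repeat_bp / self.length


def chromosome_profiles(
    labeled: list[LabeledBlock],
    ref_catalog: AssemblyCatalog,
    repeats: RepeatTrack,
) -> list[ChromosomeProfile]:
    """Per-reference-chromosome discrepancy and repeat percentages.

    Discrepancy bp of a chromosome is the summed query bp of
    discrepancy-labeled blocks aligning to it (debris attributed to the
    chromosome its blocks hit); repeat bp comes from the merged track.
    Every catalog chromosome gets a profile, discrepancy-free ones at 0%.
    """
    disc_bp: dict[str, int] = {}
    for lb in labeled:
        if lb.label in DISCREPANCY_LABELS:
            disc_bp[lb.block.target_name] = (
                disc_bp.get(lb.block.target_name, 0) + lb.block.query_span
            )
    return [
        ChromosomeProfile(
            name=rec.name,
            length=rec.length,
            discrepancy_bp=disc_bp.get(rec.name, 0),
            repeat_bp=repeats.repeat_bp(rec.name),
            is_x=rec.is_x,
        )
        for rec in ref_catalog.chromosomes
    ]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n_chromosomes: int
    alpha_corrected: float
    significant: bool
    excluded_x: bool


def regress(
    profiles: list[ChromosomeProfile],
    exclude_x: bool = False,
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS of per-chromosome discrepancy % on repeat %.

    The two-sided slope p-value is compared against a Bonferroni-corrected
    threshold alpha / n_comparisons, with n_comparisons the number of
    pairwise genome comparisons in the study.
    """
    points = [p for p in profiles if not (exclude_x and p.is_x)]
    if len(points) < 3:
        raise ValueError(f"need >= 3 chromosomes for regression, have {len(points)}")
    x = [p.repeat_pct for p in points]
    y = [p.discrepancy_pct for p in points]
    if len(set(x)) == 1:
        raise ValueError("repeat % identical across chromosomes; slope undefined")
    fit = stats.linregress(x, y)
    alpha_corrected = alpha / n_comparisons
    r_squared = fit.rvalue**2
    if math.isnan(r_squared):  # constant response: no variance to explain
        r_squared = 0.0
    return RegressionResult(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=r_squared,
        p_value=fit.pvalue,
        slope_stderr=fit.stderr,
        n_chromosomes=len(points),
        alpha_corrected=alpha_corrected,
        significant=bool(fit.pvalue < alpha_corrected),
        excluded_x=exclude_x,
    )
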