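"""Pairing NIPT reports with newborn serology and participant-flow accounting.

The reference standard is the newborn's serological RhD phenotype from
cord blood, aggregated per pregnancy: a multiple pregnancy counts as one
RhD-positive newborn if at least one child is RhD positive or weak D.
Only pregnancies with a conclusive NIPT report and a known reference
enter the 2x2 contingency table; the flow summary accounts for everyone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .cohort import Pregnancy, Reference, aggregate_reference
from .interpret import Category, INCONCLUSIVE_CATEGORIES, NiptReport

__all__ = [
    "ComparisonRecord",
    "FlowSummary",
    "TwoByTwo",
    "build_records",
    "make_flow",
    "two_by_two",
    "subset_by_ga",
    "records_to_dataframe",
    "write_comparison_csv",
    "read_comparison_csv",
]

#: records sampled before this day count as "up to 19 completed weeks"
GA_19WG_BOUNDARY_DAYS = 140


@dataclass(frozen=True)
class ComparisonRecord:
    """Paired NIPT report and aggregated serology for one pregnancy."""

    id: str
    nipt: NiptReport
    reference: Reference
    ga_total_days: int
    n_fetuses: int


@dataclass(frozen=True)
class TwoByTwo:
    """Diagnostic 2x2 contingency counts (reference in columns)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class FlowSummary:
    """Participant-flow counts mirroring a study flow diagram."""

    n_total: int
    n_conclusive: int
    n_inconclusive: int
    inconclusive_by_reason: dict[Category, int]
    n_with_followup: int
    n_ref_positive: int
    n_ref_negative: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_conclusive + self.n_inconclusive:
            raise ValueError("n_total must equal conclusive + inconclusive")
        if sum(self.inconclusive_by_reason.values()) != self.n_inconclusive:
            raise ValueError("inconclusive reasons must sum to n_inconclusive")
        if self.n_with_followup != self.n_ref_positive + self.n_ref_negative:
            raise ValueError("followup must equal ref positive + ref negative")
        if self.n_with_followup > self.n_conclusive:
            raise ValueError("followup cannot exceed conclusive")

    def to_dict(self) -> dict:
        from .accuracy import format_pct

        d = {
            "n_total": self.n_total,
            "n_conclusive": self.n_conclusive,
            "n_inconclusive": self.n_inconclusive,
            "inconclusive_by_reason": {
                k.value: v for k, v in self.inconclusive_by_reason.items()
            },
            "n_with_followup": self.n_with_followup,
            "n_ref_positive": self.n_ref_positive,
            "n_ref_negative": self.n_ref_negative,
        }
        if self.n_total:
            d["conclusive_pct"] = format_pct(self.n_conclusive / self.n_total)
            d["inconclusive_pct"] = format_pct(self.n_inconclusive / self.n_total)
        if self.n_conclusive:
            d["followup_pct"] = format_pct(self.n_with_followup / self.n_conclusive)
        return d


def build_records(
    cohort: list[Pregnancy], reports: list[NiptReport]
) -> list[ComparisonRecord]:
    """Join pregnancies with their NIPT reports by id (strict 1:1).

    The reference is the serology aggregate over live (non-vanished)
    fetuses when newborn follow-up is available, else MISSING.
    """
    by_id: dict[str, NiptReport] = {}
    for r in reports:
        if r.id is None:
            raise ValueError("report without id cannot be joined")
        if r.id in by_id:
            raise ValueError(f"duplicate report id: {r.id}")
        by_id[r.id] = r
    seen = set()
    records = []
    for p in cohort:
        if p.id in seen:
            raise ValueError(f"duplicate pregnancy id: {p.id}")
        seen.add(p.id)
        if p.id not in by_id:
            raise ValueError(f"pregnancy without report: {p.id}")
        live = p.live_fetuses
        if p.followup_available and live:
            ref = aggregate_reference(live)
        else:
            ref = Reference.MISSING
        records.append(
            ComparisonRecord(
                id=p.id,
                nipt=by_id.pop(p.id),
                reference=ref,
                ga_total_days=p.ga_at_sampling.total_days,
                n_fetuses=p.n_fetuses,
            )
        )
    if by_id:
        raise ValueError(f"reports without pregnancy: {sorted(by_id)}")
    return records


def make_flow(records: list[ComparisonRecord]) -> FlowSummary:
    """Count participants through the testing flow."""
    if not records:
        warnings.warn("empty record list: all-zero flow summary", stacklevel=2)
    by_reason = {c: 0 for c in INCONCLUSIVE_CATEGORIES}
    n_concl = n_fu = n_pos = n_neg = 0
    for r in records:
        if r.nipt.category.conclusive:
            n_concl += 1
            if r.reference is Reference.REF_POSITIVE:
                n_fu += 1
                n_pos += 1
            elif r.reference is Reference.REF_NEGATIVE:
                n_fu += 1
                n_neg += 1
        else:
            by_reason[r.nipt.category] += 1
    return FlowSummary(
        n_total=len(records),
        n_conclusive=n_concl,
        n_inconclusive=len(records) - n_concl,
        inconclusive_by_reason=by_reason,
        n_with_followup=n_fu,
        n_ref_positive=n_pos,
        n_ref_negative=n_neg,
    )


def two_by_two(records: list[ComparisonRecord]) -> TwoByTwo:
    """2x2 counts over conclusive records with a known reference."""
    tp = fn = tn = fp = 0
    for r in records:
        if not r.nipt.category.conclusive or r.reference is Reference.MISSING:
            continue
        pos_pred = r.nipt.category is Category.POSITIVE
        pos_ref = r.reference is Reference.REF_POSITIVE
        if pos_pred and pos_ref:
            tp += 1
        elif not pos_pred and pos_ref:
            fn += 1
        elif not pos_pred and not pos_ref:
            tn += 1
        else:
            fp += 1
    return TwoByTwo(tp=tp, fn=fn, tn=tn, fp=fp)


def subset_by_ga(
    records: list[ComparisonRecord], max_total_days: int
) -> tuple[list[ComparisonRecord], list[ComparisonRecord]]:
    """Partition records at a gestational-age boundary.

    Returns (kept, excluded): kept are sampled strictly before
    ``max_total_days`` (140 days keeps everything up to 19+6 weeks).
    """
    if max_total_days < 0:
        raise ValueError("max_total_days must be >= 0")
    kept = [r for r in records if r.ga_total_days < max_total_days]
    excluded = [r for r in records if r.ga_total_days >= max_total_days]
    return kept, excluded


# ---------------------------------------------------------------------------
# comparison CSV
# ---------------------------------------------------------------------------

def records_to_dataframe(records: list[ComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "category": [r.nipt.category.value for r in records],
            "call_count": [r.nipt.call_count for r in records],
            "reference": [r.reference.value for r in records],
            "ga_total_days": [r.ga_total_days for r in records],
            "n_fetuses": [r.n_fetuses for r in records],
        }
    )


def write_comparison_csv(records: list[ComparisonRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False, encoding="utf-8")


def read_comparison_csv(path) -> list[ComparisonRecord]:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
    return [
        ComparisonRecord(
            id=row["id"],
            nipt=NiptReport(
                category=Category(row["category"]),
                call_count=int(row["call_count"]),
                id=row["id"],
            ),
            reference=Reference(row["reference"]),
            ga_total_days=int(row["ga_total_days"]),
            n_fetuses=int(row["n_fetuses"]),
        )
        for _, row in df.iterrows()
    ]
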