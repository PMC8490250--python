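"""Reference counts from a large routine NIPT-RhD performance evaluation.

These are the printed counts of a single-center clinical evaluation of a
triplicate 3-exon real-time-PCR NIPT-RhD assay: 2968 RhD-negative
pregnancies tested between 5+6 and 40+0 weeks (199 twin, 7 triplet),
2888 conclusive results, 2244 with newborn serology follow-up, one
false negative and three false positives.  They serve as the package's
worked example: feeding them through the accuracy model reproduces the
published sensitivity/specificity/accuracy figures, and the synthetic
record reconstruction lets every pipeline stage downstream of
interpretation run on the real study margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import Reference
from .concordance import ComparisonRecord, TwoByTwo
from .interpret import Category, NiptReport

__all__ = ["StudyCounts", "clinical_evaluation_counts", "records_from_counts"]


@dataclass(frozen=True)
class StudyCounts:
    """Participant-flow and contingency counts of the evaluation study."""

    n_total: int
    inconclusive_by_reason: dict[Category, int]
    n_with_followup: int
    overall: TwoByTwo
    early: TwoByTwo          # sampled before 20+0 weeks
    n_multiples: int
    n_multiples_conclusive: int
    n_multiples_followup: int
    multiples_ref_positive: int
    multiples_ref_negative: int

    @property
    def n_inconclusive(self) -> int:
        return sum(self.inconclusive_by_reason.values())

    @property
    def n_conclusive(self) -> int:
        return self.n_total - self.n_inconclusive


def clinical_evaluation_counts() -> StudyCounts:
    """Counts as printed by the evaluation study (n = 2968)."""
    return StudyCounts(
        n_total=2968,
        inconclusive_by_reason={
            Category.INC_MATERNAL_VARIANT: 15,
            Category.INC_CALLS: 29,
            Category.INC_D_VARIANT: 9,
            Category.INC_FETAL_MARKER: 27,
        },
        n_with_followup=2244,
        overall=TwoByTwo(tp=1474, fn=1, tn=766, fp=3),
        early=TwoByTwo(tp=1143, fn=1, tn=609, fp=3),
        n_multiples=206,
        n_multiples_conclusive=205,
        n_multiples_followup=203,
        multiples_ref_positive=142,  # incl. the both-twins-weak-D pregnancy
        multiples_ref_negative=61,
    )


def _rec(i: int, category: Category, reference: Reference, ga_days: int,
         n_fetuses: int = 1, call_count: int | None = None) -> ComparisonRecord:
    if call_count is None:
        call_count = {Category.POSITIVE: 9, Category.NEGATIVE: 0}.get(category, 5)
    rid = f"S{i:06d}"
    return ComparisonRecord(
        id=rid,
        nipt=NiptReport(category=category, call_count=call_count, id=rid),
        reference=reference,
        ga_total_days=ga_days,
        n_fetuses=n_fetuses,
    )


def records_from_counts(counts: StudyCounts | None = None) -> list[ComparisonRecord]:
    """Synthetic comparison records reproducing the study margins exactly.

    Individual-level data were never published; this reconstruction
    assigns gestational ages (90 d for early records, 150 d for late,
    the single false negative at 13+4 = 95 d) and pluralities so that
    the overall, early-gestation and multiple-pregnancy strata and the
    participant flow all reproduce the printed counts.
    """
    c = counts or clinical_evaluation_counts()
    early_d, late_d = 90, 150
    records: list[ComparisonRecord] = []
    i = 0

    def add(n, category, reference, ga_days, n_fetuses=1):
        nonlocal i
        for _ in range(n):
            records.append(_rec(i, category, reference, ga_days, n_fetuses))
            i += 1

    ov, ea = c.overall, c.early
    late = TwoByTwo(ov.tp - ea.tp, ov.fn - ea.fn, ov.tn - ea.tn, ov.fp - ea.fp)

    # multiples were fully concordant; place them among early true calls
    m_pos, m_neg = c.multiples_ref_positive, c.multiples_ref_negative
    add(m_pos, Category.POSITIVE, Reference.REF_POSITIVE, early_d, n_fetuses=2)
    add(m_neg, Category.NEGATIVE, Reference.REF_NEGATIVE, early_d, n_fetuses=2)
    add(ea.tp - m_pos, Category.POSITIVE, Reference.REF_POSITIVE, early_d)
    add(ea.tn - m_neg, Category.NEGATIVE, Reference.REF_NEGATIVE, early_d)
    add(ea.fn, Category.NEGATIVE, Reference.REF_POSITIVE, 95)  # the 13+4 case
    add(ea.fp, Category.POSITIVE, Reference.REF_NEGATIVE, early_d)
    add(late.tp, Category.POSITIVE, Reference.REF_POSITIVE, late_d)
    add(late.tn, Category.NEGATIVE, Reference.REF_NEGATIVE, late_d)
    add(late.fn, Category.NEGATIVE, Reference.REF_POSITIVE, late_d)
    add(late.fp, Category.POSITIVE, Reference.REF_NEGATIVE, late_d)

    # conclusive results whose newborns were typed elsewhere
    n_lost = c.n_conclusive - c.n_with_followup
    m_lost = c.n_multiples_conclusive - c.n_multiples_followup
    add(m_lost, Category.POSITIVE, Reference.MISSING, early_d, n_fetuses=2)
    add(n_lost - m_lost, Category.POSITIVE, Reference.MISSING, early_d)

    # the four inconclusive-report groups
    m_inc = c.n_multiples - c.n_multiples_conclusive
    add(m_inc, Category.INC_CALLS, Reference.MISSING, early_d, n_fetuses=2)
    for cat, n in c.inconclusive_by_reason.items():
        if cat is Category.INC_CALLS:
            n -= m_inc
        add(n, cat, Reference.MISSING, early_d)

    assert len(records) == c.n_total
    return records
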