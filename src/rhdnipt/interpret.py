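"""Call-interpretation rules for the triplicate 3-exon NIPT-RhD assay.

Samples with 0-2 of 9 RHD-specific calls are reported fetal RhD
negative, 7-9 calls RhD positive, 3-6 calls inconclusive.  On top of
the call bands sit three guards: a uniformly low ct in a fully positive
sample suggests a maternal non-coding RHD gene; an all-or-none exon
pattern in the 3-6 band suggests a fetal D-variant missing one or two
exons; and a negative call band is only reported negative when a fetal
marker confirms that fetal DNA was present.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import AssayResult, FetalMarkerPanel, N_REPLICATES, ReplicateCallMatrix
from .cohort import ASSAY_EXONS

__all__ = [
    "Category",
    "MarkerStatus",
    "Flag",
    "InterpretConfig",
    "NiptReport",
    "count_calls",
    "detect_maternal_variant",
    "detect_d_variant_pattern",
    "marker_status",
    "classify",
    "interpret_assays",
    "reports_to_dataframe",
    "write_reports_csv",
    "read_reports_csv",
]


class Category(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INC_MATERNAL_VARIANT = "INC_MATERNAL_VARIANT"
    INC_CALLS = "INC_CALLS"
    INC_D_VARIANT = "INC_D_VARIANT"
    INC_FETAL_MARKER = "INC_FETAL_MARKER"

    @property
    def conclusive(self) -> bool:
        return self in (Category.POSITIVE, Category.NEGATIVE)


INCONCLUSIVE_CATEGORIES = (
    Category.INC_MATERNAL_VARIANT,
    Category.INC_CALLS,
    Category.INC_D_VARIANT,
    Category.INC_FETAL_MARKER,
)


class MarkerStatus(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    INCONCLUSIVE = "INCONCLUSIVE"


class Flag(str, enum.Enum):
    LOW_CT = "LOW_CT"
    EXON_DROPOUT = "EXON_DROPOUT"
    MARKER_FAIL = "MARKER_FAIL"


@dataclass
class InterpretConfig:
    """Thresholds of the reporting rules.

    maternal_ct_threshold: median positive-well ct below which a fully
    positive sample is suspected to reflect a maternal RHD gene (maternal
    template outweighs fetal template by ~1/ff, i.e. several ct cycles).
    marker_positive_min_calls: replicate calls needed to call a fetal
    marker positive.  require_marker_for_negative: gate negative reports
    on a positive fetal marker.
    """

    maternal_ct_threshold: float = 32.0
    marker_positive_min_calls: int = 2
    require_marker_for_negative: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maternal_ct_threshold < 45.0:
            raise ValueError("maternal_ct_threshold must be in (0, 45)")
        if not 1 <= self.marker_positive_min_calls <= N_REPLICATES:
            raise ValueError("marker_positive_min_calls must be in 1..3")


@dataclass
class NiptReport:
    """The reported NIPT-RhD result for one sample."""

    category: Category
    call_count: int
    flags: frozenset[Flag] = frozenset()
    id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.call_count <= 9:
            raise ValueError("call_count must be in 0..9")


def count_calls(matrix: ReplicateCallMatrix) -> int:
    """Number of positive wells among the 9 RHD-specific reactions."""
    return matrix.n_calls


def detect_maternal_variant(matrix: ReplicateCallMatrix, cfg: InterpretConfig) -> bool:
    """Suspect a maternal non-coding RHD gene: full positivity at low ct.

    Maternal template amplifies in every well, so the flag requires a
    positive call band (>= 7 calls) in addition to the low median ct.
    """
    if matrix.n_calls < 7:
        return False
    med = matrix.median_ct()
    return med is not None and med < cfg.maternal_ct_threshold


def detect_d_variant_pattern(matrix: ReplicateCallMatrix) -> bool:
    """Suspect a fetal D-variant: 1-2 exons completely negative, rest full.

    Requires call count 3-6 with every exon all-or-none (0/3 or 3/3),
    at least one full exon and at least one empty exon.  Scattered
    partial positivity is stochastic dropout, not exon absence.
    """
    n = matrix.n_calls
    if not 3 <= n <= 6:
        return False
    per_exon = [matrix.exon_calls(e) for e in ASSAY_EXONS]
    return (
        all(c in (0, N_REPLICATES) for c in per_exon)
        and any(c == N_REPLICATES for c in per_exon)
        and any(c == 0 for c in per_exon)
    )


def marker_status(calls: int, cfg: InterpretConfig) -> MarkerStatus:
    """Replicate-count status of a single fetal-DNA marker."""
    if not 0 <= calls <= N_REPLICATES:
        raise ValueError(f"marker calls must be in 0..3, got {calls}")
    if calls >= cfg.marker_positive_min_calls:
        return MarkerStatus.POSITIVE
    if calls == 0:
        return MarkerStatus.NEGATIVE
    return MarkerStatus.INCONCLUSIVE


def classify(
    matrix: ReplicateCallMatrix,
    markers: FetalMarkerPanel,
    cfg: InterpretConfig | None = None,
) -> NiptReport:
    """Apply the reporting rules in fixed precedence order.

    1. maternal-variant suspicion (low-ct full positivity) -> inconclusive;
    2. 7-9 calls -> RhD positive;
    3. 3-6 calls with the all-or-none exon pattern -> D-variant suspected;
    4. 3-6 calls otherwise -> inconclusive call count;
    5. 0-2 calls -> RhD negative if a fetal marker is positive (or the
       marker gate is disabled), else inconclusive for missing fetal DNA.
    """
    cfg = cfg or InterpretConfig()
    n = count_calls(matrix)
    if detect_maternal_variant(matrix, cfg):
        return NiptReport(Category.INC_MATERNAL_VARIANT, n, frozenset({Flag.LOW_CT}))
    if n >= 7:
        return NiptReport(Category.POSITIVE, n)
    if n >= 3:
        if detect_d_variant_pattern(matrix):
            return NiptReport(Category.INC_D_VARIANT, n, frozenset({Flag.EXON_DROPOUT}))
        return NiptReport(Category.INC_CALLS, n)
    marker_ok = (
        marker_status(markers.sry_calls, cfg) is MarkerStatus.POSITIVE
        or marker_status(markers.rassf1a_calls, cfg) is MarkerStatus.POSITIVE
    )
    if marker_ok or not cfg.require_marker_for_negative:
        return NiptReport(Category.NEGATIVE, n)
    return NiptReport(Category.INC_FETAL_MARKER, n, frozenset({Flag.MARKER_FAIL}))


def interpret_assays(
    results: list[AssayResult], cfg: InterpretConfig | None = None
) -> list[NiptReport]:
    """Stage-2 driver: classify every assay result, preserving ids."""
    cfg = cfg or InterpretConfig()
    out = []
    for r in results:
        rep = classify(r.matrix, r.markers, cfg)
        rep.id = r.id
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# reports CSV
# ---------------------------------------------------------------------------

def reports_to_dataframe(reports: list[NiptReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in reports],
            "category": [r.category.value for r in reports],
            "call_count": [r.call_count for r in reports],
            "flags": [";".join(sorted(f.value for f in r.flags)) for r in reports],
        }
    )


def write_reports_csv(reports: list[NiptReport], path) -> None:
    reports_to_dataframe(reports).to_csv(path, index=False, encoding="utf-8")


def read_reports_csv(path) -> list[NiptReport]:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        flags = frozenset(Flag(t) for t in str(row["flags"]).split(";") if t)
        out.append(
            NiptReport(
                category=Category(row["category"]),
                call_count=int(row["call_count"]),
                flags=flags,
                id=row["id"],
            )
        )
    return out
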