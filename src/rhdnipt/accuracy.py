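"""Diagnostic-accuracy statistics with Wilson score confidence intervals.

Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
(TP+TN)/N are binomial proportions; each is reported with a Wilson
score interval

    center = (p + z^2/2n) / (1 + z^2/n)
    halfwidth = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)

with z the standard-normal quantile at (1+conf)/2 computed at full
double precision (no continuity correction).  Display rounding is
round-half-up on the percent scale.

The user-facing surface is a statsmodels-style pair: the
``DiagnosticAccuracy`` model is built from comparison records, counts
or a DataFrame, and ``fit()`` returns a ``DiagnosticAccuracyResults``
carrying the stratified estimates, their intervals, the participant
flow, and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import pandas as pd
from scipy.stats import norm

from .concordance import (
    GA_19WG_BOUNDARY_DAYS,
    ComparisonRecord,
    FlowSummary,
    TwoByTwo,
    make_flow,
    two_by_two,
)

__all__ = [
    "ProportionCI",
    "StratumAccuracy",
    "DiagnosticAccuracy",
    "DiagnosticAccuracyResults",
    "wilson_ci",
    "sens_spec_acc",
    "evaluate",
    "format_pct",
]


def format_pct(x: float, decimals: int = 2) -> str:
    """Percent string with round-half-up at the given precision."""
    q = Decimal(10) ** -decimals
    return str(Decimal(repr(float(x) * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion k/n with its Wilson score interval."""

    k: int
    n: int
    point: float
    lo: float
    hi: float
    conf: float = 0.95
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo <= self.point <= self.hi <= 1.0:
            raise ValueError("interval must satisfy 0 <= lo <= point <= hi <= 1")

    def pct(self, decimals: int = 2) -> str:
        return format_pct(self.point, decimals)

    def ci_pct(self, decimals: int = 2) -> tuple[str, str]:
        return format_pct(self.lo, decimals), format_pct(self.hi, decimals)

    def __str__(self) -> str:
        lo, hi = self.ci_pct()
        return f"{self.pct()}% ({int(self.conf * 100)}% CI {lo}-{hi}%)"


def wilson_ci(k: int, n: int, conf: float = 0.95) -> ProportionCI:
    """Wilson score interval for k successes out of n."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in 0..n, got k={k}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must be in (0, 1)")
    z = float(norm.ppf((1.0 + conf) / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # clip to [0,1]; the interval always contains p-hat, enforce it under
    # floating-point rounding at the k=0 / k=n boundaries
    lo = min(max(center - half, 0.0), p)
    hi = max(min(center + half, 1.0), p)
    return ProportionCI(k=k, n=n, point=p, lo=lo, hi=hi, conf=conf)


def sens_spec_acc(
    tb: TwoByTwo, conf: float = 0.95
) -> tuple[ProportionCI, ProportionCI, ProportionCI]:
    """Sensitivity, specificity and accuracy with Wilson intervals."""
    if tb.positives < 1:
        raise ValueError("empty positive margin (tp + fn = 0)")
    if tb.negatives < 1:
        raise ValueError("empty negative margin (tn + fp = 0)")
    return (
        wilson_ci(tb.tp, tb.positives, conf),
        wilson_ci(tb.tn, tb.negatives, conf),
        wilson_ci(tb.tp + tb.tn, tb.total, conf),
    )


@dataclass
class StratumAccuracy:
    """Accuracy triple for one stratum; triple is None on an empty margin."""

    name: str
    table: TwoByTwo
    sensitivity: ProportionCI | None
    specificity: ProportionCI | None
    accuracy: ProportionCI | None

    def to_dict(self) -> dict:
        d: dict = {
            "table": {"tp": self.table.tp, "fn": self.table.fn,
                      "tn": self.table.tn, "fp": self.table.fp},
        }
        for stat in ("sensitivity", "specificity", "accuracy"):
            ci = getattr(self, stat)
            if ci is None:
                d[stat] = None
            else:
                lo, hi = ci.ci_pct()
                d[stat] = {
                    "k": ci.k, "n": ci.n, "point": ci.point,
                    "lo": ci.lo, "hi": ci.hi, "conf": ci.conf,
                    "method": ci.method,
                    "pct": ci.pct(), "lo_pct": lo, "hi_pct": hi,
                }
        return d


def _default_subsets() -> dict[str, Callable[[ComparisonRecord], bool]]:
    return {
        "ga_le_19wg": lambda r: r.ga_total_days < GA_19WG_BOUNDARY_DAYS,
        "multiples": lambda r: r.n_fetuses >= 2,
    }


class DiagnosticAccuracy:
    """Diagnostic-accuracy model over paired test/reference records.

    Parameters
    ----------
    records
        Comparison records (one pregnancy each); may be None when the
        model is built from bare counts.
    subsets
        Mapping of stratum name to record predicate.  By default the
        early-gestation stratum (sampled before 20+0 weeks) and the
        multiple-pregnancy stratum are evaluated alongside the overall
        cohort.

    Examples
    --------
    >>> from rhdnipt import DiagnosticAccuracy
    >>> res = DiagnosticAccuracy.from_counts(tp=1474, fn=1, tn=766, fp=3).fit()
    >>> res.sensitivity.pct()
    '99.93'
    """

    def __init__(
        self,
        records: list[ComparisonRecord] | None = None,
        subsets: dict[str, Callable[[ComparisonRecord], bool]] | None = None,
        table: TwoByTwo | None = None,
    ) -> None:
        if records is None and table is None:
            raise ValueError("need records or a contingency table")
        self.records = records
        self.subsets = _default_subsets() if subsets is None else dict(subsets)
        self._table = table

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "DiagnosticAccuracy":
        """Model from bare 2x2 counts (no strata, no flow)."""
        return cls(records=None, subsets={}, table=TwoByTwo(tp, fn, tn, fp))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DiagnosticAccuracy":
        """Model from a comparison table (schema of the comparison CSV)."""
        from .concordance import read_comparison_csv  # schema lives there
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(records=read_comparison_csv(buf), **kwargs)

    def fit(self, conf: float = 0.95) -> "DiagnosticAccuracyResults":
        """Compute all strata, intervals and the participant flow."""
        strata: dict[str, StratumAccuracy] = {}
        flow = None
        if self.records is not None:
            strata["overall"] = self._stratum("overall", two_by_two(self.records), conf)
            for name, pred in self.subsets.items():
                sub = [r for r in self.records if pred(r)]
                strata[name] = self._stratum(name, two_by_two(sub), conf)
            flow = make_flow(self.records)
        else:
            strata["overall"] = self._stratum("overall", self._table, conf)
        return DiagnosticAccuracyResults(model=self, strata=strata, flow=flow, conf=conf)

    @staticmethod
    def _stratum(name: str, tb: TwoByTwo, conf: float) -> StratumAccuracy:
        try:
            sens, spec, acc = sens_spec_acc(tb, conf)
        except ValueError as exc:
            warnings.warn(f"stratum {name!r}: {exc}; triple omitted", stacklevel=2)
            sens = spec = acc = None
        return StratumAccuracy(name, tb, sens, spec, acc)


@dataclass
class DiagnosticAccuracyResults:
    """Fitted accuracy estimates, their intervals and the flow summary."""

    model: DiagnosticAccuracy
    strata: dict[str, StratumAccuracy]
    flow: FlowSummary | None
    conf: float

    @property
    def overall(self) -> StratumAccuracy:
        return self.strata["overall"]

    @property
    def sensitivity(self) -> ProportionCI | None:
        return self.overall.sensitivity

    @property
    def specificity(self) -> ProportionCI | None:
        return self.overall.specificity

    @property
    def accuracy(self) -> ProportionCI | None:
        return self.overall.accuracy

    def to_dict(self) -> dict:
        d: dict = {
            "conf": self.conf,
            "strata": {name: s.to_dict() for name, s in self.strata.items()},
        }
        if self.flow is not None:
            d["flow"] = self.flow.to_dict()
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable accuracy table."""
        lines = [
            "Diagnostic accuracy (Wilson score intervals, "
            f"{int(self.conf * 100)}% confidence)",
            "=" * 74,
            f"{'stratum':<12}{'TP':>6}{'FN':>5}{'TN':>6}{'FP':>5}"
            f"  {'sensitivity':<22}{'specificity':<22}{'accuracy':<22}",
            "-" * 74,
        ]
        for name, s in self.strata.items():
            cells = []
            for ci in (s.sensitivity, s.specificity, s.accuracy):
                if ci is None:
                    cells.append(f"{'--':<22}")
                else:
                    lo, hi = ci.ci_pct()
                    cells.append(f"{ci.pct()}% ({lo}-{hi})".ljust(22))
            lines.append(
                f"{name:<12}{s.table.tp:>6}{s.table.fn:>5}{s.table.tn:>6}"
                f"{s.table.fp:>5}  " + "".join(cells)
            )
        if self.flow is not None:
            f = self.flow
            lines += [
                "-" * 74,
                f"flow: {f.n_total} tested, {f.n_conclusive} conclusive "
                f"({format_pct(f.n_conclusive / f.n_total) if f.n_total else '--'}%), "
                f"{f.n_inconclusive} inconclusive, "
                f"{f.n_with_followup} with newborn serology",
            ]
        return "\n".join(lines)


def evaluate(
    records: list[ComparisonRecord],
    subsets: dict[str, Callable[[ComparisonRecord], bool]] | None = None,
    conf: float = 0.95,
) -> DiagnosticAccuracyResults:
    """Stage-4 driver: fit the accuracy model over records and strata."""
    return DiagnosticAccuracy(records=records, subsets=subsets).fit(conf=conf)
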