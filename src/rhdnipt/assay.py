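"""Replicate-level real-time PCR simulator.

Each pregnancy yields a 3-exon x 3-replicate RHD call matrix with ct
values plus a fetal-marker panel (SRY for male fetuses, hypermethylated
RASSF1A as the sex-independent control).  The physical model is
limiting-dilution template sampling: template molecules per well are
Poisson, each is detected independently, a well is positive when at
least one molecule is detected, and ct follows a log-linear standard
curve in the number of detected copies.  Maternal non-coding RHD
variants add maternal-scale template (low ct) to every exon; vanished
fetuses keep contributing cfDNA at a decayed level; sample swaps model
mislabeling at blood draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ASSAY_EXONS, GestationalAge, Pregnancy, Sex

__all__ = [
    "AssayParams",
    "ReplicateCallMatrix",
    "FetalMarkerPanel",
    "AssayResult",
    "fetal_fraction",
    "simulate_rhd_matrix",
    "simulate_markers",
    "simulate_assays",
    "apply_mislabel",
    "assays_to_dataframe",
    "write_calls_csv",
    "read_calls_csv",
]

N_REPLICATES = 3


@dataclass
class AssayParams:
    """Physical calibration of the simulated assay.

    Defaults put ~13 fetal genome-equivalents into each well at the median
    booking visit (1000 GE/mL total cfDNA, 0.33 mL plasma per replicate,
    4% median fetal fraction at 12+6), so template dropout is rare but not
    absent in the first trimester, and give maternal-variant wells a ct
    roughly 5 cycles below fetal-only wells.
    """

    total_cfdna_copies_per_ml: float = 1000.0
    plasma_ml_per_replicate: float = 0.33
    # log fetal fraction ~ Normal(ff_intercept + ff_slope * ga_days, ff_sd);
    # intercept set so the median is 4% at 90 days with slope ln(2)/70
    ff_slope: float = math.log(2) / 70.0
    ff_intercept: float = math.log(0.04) - (math.log(2) / 70.0) * 90.0
    ff_sd: float = 0.6
    ff_max: float = 0.3
    detection_prob_per_copy: float = 0.5
    ct_intercept: float = 38.0   # ct of a single detected copy
    ct_slope: float = 3.32       # cycles per log10 copies (perfect efficiency)
    ct_noise_sd: float = 0.3
    spurious_call_prob: float = 0.002
    sry_efficiency: float = 1.0
    rassf1a_efficiency: float = 0.4  # methylation-digest losses
    vanished_cfdna_fraction: float = 0.5
    ipc_fail_prob: float = 0.0

    def validate(self) -> None:
        for name in (
            "total_cfdna_copies_per_ml",
            "plasma_ml_per_replicate",
            "ct_slope",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "detection_prob_per_copy",
            "spurious_call_prob",
            "sry_efficiency",
            "rassf1a_efficiency",
            "vanished_cfdna_fraction",
            "ipc_fail_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ff_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0.0 < self.ff_max <= 1.0:
            raise ValueError("ff_max must be in (0, 1]")


@dataclass
class ReplicateCallMatrix:
    """3 exons x 3 replicates of RHD-specific calls; max 9 positive calls."""

    calls: dict[tuple[int, int], bool]
    ct: dict[tuple[int, int], float]
    ipc_ok: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        expected = {(e, r) for e in ASSAY_EXONS for r in range(1, N_REPLICATES + 1)}
        if set(self.calls) != expected:
            raise ValueError("calls must cover 3 exons x 3 replicates")
        if set(self.ct) != {k for k, v in self.calls.items() if v}:
            raise ValueError("ct values must exist exactly for positive wells")

    @property
    def n_calls(self) -> int:
        return sum(self.calls.values())

    def exon_calls(self, exon: int) -> int:
        return sum(self.calls[(exon, r)] for r in range(1, N_REPLICATES + 1))

    def median_ct(self) -> float | None:
        """Median ct over positive wells; None when there is no call."""
        if not self.ct:
            return None
        return float(np.median(list(self.ct.values())))


@dataclass
class FetalMarkerPanel:
    """Replicate call counts of the fetal-DNA controls (0-3 each).

    Statuses (positive / negative / inconclusive) are assigned downstream
    by the interpretation rules, not here.
    """

    sry_calls: int
    rassf1a_calls: int

    def __post_init__(self) -> None:
        if not 0 <= self.sry_calls <= N_REPLICATES:
            raise ValueError("sry_calls out of range")
        if not 0 <= self.rassf1a_calls <= N_REPLICATES:
            raise ValueError("rassf1a_calls out of range")


@dataclass
class AssayResult:
    """Observed assay output for one sample tube."""

    id: str
    matrix: ReplicateCallMatrix
    markers: FetalMarkerPanel
    fetal_fraction: float
    mislabeled: bool = False


def fetal_fraction(
    ga: GestationalAge, params: AssayParams, rng: np.random.Generator
) -> float:
    """Draw a fetal fraction: log-normal, median increasing with gestation."""
    params.validate()
    loc = params.ff_intercept + params.ff_slope * ga.total_days
    ff = math.exp(rng.normal(loc, params.ff_sd)) if params.ff_sd > 0 else math.exp(loc)
    return min(ff, params.ff_max)


def _contributions(pregnancy: Pregnancy, ff: float, params: AssayParams):
    """Per-fetus share of the fetal fraction.

    The drawn ff is the combined live-fetus fraction, split evenly; a
    vanished fetus adds a decayed extra share on top.
    """
    live = [f for f in pregnancy.fetuses if not f.vanished]
    n_live = max(len(live), 1)
    out = []
    for f in pregnancy.fetuses:
        share = ff / n_live
        if f.vanished:
            share *= params.vanished_cfdna_fraction
        out.append((f, share))
    return out


def _well_ct(detected: int, params: AssayParams, rng: np.random.Generator) -> float:
    return (
        params.ct_intercept
        - params.ct_slope * math.log10(detected)
        + (rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd > 0 else 0.0)
    )


def simulate_rhd_matrix(
    pregnancy: Pregnancy, ff: float, params: AssayParams, rng: np.random.Generator
) -> ReplicateCallMatrix:
    """Simulate the triplicate 3-exon RHD PCR for one sample."""
    params.validate()
    if not 0.0 < ff < 1.0:
        raise ValueError(f"fetal fraction must be in (0, 1), got {ff}")
    scale = params.total_cfdna_copies_per_ml * params.plasma_ml_per_replicate
    contribs = _contributions(pregnancy, ff, params)
    calls: dict[tuple[int, int], bool] = {}
    ct: dict[tuple[int, int], float] = {}
    for exon in ASSAY_EXONS:
        lam = scale * sum(share for f, share in contribs if f.exon_presence[exon])
        if pregnancy.maternal_rhd_variant:
            # maternal template is not diluted by the fetal fraction
            lam += scale
        for rep in range(1, N_REPLICATES + 1):
            copies = rng.poisson(lam) if lam > 0 else 0
            detected = rng.binomial(copies, params.detection_prob_per_copy) if copies else 0
            if detected == 0 and rng.random() < params.spurious_call_prob:
                detected = 1  # off-target/contamination artifact: late ct
            calls[(exon, rep)] = detected > 0
            if detected > 0:
                ct[(exon, rep)] = _well_ct(detected, params, rng)
    ipc = tuple(rng.random() >= params.ipc_fail_prob for _ in range(N_REPLICATES))
    return ReplicateCallMatrix(calls=calls, ct=ct, ipc_ok=ipc)


def _marker_calls(lam: float, params: AssayParams, rng: np.random.Generator) -> int:
    n = 0
    for _ in range(N_REPLICATES):
        copies = rng.poisson(lam) if lam > 0 else 0
        detected = rng.binomial(copies, params.detection_prob_per_copy) if copies else 0
        n += detected > 0
    return n


def simulate_markers(
    pregnancy: Pregnancy, ff: float, params: AssayParams, rng: np.random.Generator
) -> FetalMarkerPanel:
    """Simulate the SRY and hypermethylated-RASSF1A fetal-DNA controls.

    SRY wells see only cfDNA from male fetuses; RASSF1A sees all fetal
    cfDNA but pays a digest-efficiency penalty.  Spurious calls are
    disabled for the markers.
    """
    params.validate()
    if not 0.0 < ff < 1.0:
        raise ValueError(f"fetal fraction must be in (0, 1), got {ff}")
    scale = params.total_cfdna_copies_per_ml * params.plasma_ml_per_replicate
    contribs = _contributions(pregnancy, ff, params)
    ff_total = sum(share for _, share in contribs)
    ff_male = sum(share for f, share in contribs if f.sex is Sex.MALE)
    sry = _marker_calls(scale * ff_male * params.sry_efficiency, params, rng)
    rassf1a = _marker_calls(scale * ff_total * params.rassf1a_efficiency, params, rng)
    return FetalMarkerPanel(sry_calls=sry, rassf1a_calls=rassf1a)


def simulate_assays(
    cohort: list[Pregnancy],
    params: AssayParams,
    rng: np.random.Generator,
    mislabel_prob: float = 0.0,
) -> list[AssayResult]:
    """Stage-1 driver: one AssayResult per pregnancy, swaps applied last."""
    results = []
    for p in cohort:
        ff = fetal_fraction(p.ga_at_sampling, params, rng)
        matrix = simulate_rhd_matrix(p, ff, params, rng)
        markers = simulate_markers(p, ff, params, rng)
        results.append(AssayResult(p.id, matrix, markers, ff))
    return apply_mislabel(results, rng, mislabel_prob)


def apply_mislabel(
    records: list[AssayResult], rng: np.random.Generator, mislabel_prob: float
) -> list[AssayResult]:
    """Swap assay observations between tubes to model labeling errors.

    Each record triggers a swap with probability ``mislabel_prob`` with a
    uniformly chosen partner; a record already involved in a swap is not
    drawn again, so the operation stays a permutation of the observations
    and both partners are flagged.
    """
    if not 0.0 <= mislabel_prob <= 1.0:
        raise ValueError("mislabel_prob outside [0, 1]")
    out = list(records)
    if mislabel_prob == 0.0:
        return out
    if len(out) < 2:
        warnings.warn("mislabel requested but fewer than 2 records; no-op", stacklevel=2)
        return out
    swapped: set[int] = set()
    for i in range(len(out)):
        if i in swapped or rng.random() >= mislabel_prob:
            continue
        candidates = [j for j in range(len(out)) if j != i and j not in swapped]
        if not candidates:
            continue
        j = candidates[int(rng.integers(len(candidates)))]
        a, b = out[i], out[j]
        out[i] = AssayResult(a.id, b.matrix, b.markers, b.fetal_fraction, mislabeled=True)
        out[j] = AssayResult(b.id, a.matrix, a.markers, a.fetal_fraction, mislabeled=True)
        swapped.update((i, j))
    return out


# ---------------------------------------------------------------------------
# calls CSV
# ---------------------------------------------------------------------------

def assays_to_dataframe(results: list[AssayResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {"id": r.id}
        for exon in ASSAY_EXONS:
            for rep in range(1, N_REPLICATES + 1):
                row[f"exon{exon}_r{rep}"] = int(r.matrix.calls[(exon, rep)])
        for exon in ASSAY_EXONS:
            for rep in range(1, N_REPLICATES + 1):
                v = r.matrix.ct.get((exon, rep))
                row[f"ct_e{exon}_r{rep}"] = "" if v is None else round(v, 3)
        row["sry_calls"] = r.markers.sry_calls
        row["rassf1a_calls"] = r.markers.rassf1a_calls
        row["ipc_ok"] = int(all(r.matrix.ipc_ok))
        row["mislabeled"] = int(r.mislabeled)
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_csv(results: list[AssayResult], path) -> None:
    assays_to_dataframe(results).to_csv(path, index=False, encoding="utf-8")


def read_calls_csv(path) -> list[AssayResult]:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
    results = []
    for _, row in df.iterrows():
        calls, ct = {}, {}
        for exon in ASSAY_EXONS:
            for rep in range(1, N_REPLICATES + 1):
                pos = bool(int(row[f"exon{exon}_r{rep}"]))
                calls[(exon, rep)] = pos
                if pos:
                    ct[(exon, rep)] = float(row[f"ct_e{exon}_r{rep}"])
        ipc = bool(int(row["ipc_ok"]))
        results.append(
            AssayResult(
                id=row["id"],
                matrix=ReplicateCallMatrix(calls=calls, ct=ct, ipc_ok=(ipc,) * 3),
                markers=FetalMarkerPanel(
                    sry_calls=int(row["sry_calls"]),
                    rassf1a_calls=int(row["rassf1a_calls"]),
                ),
                fetal_fraction=float("nan"),
                mislabeled=bool(int(row.get("mislabeled", 0))),
            )
        )
    return results
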