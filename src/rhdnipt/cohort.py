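"""Synthetic pregnancy-cohort generator.

Emulates a routine NIPT-RhD testing population of RhD-negative pregnant
women: gestational age at sampling (booking-visit bulk in late first
trimester plus a later tail), plurality (singletons, twins, triplets),
fetal RHD genotype classes (conventional D-positive, D-negative, weak D,
partial D-variants lacking one or two assay exons), rare maternal
non-coding RHD variants, vanishing twins, and loss to newborn follow-up.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GestationalAge",
    "RhdClass",
    "Sex",
    "Reference",
    "FetalGenotype",
    "Pregnancy",
    "CohortConfig",
    "ConfigurationError",
    "generate_cohort",
    "sample_gestational_age",
    "aggregate_reference",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: days marking the end of the first trimester (14 + 0 weeks)
FIRST_TRIMESTER_DAYS = 98

ASSAY_EXONS = (5, 7, 10)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True, order=True)
class GestationalAge:
    """Gestational age in the obstetric weeks+days convention (e.g. 12+6)."""

    weeks: int
    days: int

    def __post_init__(self) -> None:
        if self.weeks < 0:
            raise ValueError(f"weeks must be >= 0, got {self.weeks}")
        if not 0 <= self.days <= 6:
            raise ValueError(f"days must be in 0..6, got {self.days}")

    @property
    def total_days(self) -> int:
        return 7 * self.weeks + self.days

    @classmethod
    def from_days(cls, total_days: int) -> "GestationalAge":
        if total_days < 0:
            raise ValueError("total_days must be >= 0")
        return cls(total_days // 7, total_days % 7)

    def __str__(self) -> str:
        return f"{self.weeks}+{self.days}"


class RhdClass(str, enum.Enum):
    RHD_POSITIVE = "RHD_POSITIVE"
    RHD_NEGATIVE = "RHD_NEGATIVE"
    WEAK_D = "WEAK_D"
    D_VARIANT_PARTIAL = "D_VARIANT_PARTIAL"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Reference(str, enum.Enum):
    """Aggregated newborn serology reference class for one pregnancy."""

    REF_POSITIVE = "REF_POSITIVE"
    REF_NEGATIVE = "REF_NEGATIVE"
    MISSING = "MISSING"


#: rhd classes whose newborn serology counts as D-antigen positive
_SEROLOGICALLY_POSITIVE = frozenset(
    {RhdClass.RHD_POSITIVE, RhdClass.WEAK_D, RhdClass.D_VARIANT_PARTIAL}
)


@dataclass(frozen=True)
class FetalGenotype:
    """One fetus: RHD class, per-exon amplifiable targets, sex, vital status.

    Invariants: a conventional D-positive or weak-D fetus carries all three
    assay exons (5, 7, 10); a D-negative fetus carries none; a partial
    D-variant carries one or two.
    """

    rhd_class: RhdClass
    exon_presence: dict[int, bool]
    sex: Sex
    vanished: bool = False

    def __post_init__(self) -> None:
        if set(self.exon_presence) != set(ASSAY_EXONS):
            raise ValueError(f"exon_presence must cover exons {ASSAY_EXONS}")
        n_present = sum(self.exon_presence.values())
        if self.rhd_class in (RhdClass.RHD_POSITIVE, RhdClass.WEAK_D) and n_present != 3:
            raise ValueError(f"{self.rhd_class.value} requires all three exons present")
        if self.rhd_class is RhdClass.RHD_NEGATIVE and n_present != 0:
            raise ValueError("RHD_NEGATIVE requires no exon present")
        if self.rhd_class is RhdClass.D_VARIANT_PARTIAL and n_present not in (1, 2):
            raise ValueError("D_VARIANT_PARTIAL requires 1 or 2 exons present")

    @property
    def serologically_positive(self) -> bool:
        return self.rhd_class in _SEROLOGICALLY_POSITIVE


def _full_exons(present: bool) -> dict[int, bool]:
    return {e: present for e in ASSAY_EXONS}


def make_fetus(
    rhd_class: RhdClass,
    sex: Sex = Sex.FEMALE,
    present_exons: tuple[int, ...] | None = None,
    vanished: bool = False,
) -> FetalGenotype:
    """Convenience constructor deriving exon presence from the RHD class."""
    if rhd_class is RhdClass.D_VARIANT_PARTIAL:
        if not present_exons:
            raise ValueError("D_VARIANT_PARTIAL needs explicit present_exons")
        exons = {e: e in present_exons for e in ASSAY_EXONS}
    else:
        exons = _full_exons(rhd_class is not RhdClass.RHD_NEGATIVE)
    return FetalGenotype(rhd_class, exons, sex, vanished)


@dataclass(frozen=True)
class Pregnancy:
    id: str
    ga_at_sampling: GestationalAge
    maternal_age: int
    n_fetuses: int
    fetuses: tuple[FetalGenotype, ...]
    maternal_rhd_variant: bool = False
    followup_available: bool = True
    mislabeled: bool = False

    def __post_init__(self) -> None:
        if not 16 <= self.maternal_age <= 50:
            raise ValueError(f"maternal_age must be in 16..50, got {self.maternal_age}")
        if not 1 <= self.n_fetuses <= 3:
            raise ValueError(f"n_fetuses must be in 1..3, got {self.n_fetuses}")
        if len(self.fetuses) != self.n_fetuses:
            raise ValueError("len(fetuses) must equal n_fetuses")
        if sum(f.vanished for f in self.fetuses) > 1:
            raise ValueError("at most one fetus may be flagged vanished")

    @property
    def live_fetuses(self) -> tuple[FetalGenotype, ...]:
        return tuple(f for f in self.fetuses if not f.vanished)


_PROB_FIELDS = (
    "twin_prob",
    "triplet_prob",
    "fetal_rhd_pos_prob",
    "weak_d_frac",
    "d_variant_frac",
    "maternal_variant_prob",
    "followup_prob",
    "mislabel_prob",
    "vanishing_twin_prob",
    "first_trimester_frac",
    "identical_twin_prob",
    "male_prob",
)


@dataclass
class CohortConfig:
    """Study-population parameters.

    Defaults emulate a routine clinical evaluation cohort of 2968
    RhD-negative pregnancies: 199 twin and 7 triplet pregnancies, 77.7%
    newborn follow-up, 50.9% first-trimester sampling, 65.7% D-positive
    deliveries (1475/2244), 13/1475 weak-D among positives, ~15/2968
    maternal non-coding RHD variants and ~9/2968 fetal partial D-variants.
    """

    n_pregnancies: int = 2968
    twin_prob: float = 199 / 2968
    triplet_prob: float = 7 / 2968
    fetal_rhd_pos_prob: float = 1475 / 2244
    weak_d_frac: float = 13 / 1475
    d_variant_frac: float = 9 / 2968
    maternal_variant_prob: float = 15 / 2968
    followup_prob: float = 0.777
    mislabel_prob: float = 0.001
    vanishing_twin_prob: float = 1 / 2968
    first_trimester_frac: float = 0.509
    ga_min_days: int = 41   # 5+6
    ga_max_days: int = 280  # 40+0
    ga_median_days: int = 90  # 12+6
    identical_twin_prob: float = 0.3
    male_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_pregnancies < 0:
            raise ConfigurationError(f"n_pregnancies must be >= 0, got {self.n_pregnancies}")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.twin_prob + self.triplet_prob > 1.0:
            raise ConfigurationError("twin_prob + triplet_prob exceeds 1")
        if self.ga_min_days > self.ga_max_days:
            raise ConfigurationError(
                f"degenerate gestational-age range: {self.ga_min_days} > {self.ga_max_days}"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# gestational-age sampling
# ---------------------------------------------------------------------------

def _ga_quantile(u: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    """Piecewise quantile function for gestational age in days.

    Three segments pin the printed summaries exactly: a Beta(3, 1.5)-shaped
    booking bulk on [min, median) carrying mass 0.5, a uniform bridge on
    [median, 98) carrying first_trimester_frac - 0.5, and a linearly
    decreasing tail on [98, max] carrying the rest.  The median and the
    first-trimester fraction hold by construction.
    """
    from scipy.stats import beta as _beta

    lo, med, hi = cfg.ga_min_days, cfg.ga_median_days, cfg.ga_max_days
    ft, p_med = cfg.first_trimester_frac, 0.5
    out = np.empty_like(u, dtype=float)

    m1 = u < p_med
    out[m1] = lo + (med - lo) * _beta.ppf(u[m1] / p_med, 3.0, 1.5)

    m2 = (~m1) & (u < ft)
    out[m2] = med + (FIRST_TRIMESTER_DAYS - med) * (u[m2] - p_med) / (ft - p_med)

    m3 = u >= ft
    v = (u[m3] - ft) / (1.0 - ft)
    out[m3] = FIRST_TRIMESTER_DAYS + (hi - FIRST_TRIMESTER_DAYS) * (1.0 - np.sqrt(1.0 - v))
    return out


def sample_gestational_age(
    config: CohortConfig, rng: np.random.Generator, size: int | None = None
) -> GestationalAge | list[GestationalAge]:
    """Draw gestational age(s) at sampling.

    The implied distribution has its median at ``ga_median_days`` (12+6 by
    default) and puts ``first_trimester_frac`` of its mass before 14+0.
    """
    if config.ga_min_days > config.ga_max_days:
        raise ConfigurationError("ga_min_days > ga_max_days")
    n = 1 if size is None else size
    if config.ga_min_days == config.ga_max_days:
        days = np.full(n, config.ga_min_days)
    elif not (
        config.ga_min_days < config.ga_median_days < FIRST_TRIMESTER_DAYS <= config.ga_max_days
        and config.first_trimester_frac > 0.5
    ):
        # fall back to a plain uniform draw when the pinned summaries cannot
        # all sit inside the requested range
        days = rng.integers(config.ga_min_days, config.ga_max_days + 1, size=n)
    else:
        u = rng.random(n)
        days = np.minimum(
            np.floor(_ga_quantile(u, config)).astype(int), config.ga_max_days
        )
    gas = [GestationalAge.from_days(int(d)) for d in days]
    return gas[0] if size is None else gas


def _sample_maternal_age(rng: np.random.Generator) -> int:
    # triangular on [16, 50], mode 31 -> median ~32; age feeds nothing downstream
    return int(np.clip(round(rng.triangular(16, 31, 50)), 16, 50))


def _draw_fetus(config: CohortConfig, rng: np.random.Generator, vanished: bool = False) -> FetalGenotype:
    sex = Sex.MALE if rng.random() < config.male_prob else Sex.FEMALE
    if rng.random() >= config.fetal_rhd_pos_prob:
        return make_fetus(RhdClass.RHD_NEGATIVE, sex, vanished=vanished)
    # antigen-positive fetus: mostly conventional, rarely weak D or partial D
    u = rng.random()
    if u < config.d_variant_frac:
        n_present = 1 + int(rng.random() < 0.5)
        present = tuple(rng.choice(ASSAY_EXONS, size=n_present, replace=False))
        return make_fetus(RhdClass.D_VARIANT_PARTIAL, sex, present_exons=present, vanished=vanished)
    if u < config.d_variant_frac + config.weak_d_frac:
        return make_fetus(RhdClass.WEAK_D, sex, vanished=vanished)
    return make_fetus(RhdClass.RHD_POSITIVE, sex, vanished=vanished)


def generate_cohort(config: CohortConfig) -> list[Pregnancy]:
    """Generate the synthetic study population (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gas = sample_gestational_age(config, rng, size=config.n_pregnancies) if config.n_pregnancies else []
    out: list[Pregnancy] = []
    for i in range(config.n_pregnancies):
        u = rng.random()
        if u < config.triplet_prob:
            n_live = 3
        elif u < config.triplet_prob + config.twin_prob:
            n_live = 2
        else:
            n_live = 1
        fetuses = [_draw_fetus(config, rng) for _ in range(n_live)]
        if n_live > 1 and rng.random() < config.identical_twin_prob:
            fetuses = [fetuses[0]] * n_live  # monozygotic: shared genotype
        # a demised co-fetus still sheds cfDNA but never reaches serology
        if n_live < 3 and rng.random() < config.vanishing_twin_prob:
            fetuses.append(_draw_fetus(config, rng, vanished=True))
        out.append(
            Pregnancy(
                id=f"P{i:06d}",
                ga_at_sampling=gas[i],
                maternal_age=_sample_maternal_age(rng),
                n_fetuses=len(fetuses),
                fetuses=tuple(fetuses),
                maternal_rhd_variant=rng.random() < config.maternal_variant_prob,
                followup_available=rng.random() < config.followup_prob,
                mislabeled=False,
            )
        )
    return out


def aggregate_reference(fetuses: list[FetalGenotype] | tuple[FetalGenotype, ...]) -> Reference:
    """Aggregate newborn serology over a pregnancy's (live) fetuses.

    A multiple pregnancy counts as one RhD-positive newborn if at least one
    child is RhD positive or weak D; it counts as one RhD-negative newborn
    only if every child is RhD negative.  Vanished fetuses must be excluded
    by the caller.
    """
    if not fetuses:
        raise ValueError("no newborn to type: empty fetus list")
    if any(f.serologically_positive for f in fetuses):
        return Reference.REF_POSITIVE
    return Reference.REF_NEGATIVE


# ---------------------------------------------------------------------------
# CSV round-trip (RFC 4180, UTF-8, blank = missing)
# ---------------------------------------------------------------------------

def cohort_to_dataframe(cohort: list[Pregnancy]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row: dict[str, object] = {
            "id": p.id,
            "ga_weeks": p.ga_at_sampling.weeks,
            "ga_days": p.ga_at_sampling.days,
            "maternal_age": p.maternal_age,
            "n_fetuses": p.n_fetuses,
        }
        for i in range(3):
            if i < len(p.fetuses):
                f = p.fetuses[i]
                row[f"fetus{i + 1}_class"] = f.rhd_class.value
                row[f"fetus{i + 1}_sex"] = f.sex.value
                row[f"fetus{i + 1}_vanished"] = int(f.vanished)
                row[f"fetus{i + 1}_exons"] = ";".join(
                    str(e) for e in ASSAY_EXONS if f.exon_presence[e]
                )
            else:
                row[f"fetus{i + 1}_class"] = ""
                row[f"fetus{i + 1}_sex"] = ""
                row[f"fetus{i + 1}_vanished"] = ""
                row[f"fetus{i + 1}_exons"] = ""
        row["maternal_rhd_variant"] = int(p.maternal_rhd_variant)
        row["followup_available"] = int(p.followup_available)
        row["mislabeled"] = int(p.mislabeled)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: list[Pregnancy], path) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> list[Pregnancy]:
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=False)
    cohort: list[Pregnancy] = []
    for _, row in df.iterrows():
        fetuses = []
        for i in range(3):
            cls = row[f"fetus{i + 1}_class"]
            if cls == "":
                continue
            exons_txt = str(row[f"fetus{i + 1}_exons"])
            present = {int(t) for t in exons_txt.split(";") if t}
            fetuses.append(
                FetalGenotype(
                    rhd_class=RhdClass(cls),
                    exon_presence={e: e in present for e in ASSAY_EXONS},
                    sex=Sex(row[f"fetus{i + 1}_sex"]),
                    vanished=bool(int(row[f"fetus{i + 1}_vanished"])),
                )
            )
        cohort.append(
            Pregnancy(
                id=row["id"],
                ga_at_sampling=GestationalAge(int(row["ga_weeks"]), int(row["ga_days"])),
                maternal_age=int(row["maternal_age"]),
                n_fetuses=int(row["n_fetuses"]),
                fetuses=tuple(fetuses),
                maternal_rhd_variant=bool(int(row["maternal_rhd_variant"])),
                followup_available=bool(int(row["followup_available"])),
                mislabeled=bool(int(row["mislabeled"])),
            )
        )
    return cohort
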