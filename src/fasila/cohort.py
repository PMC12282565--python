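"""Cohort construction: deterministic fixture expansion and stochastic simulation.

Two sources of patient-level data share one schema:

* :func:`expand_fixture` deterministically expands per-score-level count
  specifications (group sizes plus per-outcome counts) into
  :class:`~fasila.scores.PatientRecord` lists whose recomputed scores and
  outcome margins match the specification exactly.  Continuous covariates are
  filled from per-level summary statistics and are reconstructions, not data.
* :func:`simulate_cohort` draws a seeded synthetic cohort with the
  correlational structure the evaluation pipeline assumes: lactate rising
  with shock index, FAST positivity rising with abdominal injury severity,
  outcome odds log-linear in the score total, severity scores positively and
  fibrinogen negatively coupled to the total.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scores import (
    FastResult,
    Management,
    Mechanism,
    PatientRecord,
    Sex,
    fasila_score,
)

__all__ = [
    "FixtureError",
    "ConfigError",
    "FixtureSpec",
    "CohortConfig",
    "OutcomeModel",
    "table1_fixture",
    "expand_fixture",
    "simulate_cohort",
    "SCHEMA_VERSION",
    "N_LEVELS",
]

SCHEMA_VERSION = "1"
N_LEVELS = 7  # score totals 0..6


class FixtureError(ValueError):
    """Fixture specification violates its invariants."""


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# fixture specification


@dataclass(frozen=True)
class FixtureSpec:
    """Per-score-level counts defining a deterministic cohort.

    ``management_counts`` maps each management category to its 7 per-level
    counts and must partition every level; the other count vectors flag the
    first k records of each level independently, so per-outcome margins match
    exactly while joint cross-tabulations are not claimed to.
    """

    label: str
    group_sizes: tuple[int, ...]
    management_counts: Mapping[str, tuple[int, ...]]
    laparotomy: tuple[int, ...]
    transfusion: tuple[int, ...]
    mtp: tuple[int, ...]
    mortality: tuple[int, ...]
    males: tuple[int, ...]
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        vectors = {
            "group_sizes": self.group_sizes,
            "laparotomy": self.laparotomy,
            "transfusion": self.transfusion,
            "mtp": self.mtp,
            "mortality": self.mortality,
            "males": self.males,
            **{f"management[{k}]": v for k, v in self.management_counts.items()},
        }
        for name, vec in vectors.items():
            if len(vec) != N_LEVELS:
                raise FixtureError(f"{name} must have {N_LEVELS} entries")
            if any(c < 0 for c in vec):
                raise FixtureError(f"{name} has a negative count")
        for name in ("laparotomy", "transfusion", "mtp", "mortality", "males"):
            vec = vectors[name]
            for lvl, (c, g) in enumerate(zip(vec, self.group_sizes)):
                if c > g:
                    raise FixtureError(
                        f"{name} count {c} exceeds group size {g} at level {lvl}"
                    )
        for lvl in range(N_LEVELS):
            mgmt_total = sum(v[lvl] for v in self.management_counts.values())
            if mgmt_total != self.group_sizes[lvl]:
                raise FixtureError(
                    f"management counts sum to {mgmt_total} at level {lvl}, "
                    f"expected {self.group_sizes[lvl]}"
                )
        for lvl, (m, t) in enumerate(zip(self.mtp, self.transfusion)):
            if m > t:
                raise FixtureError(
                    f"MTP count exceeds transfusion count at level {lvl}"
                )
        unknown = set(self.management_counts) - {m.value for m in Management}
        if unknown:
            raise FixtureError(f"unknown management categories: {sorted(unknown)}")

    @property
    def n(self) -> int:
        return sum(self.group_sizes)

    @property
    def surgical(self) -> tuple[int, ...]:
        """Per-level 'surgical intervention' counts (surgical + surgical-plus-IR)."""
        s = self.management_counts.get(Management.SURGICAL.value, (0,) * N_LEVELS)
        sp = self.management_counts.get(
            Management.SURGICAL_PLUS_IR.value, (0,) * N_LEVELS
        )
        return tuple(a + b for a, b in zip(s, sp))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["management_counts"] = dict(self.management_counts)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FixtureSpec":
        kw = dict(d)
        kw["group_sizes"] = tuple(kw["group_sizes"])
        kw["management_counts"] = {
            k: tuple(v) for k, v in kw["management_counts"].items()
        }
        for name in ("laparotomy", "transfusion", "mtp", "mortality", "males"):
            kw[name] = tuple(kw[name])
        return cls(**kw)


def table1_fixture() -> FixtureSpec:
    """Built-in 400-patient per-score-level count specification."""
    return FixtureSpec(
        label="table1",
        group_sizes=(82, 125, 72, 44, 41, 25, 11),
        management_counts={
            "surgical": (9, 19, 21, 15, 13, 10, 7),
            "surgical_plus_ir": (0, 0, 0, 0, 0, 1, 2),
            "ir_only": (3, 6, 3, 4, 4, 5, 1),
            "conservative_plus_ir": (2, 2, 0, 0, 2, 0, 0),
            "conservative": (68, 98, 48, 25, 22, 9, 1),
        },
        laparotomy=(10, 15, 14, 13, 7, 10, 9),
        transfusion=(7, 26, 15, 19, 20, 21, 11),
        mtp=(0, 0, 0, 0, 2, 4, 7),
        mortality=(2, 2, 0, 1, 1, 2, 2),
        males=(74, 110, 68, 39, 38, 23, 9),
    )


# ---------------------------------------------------------------------------
# deterministic expansion

# canonical decomposition of each total: SI points first, then lactate, then FAST
_DECOMPOSITION = {
    0: (0, 0, 0),  # (fast, si, lactate)
    1: (0, 1, 0),
    2: (0, 2, 0),
    3: (0, 3, 0),
    4: (0, 3, 1),
    5: (0, 3, 2),
    6: (1, 3, 2),
}

# representative vitals landing mid-bin: (hr, sbp) per SI point value
_SI_REP_VITALS = {0: (60.0, 100.0), 1: (75.0, 100.0), 2: (85.0, 100.0), 3: (95.0, 100.0)}
_LACTATE_REP = {0: 1.5, 1: 3.0, 2: 4.5}
_FIXTURE_DBP = 70.0

# per-level covariate summaries used to fill continuous fields (reconstructions)
_LEVEL_AGE = (38.0, 37.3, 34.7, 32.9, 36.3, 32.8, 44.7)
_LEVEL_ISS = (9, 14, 14, 17, 19, 22, 34)
_LEVEL_SOFA = (1, 1, 1, 2, 2, 2, 3)
_LEVEL_ABD_AIS = (2, 3, 3, 3, 3, 3, 4)
_LEVEL_RTS = (7.73, 7.79, 7.72, 7.52, 7.55, 7.17, 6.10)
_LEVEL_TRISS = (0.98, 0.98, 0.98, 0.94, 0.95, 0.99, 0.70)
_LEVEL_GCS = (15, 15, 15, 15, 15, 15, 13)
_LEVEL_ICU_LOS = (2, 2, 2, 4, 4, 4, 6)
_LEVEL_HOSP_LOS = (5, 6, 6, 10, 18, 16, 18)

# penetrating-mechanism records: 14 in the low-score group, 2 in the high
_LEVEL_PENETRATING = (14, 0, 0, 0, 2, 0, 0)
# hypofibrinogenemia (< 2.0 g/L) allocation: 37 low-group, 18 high-group
_LEVEL_HYPOFIB = (10, 14, 8, 5, 10, 6, 2)
_FIB_LOW, _FIB_NORMAL = 1.8, 2.5

_MTP_UNITS = 12
_TRANSFUSION_UNITS = 4


def expand_fixture(spec: FixtureSpec) -> list[PatientRecord]:
    """Deterministically expand a count specification into patient records.

    Each record's FASILA components follow the canonical decomposition of its
    level, with vitals and lactate back-solved to representative mid-bin
    values; every outcome flag is assigned to the first k records of its
    level.  Calling twice yields identical cohorts.
    """
    records: list[PatientRecord] = []
    for level, size in enumerate(spec.group_sizes):
        fast_pt, si_pt, lac_pt = _DECOMPOSITION[level]
        hr, sbp = _SI_REP_VITALS[si_pt]
        lactate = _LACTATE_REP[lac_pt]
        fast = FastResult.POSITIVE if fast_pt else FastResult.NEGATIVE

        managements: list[Management] = []
        for cat in (
            Management.SURGICAL,
            Management.SURGICAL_PLUS_IR,
            Management.IR_ONLY,
            Management.CONSERVATIVE_PLUS_IR,
            Management.CONSERVATIVE,
        ):
            managements += [cat] * spec.management_counts.get(cat.value, (0,) * N_LEVELS)[level]

        for i in range(size):
            transfused = i < spec.transfusion[level]
            mtp = i < spec.mtp[level]
            units = _MTP_UNITS if mtp else (_TRANSFUSION_UNITS if transfused else 0)
            records.append(
                PatientRecord(
                    patient_id=f"{spec.label}-s{level}-{i:03d}",
                    age=_LEVEL_AGE[level],
                    sex=Sex.MALE if i < spec.males[level] else Sex.FEMALE,
                    mechanism=(
                        Mechanism.PENETRATING
                        if i >= size - _LEVEL_PENETRATING[level]
                        else Mechanism.BLUNT
                    ),
                    hr=hr,
                    sbp=sbp,
                    dbp=_FIXTURE_DBP,
                    fast=fast,
                    lactate=lactate,
                    gcs=_LEVEL_GCS[level],
                    iss=_LEVEL_ISS[level],
                    abdominal_ais=_LEVEL_ABD_AIS[level],
                    rts=_LEVEL_RTS[level],
                    triss=_LEVEL_TRISS[level],
                    sofa=_LEVEL_SOFA[level],
                    fibrinogen=(
                        _FIB_LOW if i < _LEVEL_HYPOFIB[level] else _FIB_NORMAL
                    ),
                    transfused=transfused,
                    blood_units=units,
                    mtp=mtp,
                    laparotomy=i < spec.laparotomy[level],
                    management=managements[i],
                    icu_los=float(_LEVEL_ICU_LOS[level]),
                    hospital_los=float(_LEVEL_HOSP_LOS[level]),
                    mortality=i < spec.mortality[level],
                )
            )
    return records


# ---------------------------------------------------------------------------
# stochastic simulation


@dataclass(frozen=True)
class OutcomeModel:
    """Bernoulli outcome with log-odds linear in the score total."""

    intercept: float
    slope: float

    def prob(self, total) -> np.ndarray:
        eta = self.intercept + self.slope * np.asarray(total, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the stochastic cohort simulator."""

    n: int = 400
    seed: int = 0
    penetrating_prob: float = 0.04
    male_prob: float = 0.903
    age_mean: float = 36.3
    age_sd: float = 12.7
    hr_mean: float = 85.0
    hr_sd: float = 22.0
    hr_bounds: tuple[float, float] = (40.0, 180.0)
    sbp_mean: float = 118.0
    sbp_sd: float = 22.0
    sbp_bounds: tuple[float, float] = (60.0, 200.0)
    dbp_ratio: float = 0.62  # dbp ~ ratio * sbp + noise
    dbp_sd: float = 8.0
    # log(lactate) ~ N(intercept + slope * systolic SI, sd)
    lactate_log_intercept: float = -0.35
    lactate_log_slope: float = 1.1
    lactate_log_sd: float = 0.45
    # P(FAST positive) logistic in abdominal AIS
    fast_intercept: float = -3.4
    fast_ais_slope: float = 0.85
    outcome_models: Mapping[str, OutcomeModel] = field(
        default_factory=lambda: {
            "transfusion": OutcomeModel(-2.1, 0.55),
            "surgery": OutcomeModel(-2.0, 0.35),
            "laparotomy": OutcomeModel(-2.2, 0.35),
            "mtp": OutcomeModel(-7.5, 1.0),
            "mortality": OutcomeModel(-4.6, 0.45),
        }
    )
    # severity couplings to the score total
    iss_base: float = 10.0
    iss_slope: float = 2.8
    iss_sd: float = 6.0
    sofa_base: float = 1.0
    sofa_slope: float = 0.5
    sofa_sd: float = 1.5
    fibrinogen_base: float = 2.9
    fibrinogen_slope: float = -0.15
    fibrinogen_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        for name in ("penetrating_prob", "male_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not (20.0 <= self.hr_bounds[0] < self.hr_bounds[1] <= 250.0):
            raise ConfigError(f"hr_bounds {self.hr_bounds} outside sanity range 20-250")
        if not (40.0 <= self.sbp_bounds[0] < self.sbp_bounds[1] <= 300.0):
            raise ConfigError(f"sbp_bounds {self.sbp_bounds} outside sanity range 40-300")
        for name in ("age_sd", "hr_sd", "sbp_sd", "dbp_sd", "lactate_log_sd",
                     "iss_sd", "sofa_sd", "fibrinogen_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        missing = {"transfusion", "surgery", "laparotomy", "mtp", "mortality"} - set(
            self.outcome_models
        )
        if missing:
            raise ConfigError(f"outcome_models missing entries: {sorted(missing)}")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    # resample out-of-bounds draws; clip as a last resort for tiny tails
    x = rng.normal(mean, sd, size)
    for _ in range(20):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(x, lo, hi)


def simulate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort under ``config``.

    The same seed always yields the identical cohort.
    """
    n = config.n
    rng = np.random.default_rng(config.seed)
    if n == 0:
        return []

    age = _truncated_normal(rng, config.age_mean, config.age_sd, 18.0, 95.0, n)
    male = rng.random(n) < config.male_prob
    penetrating = rng.random(n) < config.penetrating_prob
    hr = _truncated_normal(rng, config.hr_mean, config.hr_sd, *config.hr_bounds, n)
    sbp = _truncated_normal(rng, config.sbp_mean, config.sbp_sd, *config.sbp_bounds, n)
    # round to recorded precision up front so stored records re-score identically
    hr = np.round(hr, 1)
    sbp = np.round(sbp, 1)
    dbp = np.round(
        np.clip(config.dbp_ratio * sbp + rng.normal(0, config.dbp_sd, n), 30.0, 140.0), 1
    )
    si = hr / sbp
    lactate = np.round(
        np.exp(
            rng.normal(
                config.lactate_log_intercept + config.lactate_log_slope * si,
                config.lactate_log_sd,
            )
        ),
        2,
    )
    abd_ais = np.clip(1 + rng.binomial(5, 0.35, n), 0, 6)
    p_fast = 1.0 / (
        1.0 + np.exp(-(config.fast_intercept + config.fast_ais_slope * abd_ais))
    )
    fast_pos = rng.random(n) < p_fast

    totals = np.array(
        [
            fasila_score(
                FastResult.POSITIVE if fp else FastResult.NEGATIVE,
                h, s, la, ignore_sanity_bounds=True,
            ).total
            for fp, h, s, la in zip(fast_pos, hr, sbp, lactate)
        ]
    )

    draws = {
        name: rng.random(n) < model.prob(totals)
        for name, model in config.outcome_models.items()
    }
    mtp = draws["mtp"]
    transfused = draws["transfusion"] | mtp  # MTP implies transfusion
    units = np.where(
        mtp,
        10 + rng.poisson(5, n),
        np.where(transfused, 1 + rng.poisson(2.5, n), 0),
    )
    surgical = draws["surgery"]
    laparotomy = np.where(surgical, rng.random(n) < 0.8, draws["laparotomy"] & ~surgical)
    ir = rng.random(n) < 0.08

    iss = np.clip(
        np.rint(config.iss_base + config.iss_slope * totals + rng.normal(0, config.iss_sd, n)),
        1, 75,
    ).astype(int)
    sofa = np.clip(
        np.rint(config.sofa_base + config.sofa_slope * totals + rng.normal(0, config.sofa_sd, n)),
        0, 24,
    ).astype(int)
    fibrinogen = np.clip(
        config.fibrinogen_base + config.fibrinogen_slope * totals
        + rng.normal(0, config.fibrinogen_sd, n),
        0.3, 7.0,
    )
    rts = np.clip(7.84 - 0.15 * totals + rng.normal(0, 0.35, n), 0.0, 7.8408)
    triss = np.clip(0.99 - 0.02 * totals - 0.002 * iss + rng.normal(0, 0.04, n), 0.01, 1.0)
    gcs = np.clip(np.rint(15 - 0.3 * totals - rng.poisson(0.3, n)), 3, 15).astype(int)
    mortality = draws["mortality"]
    icu_los = np.rint(np.exp(rng.normal(0.8 + 0.15 * totals, 0.7))).astype(int) + 1
    hosp_los = icu_los + np.rint(np.exp(rng.normal(1.4 + 0.1 * totals, 0.7))).astype(int)
    pelvic = np.where(rng.random(n) < 0.3, rng.integers(1, 5, n), -1)

    records = []
    for i in range(n):
        if surgical[i]:
            mgmt = Management.SURGICAL_PLUS_IR if ir[i] else Management.SURGICAL
        elif ir[i]:
            mgmt = Management.CONSERVATIVE_PLUS_IR if rng.random() < 0.3 else Management.IR_ONLY
        else:
            mgmt = Management.CONSERVATIVE
        records.append(
            PatientRecord(
                patient_id=f"sim-{config.seed}-{i:05d}",
                age=float(round(age[i], 1)),
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                mechanism=Mechanism.PENETRATING if penetrating[i] else Mechanism.BLUNT,
                hr=float(hr[i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                fast=FastResult.POSITIVE if fast_pos[i] else FastResult.NEGATIVE,
                lactate=float(lactate[i]),
                gcs=int(gcs[i]),
                iss=int(iss[i]),
                abdominal_ais=int(abd_ais[i]),
                pelvic_ais=None if pelvic[i] < 0 else int(pelvic[i]),
                rts=float(round(rts[i], 2)),
                triss=float(round(triss[i], 3)),
                sofa=int(sofa[i]),
                fibrinogen=float(round(fibrinogen[i], 2)),
                transfused=bool(transfused[i]),
                blood_units=int(units[i]),
                mtp=bool(mtp[i]),
                laparotomy=bool(laparotomy[i]),
                management=mgmt,
                icu_los=float(icu_los[i]),
                hospital_los=float(hosp_los[i]),
                mortality=bool(mortality[i]),
            )
        )
    return records
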