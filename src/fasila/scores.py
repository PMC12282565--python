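"""Bedside triage scores for abdominopelvic trauma.

Implements the FASILA score (FAST + shock-index + lactate, 0-6), the ABC
massive-transfusion score, and the systolic/diastolic shock indices, together
with the patient-level record type consumed by the rest of the package.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Sex",
    "Mechanism",
    "FastResult",
    "Management",
    "IndeterminatePolicy",
    "RiskClass",
    "PatientRecord",
    "FasilaBreakdown",
    "AbcBreakdown",
    "ScoreDomainError",
    "UnscorableError",
    "systolic_shock_index",
    "diastolic_shock_index",
    "fasila_si_points",
    "fasila_lactate_points",
    "fasila_score",
    "fasila_risk_class",
    "abc_score",
    "DEFAULT_CUTOFF",
    "HR_SANITY",
    "SBP_SANITY",
    "SURGICAL_MANAGEMENTS",
]

DEFAULT_CUTOFF = 4

# unit-mistake guards for CSV input; values outside trigger a warning only
HR_SANITY = (20.0, 250.0)
SBP_SANITY = (40.0, 300.0)


class ScoreDomainError(ValueError):
    """Raised when a scoring input is outside its physical domain."""


class UnscorableError(ScoreDomainError):
    """Raised when a record cannot be scored under the active policy."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Mechanism(str, enum.Enum):
    BLUNT = "blunt"
    PENETRATING = "penetrating"


class FastResult(str, enum.Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    INDETERMINATE = "indeterminate"


class Management(str, enum.Enum):
    CONSERVATIVE = "conservative"
    CONSERVATIVE_PLUS_IR = "conservative_plus_ir"
    SURGICAL = "surgical"
    IR_ONLY = "ir_only"
    SURGICAL_PLUS_IR = "surgical_plus_ir"


#: management categories that count as "surgical intervention" in evaluations
SURGICAL_MANAGEMENTS = frozenset({Management.SURGICAL, Management.SURGICAL_PLUS_IR})


class IndeterminatePolicy(str, enum.Enum):
    """How to score a record whose FAST result is indeterminate."""

    STRICT = "strict"  # refuse to score (default)
    AS_NEGATIVE = "as_negative"
    AS_POSITIVE = "as_positive"


class RiskClass(str, enum.Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class FasilaBreakdown:
    """Component points and total of a FASILA score.

    Attributes
    ----------
    fast_points : int
        0 for a negative FAST, 1 for positive.
    si_points : int
        Shock-index bin points, 0-3.
    lactate_points : int
        Lactate bin points, 0-2.
    total : int
        Sum of the three components, 0-6.
    """

    fast_points: int
    si_points: int
    lactate_points: int
    total: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.total == -1:
            object.__setattr__(
                self, "total", self.fast_points + self.si_points + self.lactate_points
            )
        if self.total != self.fast_points + self.si_points + self.lactate_points:
            raise ScoreDomainError("total must equal the sum of component points")
        if not (0 <= self.total <= 6):
            raise ScoreDomainError(f"FASILA total {self.total} outside 0-6")


@dataclass(frozen=True)
class AbcBreakdown:
    """Component points, total and massive-transfusion prediction of the ABC score."""

    penetrating_point: int
    fast_point: int
    sbp_point: int
    hr_point: int

    @property
    def total(self) -> int:
        return self.penetrating_point + self.fast_point + self.sbp_point + self.hr_point

    @property
    def mtp_predicted(self) -> bool:
        return self.total >= 2


@dataclass
class PatientRecord:
    """One trauma admission.

    Registry severity scores (ISS, AIS, GCS, RTS, TRISS, SOFA) are consumed as
    provided; they are never recomputed here.
    """

    patient_id: str
    age: float
    sex: Sex
    mechanism: Mechanism
    hr: float
    sbp: float
    dbp: float
    fast: FastResult
    lactate: float
    gcs: int
    iss: int
    abdominal_ais: int
    rts: float
    triss: float
    sofa: int
    transfused: bool
    blood_units: int
    mtp: bool
    laparotomy: bool
    management: Management
    icu_los: float
    hospital_los: float
    mortality: bool
    pelvic_ais: Optional[int] = None
    fibrinogen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hr <= 0 or self.sbp <= 0 or self.dbp <= 0:
            raise ScoreDomainError(
                f"{self.patient_id}: vitals must be positive "
                f"(hr={self.hr}, sbp={self.sbp}, dbp={self.dbp})"
            )
        if self.lactate is not None and self.lactate < 0:
            raise ScoreDomainError(f"{self.patient_id}: lactate must be >= 0")
        if self.mtp and self.blood_units < 10:
            raise ScoreDomainError(
                f"{self.patient_id}: MTP requires >= 10 PRBC units in 24 h, "
                f"got {self.blood_units}"
            )
        if self.blood_units < 0:
            raise ScoreDomainError(f"{self.patient_id}: blood_units must be >= 0")

    @property
    def is_surgical(self) -> bool:
        """Whether the record counts as 'surgical intervention'."""
        return self.management in SURGICAL_MANAGEMENTS


def systolic_shock_index(hr: float, sbp: float) -> float:
    """Heart rate divided by systolic blood pressure."""
    if hr <= 0 or sbp <= 0:
        raise ScoreDomainError(f"hr and sbp must be positive, got hr={hr}, sbp={sbp}")
    return hr / sbp


def diastolic_shock_index(hr: float, dbp: float) -> float:
    """Heart rate divided by diastolic blood pressure."""
    if hr <= 0 or dbp <= 0:
        raise ScoreDomainError(f"hr and dbp must be positive, got hr={hr}, dbp={dbp}")
    return hr / dbp


def fasila_si_points(si: float) -> int:
    """Shock-index component of the FASILA score.

    Half-open bins: [0, 0.70) -> 0, [0.70, 0.80) -> 1, [0.80, 0.90) -> 2,
    [0.90, inf) -> 3.  Values below 0.50 fall in the lowest bin (least
    shocked); the published bin table starts at 0.50 and leaves them
    unaddressed.
    """
    if si <= 0:
        raise ScoreDomainError(f"shock index must be positive, got {si}")
    if si < 0.70:
        return 0
    if si < 0.80:
        return 1
    if si < 0.90:
        return 2
    return 3


def fasila_lactate_points(lactate: float) -> int:
    """Lactate component of the FASILA score.

    0 for <= 2.0 mmol/L, 1 for (2.0, 4.0), 2 for >= 4.0.  The explicit <=/>=
    qualifiers of the outer bins win at the shared endpoints.
    """
    if lactate < 0:
        raise ScoreDomainError(f"lactate must be >= 0, got {lactate}")
    if lactate <= 2.0:
        return 0
    if lactate < 4.0:
        return 1
    return 2


def _resolve_fast(
    fast: FastResult, policy: IndeterminatePolicy
) -> FastResult:
    if fast is not FastResult.INDETERMINATE:
        return fast
    if policy is IndeterminatePolicy.AS_NEGATIVE:
        return FastResult.NEGATIVE
    if policy is IndeterminatePolicy.AS_POSITIVE:
        return FastResult.POSITIVE
    raise UnscorableError("indeterminate FAST result under strict policy")


def _check_vital_sanity(hr: float, sbp: float, ignore: bool) -> None:
    if ignore:
        return
    if not (HR_SANITY[0] <= hr <= HR_SANITY[1]):
        warnings.warn(
            f"hr={hr} outside sanity range {HR_SANITY}; check input units",
            stacklevel=3,
        )
    if not (SBP_SANITY[0] <= sbp <= SBP_SANITY[1]):
        warnings.warn(
            f"sbp={sbp} outside sanity range {SBP_SANITY}; check input units",
            stacklevel=3,
        )


def fasila_score(
    fast: FastResult | str,
    hr: float,
    sbp: float,
    lactate: float,
    *,
    indeterminate_policy: IndeterminatePolicy = IndeterminatePolicy.STRICT,
    ignore_sanity_bounds: bool = False,
) -> FasilaBreakdown:
    """Compute the FASILA score from its four raw inputs.

    Parameters
    ----------
    fast : FastResult or str
        FAST scan result; indeterminate results are handled per
        ``indeterminate_policy`` (strict policy raises :class:`UnscorableError`).
    hr, sbp : float
        Heart rate (beats/min) and systolic blood pressure (mmHg).
    lactate : float
        Initial serum lactate (mmol/L).

    Returns
    -------
    FasilaBreakdown
        Component points and the 0-6 total.
    """
    fast = _resolve_fast(FastResult(fast), IndeterminatePolicy(indeterminate_policy))
    _check_vital_sanity(hr, sbp, ignore_sanity_bounds)
    fast_points = 1 if fast is FastResult.POSITIVE else 0
    si_points = fasila_si_points(systolic_shock_index(hr, sbp))
    lactate_points = fasila_lactate_points(lactate)
    return FasilaBreakdown(fast_points, si_points, lactate_points)


def fasila_risk_class(total: int, cutoff: int = DEFAULT_CUTOFF) -> RiskClass:
    """Dichotomize a FASILA total into low (< cutoff) vs high (>= cutoff)."""
    if not (0 <= total <= 6):
        raise ScoreDomainError(f"FASILA total {total} outside 0-6")
    return RiskClass.HIGH if total >= cutoff else RiskClass.LOW


def abc_score(
    mechanism: Mechanism | str,
    fast: FastResult | str,
    sbp: float,
    hr: float,
    *,
    indeterminate_policy: IndeterminatePolicy = IndeterminatePolicy.STRICT,
) -> AbcBreakdown:
    """Assessment of Blood Consumption score.

    One point each for penetrating mechanism, positive FAST, SBP <= 90 mmHg
    and HR >= 120 beats/min; a total >= 2 predicts massive transfusion.
    """
    if sbp <= 0 or hr <= 0:
        raise ScoreDomainError(f"hr and sbp must be positive, got hr={hr}, sbp={sbp}")
    fast = _resolve_fast(FastResult(fast), IndeterminatePolicy(indeterminate_policy))
    mechanism = Mechanism(mechanism)
    return AbcBreakdown(
        penetrating_point=int(mechanism is Mechanism.PENETRATING),
        fast_point=int(fast is FastResult.POSITIVE),
        sbp_point=int(sbp <= 90),
        hr_point=int(hr >= 120),
    )
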