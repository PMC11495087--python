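"""Cohort life table: impacted mortality rates, survival, life expectancy,
days of life lost and (excess) deaths per million.

Baseline cause-specific mortality is scaled by the lagged relative risks:
iMR_cause(a) = RR_cause(a) · MR_cause(a).  The non-pollution-sensitive
remainder NPS(a) = all_cause(a) − Σ MR_cause(a) is unaffected by PM2.5 and
added back, so all-cause iMR(a) = NPS(a) + Σ iMR_cause(a).

The life table assumes deaths at the mid-point of each year, giving the
survival probability (2 − m) / (2 + m) for an annual mortality rate m.
Life-years are accumulated from birth to the age-100 horizon; the cohort is
closed at exact age 100 (remaining survivors are assigned to the closing
interval and credited no further life-years), so a zero-mortality cohort
has a horizon-truncated life expectancy of exactly 100 years.

Deaths per million are cohort-weighted: deaths(a) = 10⁶ · l(a) · q(a) with
l the cumulative survival, which conserves the cohort exactly —
deaths within the horizon plus survivors at the horizon equal 10⁶.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crf import CAUSES
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Terminal age of the life table (exclusive horizon: ages 0..99 are lived,
#: survivors are closed out at exact age 100).
HORIZON = 100

#: Cohort size for deaths-per-million reporting.
COHORT = 1_000_000

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class MortalitySchedule:
    """Age- and sex-specific baseline annual mortality probabilities.

    Arrays cover ages 0..100 (101 entries).  ``cause_rates`` holds the six
    pollution-sensitive causes; their sum may not exceed the all-cause rate
    at any age.
    """

    sex: str
    all_cause: np.ndarray
    cause_rates: dict[str, np.ndarray]

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male|female, got {self.sex!r}")
        ac = np.asarray(self.all_cause, dtype=float)
        if ac.shape != (HORIZON + 1,):
            raise ValidationError(f"all_cause must cover ages 0..{HORIZON} ({HORIZON + 1} values)")
        if np.any(ac < 0) or np.any(ac > 1):
            raise ValidationError("all_cause rates must lie in [0, 1]")
        missing = set(CAUSES) - set(self.cause_rates)
        if missing:
            raise ValidationError(f"missing cause rates: {sorted(missing)}")
        rates = {}
        total = np.zeros_like(ac)
        for cause in CAUSES:
            r = np.asarray(self.cause_rates[cause], dtype=float)
            if r.shape != ac.shape:
                raise ValidationError(f"{cause}: rate array length mismatch")
            if np.any(r < 0) or np.any(r > 1):
                raise ValidationError(f"{cause}: rates must lie in [0, 1]")
            rates[cause] = r
            total += r
        if np.any(total > ac + 1e-12):
            bad = np.nonzero(total > ac + 1e-12)[0]
            raise ValidationError(
                f"sum of cause rates exceeds all-cause at ages {bad.tolist()[:10]}"
            )
        object.__setattr__(self, "all_cause", ac)
        object.__setattr__(self, "cause_rates", rates)

    @property
    def nps(self) -> np.ndarray:
        """Non-pollution-sensitive remainder rate per age."""
        return self.all_cause - sum(self.cause_rates.values())

    @classmethod
    def from_csv(cls, path, sex: str) -> "MortalitySchedule":
        """Read the long-format table ``sex,age,cause,rate``.

        ``cause`` takes ``all_cause`` or one of the six pollution-sensitive
        causes.
        """
        df = pd.read_csv(path)
        required = {"sex", "age", "cause", "rate"}
        if not required <= set(df.columns):
            raise ValidationError(f"mortality CSV needs columns {sorted(required)}")
        df = df[df["sex"] == sex]
        if df.empty:
            raise ValidationError(f"no rows for sex {sex!r} in mortality table")
        wide = df.pivot_table(index="age", columns="cause", values="rate")
        ages = np.arange(HORIZON + 1)
        if not np.array_equal(wide.index.to_numpy(), ages):
            raise ValidationError(f"mortality table must cover ages 0..{HORIZON} exactly")
        return cls(
            sex=sex,
            all_cause=wide["all_cause"].to_numpy(float),
            cause_rates={c: wide[c].to_numpy(float) for c in CAUSES},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cause in ("all_cause",) + CAUSES:
            arr = self.all_cause if cause == "all_cause" else self.cause_rates[cause]
            for age, rate in enumerate(arr):
                rows.append({"sex": self.sex, "age": age, "cause": cause, "rate": rate})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImpactedMortality:
    """Baseline mortality scaled by lagged relative risks."""

    all_cause: np.ndarray
    cause_rates: dict[str, np.ndarray]
    nps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "all_cause", np.asarray(self.all_cause, dtype=float))
        object.__setattr__(self, "nps", np.asarray(self.nps, dtype=float))


def impacted_rates(baseline: MortalitySchedule, lagged_rr: pd.DataFrame) -> ImpactedMortality:
    """Apply per-age, per-cause relative risks to a baseline schedule.

    ``lagged_rr`` is indexed by age 0..100 with one column per cause.
    Rates are capped at 1 with a warning if the RR multiplication exceeds 1
    (possible only for extreme synthetic inputs).
    """
    n = HORIZON + 1
    if len(lagged_rr) != n:
        raise ValidationError(f"lagged RR frame must cover ages 0..{HORIZON}")
    nps = baseline.nps
    cause_imr = {}
    total = nps.copy()
    for cause in CAUSES:
        imr = lagged_rr[cause].to_numpy(float) * baseline.cause_rates[cause]
        if np.any(imr > 1):
            logger.warning("impacted %s rate exceeds 1 at some ages; capping", cause)
            imr = np.minimum(imr, 1.0)
        cause_imr[cause] = imr
        total += imr
    if np.any(total > 1):
        logger.warning("impacted all-cause rate exceeds 1 at some ages; capping")
        total = np.minimum(total, 1.0)
    return ImpactedMortality(all_cause=total, cause_rates=cause_imr, nps=nps)


def survival_probability(m):
    """Probability of surviving a year with annual mortality rate ``m``.

    Mid-year deaths convention: p = (2 − m) / (2 + m).  ``m`` must lie in
    [0, 2); scalar or array.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0) or np.any(arr >= 2):
        raise ValidationError("mortality rate must lie in [0, 2)")
    p = (2.0 - arr) / (2.0 + arr)
    return float(p) if np.isscalar(m) else p


@dataclass(frozen=True)
class LifeTableResult:
    """Cohort projection of an impacted all-cause mortality schedule.

    ``survival[a]`` is the probability of surviving age ``a`` given alive at
    its start (ages 0..99); ``cumulative_survival[a]`` (ages 0..100) the
    probability of reaching exact age ``a``; ``deaths[a]`` the per-million
    deaths during age ``a``; ``closure_deaths`` the per-million survivors
    assigned to the closing interval at age 100.
    """

    survival: np.ndarray
    cumulative_survival: np.ndarray
    life_years: np.ndarray
    life_expectancy: float
    deaths: np.ndarray
    deaths_total: float
    closure_deaths: float


def _interval_rates(imr) -> np.ndarray:
    m = np.asarray(imr, dtype=float)
    if m.ndim != 1 or m.size < HORIZON:
        raise ValidationError(
            f"all-cause iMR must cover at least ages 0..{HORIZON - 1}; got length {m.size}"
        )
    # the age-100 entry (if provided) belongs to the closing interval and
    # does not alter the projection: the cohort is closed at exact age 100
    return m[:HORIZON]


def cohort_life_table(imr) -> LifeTableResult:
    """Project a 10⁶-person birth cohort through an all-cause iMR schedule."""
    m = _interval_rates(imr)
    p = survival_probability(m)                      # ages 0..99
    l = np.empty(HORIZON + 1)                        # reaching exact age a
    l[0] = 1.0
    np.cumprod(p, out=l[1:])
    life_years = 0.5 * (l[:-1] + l[1:])              # mid-year deaths
    le = float(life_years.sum() / l[0])
    deaths = COHORT * l[:-1] * (1.0 - p)
    deaths_total = float(deaths.sum())
    # closure is defined as the cohort remainder, so conservation
    # (deaths_total + closure_deaths == COHORT) is exact in floating point;
    # it coincides with COHORT * l[100] to rounding error
    closure = COHORT - deaths_total
    return LifeTableResult(
        survival=p,
        cumulative_survival=l,
        life_years=life_years,
        life_expectancy=le,
        deaths=deaths,
        deaths_total=deaths_total,
        closure_deaths=closure,
    )


def life_expectancy(imr, from_age: int = 0) -> float:
    """Horizon-truncated expectation of life at ``from_age``.

    Life-years from ``from_age`` to the age-100 horizon divided by the
    cumulative survival to ``from_age``.
    """
    if not 0 <= from_age < HORIZON:
        raise ValidationError(f"from_age must lie in [0, {HORIZON})")
    lt = cohort_life_table(imr)
    return float(lt.life_years[from_age:].sum() / lt.cumulative_survival[from_age])


def days_of_life_lost(le_reference: float, le_scenario: float,
                      days_per_year: float = DAYS_PER_YEAR) -> float:
    """(reference LE − scenario LE) in days; negative when the scenario wins."""
    return (le_reference - le_scenario) * days_per_year


def deaths_per_million(imr) -> tuple[np.ndarray, float]:
    """Per-age deaths and their within-horizon total per 10⁶ births.

    The total excludes the closure of survivors at age 100, so that two
    schedules can differ (a harsher schedule moves deaths into the horizon);
    per-age deaths plus closure always sum to exactly 10⁶.
    """
    lt = cohort_life_table(imr)
    return lt.deaths, lt.deaths_total


def excess_deaths(scenario_total: float, reference_total: float) -> float:
    """Scenario minus reference within-horizon deaths per million (signed)."""
    return scenario_total - reference_total
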