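"""Scenario orchestration: people, assignment fixtures, full runs and the
eight-variation sensitivity analysis.

A scenario pairs a person (birth year, sex, assignment window) with an
assignment profile and runs the whole pipeline twice — once for the
assignment and once for the counterfactual of the same person living
exclusively in the home country — so days of life lost (DLL) and excess
deaths per million are differences between two internally consistent
cohort projections.  Lags are enabled from the start of the assignment
window for both runs, so pre-window risk histories cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .crf import CAUSES, CRFSet, rr_profile
from .errors import ResourceError, ValidationError
from .exposure import (
    AssignmentProfile,
    BackgroundSeries,
    CityYearTable,
    Posting,
    apply_mitigation,
    build_lifetime_exposure,
)
from .lags import DEFAULT_THRESHOLD, alt_lag_weights, apply_lags
from .lifetable import (
    DAYS_PER_YEAR,
    HORIZON,
    MortalitySchedule,
    cohort_life_table,
    days_of_life_lost,
    excess_deaths,
    impacted_rates,
)

#: Person-group defaults: (birth_year, (first, last) assignment ages).
#: The three archetypes: an older diplomat posted in late career, a young
#: diplomat posted in early career, and a child accompanying a parent from
#: birth; all windows span the 20 assignment years 2000–2019.
PERSON_GROUPS = {
    "older": (1955, (45, 64)),
    "young": (1975, (25, 44)),
    "child": (2000, (0, 19)),
}


@dataclass(frozen=True)
class PersonSpec:
    """Who is being modelled: group archetype, sex, birth year and the
    (start_age, end_age) assignment window."""

    group: str
    sex: str
    birth_year: int
    assignment_window: tuple[int, int]

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male|female, got {self.sex!r}")
        a0, a1 = self.assignment_window
        if not (0 <= a0 <= a1 <= HORIZON):
            raise ValidationError(f"assignment window {self.assignment_window} out of range")

    @classmethod
    def for_group(cls, group: str, sex: str = "male",
                  birth_year: int | None = None,
                  assignment_window: tuple[int, int] | None = None) -> "PersonSpec":
        if group not in PERSON_GROUPS:
            raise ValidationError(f"unknown person group {group!r}; expected {sorted(PERSON_GROUPS)}")
        default_birth, default_window = PERSON_GROUPS[group]
        return cls(
            group=group,
            sex=sex,
            birth_year=birth_year if birth_year is not None else default_birth,
            assignment_window=assignment_window or default_window,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Tunable model choices for one run.

    ``lag_overrides`` maps a cause to a schedule name applied as the
    (inception, cessation) complement pair for that cause only — the
    mechanism behind the short-lag/long-lag sensitivity variations.
    """

    bound: str = "central"                       # C-R curve: central|lower|upper
    inception: str = "epa"                       # schedule name for upward moves
    cessation: str = "epa"                       # schedule name for downward moves
    lag_overrides: dict = field(default_factory=dict)   # cause -> schedule name
    threshold: float = DEFAULT_THRESHOLD         # µg/m³ trigger
    mitigation_factor: float = 0.5
    mortality_source: str = "default"            # default | alt (high-income)
    horizon: int = HORIZON
    days_per_year: float = DAYS_PER_YEAR

    def schedules_for(self, cause: str):
        name_inc, name_ces = self.inception, self.cessation
        if cause in self.lag_overrides:
            name_inc = name_ces = self.lag_overrides[cause]
        return (
            alt_lag_weights(name_inc, kind="inception"),
            alt_lag_weights(name_ces, kind="cessation"),
        )


@dataclass
class Resources:
    """Validated external inputs of a run."""

    mortality: dict[str, MortalitySchedule]
    crfs: CRFSet
    city_table: CityYearTable | None
    background: BackgroundSeries
    mortality_alt: dict[str, MortalitySchedule] | None = None

    def schedule(self, sex: str, source: str = "default") -> MortalitySchedule:
        if source == "default":
            pool = self.mortality
        elif source == "alt":
            if self.mortality_alt is None:
                raise ResourceError(
                    "alternate (high-income) mortality table requested but not provided"
                )
            pool = self.mortality_alt
        else:
            raise ValidationError(f"unknown mortality source {source!r}")
        try:
            return pool[sex]
        except KeyError:
            raise ResourceError(f"no mortality schedule for sex {sex!r}") from None


@dataclass
class ArmResult:
    """One arm (assignment or counterfactual) of a scenario."""

    exposure: "pd.DataFrame"
    unlagged_rr: pd.DataFrame
    lagged_rr: pd.DataFrame
    imr_all_cause: np.ndarray
    life_expectancy: float
    deaths_total: float
    deaths: np.ndarray
    lag_episodes: dict


@dataclass
class ScenarioResult:
    """Paired assignment/counterfactual outcome for one person."""

    label: str
    person: PersonSpec
    config: ModelConfig
    scenario: ArmResult
    reference: ArmResult
    dll: float
    excess_deaths: float

    def summary_row(self) -> dict:
        return {
            "scenario": self.label,
            "sex": self.person.sex,
            "group": self.person.group,
            "life_expectancy": self.scenario.life_expectancy,
            "reference_life_expectancy": self.reference.life_expectancy,
            "dll": self.dll,
            "deaths_per_million": self.scenario.deaths_total,
            "excess_deaths": self.excess_deaths,
        }


def _run_arm(exposure, person: PersonSpec, config: ModelConfig,
             resources: Resources) -> ArmResult:
    unlagged = rr_profile(resources.crfs, exposure, bound=config.bound)
    lag_start = person.assignment_window[0]
    lagged = unlagged.copy()
    episodes = {}
    for cause in CAUSES:
        inc, ces = config.schedules_for(cause)
        lagged[cause], episodes[cause] = apply_lags(
            unlagged[cause].to_numpy(float),
            exposure.values,
            inc,
            ces,
            threshold=config.threshold,
            lag_start_index=lag_start,
            return_episodes=True,
        )
    baseline = resources.schedule(person.sex, config.mortality_source)
    imr = impacted_rates(baseline, lagged)
    lt = cohort_life_table(imr.all_cause)
    return ArmResult(
        exposure=exposure.to_frame(),
        unlagged_rr=unlagged,
        lagged_rr=lagged,
        imr_all_cause=imr.all_cause,
        life_expectancy=lt.life_expectancy,
        deaths_total=lt.deaths_total,
        deaths=lt.deaths,
        lag_episodes=episodes,
    )


def run_scenario(profile: AssignmentProfile, person: PersonSpec,
                 config: ModelConfig, resources: Resources) -> ScenarioResult:
    """Run one assignment against its lived-exclusively-at-home reference."""
    scen_exposure = build_lifetime_exposure(
        profile, resources.city_table, resources.background,
        person.birth_year, terminal_age=config.horizon,
    )
    if profile.mitigated:
        scen_exposure = apply_mitigation(scen_exposure, profile, config.mitigation_factor)
    ref_exposure = build_lifetime_exposure(
        AssignmentProfile(label=f"{profile.label} (reference)"),
        resources.city_table, resources.background,
        person.birth_year, terminal_age=config.horizon,
    )
    scen = _run_arm(scen_exposure, person, config, resources)
    ref = _run_arm(ref_exposure, person, config, resources)
    return ScenarioResult(
        label=profile.label,
        person=person,
        config=config,
        scenario=scen,
        reference=ref,
        dll=days_of_life_lost(ref.life_expectancy, scen.life_expectancy,
                              config.days_per_year),
        excess_deaths=excess_deaths(scen.deaths_total, ref.deaths_total),
    )


#: The eight sensitivity variations, keyed by number.
SENSITIVITY_VARIATIONS = {
    1: "high-income baseline mortality",
    2: "short 8-year lag on COPD and LRI only",
    3: "triphasic 38-year lag on lung cancer only",
    4: "no inception lag",
    5: "no cessation lag",
    6: "no lags",
    7: "upper-CI concentration-response curves",
    8: "lower-CI concentration-response curves",
}


def _variation_config(base: ModelConfig, variation: int) -> ModelConfig:
    if variation == 1:
        return replace(base, mortality_source="alt")
    if variation == 2:
        overrides = dict(base.lag_overrides)
        overrides.update({"copd": "short8", "lri": "short8"})
        return replace(base, lag_overrides=overrides)
    if variation == 3:
        overrides = dict(base.lag_overrides)
        overrides["lung_cancer"] = "triphasic38"
        return replace(base, lag_overrides=overrides)
    if variation == 4:
        return replace(base, inception="none")
    if variation == 5:
        return replace(base, cessation="none")
    if variation == 6:
        return replace(base, inception="none", cessation="none", lag_overrides={})
    if variation == 7:
        return replace(base, bound="upper")
    if variation == 8:
        return replace(base, bound="lower")
    raise ValidationError(f"unknown sensitivity variation {variation}")


def sensitivity_suite(profile: AssignmentProfile, person: PersonSpec,
                      base_config: ModelConfig, resources: Resources,
                      variations=tuple(range(1, 9))) -> pd.DataFrame:
    """Central run plus the requested variations; DLL deltas vs central.

    Returns one row per run with columns ``variation`` (0 = central),
    ``description``, ``dll``, ``delta_dll``, ``delta_dll_pct``,
    ``life_expectancy`` and ``excess_deaths``.
    """
    central = run_scenario(profile, person, base_config, resources)
    rows = [
        {
            "variation": 0,
            "description": "central",
            "dll": central.dll,
            "delta_dll": 0.0,
            "delta_dll_pct": 0.0,
            "life_expectancy": central.scenario.life_expectancy,
            "excess_deaths": central.excess_deaths,
        }
    ]
    for v in variations:
        if v not in SENSITIVITY_VARIATIONS:
            raise ValidationError(f"unknown sensitivity variation {v}")
        res = run_scenario(profile, person, _variation_config(base_config, v), resources)
        delta = res.dll - central.dll
        rows.append(
            {
                "variation": v,
                "description": SENSITIVITY_VARIATIONS[v],
                "dll": res.dll,
                "delta_dll": delta,
                "delta_dll_pct": (100.0 * delta / central.dll) if central.dll != 0 else np.nan,
                "life_expectancy": res.scenario.life_expectancy,
                "excess_deaths": res.excess_deaths,
            }
        )
    return pd.DataFrame(rows)


def _cycle_postings(high_city: str, low_city: str, k_high: int,
                    start_year: int = 2000, n_cycles: int = 5,
                    region: str = "africa_asia") -> tuple[Posting, ...]:
    """k high years then (4 − k) low years, repeated."""
    postings = []
    year = start_year
    for _ in range(n_cycles):
        if k_high:
            postings.append(Posting(high_city, year, k_high, region=region))
            year += k_high
        k_low = 4 - k_high
        if k_low:
            postings.append(Posting(low_city, year, k_low, region="other"))
            year += k_low
    return tuple(postings)


def _standard_a_postings(start_year: int, mitigated: bool | None = None) -> tuple[Posting, ...]:
    """A 20-year career with three exposure peaks, home rotations between.

    Stand-in for the real diplomat's itinerary (which is not published):
    high posting years 1–4, home 5–10, moderate posting 11–14, home 15–17,
    high posting 18–19, home year 20.
    """
    y = start_year
    return (
        Posting("city_high_a", y, 4, region="africa_asia", mitigated=mitigated),
        Posting("city_home", y + 4, 6, region="other"),
        Posting("city_mod", y + 10, 4, region="africa_asia", mitigated=mitigated),
        Posting("city_home", y + 14, 3, region="other"),
        Posting("city_high_b", y + 17, 2, region="africa_asia", mitigated=mitigated),
        Posting("city_home", y + 19, 1, region="other"),
    )


def builtin_profiles(start_year: int = 2000) -> dict[str, AssignmentProfile]:
    """The ten named assignment fixtures.

    All are 20-year assignments starting in ``start_year`` except
    "Standard A x 2" (40 years).  City PM2.5 levels come from the synthetic
    city table's bands: low < 20, moderate 21–40, high 41–60, very high
    > 61 µg/m³.
    """
    y = start_year
    profiles = {
        "standard_a": AssignmentProfile("Standard A", _standard_a_postings(y)),
        "standard_b": AssignmentProfile(
            "Standard B",
            (
                Posting("city_mod", y, 3, region="africa_asia"),
                Posting("city_home", y + 3, 3, region="other"),
                Posting("city_high_a", y + 6, 4, region="africa_asia"),
                Posting("city_home", y + 10, 3, region="other"),
                Posting("city_high_b", y + 13, 4, region="africa_asia"),
                Posting("city_home", y + 17, 3, region="other"),
            ),
        ),
        "standard_a_x2": AssignmentProfile(
            "Standard A x 2",
            _standard_a_postings(y) + _standard_a_postings(y + 20),
        ),
        "high_1_low_3": AssignmentProfile(
            "High 1 year & low 3 years cycle",
            _cycle_postings("city_high_c", "city_low", 1, y),
        ),
        "high_2_low_2": AssignmentProfile(
            "High 2 years & low 2 years cycle",
            _cycle_postings("city_high_c", "city_low", 2, y),
        ),
        "high_3_low_1": AssignmentProfile(
            "High 3 years & low 1 year cycle",
            _cycle_postings("city_high_c", "city_low", 3, y),
        ),
        "high_4x5": AssignmentProfile(
            "High 4 years x 5",
            tuple(
                Posting(c, y + 4 * i, 4, region="africa_asia")
                for i, c in enumerate(
                    ["city_high_a", "city_high_b", "city_high_c", "city_high_d", "city_high_e"]
                )
            ),
        ),
        "very_high_2_low_2": AssignmentProfile(
            "Very high 2 years & low 2 years cycle",
            _cycle_postings("city_vhigh", "city_low", 2, y),
        ),
        "very_high_20": AssignmentProfile(
            "Very high 20 years",
            (Posting("city_vhigh", y, 20, region="africa_asia"),),
        ),
        "standard_a_mitigated": AssignmentProfile(
            "Standard A with mitigation",
            _standard_a_postings(y, mitigated=True),
            mitigated=True,
        ),
    }
    return profiles
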