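"""Synthetic inputs with known ground truth.

Real runs of the model need external data — national baseline mortality by
age and sex, GBD-style concentration–response curves, and WHO/EPA city
annual-mean PM2.5 series — none of which are bundled.  This module
generates structurally faithful stand-ins:

* baseline mortality as a Gompertz–Makeham hazard (a constant "Makeham"
  floor plus an exponentially age-increasing term) with fixed
  pollution-sensitive cause fractions;
* concentration–response curves from closed-form families (log-linear or
  saturating-exponential) flattened to grids, so pipeline output can be
  checked against the closed form exactly;
* a city-year table whose levels sit at representative values of the
  pollution bands used throughout (low < 20, moderate 21–40, high 41–60,
  very high > 61 µg/m³) and a declining US-like background series.

Generated artifacts pass the consuming modules' validators by construction
and are deterministic per seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crf import AGE_BANDS, AGE_SPECIFIC_CAUSES, CAUSES, CRFCurve, CRFSet
from .errors import ValidationError
from .exposure import BackgroundSeries, CityYearTable
from .lifetable import HORIZON, MortalitySchedule

#: Default fraction of all-cause mortality attributed to each
#: pollution-sensitive cause (roughly ordered like US cause-of-death
#: shares; they sum to 0.32, leaving 68% non-pollution-sensitive).
DEFAULT_CAUSE_FRACTIONS = {
    "ihd": 0.12,
    "stroke": 0.06,
    "copd": 0.05,
    "lri": 0.02,
    "t2dm": 0.03,
    "lung_cancer": 0.04,
}

#: Default per-µg/m³ log-RR slopes.  Sized so that ~50 µg/m³ above the
#: TMREL yields RRs in the 1.1–1.2 range, the order of magnitude of the
#: GBD curves at high ambient levels.
DEFAULT_CRF_SLOPES = {
    "ihd": 0.0025,
    "stroke": 0.0030,
    "copd": 0.0018,
    "lri": 0.0020,
    "t2dm": 0.0012,
    "lung_cancer": 0.0015,
}

#: Representative annual-mean levels (µg/m³) for the exposure bands.
DEFAULT_BAND_LEVELS = {
    "home": 9.0,        # recent US ambient level
    "low": 12.0,        # low band: < 20
    "moderate": 27.0,   # moderate band: 21–40
    "high": 50.0,       # high band: 41–60
    "very_high": 70.0,  # very-high band: > 61
}

_BAND_RANGES = {
    "home": (0.0, 20.0),
    "low": (0.0, 20.0),
    "moderate": (21.0, 40.0),
    "high": (41.0, 60.0),
    "very_high": (61.0, np.inf),
}


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic world ("desk_default" when unchanged).

    Mortality: all_cause(a) = min(1, makeham + level · e^(slope·a)); the
    defaults give ~2.6e-4 at birth and ~0.25 at age 100, a plausible
    Gompertz-like human schedule.  Females are scaled by
    ``female_mortality_scale``.

    Curves: ``crf_family`` is ``log_linear`` (RR = exp(β·(C − TMREL)₊)) or
    ``saturating`` (RR = 1 + γ·(1 − e^(−k·(C − TMREL)₊))).  CI bounds are
    central × (1 ∓ δ) floored at 1.  IHD/stroke slopes are attenuated by
    ``age_attenuation`` per 5-year band step (older bands have flatter
    relative risks, as in the GBD curves).
    """

    seed: int = 0
    # mortality
    makeham: float = 2.0e-4
    gompertz_level: float = 3.0e-5
    gompertz_slope: float = 0.09
    cause_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CAUSE_FRACTIONS))
    female_mortality_scale: float = 0.8
    # concentration-response
    crf_family: str = "log_linear"
    tmrel: float = 5.0
    crf_slopes: dict = field(default_factory=lambda: dict(DEFAULT_CRF_SLOPES))
    saturating_gamma: float = 0.5
    saturating_k: float = 0.02
    ci_delta: float = 0.3
    age_attenuation: float = 0.95
    grid_max: float = 150.0
    grid_step: float = 5.0
    # exposure
    band_levels: dict = field(default_factory=lambda: dict(DEFAULT_BAND_LEVELS))
    pm_jitter: float = 0.0   # seeded uniform jitter (± µg/m³) on city levels
    year_min: int = 2000
    year_max: int = 2039
    background_start: int = 1981
    background_end: int = 2021

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic stream per component.

        Uses crc32 of the stream name (not ``hash``, which is salted per
        process) so regeneration is stable across runs and platforms.
        """
        stream_key = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(
            np.random.SeedSequence([self.seed % (2**31), stream_key])
        )


def synth_mortality_schedule(params: SynthParams, sex: str = "male") -> MortalitySchedule:
    """Gompertz–Makeham baseline mortality with fixed cause fractions."""
    scale = 1.0 if sex == "male" else params.female_mortality_scale
    ages = np.arange(HORIZON + 1)
    all_cause = np.minimum(
        1.0,
        scale * (params.makeham + params.gompertz_level * np.exp(params.gompertz_slope * ages)),
    )
    if np.any(all_cause >= 1.0):
        raise ValidationError(
            "mortality parameters produce rates >= 1 before age 100; "
            "reduce gompertz_level or gompertz_slope"
        )
    frac_sum = sum(params.cause_fractions.get(c, 0.0) for c in CAUSES)
    if frac_sum > 1.0:
        raise ValidationError(f"cause fractions sum to {frac_sum} > 1")
    cause_rates = {c: params.cause_fractions.get(c, 0.0) * all_cause for c in CAUSES}
    return MortalitySchedule(sex=sex, all_cause=all_cause, cause_rates=cause_rates)


def _central_rr(params: SynthParams, cause: str, conc: np.ndarray,
                band_index: int = 0) -> np.ndarray:
    beta = params.crf_slopes.get(cause)
    if beta is None or beta < 0:
        raise ValidationError(f"{cause}: slope must be present and >= 0")
    excess_conc = np.maximum(0.0, conc - params.tmrel)
    atten = params.age_attenuation ** band_index if cause in AGE_SPECIFIC_CAUSES else 1.0
    if params.crf_family == "log_linear":
        return np.exp(beta * atten * excess_conc)
    if params.crf_family == "saturating":
        gamma = params.saturating_gamma * atten
        return 1.0 + gamma * (1.0 - np.exp(-params.saturating_k * excess_conc))
    raise ValidationError(f"unknown crf family {params.crf_family!r}")


def synth_crf_set(params: SynthParams) -> CRFSet:
    """Closed-form concentration–response curves tabulated on a grid."""
    conc = np.arange(0.0, params.grid_max + params.grid_step / 2, params.grid_step)
    curves = []
    for cause in CAUSES:
        bands = AGE_BANDS if cause in AGE_SPECIFIC_CAUSES else (None,)
        for i, band in enumerate(bands):
            central = _central_rr(params, cause, conc, band_index=i)
            lower = np.maximum(1.0, central * (1.0 - params.ci_delta))
            upper = np.maximum(1.0, central * (1.0 + params.ci_delta))
            # keep RR exactly 1 at/below the TMREL on every bound
            at_or_below = conc <= params.tmrel
            for arr in (central, lower, upper):
                arr[at_or_below] = 1.0
            curves.append(
                CRFCurve(
                    cause=cause,
                    age_band=band,
                    tmrel=params.tmrel,
                    grid_conc=conc.copy(),
                    rr_central=central,
                    rr_lower=lower,
                    rr_upper=upper,
                )
            )
    return CRFSet(curves)


def closed_form_rr(params: SynthParams, cause: str, concentration: float,
                   age: int | None = None) -> float:
    """Ground-truth RR of the synthetic family (for known-truth tests)."""
    band_index = 0
    if cause in AGE_SPECIFIC_CAUSES:
        if age is None or age < 25:
            return 1.0
        band_index = min((age - 25) // 5, len(AGE_BANDS) - 1)
    return float(_central_rr(params, cause, np.asarray([concentration]), band_index)[0])


def synth_background_series(params: SynthParams) -> BackgroundSeries:
    """US-like background: linear decline 22.1 → 8.0 over 1981–2021."""
    years = np.arange(params.background_start, params.background_end + 1)
    pm = np.linspace(22.1, 8.0, len(years))
    return BackgroundSeries(pd.Series(pm, index=years))


def _city_level(params: SynthParams, band: str, rng: np.random.Generator) -> float:
    base = params.band_levels.get(band)
    if base is None:
        raise ValidationError(f"unknown exposure band {band!r}")
    level = base + (rng.uniform(-params.pm_jitter, params.pm_jitter) if params.pm_jitter else 0.0)
    lo, hi = _BAND_RANGES[band]
    if not (lo <= level <= hi) or level < 0:
        raise ValidationError(
            f"band {band!r} level {level:.1f} µg/m³ falls outside its range [{lo}, {hi}]"
        )
    return float(level)


#: city_id → exposure band of the synthetic world.
SYNTH_CITIES = {
    "city_home": "home",
    "city_low": "low",
    "city_mod": "moderate",
    "city_high_a": "high",
    "city_high_b": "high",
    "city_high_c": "high",
    "city_high_d": "high",
    "city_high_e": "high",
    "city_vhigh": "very_high",
}

#: Offsets (µg/m³) distinguishing the five high-band cities while keeping
#: all of them inside the 41–60 band.
_HIGH_OFFSETS = {"city_high_a": -5.0, "city_high_b": 5.0, "city_high_c": 0.0,
                 "city_high_d": -2.0, "city_high_e": 2.0}


def synth_city_table(params: SynthParams) -> CityYearTable:
    """City-year PM2.5 rows for the synthetic cities over the model years."""
    rng = params.rng("city_table")
    rows = []
    years = range(params.year_min, params.year_max + 1)
    for city, band in SYNTH_CITIES.items():
        level = _city_level(params, band, rng) + _HIGH_OFFSETS.get(city, 0.0)
        lo, hi = _BAND_RANGES[band]
        if not (lo <= level <= hi):
            raise ValidationError(f"{city}: level {level:.1f} outside band {band!r}")
        for y in years:
            rows.append({"city_id": city, "year": y, "pm25": level})
    return CityYearTable(pd.DataFrame(rows))


def synth_resources(params: SynthParams | None = None):
    """The complete desk-default input bundle.

    Returns a :class:`relolife.scenarios.Resources` with both sexes'
    mortality schedules, a synthetic high-income alternative schedule
    (baseline scaled down — a stand-in for top-income-county statistics),
    the curve set, city table and background series.
    """
    from .scenarios import Resources  # local import to avoid a cycle

    params = params or SynthParams()
    mortality = {s: synth_mortality_schedule(params, s) for s in ("male", "female")}
    alt_scale = 0.8

    def scaled(ms: MortalitySchedule) -> MortalitySchedule:
        return MortalitySchedule(
            sex=ms.sex,
            all_cause=ms.all_cause * alt_scale,
            cause_rates={c: r * alt_scale for c, r in ms.cause_rates.items()},
        )

    return Resources(
        mortality=mortality,
        mortality_alt={s: scaled(m) for s, m in mortality.items()},
        crfs=synth_crf_set(params),
        city_table=synth_city_table(params),
        background=synth_background_series(params),
    )
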