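"""Lifetime annual-mean PM2.5 exposure assembly.

A person's exposure history is built at annual resolution: life-year ``a``
corresponds to calendar year ``birth_year + a`` and carries the annual mean
ambient PM2.5 concentration (µg/m³) of wherever they lived that year.
Posting years take city values from a city-year table (with a nearest-year
fallback when the exact year is absent); all other years take a background
country series; years outside the background series take constant backfill
values.  The defaults — 22.1 µg/m³ before the series starts and 8.0 µg/m³
after it ends — are the historical and recent US annual means.

An indoor-mitigation transform (air purifiers, home sealing) halves the
ambient concentration during qualifying postings; the 0.5 factor comes from
personal-monitoring measurements of the personal/ambient exposure ratio
before and after enhanced residential filtration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CityLookupError, CoverageGapError, ValidationError

logger = logging.getLogger(__name__)

#: Source provenance flags carried per life-year.
FLAG_POSTING = "posting"
FLAG_BACKGROUND = "background"
FLAG_BACKFILL = "backfill_constant"
FLAG_MITIGATED = "mitigated"

#: Region tag that qualifies a posting for the indoor-mitigation transform.
MITIGATION_REGION = "africa_asia"


@dataclass(frozen=True)
class Posting:
    """One consecutive block of years in a single city.

    ``mitigated`` overrides the region-derived mitigation eligibility for
    this posting; when ``None`` the posting qualifies iff its region tag is
    ``"africa_asia"``.
    """

    city_id: str
    start_year: int
    n_years: int
    region: str = "other"
    mitigated: bool | None = None

    def __post_init__(self):
        if self.n_years < 1:
            raise ValidationError(
                f"posting {self.city_id!r}: n_years must be >= 1, got {self.n_years}"
            )

    @property
    def end_year(self) -> int:
        """Last calendar year of the posting (inclusive)."""
        return self.start_year + self.n_years - 1

    @property
    def mitigation_eligible(self) -> bool:
        if self.mitigated is not None:
            return self.mitigated
        return self.region == MITIGATION_REGION

    def years(self) -> range:
        return range(self.start_year, self.start_year + self.n_years)


@dataclass(frozen=True)
class AssignmentProfile:
    """An ordered, contiguous, non-overlapping sequence of postings.

    ``mitigated`` marks the profile as an indoor-mitigation variant: the
    scenario runner applies :func:`apply_mitigation` to it.  Which posting
    years are scaled is decided per posting (see :class:`Posting`).
    """

    label: str
    postings: tuple[Posting, ...] = ()
    mitigated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "postings", tuple(self.postings))
        prev = None
        for p in self.postings:
            if prev is not None:
                if p.start_year != prev.end_year + 1:
                    raise ValidationError(
                        f"profile {self.label!r}: postings must be contiguous and "
                        f"ordered; {prev.city_id!r} ends {prev.end_year}, "
                        f"{p.city_id!r} starts {p.start_year}"
                    )
            prev = p

    @property
    def start_year(self) -> int | None:
        return self.postings[0].start_year if self.postings else None

    @property
    def end_year(self) -> int | None:
        return self.postings[-1].end_year if self.postings else None

    @classmethod
    def from_dict(cls, d: dict) -> "AssignmentProfile":
        postings = tuple(
            Posting(
                city_id=str(p["city"]),
                start_year=int(p["start_year"]),
                n_years=int(p["n_years"]),
                region=str(p.get("region", "other")),
                mitigated=p.get("mitigated"),
            )
            for p in d.get("postings", [])
        )
        return cls(
            label=str(d.get("label", "unnamed")),
            postings=postings,
            mitigated=bool(d.get("mitigated", False)),
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mitigated": self.mitigated,
            "postings": [
                {
                    "city": p.city_id,
                    "start_year": p.start_year,
                    "n_years": p.n_years,
                    "region": p.region,
                    **({"mitigated": p.mitigated} if p.mitigated is not None else {}),
                }
                for p in self.postings
            ],
        }


class CityYearTable:
    """City/year annual-mean PM2.5 table (µg/m³).

    Emulates the WHO ambient air pollution database: one row per
    (city_id, year).  CSV header: ``city_id,year,pm25``.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"city_id", "year", "pm25"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"city table missing columns: {sorted(missing)}")
        frame = frame[["city_id", "year", "pm25"]].copy()
        frame["year"] = frame["year"].astype(int)
        frame["pm25"] = frame["pm25"].astype(float)
        if (frame["pm25"] < 0).any():
            raise ValidationError("city table contains negative pm25 values")
        if frame.duplicated(["city_id", "year"]).any():
            dups = frame[frame.duplicated(["city_id", "year"])]
            raise ValidationError(
                f"duplicate (city_id, year) rows: {dups[['city_id', 'year']].values.tolist()}"
            )
        self.frame = frame.sort_values(["city_id", "year"]).reset_index(drop=True)
        # year-indexed series per city for fast nearest-year lookup
        self._by_city = {
            cid: g.set_index("year")["pm25"]
            for cid, g in self.frame.groupby("city_id", sort=False)
        }

    @classmethod
    def from_csv(cls, path) -> "CityYearTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def city_ids(self) -> list[str]:
        return list(self._by_city)

    def series_for(self, city_id: str) -> pd.Series:
        try:
            return self._by_city[city_id]
        except KeyError:
            raise CityLookupError(city_id) from None


def lookup_city_pm25(table: CityYearTable, city_id: str, year: int) -> float:
    """Annual-mean PM2.5 for ``(city_id, year)``, with nearest-year fallback.

    When the exact year is absent the value for the nearest available year
    for that city is used; an equidistant tie resolves to the earlier year.
    Substitutions are logged at INFO for audit.
    """
    s = table.series_for(city_id)
    if year in s.index:
        return float(s.loc[year])
    years = s.index.to_numpy()
    # stable argmin prefers the earlier year on an equidistant tie because
    # the series is sorted ascending
    nearest = years[np.argmin(np.abs(years - year))]
    logger.info(
        "city %s has no PM2.5 for %d; using nearest year %d (%.2f µg/m³)",
        city_id, year, nearest, s.loc[nearest],
    )
    return float(s.loc[nearest])


@dataclass(frozen=True)
class BackgroundSeries:
    """Home-country annual-mean PM2.5 series plus backfill constants.

    Years before the series' first year take ``backfill_before`` (default
    22.1 µg/m³, the estimated 1981 US mean); years after its last year take
    ``backfill_after`` (default 8.0 µg/m³, the 2021 US mean).
    """

    series: pd.Series  # index: calendar year, values: µg/m³
    backfill_before: float = 22.1
    backfill_after: float = 8.0

    def __post_init__(self):
        s = self.series.astype(float).sort_index()
        if (s < 0).any() or self.backfill_before < 0 or self.backfill_after < 0:
            raise ValidationError("background PM2.5 values must be non-negative")
        object.__setattr__(self, "series", s)

    @classmethod
    def from_csv(cls, path, backfill_before: float = 22.1,
                 backfill_after: float = 8.0) -> "BackgroundSeries":
        df = pd.read_csv(path)
        if not {"year", "pm25"} <= set(df.columns):
            raise ValidationError("background CSV needs columns year,pm25")
        s = pd.Series(df["pm25"].values, index=df["year"].astype(int).values)
        return cls(s, backfill_before, backfill_after)

    def value_for(self, year: int) -> tuple[float, str]:
        """Return (pm25, source_flag) for a calendar year."""
        if len(self.series) == 0:
            return self.backfill_before, FLAG_BACKFILL
        if year < self.series.index[0]:
            return self.backfill_before, FLAG_BACKFILL
        if year > self.series.index[-1]:
            return self.backfill_after, FLAG_BACKFILL
        if year in self.series.index:
            return float(self.series.loc[year]), FLAG_BACKGROUND
        # interior gap: no defensible value — caller turns this into an error
        raise CoverageGapError([year])


@dataclass(frozen=True)
class ExposureSeries:
    """Per-life-year annual-mean PM2.5 from birth to the terminal age.

    ``values[a]`` is the concentration during life-year ``a`` (calendar year
    ``birth_year + a``); ``source_flags[a]`` records provenance.
    """

    birth_year: int
    values: np.ndarray
    source_flags: tuple[str, ...] = field(default=())

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise ValidationError("exposure values must be a non-empty 1-D array")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValidationError("exposure values must be finite and >= 0")
        object.__setattr__(self, "values", v)
        flags = tuple(self.source_flags) or (FLAG_BACKGROUND,) * len(v)
        if len(flags) != len(v):
            raise ValidationError("source_flags length must match values length")
        object.__setattr__(self, "source_flags", flags)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def terminal_age(self) -> int:
        return len(self.values) - 1

    def calendar_years(self) -> np.ndarray:
        return self.birth_year + np.arange(len(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": np.arange(len(self.values)),
                "year": self.calendar_years(),
                "pm25": self.values,
                "source": list(self.source_flags),
            }
        )


def build_lifetime_exposure(
    profile: AssignmentProfile,
    city_table: CityYearTable | None,
    background: BackgroundSeries,
    birth_year: int,
    terminal_age: int = 100,
) -> ExposureSeries:
    """Assemble the exposure series for one person.

    Posting years take city values via :func:`lookup_city_pm25`; every other
    life-year takes the background series, with the backfill constants
    covering years before/after it.  Interior gaps in the background series
    raise :class:`CoverageGapError` listing the uncovered years.
    """
    n = terminal_age + 1
    values = np.empty(n, dtype=float)
    flags: list[str] = [FLAG_BACKGROUND] * n

    posting_by_year: dict[int, Posting] = {}
    for p in profile.postings:
        for y in p.years():
            posting_by_year[y] = p

    gaps: list[int] = []
    for a in range(n):
        year = birth_year + a
        p = posting_by_year.get(year)
        if p is not None:
            if city_table is None:
                raise ValidationError(
                    f"profile {profile.label!r} has postings but no city table was given"
                )
            values[a] = lookup_city_pm25(city_table, p.city_id, year)
            flags[a] = FLAG_POSTING
        else:
            try:
                values[a], flags[a] = background.value_for(year)
            except CoverageGapError as e:
                gaps.extend(e.years)
                values[a] = np.nan
    if gaps:
        raise CoverageGapError(gaps)
    return ExposureSeries(birth_year=birth_year, values=values,
                          source_flags=tuple(flags))


def apply_mitigation(
    series: ExposureSeries,
    profile: AssignmentProfile,
    factor: float = 0.5,
) -> ExposureSeries:
    """Scale qualifying posting years by ``factor`` (default 0.5).

    A posting year qualifies when its posting's ``mitigation_eligible`` is
    true (explicit flag, or region tag ``africa_asia``).  Non-posting years
    and non-qualifying postings are untouched.  ``factor`` must lie in
    (0, 1]; ``factor == 1`` is the identity.
    """
    if not (0.0 < factor <= 1.0):
        raise ValidationError(f"mitigation factor must be in (0, 1], got {factor}")
    values = series.values.copy()
    flags = list(series.source_flags)
    for p in profile.postings:
        if not p.mitigation_eligible:
            continue
        for y in p.years():
            a = y - series.birth_year
            if 0 <= a < len(values):
                values[a] *= factor
                if factor < 1.0:
                    flags[a] = FLAG_MITIGATED
    return replace(series, values=values, source_flags=tuple(flags))
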