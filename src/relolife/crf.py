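"""Concentration–response curves for PM2.5-sensitive mortality.

Curves follow the GBD 2019 MR-BRT shape: a tabulated grid of relative risks
(central plus 95% CI bounds) versus long-term ambient PM2.5 concentration,
with a theoretical minimum-risk exposure level (TMREL) below which RR = 1.
Ischaemic heart disease and stroke carry separate curves per 5-year age
band from age 25 and contribute no added risk under 25; the remaining four
causes (COPD, lower respiratory infection, type-2 diabetes, lung cancer)
each have a single all-age curve.

Evaluation interpolates linearly in concentration between grid points and
clamps at the last grid RR beyond the grid (GBD curves flatten at high
exposure, so clamping is conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exposure import ExposureSeries

#: The six pollution-sensitive causes of death.
CAUSES = ("ihd", "stroke", "copd", "lri", "t2dm", "lung_cancer")

#: Causes whose curves vary by 5-year age band starting at 25.
AGE_SPECIFIC_CAUSES = ("ihd", "stroke")

#: Minimum age at which IHD/stroke curves contribute risk.
MIN_RISK_AGE = 25

BOUNDS = ("central", "lower", "upper")

#: 5-year age-band labels from 25; the open band 95+ covers ages 95–100.
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(25, 95, 5)) + ("95+",)


def band_for_age(age: int) -> str | None:
    """Age-band label for an attained age, or None below 25."""
    if age < MIN_RISK_AGE:
        return None
    if age >= 95:
        return "95+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


@dataclass(frozen=True)
class CRFCurve:
    """One tabulated concentration→RR relation.

    ``grid_conc`` is strictly increasing; ``rr_central/lower/upper`` are the
    RRs at those concentrations.  All RRs are >= 1 (grids dipping below 1
    are rejected, not clamped) and the central curve is non-decreasing.
    """

    cause: str
    tmrel: float
    grid_conc: np.ndarray
    rr_central: np.ndarray
    rr_lower: np.ndarray
    rr_upper: np.ndarray
    age_band: str | None = None

    def __post_init__(self):
        if self.cause not in CAUSES:
            raise ValidationError(f"unknown cause {self.cause!r}; expected one of {CAUSES}")
        conc = np.asarray(self.grid_conc, dtype=float)
        if conc.size == 0:
            raise ValidationError(f"{self._name()}: empty concentration grid")
        if np.any(np.diff(conc) <= 0):
            raise ValidationError(f"{self._name()}: grid concentrations must be strictly increasing")
        if self.tmrel < 0:
            raise ValidationError(f"{self._name()}: tmrel must be >= 0")
        arrays = {}
        for bound in BOUNDS:
            arr = np.asarray(getattr(self, f"rr_{bound}"), dtype=float)
            if arr.shape != conc.shape:
                raise ValidationError(f"{self._name()}: rr_{bound} length mismatch with grid")
            if np.any(arr < 1.0):
                raise ValidationError(
                    f"{self._name()}: rr_{bound} dips below 1 — curves must satisfy RR >= 1"
                )
            arrays[bound] = arr
        if np.any(arrays["lower"] > arrays["central"]) or np.any(
            arrays["central"] > arrays["upper"]
        ):
            raise ValidationError(f"{self._name()}: CI bound ordering lower <= central <= upper violated")
        if np.any(np.diff(arrays["central"]) < 0):
            raise ValidationError(f"{self._name()}: central curve must be non-decreasing")
        object.__setattr__(self, "grid_conc", conc)
        for bound in BOUNDS:
            object.__setattr__(self, f"rr_{bound}", arrays[bound])
        if self.cause in AGE_SPECIFIC_CAUSES and self.age_band is None:
            raise ValidationError(f"{self.cause}: age_band is required for age-specific causes")

    def _name(self) -> str:
        return f"{self.cause}[{self.age_band}]" if self.age_band else self.cause


def rr_at(curve: CRFCurve, concentration, bound: str = "central"):
    """Relative risk at a concentration (scalar or array).

    RR = 1 at or below the TMREL; linear interpolation on the grid;
    constant extrapolation beyond the last grid point.  The result is
    always >= 1.
    """
    if bound not in BOUNDS:
        raise ValidationError(f"bound must be one of {BOUNDS}, got {bound!r}")
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    grid = curve.grid_conc
    rr = getattr(curve, f"rr_{bound}")
    if grid[0] > curve.tmrel:
        # anchor the curve at (tmrel, 1) so interpolation starts from no risk
        grid = np.concatenate(([curve.tmrel], grid))
        rr = np.concatenate(([1.0], rr))
    out = np.interp(c, grid, rr)  # np.interp clamps at both ends
    out = np.where(c <= curve.tmrel, 1.0, out)
    out = np.maximum(out, 1.0)
    return float(out) if np.isscalar(concentration) else out


class CRFSet:
    """Curves keyed by (cause, age_band).

    IHD and stroke must cover every age band for ages 25–100; the other
    four causes carry exactly one curve each (``age_band`` None).
    """

    def __init__(self, curves):
        self._curves: dict[tuple[str, str | None], CRFCurve] = {}
        for c in curves:
            key = (c.cause, c.age_band)
            if key in self._curves:
                raise ValidationError(f"duplicate curve for {key}")
            self._curves[key] = c
        for cause in CAUSES:
            if cause in AGE_SPECIFIC_CAUSES:
                missing = [b for b in AGE_BANDS if (cause, b) not in self._curves]
                if missing:
                    raise ValidationError(
                        f"{cause}: missing curves for age bands {missing}"
                    )
            else:
                if (cause, None) not in self._curves:
                    raise ValidationError(f"missing curve for cause {cause!r}")

    def curve(self, cause: str, age: int | None = None) -> CRFCurve:
        """Curve for a cause and (for IHD/stroke) an attained age."""
        if cause in AGE_SPECIFIC_CAUSES:
            if age is None:
                raise ValidationError(f"{cause}: attained age required for age-specific cause")
            band = band_for_age(age)
            if band is None:
                raise ValidationError(f"{cause}: no curve below age {MIN_RISK_AGE}")
            try:
                return self._curves[(cause, band)]
            except KeyError:
                raise ValidationError(f"{cause}: no curve for age band {band!r}") from None
        return self._curves[(cause, None)]

    def __iter__(self):
        return iter(self._curves.values())

    def __len__(self) -> int:
        return len(self._curves)

    @classmethod
    def from_csv(cls, path) -> "CRFSet":
        """Read the long-format curve table.

        Header: ``cause,age_band,tmrel,concentration,rr,rr_lower,rr_upper``
        with ``age_band`` empty for the non-age-specific causes.
        """
        df = pd.read_csv(path)
        required = {"cause", "age_band", "tmrel", "concentration", "rr", "rr_lower", "rr_upper"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"CRF table missing columns: {sorted(missing)}")
        curves = []
        df["age_band"] = df["age_band"].where(df["age_band"].notna(), None)
        for (cause, band), g in df.groupby(["cause", "age_band"], dropna=False, sort=False):
            band = None if (band is None or (isinstance(band, float) and np.isnan(band))) else str(band)
            g = g.sort_values("concentration")
            tmrel = float(g["tmrel"].iloc[0])
            curves.append(
                CRFCurve(
                    cause=str(cause),
                    age_band=band,
                    tmrel=tmrel,
                    grid_conc=g["concentration"].to_numpy(float),
                    rr_central=g["rr"].to_numpy(float),
                    rr_lower=g["rr_lower"].to_numpy(float),
                    rr_upper=g["rr_upper"].to_numpy(float),
                )
            )
        return cls(curves)

    def to_csv(self, path) -> None:
        rows = []
        for c in self._curves.values():
            for i, conc in enumerate(c.grid_conc):
                rows.append(
                    {
                        "cause": c.cause,
                        "age_band": c.age_band or "",
                        "tmrel": c.tmrel,
                        "concentration": conc,
                        "rr": c.rr_central[i],
                        "rr_lower": c.rr_lower[i],
                        "rr_upper": c.rr_upper[i],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def rr_profile(crfs: CRFSet, series: ExposureSeries, bound: str = "central") -> pd.DataFrame:
    """Per-life-year, per-cause unlagged RR for an exposure series.

    Returns a DataFrame indexed by age 0..terminal with one column per
    cause.  IHD and stroke use the curve for the person's attained-age band
    in each year and return 1.0 below age 25.
    """
    n = len(series)
    ages = np.arange(n)
    out = pd.DataFrame(index=pd.Index(ages, name="age"), columns=list(CAUSES), dtype=float)
    for cause in CAUSES:
        if cause in AGE_SPECIFIC_CAUSES:
            col = np.ones(n)
            for a in ages:
                if a >= MIN_RISK_AGE:
                    col[a] = rr_at(crfs.curve(cause, age=int(a)), float(series.values[a]), bound)
            out[cause] = col
        else:
            out[cause] = rr_at(crfs.curve(cause), series.values, bound)
    return out
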