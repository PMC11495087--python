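"""Inception and cessation lags between exposure change and risk change.

When ambient PM2.5 rises, the associated excess mortality risk does not
appear at once; when it falls, the accrued excess does not vanish at once.
The central schedules here are the US EPA 20-year biphasic cessation lag —
70% of the risk difference retained in the first year after the change,
declining 12.5%/year through year 5 to 20%, then the remaining 20% spread
evenly over years 6–20 (0.20/15 ≈ 1.33%/year, reaching exactly 0 at year
20) — and an inception lag defined as its exact complement (30% applied in
year 1, full risk from year 20).

A lag episode is triggered whenever the annual mean changes by at least
5 µg/m³ year-over-year.  During an upward episode (old RR_A, new RR_B) the
effective relative risk in lag year τ is

    RR_A · (1 + w_inc(τ) · (RR_B / RR_A − 1))

and during a downward episode

    RR_B · (1 + w_ces(τ) · (RR_A / RR_B − 1)).

If a new qualifying change occurs while an episode is still evolving, the
remaining portion of the active episode is removed: the episode terminates
at its current effective RR and a fresh episode starts from that value.
Sub-threshold changes take effect immediately, without a lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default exposure-change trigger (µg/m³, year-over-year annual mean).
DEFAULT_THRESHOLD = 5.0

SCHEDULE_NAMES = ("epa", "short8", "triphasic38", "none")


@dataclass(frozen=True)
class LagSchedule:
    """Fraction-of-effect weights over lag years.

    ``weights[τ-1]`` is the weight in lag year τ (1-based).  For a
    cessation schedule it is the fraction of the risk difference still
    retained (non-increasing, ending at 0); for an inception schedule the
    fraction already applied (non-decreasing, ending at 1).  Beyond the
    schedule length the terminal weight holds.
    """

    kind: str  # "inception" | "cessation"
    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        if self.kind not in ("inception", "cessation"):
            raise ValidationError(f"lag kind must be inception|cessation, got {self.kind!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("lag weights must be a non-empty 1-D array")
        if np.any(w < 0) or np.any(w > 1):
            raise ValidationError("lag weights must lie in [0, 1]")
        if self.kind == "cessation":
            if np.any(np.diff(w) > 1e-12) or abs(w[-1]) > 1e-12:
                raise ValidationError("cessation weights must be non-increasing and end at 0")
        else:
            if np.any(np.diff(w) < -1e-12) or abs(w[-1] - 1.0) > 1e-12:
                raise ValidationError("inception weights must be non-decreasing and end at 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def weight(self, lag_year: int) -> float:
        """Weight in 1-based lag year; the terminal weight holds beyond."""
        if lag_year < 1:
            raise ValidationError(f"lag year must be >= 1, got {lag_year}")
        idx = min(lag_year, len(self.weights)) - 1
        return float(self.weights[idx])

    @property
    def terminal_weight(self) -> float:
        return float(self.weights[-1])

    def complement(self) -> "LagSchedule":
        other = "inception" if self.kind == "cessation" else "cessation"
        return LagSchedule(kind=other, weights=1.0 - self.weights, name=self.name)

    def to_frame(self) -> pd.DataFrame:
        """Serializable (lag_year, weight) table for audit."""
        return pd.DataFrame(
            {"lag_year": np.arange(1, len(self.weights) + 1), "weight": self.weights}
        )


def epa_cessation_weights() -> LagSchedule:
    """The EPA 20-year biphasic cessation lag.

    Year 1 retains 0.70 of the risk difference; years 2–5 decline by
    0.125/year to 0.20; years 6–20 decline by 0.20/15 per year, reaching
    exactly 0 at year 20.
    """
    w = np.empty(20)
    w[0] = 0.70
    for t in range(2, 6):          # years 2..5
        w[t - 1] = 0.70 - 0.125 * (t - 1)
    for t in range(6, 21):         # years 6..20
        w[t - 1] = 0.20 - (0.20 / 15.0) * (t - 5)
    w[19] = 0.0                    # exact endpoint despite float accumulation
    return LagSchedule(kind="cessation", weights=w, name="epa")


def epa_inception_weights() -> LagSchedule:
    """The 20-year inception lag: exact complement of the EPA cessation lag.

    0.30 of the risk is applied in year 1; the full risk from year 20.
    """
    return epa_cessation_weights().complement()


#: Geometric retention ratio for the steep 8-year schedule (first-year
#: retention 0.5; <= 10% of the effect remains by year 5).
_SHORT8_RATIO = 0.5

#: (lag_year, retained fraction) anchors of the 38-year triphasic schedule.
#: Interior values are this package's choice; only the 38-year span, the
#: three-segment piecewise-linear form and the 0 endpoint are pinned.
_TRIPHASIC38_ANCHORS = ((1, 0.85), (5, 0.45), (20, 0.25), (38, 0.0))


def alt_lag_weights(name: str, kind: str = "cessation") -> LagSchedule:
    """Alternative lag schedules used in the sensitivity analysis.

    ``short8``      — steep 8-year geometric decline (most of the effect
                      resolves within 5 years; 0 at year 8), motivated by
                      all-cause mortality cohort evidence.
    ``triphasic38`` — 38-year three-segment piecewise-linear decline
                      motivated by smoking-cessation/lung-cancer studies.
    ``none``        — length-1 schedule: the full effect applies
                      immediately (no lag).
    ``epa``         — the central 20-year biphasic schedule.

    ``kind`` selects the cessation form or its inception complement.
    """
    if name == "epa":
        ces = epa_cessation_weights()
    elif name == "short8":
        w = _SHORT8_RATIO ** np.arange(1, 9, dtype=float)
        w[-1] = 0.0
        ces = LagSchedule(kind="cessation", weights=w, name="short8")
    elif name == "triphasic38":
        yrs, vals = zip(*_TRIPHASIC38_ANCHORS)
        w = np.interp(np.arange(1, 39), yrs, vals)
        ces = LagSchedule(kind="cessation", weights=w, name="triphasic38")
    elif name == "none":
        ces = LagSchedule(kind="cessation", weights=np.array([0.0]), name="none")
    else:
        raise ValidationError(f"unknown lag schedule {name!r}; expected one of {SCHEDULE_NAMES}")
    if kind == "cessation":
        return ces
    if kind == "inception":
        return ces.complement()
    raise ValidationError(f"lag kind must be inception|cessation, got {kind!r}")


class Transition(NamedTuple):
    """A qualifying year-over-year exposure change."""

    year_index: int   # life-year index at which the new level starts
    direction: str    # "up" | "down"
    delta: float      # signed change in µg/m³


def detect_transitions(values, threshold: float = DEFAULT_THRESHOLD) -> list[Transition]:
    """Qualifying transitions in an annual exposure series.

    A transition is emitted for every year whose annual mean differs from
    the previous year's by at least ``threshold`` (absolute).  Accepts an
    :class:`~relolife.exposure.ExposureSeries` or a plain array.
    """
    v = np.asarray(getattr(values, "values", values), dtype=float)
    out = []
    for t in range(1, len(v)):
        d = v[t] - v[t - 1]
        if abs(d) >= threshold:
            out.append(Transition(t, "up" if d > 0 else "down", float(d)))
    return out


class LagEpisode(NamedTuple):
    """Bookkeeping record of one lag episode (for the audit log)."""

    start_index: int
    direction: str
    delta: float
    from_rr: float
    schedule: str


def apply_lags(
    unlagged,
    exposure_values,
    inception: LagSchedule,
    cessation: LagSchedule,
    threshold: float = DEFAULT_THRESHOLD,
    lag_start_index: int = 0,
    return_episodes: bool = False,
):
    """Convert an unlagged RR series into a lagged one.

    ``unlagged`` may be a 1-D array (one cause) or a DataFrame with one
    column per cause (the same schedule pair applied to each).  Before
    ``lag_start_index`` (life-year index of the start of the assignment) no
    lags apply and the lagged series equals the unlagged one.

    During an episode the target RR is re-evaluated every year from the
    unlagged series, so age-band transitions of the IHD/stroke curves and
    sub-threshold exposure drift are tracked within the episode.
    """
    if inception.kind != "inception" or cessation.kind != "cessation":
        raise ValidationError("schedule kinds must be (inception, cessation)")
    if isinstance(unlagged, pd.DataFrame):
        lagged = unlagged.copy()
        episodes: dict[str, list[LagEpisode]] = {}
        for col in unlagged.columns:
            res = apply_lags(
                unlagged[col].to_numpy(float), exposure_values, inception,
                cessation, threshold, lag_start_index, return_episodes=True,
            )
            lagged[col], episodes[col] = res
        return (lagged, episodes) if return_episodes else lagged

    rr = np.asarray(unlagged, dtype=float)
    pm = np.asarray(getattr(exposure_values, "values", exposure_values), dtype=float)
    if rr.shape != pm.shape:
        raise ValidationError(
            f"unlagged RR series (len {rr.size}) must align with exposure series (len {pm.size})"
        )
    n = rr.size
    out = np.empty(n)
    episode: list | None = None  # [from_rr, direction, tau]
    log: list[LagEpisode] = []
    for t in range(n):
        if t < lag_start_index or t == 0:
            out[t] = rr[t]
            continue
        d = pm[t] - pm[t - 1]
        if abs(d) >= threshold:
            # terminate any active episode at its current effective RR and
            # start a new one from there ("remaining portion removed")
            from_rr = out[t - 1]
            direction = "up" if d > 0 else "down"
            episode = [from_rr, direction, 1]
            sched = inception if direction == "up" else cessation
            log.append(LagEpisode(t, direction, float(d), float(from_rr), sched.name))
        if episode is None:
            out[t] = rr[t]
            continue
        from_rr, direction, tau = episode
        target = rr[t]
        if direction == "up":
            w = inception.weight(tau)
            # w == 1 means the full risk applies: return the target exactly
            out[t] = target if w == 1.0 else from_rr * (1.0 + w * (target / from_rr - 1.0))
            done = tau >= len(inception)
        else:
            w = cessation.weight(tau)
            out[t] = target if w == 0.0 else target * (1.0 + w * (from_rr / target - 1.0))
            done = tau >= len(cessation)
        if done:
            episode = None
        else:
            episode[2] = tau + 1
    return (out, log) if return_episodes else out
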