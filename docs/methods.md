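# Methods

## Model structure

The pipeline has four stages, each a module with a validated interface:

1. **exposure** — a lifetime annual-mean PM2.5 series.  Life-year *a* maps
   to calendar year `birth_year + a` and takes a single annual value:
   the posting city's annual mean during assignments (WHO-style city-year
   table, nearest-year fallback with equidistant ties resolved to the
   earlier year), otherwise the home-country background series, and
   outside that series two backfill constants (22.1 µg/m³ before its first
   year, 8.0 µg/m³ after its last — the historical and recent US annual
   means; both configurable).  An indoor-mitigation transform multiplies
   qualifying posting years by a factor (default 0.5, from measured
   personal/ambient exposure ratios with residential filtration);
   eligibility is per posting, derived from an `africa_asia` region tag
   and overridable posting-by-posting.

2. **crf** — tabulated concentration–response curves per cause with
   central/lower/upper RR columns and a TMREL.  Evaluation is linear in
   concentration between grid points, anchored at (TMREL, 1), with
   constant extrapolation beyond the last point (GBD curves flatten at
   high exposure, so clamping is conservative).  Grids whose RR dips below
   1 are rejected rather than silently clamped.  IHD and stroke use the
   person's attained-age 5-year band each year (bands 25–29 … 90–94, an
   open 95+ band covering 95–100) and contribute RR = 1 below 25.  Curves
   are not sex-specific; sex enters through baseline mortality.

3. **lags** — the EPA biphasic 20-year cessation schedule and its exact
   complement as the inception schedule.  The long-phase decrement is
   implemented as exactly 0.20/15 per year (≈ 1.333 %/yr, usually quoted
   rounded as 1.3 %) so the schedule reaches 0 exactly at year 20.
   Episodes are triggered by any year-over-year change of the assigned
   annual series ≥ 5 µg/m³ — not only at relocations, since the trigger is
   defined on the ambient mean.  The composition rule pins the effective
   RR path to `origin RR × (1 + w(τ)·excess)` where the excess is
   `RR_new/RR_origin − 1` (upward) or `RR_origin/RR_new − 1` (downward);
   this reproduces the published first-year fractions (30 % of an upward
   step, 70 % retention of a downward step) and both endpoints.  On any
   new qualifying transition — opposite- or same-direction — the active
   episode terminates at its current effective RR and a new episode starts
   from that value ("the remaining portion of the lag is removed"); this
   is deterministic, avoids double counting, and keeps the effective RR
   bounded by the bracketing unlagged RRs.  During an episode the target
   RR is re-read from the unlagged series every year, so IHD/stroke
   age-band changes mid-episode are tracked.  No lags apply before the
   assignment window opens; the cessation at the end of the assignment
   falls out of the return-home exposure step.  At terminal weights
   (w = 1 up, w = 0 down) the code returns the target RR directly so the
   no-lag schedule is a strict floating-point identity.

4. **lifetable** — iMR_c(a) = RR_c(a)·MR_c(a); the non-pollution-sensitive
   remainder (all-cause minus the six cause rates) is added back.  Rates
   exceeding 1 after multiplication are capped with a logged warning
   (possible only under extreme synthetic inputs).  Survival uses the
   mid-year deaths convention p = (2 − m)/(2 + m), valid for m ∈ [0, 2).
   The cohort is projected over 100 one-year intervals (ages 0–99) and
   closed at exact age 100: remaining survivors are assigned to the
   closing interval with no further life-years, so a zero-mortality
   cohort has a horizon-truncated life expectancy of exactly 100 years,
   and the age-100 row of a mortality schedule does not influence the
   projection.  Deaths per million are cohort-weighted,
   deaths(a) = 10⁶·l(a)·q(a); the literal alternative (rate × 10⁶ summed
   without survivor weighting) does not conserve the cohort and was
   rejected.  The within-horizon total excludes the closure so that a
   harsher schedule, which shifts deaths into the horizon, yields positive
   excess deaths; closure is computed as the cohort remainder
   (10⁶ − Σ deaths), making conservation exact in floating point.
   DLL converts life-expectancy differences at 365.25 days/year
   (configurable; the source is silent on the convention).

## Scenario conventions

The reference arm ("lived exclusively at home") uses the same backfilled
background series, the same lag machinery and the same assignment-window
lag start as the scenario arm, so pre-window risk histories cancel; the
declining home series never moves ≥ 5 µg/m³ in a year, so the reference is
lag-free in practice.  The three person archetypes are an older diplomat
(born 1955, posted ages 45–64), a young diplomat (born 1975, posted 25–44)
and an accompanying child (born 2000, ages 0–19); all windows cover the
modelled years 2000–2019 (the 40-year double assignment runs to 2039).

## Tunable parameters

| parameter | default | units | note |
|---|---|---|---|
| lag threshold | 5 | µg/m³ | year-over-year trigger |
| inception / cessation schedule | `epa` | — | `short8`, `triphasic38`, `none` available, per-cause overridable |
| C-R bound | `central` | — | `lower` / `upper` for CI variations |
| mitigation factor | 0.5 | — | multiplies qualifying posting years; (0, 1] |
| backfill before / after | 22.1 / 8.0 | µg/m³ | outside the background series |
| horizon | 100 | years | life-table closure age |
| days per year | 365.25 | d/yr | DLL conversion |

The alternative lag shapes are published only as figures; here `short8` is
a geometric cessation decline (ratio 0.5 per year, ≤ 10 % of the effect
left by year 5, forced to 0 at year 8) and `triphasic38` a three-segment
piecewise-linear decline through (1, 0.85)–(5, 0.45)–(20, 0.25)–(38, 0).
Their interior values are this package's choices and should not be read as
the published curves; only the spans, monotonicity and endpoints are
pinned.

## The synthetic world

The generator emulates the *structure* of the real inputs, not their
values:

* **Mortality** — Gompertz–Makeham all-cause hazard
  `min(1, C + A·e^{B·a})` with C = 2·10⁻⁴, A = 3·10⁻⁵, B = 0.09
  (≈ 2.6·10⁻⁴ at birth, ≈ 0.25 at age 100); the six causes are fixed
  fractions of all-cause (IHD 0.12, stroke 0.06, COPD 0.05, LRI 0.02,
  T2DM 0.03, lung cancer 0.04 — roughly US-like shares summing to 0.32).
  Females are scaled by 0.8, giving the smaller female impacts seen in
  sex-stratified results.
* **Curves** — log-linear `exp(β·(C − TMREL)₊)` by default (TMREL
  5 µg/m³; β per cause in the 1.2–3·10⁻³ /(µg/m³) range, sized so ~50
  µg/m³ of excess gives RRs of 1.1–1.2, the order of the GBD curves), or a
  saturating-exponential family.  CI bounds are central × (1 ∓ 0.3)
  floored at 1 — with RRs this close to 1 the lower bound floors to 1
  everywhere, so the lower-CI sensitivity variation collapses to zero
  burden; that is a property of the stated synthetic world, not a bug.
  IHD/stroke slopes attenuate by 0.95 per 5-year band step (older bands
  flatter, as in the GBD fits).
* **Exposure** — cities at representative band values (home 9, low 12,
  moderate 27, high 50 ± small fixed offsets, very high 70 µg/m³) and a
  home background declining linearly 22.1 → 8.0 over 1981–2021.  Optional
  seeded jitter (default 0) can perturb levels within their bands.  The
  ten assignment fixtures reproduce the published temporal *patterns*
  (three-peak standard careers, k-high/(4−k)-low cycles, constant
  very-high, mitigated variant), not the unpublished city itineraries.

A green test therefore establishes that the machinery — lookup, curves,
lag algebra, life table, orchestration — is correct and that the published
*orderings* (more polluted years cost more; older > young > child;
mitigation helps; upper ≥ central ≥ lower CI; inception-lag removal raises
and cessation-lag removal lowers the burden) emerge from the model.  It
does **not** establish the published absolute burdens (e.g. 80.4 DLL for
the standard older-male assignment), which require the external GBD 2019
curves, national 2019 mortality tables and WHO city data; supplying those
as CSVs through the documented resource interface is the intended path to
absolute reproduction.

## Numerical choices and degenerate inputs

* Nearest-year city lookup breaks equidistant ties toward the earlier year
  (no rule is published); substitutions are logged.
* Interior gaps in the background series are an error listing the missing
  years — silent interpolation of exposure is never performed.
* `survival_probability` rejects m ≥ 2 (formula pole) and m < 0; the m → 2
  limit of 0 is asserted in tests, not accepted as input.
* Cohort conservation is exact by defining the closure as the remainder;
  per-age deaths agree with the brute-force loop to 1e-9 relative, with an
  absolute floor of 10⁻⁶ persons/million on the closure comparison where
  an essentially extinct cohort suffers catastrophic cancellation.
* All generators are seeded (`SynthParams.seed`) with per-component
  streams derived via crc32 of the component name, so artifacts
  regenerate identically across runs and platforms.

## Known limitations

Annual resolution only; no sub-annual exposure, personal-activity
modelling or indoor-air physics beyond the scalar mitigation factor.  No
morbidity outcomes, no abridged life tables, no period-to-cohort mortality
projection, and no uncertainty propagation beyond the CI-bound curve
variations.  The lag bookkeeping keeps at most one active episode per
cause; simultaneous partially-overlapping exposures (e.g. split years) are
out of scope.
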