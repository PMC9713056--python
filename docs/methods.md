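# Methods

## Model

The package computes, per facility and per health-worker cadre, the
workload-based staffing requirement

```
required_raw = CAF · Σ_i AW_i / SW_i + IAF
```

where `AW_i` is the annual client count for core activity `i`, `SW_i` the
standard workload (clients one worker can serve in a year), `CAF` the
category allowance factor for support work and `IAF` the staff-equivalents
of individual (additional) work. The model assumes: activity standards are
common to every facility in scope; every member of a cadre performs all core
and support activities; service statistics count each client contact once
under exactly one core activity; and staff availability is binary (no
part-time, shift, or within-day scheduling effects). Requirements are
computed per (facility, cadre) independently — statistics are not shared or
smoothed across facilities, and when two cadres are assessed against the
same statistics each cadre's requirement answers "how many workers of this
cadre would cope with this workload alone".

## Available working time

`AWT_days = A − (B + C + D + E)`. The subtraction applies to *all four*
absence components; a rendering of this identity that reads as
`A − B + C + D + E` contradicts the definitions of C, D and E as days off
and is not what any WISN computation uses. The invariant
`B + C + D + E ≤ A` is enforced at construction with the cadre named in the
error. `AWT_hours = AWT_days × hours_per_working_day`.

Defaults (all overridable in the AWT YAML/JSON): `hours_per_working_day = 8`,
the standard Nigerian public-service day. The synthetic generator's default
absence calendar is `A = 260` (52 five-day weeks), 12 public holidays,
30 days official leave, 7 days sick leave, 12 days other absence — a
conventional public-service year yielding 199 days / 1 592 hours; the real
study's approved calendar was never published, so these values are chosen
once as realistic rather than calibrated.

## Annualization conventions

Support and individual standards arrive in mixed units (minutes or hours per
day, week or month). They are converted to hours/year against the available
working year:

| unit        | annual hours                                 |
|-------------|----------------------------------------------|
| per day     | `value × AWT_days` (÷60 if minutes)          |
| per week    | `value × AWT_days / 5` (5-day working week)  |
| per month   | `value × 12`, independent of absences        |

Weekly standards scale with actually-available weeks because allowances are
expressed against time actually worked; monthly obligations (reports,
review meetings) fall due regardless of who was on leave. Both constants
(`working_days_per_week`, `months_per_year`) are keyword-overridable on the
annualization and allowance functions. A zero time value means "activity not
performed by this cadre": it annualizes to zero and, for core activities,
produces no standard workload rather than an infinite one.

## Rounding and classification

All intermediate quantities are kept at full floating precision; rounding
happens exactly twice. The final requirement is rounded **half-up** to whole
staff (5.5 → 6, 10.49 → 10), with an always-ceil mode available; half-up is
the choice consistent with every consistency check the packaged results
table allows. The WISN ratio is `available ÷ rounded required`, rounded
half-up to two decimals — the packaged table's printed 1/8 → 0.13 and
1/6 → 0.17 pin down both the denominator and the rounding rule. Pressure is
classified on the rounded ratio with exact comparison to 1, so a printed
1.00 is "balanced". A zero requirement makes the ratio undefined; such
results carry a sentinel (`ratio=None`, `pressure=undefined`) and are
excluded from ratio-based counts instead of being reported as infinite.
Aggregate coverage is `100 × available ÷ required` rounded to the nearest
integer (9/54 → 17).

Activity names are matched between standards and statistics after
whitespace-trimming and case-folding only; a statistic naming an unknown
activity is a hard error listing every offending name, because silently
dropping workload would bias requirements downward.

## Redistribution helper

`redistribute_surplus` is deliberately simple plumbing: staff move one at a
time from the facility with the largest current surplus to the facility with
the largest current absolute shortage, ties broken alphabetically, stopping
when surplus or shortage is exhausted. It conserves headcount, never moves a
donor below its requirement and never overfills a recipient. It carries no
cost, distance or equity weighting and makes no optimality claim.

## Synthetic data

The generator emulates the inputs a WISN study collects but rarely
publishes: per-cadre absence calendars, activity standards, annual facility
registers and rosters. Core unit times are drawn uniformly on 7–60
minutes/client (the observed range of the packaged standards table); support
load targets a uniform share of working time in 15–30 % split across
activities by a Dirichlet draw; individual load totals 100–400 hours/year;
annual counts per core activity are negative-binomial with mean
`utilization_scale` (default 2 500 clients/activity/facility, placing
facility requirements in the single to low-double digits as in the packaged
study) and variance `μ + α·μ²` with `α = overdispersion` (default 0.3;
`α = 0` degenerates to Poisson). Registers are overdispersed in reality —
catchment size, outreach campaigns and stock-outs differ between facilities —
which is why the dispersion is a parameter rather than an assumption. A
single seed governs everything; each facility draws from a substream keyed
by a stable hash of its name, so adding a facility never perturbs the
others' draws.

What the generator does **not** emulate: seasonality, epidemic shocks,
referral patterns, reporting gaps or digitization errors in real registers,
or correlation of workload across activities. Passing tests on synthetic
scenarios therefore demonstrate the correctness of the computation, not the
realism of any particular staffing figure.

The inverse generator (`generate_with_target`) plants a whole-staff
requirement per facility for one cadre: it solves the core term
`(target − IAF) / CAF`, spreads it across core activities in equal
requirement shares (counts proportional to `SW_i`), and rounds counts to
integers — a perturbation of at most `0.5/SW_i` per activity, orders of
magnitude below the 0.5 staff that would move the rounded result, which is
why recovery is exact. Targets are planted for a single cadre because
statistics are shared per facility: two cadres with independently planted
targets against the same counts would be mutually inconsistent. A target
below IAF is infeasible (even zero clients would require more staff) and is
rejected.

## Numerical and design notes

- Half-up rounding goes through `Decimal(repr(x))`, applying the rule to the
  number as printed and avoiding binary artifacts (2.675 → 2.68, not 2.67).
- IAF is computed from the cadre-level total of individual-activity hours,
  not apportioned to the subset of individuals actually performing each
  activity; the fuller apportionment found in some WISN manuals is out of
  scope and would only lower IAF.
- `CAS ≥ 100 %` (support work alone exceeding available time) and a positive
  client count without a usable standard workload are hard errors, not
  warnings.
- The pipeline consumes no randomness; the run manifest hashes inputs,
  configuration, package version and outputs (not the timestamp), so rerun
  equality is checkable by hash.
- Tests exercise scenarios of ≤ 100 facilities and 100 planted targets,
  sizes at which every property checked is already at full strength; the
  whole suite and the acceptance script each run in well under a minute.

## Known limitations

- End-to-end reproduction of the packaged study's per-facility requirements
  is impossible from published data alone (its service statistics and
  absence calendar are unpublished); the requirement equations are instead
  verified by construction (planted-target recovery and equivalence with a
  fused single-expression recomputation), and the metrics/aggregation layer
  is verified cell-by-cell against the published table.
- No uncertainty quantification: requirements are point values, as in the
  method itself.
- No task-shifting or multi-cadre substitution modelling; each cadre is
  assessed independently.
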