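# wisn

Workload-based staffing requirements for health facilities, implementing the
WHO **Workload Indicators of Staffing Need (WISN)** method. The package is
aimed at health-workforce planners and health-systems researchers who need a
tested, scriptable alternative to the spreadsheet calculations WISN studies
are usually run in: it computes how many workers of a cadre (e.g.
Nurse/Midwife, Community Health Worker) each facility needs to cope with its
documented workload, and turns the gap between available and required staff
into the difference and work-pressure ratio used for redistribution
decisions.

## The method

For one cadre at one facility:

1. **Available working time.** With `A` possible working days per year and
   `B, C, D, E` days off (public holidays, official leave, sick leave, other
   absences), `AWT_days = A − (B + C + D + E)` and
   `AWT_hours = AWT_days × hours_per_working_day`.
2. **Standard workloads.** For each core (clinical) activity with an
   expert-validated unit time `t_i` minutes per client, one worker can serve
   `SW_i = AWT_hours × 60 / t_i` clients per year.
3. **Core requirement.** With annual service statistics `AW_i`,
   the clinical staffing need is `Σ_i AW_i / SW_i`.
4. **Allowances.** Support activities (done by all cadre members, no routine
   statistics) absorb `CAS` percent of working time, giving the category
   allowance factor `CAF = 100 / (100 − CAS)`. Individual (additional)
   activities, done by only some members, total `IAS` hours/year and add
   `IAF = IAS / AWT_hours` staff-equivalents.
5. **Total requirement.** `required = CAF × Σ_i AW_i / SW_i + IAF`, rounded
   half-up to whole staff.
6. **Metrics.** `difference = available − required` (negative = shortage) and
   the WISN ratio `available / required` (reported at 2 decimals; < 1 means
   the cadre is under work pressure, > 1 means surplus).

Support and individual standards timed per day/week/month are annualized
against the available working year: daily values recur every available
working day, weekly values every available 5-day working week, and monthly
values twelve times a year. See `docs/methods.md` for conventions, defaults
and limitations.

The package ships two reference tables from a published WISN study of ten
primary health care facilities (Kaduna North LGA, Nigeria): the
expert-validated activity standards (26 activities for two cadres) and the
per-facility staffing results, used throughout the test suite.

## Worked example

```python
from wisn import (
    ActivityStandard, AWTComponents, Category, ServiceStatistics, StaffingRecord,
    TimeUnit, compute_awt, compute_requirement, compute_wisn_result,
)

awt = compute_awt(AWTComponents(
    cadre="Nurse/Midwife", possible_working_days=260, public_holidays=12,
    official_leave=30, sick_leave=7, other_absence=12, hours_per_working_day=8,
))
print(f"AWT: {awt.awt_days:.0f} days, {awt.awt_hours:.0f} hours")

standards = [
    ActivityStandard(cadre="Nurse/Midwife", activity="Antenatal care",
                     category=Category.CORE, time_value=10,
                     time_unit=TimeUnit.MINUTES_PER_CLIENT),
    ActivityStandard(cadre="Nurse/Midwife", activity="Delivery",
                     category=Category.CORE, time_value=60,
                     time_unit=TimeUnit.MINUTES_PER_CLIENT),
    ActivityStandard(cadre="Nurse/Midwife", activity="Documentation on patients",
                     category=Category.SUPPORT, time_value=30,
                     time_unit=TimeUnit.MINUTES_PER_DAY),
    ActivityStandard(cadre="Nurse/Midwife", activity="General administration",
                     category=Category.INDIVIDUAL, time_value=50,
                     time_unit=TimeUnit.MINUTES_PER_DAY),
]
stats = ServiceStatistics(facility="PHC Example", year=2019,
                          counts={"Antenatal care": 6000, "Delivery": 900})
req = compute_requirement(stats, standards, awt)
print(f"core={req.core_requirement:.3f}  CAS={req.total_cas:.2f}%  CAF={req.caf:.4f}  "
      f"IAF={req.iaf:.4f}  raw={req.required_raw:.3f}  required={req.required}")

result = compute_wisn_result(StaffingRecord(facility="PHC Example",
                                            cadre="Nurse/Midwife", available=1), req)
print(f"difference={result.difference}  ratio={result.ratio:.2f}  pressure={result.pressure.value}")
```

prints

```
AWT: 199 days, 1592 hours
core=1.193  CAS=6.25%  CAF=1.0667  IAF=0.1042  raw=1.377  required=1
difference=0  ratio=1.00  pressure=balanced
```

Reading: after absences this nurse/midwife works 1 592 hours a year. The
6 000 antenatal and 900 delivery clients need 1.193 full-time workers of
clinical time; daily documentation absorbs 6.25 % of every member's time
(inflating by ×1.0667) and administration adds 0.104 staff-equivalents, for
a raw requirement of 1.377 — one whole staff member. With one nurse on the
roster the facility is balanced (ratio 1.00).

## Command line

```bash
wisn simulate --out scenario/ --seed 11        # synthetic inputs (4 files)
wisn compute  --standards scenario/activity_standards.csv \
              --statistics scenario/service_statistics.csv \
              --staffing scenario/staffing.csv \
              --awt scenario/awt.yaml --out results/
wisn report   --standards ... --statistics ... --staffing ... --awt ...
wisn redistribute --results results/report.csv --cadre CHW
```

`compute` writes `requirements.csv`, `report.csv`, a human-readable
`report.txt` and a `manifest.json` whose hash is identical across reruns on
identical inputs. Validation failures exit with status 2 and name every
offending row.

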