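# mdplanner

Weekly family menu planning under Mediterranean-diet food-frequency rules.

Families who want to follow Mediterranean-diet (MD) guidance face a
coordination problem: children eat school-provided lunches that cannot be
changed, adults have individual energy and macronutrient targets, and the
family wants to share meals — while expert dietary rules constrain how
often each food group may appear per day and per week.  `mdplanner` is a
toolkit for nutrition-informatics practitioners and dietitians' technical
teams that solves this jointly:

* **Child planner** — models the week as a constraint-satisfaction problem
  over 7 days × 5 meal slots (breakfast, morning snack, lunch, afternoon
  snack, dinner).  Dated school menus pin the weekday lunches verbatim
  (even when they already break a rule — the remaining meals then
  compensate within clamped budgets); cafeteria proposals supply an
  unordered lunch pool; otherwise all slots are free.  A backtracking
  solver with forward checking enforces daily/weekly food-group frequency
  bounds (e.g. pulses 4–5/week, fruit ≥ 3/day, all meat ≤ 1/day),
  repetition limits, milk-allergy substitution (dairy rules collapse to
  zero, plant-based rules take their bounds), weekly program-snack
  insertion, and adolescent portion scaling.  When no feasible week
  exists, a relaxation ladder drops droppable rule groups (vegetable
  colors, pulse and white-meat sub-categories) and switches limiting rules
  to their expert-approved less-restrictive variants, one or two at a
  time, recording every relaxation in the plan.
* **Family (adult) recommender** — fixes the nine meals shared with the
  children (7 dinners, 2 weekend lunches), samples 100,000 daily
  combinations per day from the allergy/cuisine/season-filtered pools,
  scores each against the adult's Daily Energy Requirement
  (DER = BMR × PAL, Mifflin–St Jeor BMR) with a 0–4 score
  (DNPS = caloric + protein + fat + fruit&vegetable partial scores), and
  assembles one candidate per day into a week satisfying the MD and
  diversity rules (food-group caps, fish main/side limits, repetition
  rules).
* **Auditor** — independently re-counts portions from finished plans and
  reports per-rule compliance percentages (preferred vs. less-restrictive
  variants, per country) and adult accuracy statistics (mean caloric
  agreement, macronutrient and fruit&vegetable within-range shares).
* **Synthetic data generator** — builds rule-attainable datasets, school
  menus (optionally rule-violating, to exercise budget clamping) and
  family profiles, deterministically per seed, so the whole pipeline is
  testable without any external data.

The portion model is deliberately simple: one dish flagged with a food
group contributes one portion of that group; sub-category flags imply
their macro category and are de-duplicated per dish.  See
`docs/methods.md` for the full model, parameter defaults and limitations,
and `docs/plan_schema.md` for the file formats.

## Worked example

Generate a synthetic dataset, plan a child week around a school menu with
the weekly program snack, plan a parent's week around the shared meals,
and audit both:

```bash
mdplanner synth-data --seed 1 --out data
mdplanner plan-child --dataset data --menus data/school_menus.csv \
    --school school-0 --week 2025-09-08 --season autumn --country Spain \
    --snack --seed 7 --out child.json
mdplanner plan-family --dataset data --profiles data/profiles.json \
    --child-plan child.json --adult family0-adult0 --season autumn \
    --reference-year 2025 --n-candidates 20000 --seed 7 --out family.json
mkdir plans fplans && cp child.json plans/ && cp family.json fplans/
mdplanner audit --plans plans  --dataset data --ruleset child --out report.csv
mdplanner audit --plans fplans --dataset data --ruleset adult --out accuracy.csv
```

which logs:

```
INFO mdplanner: wrote 106 meals, 300 dishes, 2 menus to data (seed 1)
INFO mdplanner: seed=7 ruleset_version=1 relaxations=[] dropped=[]
INFO mdplanner: wrote child.json
INFO mdplanner: seed=7 ruleset_version=1 md_ok=True
INFO mdplanner: wrote family.json
INFO mdplanner: audited 1 child plans; daily preferred mean 100.0%, less-restrictive 100.0%
INFO mdplanner: audited 1 adult plans; mean caloric agreement 100.0%
```

`relaxations=[]` means the preferred (strictest) rules were satisfiable
around this school menu — no ladder step was needed — and `md_ok=True`
that the parent's assembled week passes every MD/diversity rule.  The
child plan's Monday reads

```
breakfast 1004, morning snack 1016, lunch 1031 (school), afternoon snack 1026, dinner 1051
```

— the lunch is the school's, everything else was generated.  The adult
accuracy report (`accuracy.csv`) for this single week:

```
weekly_nps,daily_nps,mean_caloric_agreement,fat_within_range,protein_within_range,fruit_veg_within_range
1,7,99.98739721816644,100.0,100.0,100.0
```

i.e. the seven daily plans for this parent average 99.99% caloric
agreement with their DER (caloric agreement = 100·(1 − |kcal − DER|/DER)),
and all days fall inside the recommended fat (25–40% of DER), protein
(15–20%) and fruit&vegetable (5–10 servings) bands.

The same pipeline is available as a library — `generate_dataset`,
`ChildPlanner.solve_week`, `plan_family_week`, `audit_child_compliance`,
`audit_adult_accuracy` — see the docstrings in `src/mdplanner/`.

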