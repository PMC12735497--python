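# Methods

`mdplanner` plans weekly family menus under expert-style Mediterranean-diet
(MD) food-frequency rules.  It has two planning engines — a
constraint-satisfaction child planner and a sampling/scoring adult
recommender tied to the child's shared meals — plus an auditor that
re-derives every compliance number from finished plans.  This note records
the model, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not show.

## The portion model

The unit of every rule is the *portion*: one dish flagged with a food group
contributes exactly one portion of that group, regardless of grams.
Sub-category flags imply their macro category (chicken ⇒ white meat,
lentils ⇒ pulses, cheese ⇒ dairy) and are de-duplicated per dish, so a dish
flagged both `chicken` and `white_meat` counts once toward white-meat
rules.  Gram-accurate portioning is deliberately out of scope: curated
collections of this kind acknowledge that their per-dish gram values only
approximate standard reference portions, so frequency counting is the
contract the rules are written against.  Two derived categories exist only
inside rules: *carbohydrates* is the flag sum over {bread, pasta, rice,
tubers, cereals}, and *vegetables* over {raw, cooked}.  Fish additionally
splits into main-dish and side-dish counts via the dish role (`unique` →
main, `semi` → side; unspecified roles count as main, the conservative
choice for the stricter main-dish cap).

## Child rules and the relaxation ladder

The child ruleset (`data/child_rules.yaml`) encodes daily and weekly
frequency bounds with a *preferred* and, where flexibility is allowed, a
*less restrictive* variant; rules marked "not to be changed" have no
variant.  Three droppable groups — vegetable colors, pulse sub-categories,
white-meat sub-categories — may be excluded entirely when too restrictive.
For milk-allergic children the dairy bounds collapse to zero (dairy meals
are also filtered out up front) and the plant-based alternative rules take
the same bounds instead.

The planner treats the week as 35 slot variables (7 days × 5 meal types)
and backtracks over them in (day, slot) order with forward checking: a
candidate meal is pruned when it would push a daily or weekly count past
its effective maximum, or when the maximum remaining contribution of the
still-open slots can no longer reach a minimum.  Candidate order is a
seeded shuffle, which makes every solve reproducible from the request seed.
Two implementation choices matter:

* **Fixed-lunch clamping.**  School menus are pinned verbatim and never
  altered.  If the fixed lunches alone already exceed a maximum, the bound
  is clamped to the fixed count, so the *generated* meals contribute zero
  further portions of that category; the excess reappears only in the
  audit report.  Minima are never clamped — school lunches can help meet
  them but not excuse them.
* **Restarts.**  A search that thrashes is cut at 2,000 backtracks and
  restarted with a fresh seeded shuffle, up to 50,000 backtracks per ladder
  state (both configurable).  A run that terminates *below* its budget has
  provably exhausted its subtree, so infeasibility verdicts are exact; the
  restarts only shortcut unlucky orderings.

When no assignment exists, the ladder relaxes: first it drops a droppable
group tied to the limiting categories (colors, then pulse sub-categories,
then white-meat sub-categories), then switches the limiting rules to their
less-restrictive variants, at most two per step, using prune-frequency
evidence from the failed searches to identify the limiting rules.  The
first feasible plan under the least-relaxed state is returned — no further
objective is optimized — and the relaxation record is part of the plan.

Repetition limits: a meal ID at most twice per week and never on
consecutive days; a dish ID at most 3 times per week (config; weekly
dish-ID limits are stated without a number in the source guidance, so the
cap is explicit and adjustable).  The three weekly program snacks are
exempt from repetition caps by construction (they are the same intervention
snack thrice); their placement (3 distinct days, mid-morning or afternoon)
is drawn from the request seed, with a handful of alternative placements
tried before the ladder escalates.

Adolescent plans reuse the child's meal IDs unchanged; only the age group
changes, which selects the age-specific ingredient gram column of each
dish.

## Adult scoring and weekly assembly

Adults are scored against their Daily Energy Requirement, DER = BMR × PAL,
with PAL one of the five fixed multipliers (1.2, 1.375, 1.55, 1.725, 1.9).
BMR uses the Mifflin–St Jeor equation (10·kg + 6.25·cm − 5·age + 5/−161);
it is isolated behind one function so an alternative equation can be
swapped.  Age is reference year minus birth year, the only resolution the
profile schema supports.  BMI is computed and reported but does not enter
DER; how BMI should modulate DER is not specified by the profile model, so
it is surfaced rather than guessed.

Each daily plan (5 meals; dinner fixed on weekdays, lunch + dinner fixed on
weekends, all from the child's plan) receives a Daily Nutritional Plan
Score, DNPS = CS + PS + FS + FVS ∈ [0, 4]:

| score | plateau (score = 1)   | ramp to 0            |
|-------|-----------------------|----------------------|
| CS    | kcal = DER            | 30% of DER           |
| PS    | protein 15–20% of DER | 10 percentage points |
| FS    | fat 25–40% of DER     | 10 percentage points |
| FVS   | 5–10 servings/day     | 5 servings           |

The plateaus are the expert guidance; the ramp widths are package constants
(`ScoreConfig`), and the audit metrics do not depend on them inside the
bands.  Protein and fat energy use the 4 and 9 kcal/g Atwater factors.
Fruit-and-vegetable servings are the fruit + raw + cooked vegetable portion
counts of the day.

Per day, 100,000 candidate combinations are sampled uniformly with
replacement from the filtered per-slot pools (deduplicated; the full
Cartesian product is enumerated instead whenever it is smaller), scored,
and sorted by DNPS with deterministic tie-breaking (caloric distance, then
meal-ID tuple).  The weekly assembly then picks one candidate per day so
the week passes the adult MD + diversity ruleset
(`data/adult_rules.yaml`): weekly food-group caps, fruit-salad limits,
fish main/side caps, at most one repeated dish ID per day, the
lunch-or-dinner once-per-day groups, and meal repetition ≤ 2/week and never
on consecutive days.

The assembly search is exact on enumerable spaces (complete DFS in rank
order).  On large spaces, rank-order DFS degenerates: the top-ranked
candidates of different days are nearly identical (they optimize the same
DER), so they collide on the repetition rules, and refuting each collision
costs exponential re-exploration.  The production path therefore runs a
narrow complete pass over the top ranks, then seeded uniform sampling over
the day-compliant candidates, and finally a rank-improving polish that
swaps each day to the best-ranked candidate that keeps the whole week
compliant.  All randomness is seeded; the node budget is 10⁶ visits.  If
no compliant week is found — typically because the fixed child meals
already violate an adult rule — the top-ranked candidate of each day is
returned flagged non-compliant, with the violations listed; the audit
counts such weeks as failures.

Both adults of a family are planned independently against the same fixed
child meals, and one season parameter is shared by the child and adult
plans of a family.

## The auditor

The auditor never trusts the planners: it re-counts portions and
re-evaluates every rule from the finished plans.  Child reports give, per
rule × country × variant, the share of compliant daily plans (daily rules,
one observation per plan-day) or weekly plans (weekly rules), with the
delta between variants; dairy rules are skipped for milk-allergic owners,
whose plans carry the plant-based rules instead.  Adult reports give the
mean caloric agreement, defined as the mean over daily plans of
100·(1 − |kcal − DER|/DER) — the only reading under which "accuracy in
calories" is a percentage near one minus the relative error — plus the
share of daily plans with fat, protein and fruit-and-vegetable intake
inside the recommended bands.  The share of plans whose agreement exceeds
90% is also computed, since "accuracy" could alternatively mean a
share-above-threshold; the mean is the headline.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* that makes real curated
collections plannable, not their content.  Meals are built from archetypes
(breakfast = dairy or plant beverage + carbohydrate + fruit; snacks =
fruit ± dairy; lunch/dinner = protein rotation + carbohydrate + colored
vegetable ± fruit) so that the child rules are attainable by construction,
with names, calories and macro splits randomized per seed.  Defaults: per
country, 6 dairy + 4 plant breakfasts, 5 + 2 morning snacks, 12 lunches,
5 + 4 afternoon snacks, 12 + 2 dinners, one program snack; per-meal kcal
ranges 250–650 (breakfast), 100–350 (snacks), 450–1000 (lunch), 400–900
(dinner), spanning low- to high-energy users; per-dish protein at 13–21%
and fat at 24–40% of dish energy; adult PAL drawn with sedentary-skewed
weights (0.30, 0.35, 0.25, 0.07, 0.03); 10% milk-allergy rate; 32 families.
Every meal owns its dishes, so the dish-repetition cap never binds through
shared components.

Two knobs control feasibility for testing: `flag_keep_probability` thins
any food-group flag (fruit 0 ⇒ provably infeasible weeks, the standard
infeasibility fixture), and `school_violation_fraction` plants school menus
with two red-meat lunches to exercise budget clamping.

What passing on this data shows: that the solvers satisfy, and the auditor
independently confirms, every encoded rule under realistic pool sizes,
energy spreads and conflict patterns (non-compliant school menus, allergy
filtering, snack insertion, shared-meal coupling).  What it does not show:
compliance rates on any real menu collection — real dishes carry messier
flag combinations (multi-group recipes, seasonal gaps, country asymmetries)
that can only lower compliance, as the gap between preferred and
less-restrictive weekly compliance on real cohorts illustrates.  Absolute
percentages from the synthetic study are therefore properties of the
generator's conditions, not predictions.

## Problem sizes and numerical choices

The shipped validation runs use 200 enumerable solver-oracle instances,
1,000 seeded child weeks for auditor agreement and another 1,000 for
allergy safety, and 20 adult weekly plans at a 20,000-candidate daily
sampling budget (the full 100,000 default changes the accuracy statistics
by well under a percentage point on this dataset, since the free-slot
product is orders of magnitude smaller).  Scores are plain float64; rule
evaluation is integer counting, so there are no tolerance choices anywhere
in the compliance path.  Ties in candidate ranking are broken
deterministically; all stochastic components (candidate shuffles, snack
placement, sampling) derive from the request or function seed.

## Known limitations

* The child planner returns the first feasible plan under the
  least-relaxed state; no secondary preference (variety beyond the
  repetition caps, cost, prep time) is optimized.
* A school menu containing dairy cannot be reconciled with a milk-allergic
  child; the planner accepts school lunches verbatim, so such a week fails
  plan validation rather than substituting the school dish.
* Families with several children receive plans derived from one child's
  menu per run; reconciling siblings with different school menus requires
  separate runs and manual arbitration.
* The adult assembly is exact only on enumerable candidate spaces; on
  large spaces a compliant week that exists but is extraordinarily rare
  (beyond the sampling budget) would be reported as non-compliant.
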