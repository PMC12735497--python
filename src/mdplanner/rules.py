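"""Food-group frequency rules: portion counting and rule evaluation.

Rules are *frequency* constraints over food-group portions at two horizons
(daily, weekly).  One flagged dish contributes exactly one portion of each
group it is flagged with (sub-category flags imply their macro category and
are de-duplicated per dish); grams are deliberately not weighed — the
portion is the unit of every rule.

A rule *family* bundles a preferred bound with an optional less-restrictive
variant (the relaxation ladder switches between them) and may belong to a
droppable group (vegetable colors, pulse sub-categories, white-meat
sub-categories) that can be excluded entirely when too restrictive.  Dairy
families are zeroed for milk-allergic users and the plant-based alternative
families take over with identical bounds.

Rulesets ship as versioned YAML resources (``data/child_rules.yaml``,
``data/adult_rules.yaml``) mirroring the expert-validated frequency tables
cell for cell.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .model import FOOD_GROUPS, VEG_COLORS, Dish, Meal, ModelError

__all__ = [
    "Constraint",
    "RuleFamily",
    "RuleSet",
    "RuleState",
    "RuleViolation",
    "PortionLedger",
    "PREFERRED",
    "LESS_RESTRICTIVE",
    "DROPPED",
    "load_ruleset",
    "count_portions",
    "dish_portion_counts",
    "evaluate_rules",
    "evaluate_structure",
    "remaining_budgets",
]

PREFERRED = "preferred"
LESS_RESTRICTIVE = "less_restrictive"
DROPPED = "dropped"

#: Extra countable keys beyond the food-group vocabulary.
SPECIAL_KEYS = frozenset({"fruit_salad", "fish_main", "fish_side"})
_COLOR_PREFIX = "color:"


def _valid_key(key: str) -> bool:
    if key.startswith(_COLOR_PREFIX):
        return key[len(_COLOR_PREFIX):] in VEG_COLORS
    return key in FOOD_GROUPS or key in SPECIAL_KEYS


@dataclass(frozen=True)
class Constraint:
    """min <= sum of portion counts over ``keys`` <= max (either side open)."""

    keys: tuple[str, ...]
    min: int | None = None
    max: int | None = None

    def __post_init__(self) -> None:
        for k in self.keys:
            if not _valid_key(k):
                raise ModelError(f"rule constraint references unknown key {k!r}")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ModelError(f"constraint on {self.keys}: min > max")

    def observed(self, ledger: "PortionLedger") -> int:
        return sum(ledger.get(k) for k in self.keys)


@dataclass(frozen=True)
class RuleFamily:
    id: str
    scope: str  # daily | weekly
    preferred: tuple[Constraint, ...]
    less_restrictive: tuple[Constraint, ...] | None = None  # None = fixed
    drop_group: str | None = None  # colors | pulse_subcategories | white_meat_subcategories
    dairy: bool = False  # zeroed under milk allergy
    allergy_only: bool = False  # active only under milk allergy
    note: str = ""

    def __post_init__(self) -> None:
        if self.scope not in ("daily", "weekly"):
            raise ModelError(f"rule {self.id}: bad scope {self.scope!r}")

    @property
    def relaxable(self) -> bool:
        return self.less_restrictive is not None

    @property
    def droppable(self) -> bool:
        return self.drop_group is not None

    def constraints(self, variant: str, milk_allergy: bool) -> tuple[Constraint, ...]:
        """Active constraints under a ladder state and allergy flag."""
        if variant == DROPPED:
            return ()
        if self.allergy_only and not milk_allergy:
            return ()
        if self.dairy and milk_allergy:
            # dairy excluded outright: the bound collapses to zero portions
            keys = tuple({k for c in self.preferred for k in c.keys})
            return (Constraint(keys=keys, min=None, max=0),)
        if variant == LESS_RESTRICTIVE and self.less_restrictive is not None:
            return self.less_restrictive
        return self.preferred


#: family id -> preferred | less_restrictive | dropped
RuleState = dict


@dataclass
class RuleSet:
    version: int
    audience: str
    families: tuple[RuleFamily, ...]
    meal_repetition_max: int = 2
    meal_repetition_consecutive: bool = False  # repeats on consecutive days allowed?
    dish_repetition_max: int | None = None
    by_id: dict[str, RuleFamily] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_id = {f.id: f for f in self.families}
        if len(self.by_id) != len(self.families):
            raise ModelError("duplicate rule family ids in ruleset")

    def default_state(self) -> RuleState:
        return {f.id: PREFERRED for f in self.families}

    def validate_state(self, state: RuleState) -> None:
        unknown = set(state) - set(self.by_id)
        if unknown:
            raise ModelError(f"unknown rule id(s) in variant selector: {sorted(unknown)}")

    def families_in(self, scope: str):
        return [f for f in self.families if f.scope == scope]


@dataclass(frozen=True)
class RuleViolation:
    rule_id: str
    horizon: str  # "week" or "day:<i>"
    observed: int
    min: int | None
    max: int | None

    @property
    def direction(self) -> str:
        if self.min is not None and self.observed < self.min:
            return "below"
        return "above"


# ---------------------------------------------------------------------------
# portion counting

@dataclass
class PortionLedger:
    """Portion counts for a list of meals at one horizon.

    Additive: the week ledger equals the sum of its seven day ledgers.
    """

    counts: Counter = field(default_factory=Counter)
    color_counts: Counter = field(default_factory=Counter)
    meal_id_counts: Counter = field(default_factory=Counter)
    dish_id_counts: Counter = field(default_factory=Counter)

    def get(self, key: str) -> int:
        if key.startswith(_COLOR_PREFIX):
            return self.color_counts[key[len(_COLOR_PREFIX):]]
        return self.counts[key]

    def __add__(self, other: "PortionLedger") -> "PortionLedger":
        return PortionLedger(
            counts=self.counts + other.counts,
            color_counts=self.color_counts + other.color_counts,
            meal_id_counts=self.meal_id_counts + other.meal_id_counts,
            dish_id_counts=self.dish_id_counts + other.dish_id_counts,
        )


def dish_portion_counts(dish: Dish) -> Counter:
    """Countable contributions of one dish (flag closure, special keys)."""
    c = Counter()
    for g in dish.expanded_groups:
        c[g] += 1
    if dish.fruit_salad:
        c["fruit_salad"] += 1
    if "fish_seafood" in dish.expanded_groups:
        # side-dish fish counts toward the side budget; anything else as main
        c["fish_side" if dish.role == "side" else "fish_main"] += 1
    return c


def count_portions(meals: list[Meal], dataset) -> PortionLedger:
    """Count daily/weekly portions of each food category over ``meals``."""
    ledger = PortionLedger()
    for meal in meals:
        if meal.id not in dataset.meals:
            raise ModelError(f"meal {meal.id} does not resolve in the dataset")
        ledger.meal_id_counts[meal.id] += 1
        for dish in dataset.meal_dishes(meal.id):
            ledger.dish_id_counts[dish.id] += 1
            ledger.counts.update(dish_portion_counts(dish))
            for col in dish.colors:
                ledger.color_counts[col] += 1
    return ledger


# ---------------------------------------------------------------------------
# evaluation

def evaluate_rules(
    day_ledgers: list[PortionLedger],
    week_ledger: PortionLedger | None,
    ruleset: RuleSet,
    state: RuleState | None = None,
    milk_allergy: bool = False,
) -> list[RuleViolation]:
    """Evaluate frequency rules; empty result iff fully compliant.

    ``state`` selects the active variant per rule family (defaults to all
    preferred).  Daily families run over each entry of ``day_ledgers``;
    weekly families over ``week_ledger`` when given.
    """
    if state is None:
        state = ruleset.default_state()
    ruleset.validate_state(state)
    violations: list[RuleViolation] = []

    def check(family: RuleFamily, ledger: PortionLedger, horizon: str) -> None:
        variant = state.get(family.id, PREFERRED)
        for c in family.constraints(variant, milk_allergy):
            obs = c.observed(ledger)
            if (c.min is not None and obs < c.min) or (
                c.max is not None and obs > c.max
            ):
                violations.append(
                    RuleViolation(
                        rule_id=family.id,
                        horizon=horizon,
                        observed=obs,
                        min=c.min,
                        max=c.max,
                    )
                )

    for fam in ruleset.families_in("daily"):
        for i, ledger in enumerate(day_ledgers):
            check(fam, ledger, f"day:{i}")
    if week_ledger is not None:
        for fam in ruleset.families_in("weekly"):
            check(fam, week_ledger, "week")
    return violations


def evaluate_structure(
    day_meals: list[list[Meal]],
    dataset,
    ruleset: RuleSet,
    adult: bool = False,
) -> list[RuleViolation]:
    """Repetition and slot-position rules that need the day/slot structure.

    Checked for every audience: meal-ID repetition <= ruleset cap per week
    and never on consecutive days; optional dish-ID weekly cap.  For adults
    additionally: at most one dish ID may repeat within a day, and each of
    white meat, red meat, pork, fish and pasta may appear at most once per
    day across the lunch and dinner slots.
    """
    violations: list[RuleViolation] = []
    week_meal_counts: Counter = Counter()
    week_dish_counts: Counter = Counter()
    last_day_of_meal: dict[int, int] = {}

    for i, meals in enumerate(day_meals):
        day_dish_counts: Counter = Counter()
        lunch_dinner = Counter()
        for meal in meals:
            week_meal_counts[meal.id] += 1
            prev = last_day_of_meal.get(meal.id)
            if prev is not None and prev == i - 1 and not ruleset.meal_repetition_consecutive:
                violations.append(
                    RuleViolation(
                        rule_id="wk_meal_consecutive",
                        horizon=f"day:{i}",
                        observed=2,
                        min=None,
                        max=1,
                    )
                )
            last_day_of_meal[meal.id] = i
            for dish in dataset.meal_dishes(meal.id):
                day_dish_counts[dish.id] += 1
                week_dish_counts[dish.id] += 1
                if adult and meal.type in ("lunch", "dinner"):
                    for g in ("white_meat", "red_meat", "pork", "fish_seafood", "pasta"):
                        if g in dish.expanded_groups:
                            lunch_dinner[g] += 1
        if adult:
            repeated = sum(1 for n in day_dish_counts.values() if n > 1)
            if repeated > 1:
                violations.append(
                    RuleViolation(
                        rule_id="d_repeating_dishes",
                        horizon=f"day:{i}",
                        observed=repeated,
                        min=None,
                        max=1,
                    )
                )
            for g, n in lunch_dinner.items():
                if n > 1:
                    violations.append(
                        RuleViolation(
                            rule_id=f"d_lunch_dinner_{g}",
                            horizon=f"day:{i}",
                            observed=n,
                            min=None,
                            max=1,
                        )
                    )

    for mid, n in week_meal_counts.items():
        if n > ruleset.meal_repetition_max:
            violations.append(
                RuleViolation(
                    rule_id="wk_meal_repetition",
                    horizon="week",
                    observed=n,
                    min=None,
                    max=ruleset.meal_repetition_max,
                )
            )
    if ruleset.dish_repetition_max is not None:
        for did, n in week_dish_counts.items():
            if n > ruleset.dish_repetition_max:
                violations.append(
                    RuleViolation(
                        rule_id="wk_dish_repetition",
                        horizon="week",
                        observed=n,
                        min=None,
                        max=ruleset.dish_repetition_max,
                    )
                )
    return violations


def remaining_budgets(
    ruleset: RuleSet,
    ledger: PortionLedger,
    scope: str,
    state: RuleState | None = None,
    milk_allergy: bool = False,
) -> dict[str, list[tuple[tuple[str, ...], int, int | None]]]:
    """Per rule family: (keys, portions still owed, portions still allowed).

    ``max`` budgets floor at 0 — an excess already contributed by fixed
    school lunches cannot be undone, only avoided in the remaining meals.
    ``None`` means unbounded above.
    """
    if state is None:
        state = ruleset.default_state()
    out: dict[str, list[tuple[tuple[str, ...], int, int | None]]] = {}
    for fam in ruleset.families_in(scope):
        entries = []
        for c in fam.constraints(state.get(fam.id, PREFERRED), milk_allergy):
            obs = c.observed(ledger)
            owed = max(0, (c.min or 0) - obs)
            left = None if c.max is None else max(0, c.max - obs)
            entries.append((c.keys, owed, left))
        if entries:
            out[fam.id] = entries
    return out


# ---------------------------------------------------------------------------
# YAML loading

def _parse_constraints(raw) -> tuple[Constraint, ...]:
    return tuple(
        Constraint(
            keys=tuple(c["keys"]),
            min=c.get("min"),
            max=c.get("max"),
        )
        for c in raw
    )


def load_ruleset(source: str | Path = "child") -> RuleSet:
    """Load a ruleset: ``"child"``/``"adult"`` for the packaged resources,
    or a path to a user-supplied YAML file of the same schema."""
    if source in ("child", "adult"):
        text = (
            resources.files("mdplanner.data")
            .joinpath(f"{source}_rules.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(source).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    families = tuple(
        RuleFamily(
            id=f["id"],
            scope=f["scope"],
            preferred=_parse_constraints(f["preferred"]),
            less_restrictive=(
                _parse_constraints(f["less_restrictive"])
                if f.get("less_restrictive")
                else None
            ),
            drop_group=f.get("drop_group"),
            dairy=bool(f.get("dairy", False)),
            allergy_only=bool(f.get("allergy_only", False)),
            note=f.get("note", ""),
        )
        for f in raw["families"]
    )
    return RuleSet(
        version=int(raw["version"]),
        audience=raw["audience"],
        families=families,
        meal_repetition_max=int(raw.get("meal_repetition_max", 2)),
        meal_repetition_consecutive=bool(raw.get("meal_repetition_consecutive", False)),
        dish_repetition_max=raw.get("dish_repetition_max"),
    )
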