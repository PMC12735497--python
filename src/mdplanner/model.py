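"""Domain types for dishes, meals, school menus and weekly plans.

The vocabulary here mirrors how Mediterranean-diet food-frequency guidance
is usually written down: a *dish* is the atomic food item carrying boolean
food-group flags (one flag = one countable portion of that group), a *meal*
is a typed slot entry (breakfast ... dinner) composed of 1-10 dishes, and a
*weekly plan* is 7 days x 5 slots of meal IDs with provenance.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

__all__ = [
    "FOOD_GROUPS",
    "GROUP_PARENTS",
    "VEG_COLORS",
    "MEAL_TYPES",
    "SNACK_SLOTS",
    "AGE_GROUPS",
    "ADULT",
    "COUNTRIES",
    "SEASONS",
    "WEEKDAYS",
    "PROVENANCES",
    "Nutrition",
    "Dish",
    "Meal",
    "SchoolMenu",
    "CafeteriaProposal",
    "SlotAssignment",
    "DayPlan",
    "WeeklyPlan",
    "ModelError",
    "expand_groups",
]


class ModelError(ValueError):
    """Raised when a domain object violates one of its invariants."""


#: Closed food-group vocabulary.  Sub-categories imply their macro category
#: (see :data:`GROUP_PARENTS`); ``bread`` is regulated by the frequency rules
#: even though some relational schemas omit it from the boolean list, so it
#: is a first-class flag here.
FOOD_GROUPS: frozenset[str] = frozenset(
    {
        "processed_meat",
        "white_meat",
        "chicken",
        "turkey",
        "rabbit",
        "red_meat",
        "pork",
        "fish_seafood",
        "pulses",
        "chickpeas",
        "lentils",
        "white_red_beans",
        "other_pulses",
        "dairy",
        "plant_beverage_yogurt",
        "plant_cheese",
        "milk_yogurt",
        "cheese",
        "eggs",
        "pasta",
        "rice",
        "tubers",
        "soups",
        "cereals",
        "bread",
        "fruit",
        "nuts",
        "raw_vegetables",
        "cooked_vegetables",
    }
)

#: Sub-category -> implied macro categories.  A dish flagged ``chicken``
#: counts once toward ``white_meat`` rules even if the macro flag was not
#: set explicitly; a dish flagged both counts once, not twice.
GROUP_PARENTS: dict[str, tuple[str, ...]] = {
    "chicken": ("white_meat",),
    "turkey": ("white_meat",),
    "rabbit": ("white_meat",),
    "pork": ("red_meat",),
    "chickpeas": ("pulses",),
    "lentils": ("pulses",),
    "white_red_beans": ("pulses",),
    "other_pulses": ("pulses",),
    "milk_yogurt": ("dairy",),
    "cheese": ("dairy",),
}

VEG_COLORS: frozenset[str] = frozenset(
    {"red", "green", "white", "yellow", "purple", "multicolor"}
)

MEAL_TYPES: tuple[str, ...] = (
    "breakfast",
    "morning_snack",
    "lunch",
    "afternoon_snack",
    "dinner",
)
SNACK_SLOTS: tuple[str, str] = ("morning_snack", "afternoon_snack")

AGE_GROUPS: tuple[str, ...] = ("3-6", "7-12", "13-15", "16-18", "adult")
ADULT = "adult"

COUNTRIES: tuple[str, ...] = ("Spain", "Türkiye")
SEASONS: tuple[str, ...] = ("winter", "spring", "summer", "autumn")
WEEKDAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: How a slot came to hold its meal.
PROVENANCES: tuple[str, ...] = (
    "school",
    "cafeteria",
    "child_fixed",
    "generated",
    "program_snack",
)

DAIRY_GROUPS: frozenset[str] = frozenset({"dairy", "milk_yogurt", "cheese"})


def expand_groups(groups: frozenset[str]) -> frozenset[str]:
    """Close a dish's flag set under the sub-category -> macro hierarchy."""
    out = set(groups)
    for g in groups:
        out.update(GROUP_PARENTS.get(g, ()))
    return frozenset(out)


@dataclass(frozen=True)
class Nutrition:
    """Adult per-dish nutrition (kcal and Atwater-relevant macros, grams)."""

    kcal: float
    fat_g: float
    protein_g: float
    carbs_g: float

    def __post_init__(self) -> None:
        for name in ("kcal", "fat_g", "protein_g", "carbs_g"):
            if getattr(self, name) < 0:
                raise ModelError(f"nutrition field {name} must be non-negative")


@dataclass(frozen=True)
class Dish:
    id: int
    name: str
    groups: frozenset[str] = frozenset()
    colors: frozenset[str] = frozenset()
    nutrition: Nutrition | None = None
    #: age group -> ((ingredient name, grams), ...)
    ingredients: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    recipe: str = ""
    tip: str = ""
    role: str = "unspecified"  # main | side | unspecified
    fruit_salad: bool = False

    def __post_init__(self) -> None:
        unknown = self.groups - FOOD_GROUPS
        if unknown:
            raise ModelError(
                f"dish {self.id}: unknown food group(s) {sorted(unknown)}"
            )
        bad_colors = self.colors - VEG_COLORS
        if bad_colors:
            raise ModelError(f"dish {self.id}: unknown color(s) {sorted(bad_colors)}")
        if self.colors and not (
            self.groups & {"raw_vegetables", "cooked_vegetables"}
        ):
            raise ModelError(
                f"dish {self.id}: colors set but dish is not flagged as vegetables"
            )
        if self.role not in ("main", "side", "unspecified"):
            raise ModelError(f"dish {self.id}: bad role {self.role!r}")
        for age, items in self.ingredients.items():
            if age not in AGE_GROUPS:
                raise ModelError(f"dish {self.id}: unknown age group {age!r}")
            for ing, grams in items:
                if grams <= 0:
                    raise ModelError(
                        f"dish {self.id}: ingredient {ing!r} grams must be > 0"
                    )

    @property
    def expanded_groups(self) -> frozenset[str]:
        return expand_groups(self.groups)


@dataclass(frozen=True)
class Meal:
    id: int
    name: str
    type: str
    country: str
    seasons: frozenset[str]
    dish_ids: tuple[int, ...]
    audience: str = "both"  # adult | child | both
    program_snack: bool = False

    def __post_init__(self) -> None:
        if self.type not in MEAL_TYPES:
            raise ModelError(f"meal {self.id}: unknown meal type {self.type!r}")
        if self.country not in COUNTRIES:
            raise ModelError(f"meal {self.id}: unknown country {self.country!r}")
        if not self.seasons or not self.seasons <= frozenset(SEASONS):
            raise ModelError(
                f"meal {self.id}: seasons must be a non-empty subset of {SEASONS}"
            )
        if not 1 <= len(self.dish_ids) <= 10:
            raise ModelError(
                f"meal {self.id}: must reference 1-10 dishes, got {len(self.dish_ids)}"
            )
        if self.audience not in ("adult", "child", "both"):
            raise ModelError(f"meal {self.id}: bad audience {self.audience!r}")


@dataclass(frozen=True)
class SchoolMenu:
    """Dated weekday lunches (Mon-Fri) served by one school in one week."""

    school: str
    country: str
    week_start: _dt.date  # Monday
    lunches: dict[str, int]  # weekday -> lunch meal id

    def __post_init__(self) -> None:
        if set(self.lunches) != set(WEEKDAYS[:5]):
            raise ModelError(
                f"school menu {self.school!r}: needs exactly the 5 weekday lunches"
            )
        if self.week_start.weekday() != 0:
            raise ModelError(
                f"school menu {self.school!r}: week_start must be a Monday"
            )


@dataclass(frozen=True)
class CafeteriaProposal:
    """Undated pool of lunches a school cafeteria offers during the week."""

    school: str
    country: str
    lunches: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lunches) < 5:
            raise ModelError(
                f"cafeteria {self.school!r}: needs >= 5 lunches to fill a school week"
            )


@dataclass(frozen=True)
class SlotAssignment:
    meal_id: int
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ModelError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class DayPlan:
    date: _dt.date
    slots: dict[str, SlotAssignment]

    def __post_init__(self) -> None:
        if set(self.slots) != set(MEAL_TYPES):
            raise ModelError("a day plan must fill exactly the 5 slot types")

    def meal_ids(self) -> tuple[int, ...]:
        return tuple(self.slots[t].meal_id for t in MEAL_TYPES)


@dataclass(frozen=True)
class WeeklyPlan:
    owner: str
    week_start: _dt.date
    country: str
    season: str
    days: tuple[DayPlan, ...]
    relaxations: tuple[str, ...] = ()
    dropped_rules: tuple[str, ...] = ()
    feasible: bool = True
    seed: int = 0
    age_group: str = "7-12"
    milk_allergy: bool = False

    def __post_init__(self) -> None:
        if len(self.days) != 7:
            raise ModelError("a weekly plan must cover exactly 7 days")
        if self.week_start.weekday() != 0:
            raise ModelError("weeks run Monday-Sunday; week_start must be a Monday")
        for i, day in enumerate(self.days):
            expect = self.week_start + _dt.timedelta(days=i)
            if day.date != expect:
                raise ModelError(f"day {i} dated {day.date}, expected {expect}")
        if self.country not in COUNTRIES:
            raise ModelError(f"unknown country {self.country!r}")
        if self.season not in SEASONS:
            raise ModelError(f"unknown season {self.season!r}")
        if self.age_group not in AGE_GROUPS:
            raise ModelError(f"unknown age group {self.age_group!r}")

    def with_days(self, days: tuple[DayPlan, ...]) -> "WeeklyPlan":
        return replace(self, days=days)

    def all_meal_ids(self) -> list[int]:
        return [a.meal_id for day in self.days for a in day.slots.values()]
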