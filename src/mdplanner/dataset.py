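"""Readers/writers for the meal-and-dish dataset dialect and plan exports.

File dialect (UTF-8 CSV, one table per entity): ``dishes.csv``,
``meals.csv``, ``school_menus.csv``.  List-valued cells are delimited by
``;``, booleans are 0/1, ingredient lists are ``name:grams`` pairs.  A JSON
mirror of the same content (``dataset.json``) is also accepted.  Readers
tolerate extra (e.g. translated-name) columns but key on IDs.

Weekly plans are exported as JSON documents; ``read_weekly_plan`` of
``write_weekly_plan`` output is the identity (see docs/plan_schema.md).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import (
    ADULT,
    AGE_GROUPS,
    COUNTRIES,
    DAIRY_GROUPS,
    MEAL_TYPES,
    WEEKDAYS,
    CafeteriaProposal,
    DayPlan,
    Dish,
    Meal,
    ModelError,
    Nutrition,
    SchoolMenu,
    SlotAssignment,
    WeeklyPlan,
    expand_groups,
)

__all__ = [
    "Dataset",
    "DatasetError",
    "load_dataset",
    "write_dataset",
    "load_school_menus",
    "write_school_menus",
    "write_weekly_plan",
    "read_weekly_plan",
    "validate_plan",
]

PLAN_SCHEMA_VERSION = 1


class DatasetError(ValueError):
    """Raised on malformed dataset files or broken referential integrity."""


@dataclass
class Dataset:
    """In-memory dataset: dishes and meals indexed by ID and by meal type."""

    dishes: dict[int, Dish]
    meals: dict[int, Meal]
    by_type: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self.by_type = {t: [] for t in MEAL_TYPES}
        for m in self.meals.values():
            self.by_type[m.type].append(m.id)

    def _validate(self) -> None:
        for meal in self.meals.values():
            missing = [d for d in meal.dish_ids if d not in self.dishes]
            if missing:
                raise DatasetError(
                    f"meal {meal.id} ({meal.name!r}) references unknown "
                    f"dish id(s) {missing}"
                )
            if meal.audience in ("adult", "both"):
                lacking = [
                    d for d in meal.dish_ids if self.dishes[d].nutrition is None
                ]
                if lacking:
                    raise DatasetError(
                        f"adult-audience meal {meal.id} has dishes without "
                        f"nutrition: {lacking}"
                    )

    # -- queries ---------------------------------------------------------

    def meal_dishes(self, meal_id: int) -> list[Dish]:
        return [self.dishes[d] for d in self.meals[meal_id].dish_ids]

    def meal_has_dairy(self, meal_id: int) -> bool:
        return any(
            expand_groups(d.groups) & DAIRY_GROUPS for d in self.meal_dishes(meal_id)
        )

    def meals_for(
        self,
        type: str | None = None,
        country: str | None = None,
        season: str | None = None,
        audience: str | None = None,
        exclude_dairy: bool = False,
        include_program_snack: bool = True,
    ) -> list[int]:
        """Meal IDs matching all given filters, in ascending-ID order.

        ``audience='child'`` keeps meals whose audience is child or both;
        likewise for adult.  ``exclude_dairy`` drops any meal containing a
        dish flagged dairy/milk&yogurt/cheese (milk-protein allergy).
        """
        ids = self.by_type[type] if type else list(self.meals)
        out = []
        for mid in sorted(ids):
            m = self.meals[mid]
            if country is not None and m.country != country:
                continue
            if season is not None and season not in m.seasons:
                continue
            if audience is not None and m.audience not in (audience, "both"):
                continue
            if not include_program_snack and m.program_snack:
                continue
            if exclude_dairy and self.meal_has_dairy(mid):
                continue
            out.append(mid)
        return out

    def program_snack_meals(self, country: str | None = None) -> list[int]:
        return [
            m.id
            for m in sorted(self.meals.values(), key=lambda m: m.id)
            if m.program_snack and (country is None or m.country == country)
        ]

    def counts(self) -> dict[str, int]:
        return {"meals": len(self.meals), "dishes": len(self.dishes)}


# ---------------------------------------------------------------------------
# cell codecs

def _split(cell, sep: str = ";") -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    s = str(cell).strip()
    if not s:
        return []
    return [tok.strip() for tok in s.split(sep) if tok.strip()]


def _bool(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return False
    return str(cell).strip() in ("1", "true", "True", "yes")


def _opt_float(cell) -> float | None:
    if cell is None or (isinstance(cell, str) and not cell.strip()):
        return None
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _parse_ingredients(cell) -> tuple[tuple[str, float], ...]:
    out = []
    for tok in _split(cell):
        name, _, grams = tok.rpartition(":")
        if not name:
            raise DatasetError(f"bad ingredient token {tok!r} (want name:grams)")
        out.append((name.strip(), float(grams)))
    return tuple(out)


_AGE_COLS = {age: "ingredients_" + age.replace("-", "_") for age in AGE_GROUPS}
_ROLE_MAP = {"unique": "main", "main": "main", "semi": "side", "side": "side"}


def _dish_from_row(row: dict) -> Dish:
    groups = frozenset(g.lower().strip() for g in _split(row.get("groups")))
    colors = frozenset(c.lower().strip() for c in _split(row.get("colors")))
    kcal = _opt_float(row.get("kcal"))
    nutrition = None
    if kcal is not None:
        nutrition = Nutrition(
            kcal=kcal,
            fat_g=_opt_float(row.get("fat_g")) or 0.0,
            protein_g=_opt_float(row.get("protein_g")) or 0.0,
            carbs_g=_opt_float(row.get("carbs_g")) or 0.0,
        )
    ingredients = {}
    for age, col in _AGE_COLS.items():
        if col in row:
            items = _parse_ingredients(row.get(col))
            if items:
                ingredients[age] = items
    raw_role = str(row.get("type") or row.get("role") or "").strip().lower()
    return Dish(
        id=int(row["id"]),
        name=str(row.get("name", "")),
        groups=groups,
        colors=colors,
        nutrition=nutrition,
        ingredients=ingredients,
        recipe=str(row.get("recipe") or ""),
        tip=str(row.get("tip") or ""),
        role=_ROLE_MAP.get(raw_role, "unspecified"),
        fruit_salad=_bool(row.get("fruit_salad")),
    )


def _meal_from_row(row: dict) -> Meal:
    return Meal(
        id=int(row["id"]),
        name=str(row.get("name", "")),
        type=str(row["type"]).strip().lower(),
        country=str(row["country"]).strip(),
        seasons=frozenset(s.lower() for s in _split(row.get("seasons"))),
        dish_ids=tuple(int(d) for d in _split(row.get("dish_ids"))),
        audience=str(row.get("audience") or "both").strip().lower(),
        program_snack=_bool(row.get("program_snack")),
    )


def _rows_to_objects(rows: list[dict], builder, what: str) -> dict[int, object]:
    out: dict[int, object] = {}
    errors: list[str] = []
    for i, row in enumerate(rows):
        try:
            obj = builder(row)
        except (ModelError, DatasetError, KeyError, ValueError) as exc:
            errors.append(f"{what} row {i}: {exc}")
            continue
        if obj.id in out:
            errors.append(f"{what} row {i}: duplicate id {obj.id}")
        out[obj.id] = obj
    if errors:
        raise DatasetError(f"invalid {what} table:\n  " + "\n  ".join(errors))
    return out


def load_dataset(path: str | Path, country: str | None = None) -> Dataset:
    """Load a dataset directory (CSV tables) or a single-file JSON mirror.

    ``country`` optionally restricts meals to one cuisine; dishes are kept
    in full (they carry no country).  Raises :class:`DatasetError` listing
    every offending row on malformed input.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        dish_rows = payload.get("dishes", [])
        meal_rows = payload.get("meals", [])
    else:
        dishes_csv = path / "dishes.csv"
        meals_csv = path / "meals.csv"
        for f in (dishes_csv, meals_csv):
            if not f.exists():
                raise DatasetError(f"missing dataset file: {f}")
        dish_rows = pd.read_csv(dishes_csv, dtype=str, keep_default_na=False).to_dict(
            "records"
        )
        meal_rows = pd.read_csv(meals_csv, dtype=str, keep_default_na=False).to_dict(
            "records"
        )
    dishes = _rows_to_objects(dish_rows, _dish_from_row, "dishes")
    meals = _rows_to_objects(meal_rows, _meal_from_row, "meals")
    if country is not None:
        if country not in COUNTRIES:
            raise DatasetError(f"unknown country filter {country!r}")
        meals = {i: m for i, m in meals.items() if m.country == country}
    return Dataset(dishes=dishes, meals=meals)  # validates referential integrity


def _dish_to_row(d: Dish) -> dict:
    row = {
        "id": d.id,
        "name": d.name,
        "groups": ";".join(sorted(d.groups)),
        "colors": ";".join(sorted(d.colors)),
        "kcal": "" if d.nutrition is None else d.nutrition.kcal,
        "fat_g": "" if d.nutrition is None else d.nutrition.fat_g,
        "protein_g": "" if d.nutrition is None else d.nutrition.protein_g,
        "carbs_g": "" if d.nutrition is None else d.nutrition.carbs_g,
        "role": d.role,
        "fruit_salad": int(d.fruit_salad),
        "recipe": d.recipe,
        "tip": d.tip,
    }
    for age, col in _AGE_COLS.items():
        items = d.ingredients.get(age, ())
        row[col] = ";".join(f"{n}:{g:g}" for n, g in items)
    return row


def _meal_to_row(m: Meal) -> dict:
    return {
        "id": m.id,
        "name": m.name,
        "type": m.type,
        "country": m.country,
        "seasons": ";".join(s for s in ("winter", "spring", "summer", "autumn") if s in m.seasons),
        "dish_ids": ";".join(str(d) for d in m.dish_ids),
        "audience": m.audience,
        "program_snack": int(m.program_snack),
    }


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write ``dishes.csv`` and ``meals.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([_dish_to_row(d) for d in sorted(dataset.dishes.values(), key=lambda d: d.id)]).to_csv(
        path / "dishes.csv", index=False
    )
    pd.DataFrame([_meal_to_row(m) for m in sorted(dataset.meals.values(), key=lambda m: m.id)]).to_csv(
        path / "meals.csv", index=False
    )


# ---------------------------------------------------------------------------
# school menus

def load_school_menus(
    path: str | Path,
    dataset: Dataset,
    school: str | None = None,
    week_start: _dt.date | None = None,
):
    """Load ``school_menus.csv`` and resolve one school's offering.

    Returns a :class:`SchoolMenu` when a dated menu matches ``school`` and
    ``week_start``, a :class:`CafeteriaProposal` when the school has only
    undated rows, and ``None`` when nothing matches (the child planner then
    falls back to home mode).  With ``school=None`` returns the full parsed
    list of menus/proposals.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"missing school menu file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    menus: list[SchoolMenu | CafeteriaProposal] = []
    for (sch, country, week), grp in df.groupby(
        ["school", "country", "week_start"], sort=False
    ):
        meal_ids = [int(v) for v in grp["meal_id"]]
        for mid in meal_ids:
            if mid not in dataset.meals:
                raise DatasetError(f"school {sch!r}: unknown lunch meal id {mid}")
            if dataset.meals[mid].type != "lunch":
                raise DatasetError(
                    f"school {sch!r}: meal {mid} is not a lunch "
                    f"(type={dataset.meals[mid].type})"
                )
        if str(week).strip():
            lunches = dict(zip(grp["weekday"], meal_ids))
            unknown = set(lunches) - set(WEEKDAYS[:5])
            if unknown:
                raise DatasetError(f"school {sch!r}: bad weekday(s) {sorted(unknown)}")
            if len(lunches) < 5:
                raise DatasetError(
                    f"school {sch!r}: dated menu has {len(lunches)} lunches, needs 5"
                )
            menus.append(
                SchoolMenu(
                    school=sch,
                    country=country,
                    week_start=_dt.date.fromisoformat(week),
                    lunches=lunches,
                )
            )
        else:
            menus.append(
                CafeteriaProposal(school=sch, country=country, lunches=tuple(meal_ids))
            )
    if school is None:
        return menus
    dated = [
        m
        for m in menus
        if isinstance(m, SchoolMenu)
        and m.school == school
        and (week_start is None or m.week_start == week_start)
    ]
    if dated:
        return dated[0]
    cafeterias = [
        m for m in menus if isinstance(m, CafeteriaProposal) and m.school == school
    ]
    if cafeterias:
        return cafeterias[0]
    return None


def write_school_menus(
    menus: list[SchoolMenu | CafeteriaProposal], path: str | Path
) -> None:
    rows = []
    for m in menus:
        if isinstance(m, SchoolMenu):
            for wd in WEEKDAYS[:5]:
                rows.append(
                    {
                        "school": m.school,
                        "country": m.country,
                        "week_start": m.week_start.isoformat(),
                        "weekday": wd,
                        "meal_id": m.lunches[wd],
                    }
                )
        else:
            for mid in m.lunches:
                rows.append(
                    {
                        "school": m.school,
                        "country": m.country,
                        "week_start": "",
                        "weekday": "",
                        "meal_id": mid,
                    }
                )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# weekly plan export

def validate_plan(
    plan: WeeklyPlan,
    dataset: Dataset,
    menu: SchoolMenu | None = None,
) -> None:
    """Re-check plan invariants; raise :class:`ModelError` on breach.

    Checked: every meal resolves, matches the plan's country and season and
    sits in its slot's type; school-provenance lunches match the menu
    verbatim; a milk-allergic owner's plan contains no dairy-flagged dish.
    """
    for i, day in enumerate(plan.days):
        for slot, assign in day.slots.items():
            meal = dataset.meals.get(assign.meal_id)
            if meal is None:
                raise ModelError(f"day {i} {slot}: meal {assign.meal_id} unresolved")
            if meal.type != slot and not (
                # the program snack may sit in either snack slot
                meal.program_snack
                and assign.provenance == "program_snack"
                and slot in ("morning_snack", "afternoon_snack")
            ):
                raise ModelError(
                    f"day {i} {slot}: meal {meal.id} has type {meal.type}"
                )
            if meal.country != plan.country:
                raise ModelError(
                    f"day {i} {slot}: meal {meal.id} is {meal.country}, "
                    f"plan is {plan.country}"
                )
            if plan.season not in meal.seasons and not meal.program_snack:
                raise ModelError(
                    f"day {i} {slot}: meal {meal.id} not offered in {plan.season}"
                )
            if plan.milk_allergy and dataset.meal_has_dairy(meal.id):
                raise ModelError(
                    f"day {i} {slot}: dairy meal {meal.id} in a milk-allergy plan"
                )
            if assign.provenance == "school":
                if menu is None:
                    raise ModelError(
                        "plan has school-provenance lunches but no menu was given"
                    )
                wd = WEEKDAYS[i]
                if slot != "lunch" or menu.lunches.get(wd) != meal.id:
                    raise ModelError(
                        f"day {i}: school lunch {meal.id} does not match the "
                        f"menu ({menu.lunches.get(wd)})"
                    )


def _plan_to_payload(plan: WeeklyPlan) -> dict:
    return {
        "schema_version": PLAN_SCHEMA_VERSION,
        "owner": plan.owner,
        "week_start": plan.week_start.isoformat(),
        "country": plan.country,
        "season": plan.season,
        "age_group": plan.age_group,
        "milk_allergy": plan.milk_allergy,
        "seed": plan.seed,
        "feasible": plan.feasible,
        "relaxations": list(plan.relaxations),
        "dropped_rules": list(plan.dropped_rules),
        "days": [
            {
                "date": day.date.isoformat(),
                "slots": {
                    slot: {"meal_id": a.meal_id, "provenance": a.provenance}
                    for slot, a in sorted(day.slots.items())
                },
            }
            for day in plan.days
        ],
    }


def write_weekly_plan(
    plan: WeeklyPlan,
    path: str | Path,
    dataset: Dataset | None = None,
    menu: SchoolMenu | None = None,
) -> None:
    """Export a plan as JSON; re-validates first when a dataset is given."""
    if dataset is not None:
        validate_plan(plan, dataset, menu=menu)
    Path(path).write_text(
        json.dumps(_plan_to_payload(plan), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def read_weekly_plan(path: str | Path) -> WeeklyPlan:
    p = json.loads(Path(path).read_text(encoding="utf-8"))
    days = tuple(
        DayPlan(
            date=_dt.date.fromisoformat(d["date"]),
            slots={
                slot: SlotAssignment(meal_id=s["meal_id"], provenance=s["provenance"])
                for slot, s in d["slots"].items()
            },
        )
        for d in p["days"]
    )
    return WeeklyPlan(
        owner=p["owner"],
        week_start=_dt.date.fromisoformat(p["week_start"]),
        country=p["country"],
        season=p["season"],
        days=days,
        relaxations=tuple(p.get("relaxations", ())),
        dropped_rules=tuple(p.get("dropped_rules", ())),
        feasible=p["feasible"],
        seed=p.get("seed", 0),
        age_group=p.get("age_group", "7-12"),
        milk_allergy=p.get("milk_allergy", False),
    )
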