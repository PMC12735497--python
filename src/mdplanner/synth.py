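"""Synthetic dataset, school-menu and family-profile generator.

Real meal/dish collections of this kind are built by nutritionist teams so
that complete, rule-satisfiable weekly menus exist for every family member
in every season.  The generator reproduces that *structure* rather than any
particular recipes: meals are built from archetypes (a breakfast carries a
dairy or plant-based beverage, a carbohydrate and a fruit; a lunch a
protein in rotation, a carbohydrate, a vegetable and a fruit; ...) so that
the child frequency rules are attainable by construction, while names,
calories and macro splits are randomized per seed.

The attainability knobs are explicit: ``flag_keep_probability`` can thin
out any food-group flag (a fruit probability of 0 yields a provably
infeasible dataset, used as the infeasibility fixture), and
``school_violation_fraction`` plants weekly-rule-violating school menus
(two red-meat lunches) to exercise the planner's budget clamping.
Everything is deterministic per seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .model import (
    COUNTRIES,
    SEASONS,
    WEEKDAYS,
    CafeteriaProposal,
    Dish,
    Meal,
    Nutrition,
    SchoolMenu,
)
from .profiles import AdultProfile, ChildProfile, Family, PAL_LEVELS

__all__ = [
    "SynthConfig",
    "generate_dataset",
    "generate_school_menus",
    "generate_family_profiles",
]

#: kcal per meal by type; spans realistic interquartile spreads of curated
#: Mediterranean meal collections.
DEFAULT_KCAL_RANGES: dict[str, tuple[float, float]] = {
    "breakfast": (250.0, 650.0),
    "morning_snack": (100.0, 350.0),
    "lunch": (450.0, 1000.0),
    "afternoon_snack": (100.0, 350.0),
    "dinner": (400.0, 900.0),
}

#: Sedentary through extra active; most adults sit at the low end.
PAL_WEIGHTS = (0.30, 0.35, 0.25, 0.07, 0.03)

#: Lunch/dinner protein rotations; each entry is the food-group flags of the
#: protein dish of one archetype.
_LUNCH_PROTEINS = [
    ("chickpeas",),
    ("lentils",),
    ("white_red_beans",),
    ("other_pulses",),
    ("fish_seafood",),
    ("fish_seafood",),
    ("chicken",),
    ("turkey",),
    ("red_meat",),
    ("eggs",),
    ("processed_meat",),
    ("fish_seafood", "eggs"),
]
_DINNER_PROTEINS = [
    ("fish_seafood",),
    ("eggs",),
    ("chickpeas",),
    ("lentils",),
    ("cheese",),
    ("cheese",),
    ("chicken",),
    ("white_red_beans",),
    ("other_pulses",),
    ("fish_seafood",),
    ("eggs",),
    ("rabbit",),
]
_LUNCH_CARBS = [("pasta",), ("rice",), ("bread",), ("pasta",), ("tubers",), ("bread",)]
_DINNER_CARBS = [("tubers",), ("bread",), ("pasta",), ("rice",), ("bread",), ("cereals",)]
_VEG_COLOR_CYCLE = ("green", "red", "white", "yellow", "multicolor", "purple")

_FRUITS = ("Apple", "Pear", "Orange", "Banana", "Grapes", "Kiwi", "Melon", "Plum")
_ADJ = ("Baked", "Grilled", "Stewed", "Roasted", "Steamed", "Braised")


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_breakfasts: int = 6
    n_morning_snacks: int = 5
    n_lunches: int = 12
    n_afternoon_snacks: int = 5
    n_dinners: int = 12
    n_plant_breakfasts: int = 4
    n_plant_afternoon_snacks: int = 4
    kcal_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_KCAL_RANGES)
    )
    #: group -> probability of *keeping* an archetype flag (default 1.0)
    flag_keep_probability: dict[str, float] = field(default_factory=dict)
    countries: tuple[str, ...] = COUNTRIES
    n_schools: int = 2
    n_families: int = 32
    allergy_rate: float = 0.1
    snack_rate: float = 0.5
    school_violation_fraction: float = 0.0
    protein_kcal_share: tuple[float, float] = (0.13, 0.21)
    fat_kcal_share: tuple[float, float] = (0.24, 0.40)

    def __post_init__(self) -> None:
        for g, p in self.flag_keep_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flag probability for {g!r} must be in [0,1]")
        for t, (lo, hi) in self.kcal_ranges.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad kcal range for {t!r}")


class _Builder:
    def __init__(self, config: SynthConfig, rng: np.random.Generator) -> None:
        self.cfg = config
        self.rng = rng
        self.dishes: dict[int, Dish] = {}
        self.meals: dict[int, Meal] = {}
        self._dish_id = 0
        self._meal_id = 1000

    def _keep(self, groups: tuple[str, ...]) -> frozenset[str]:
        kept = []
        for g in groups:
            p = self.cfg.flag_keep_probability.get(g, 1.0)
            if p >= 1.0 or self.rng.random() < p:
                kept.append(g)
        return frozenset(kept)

    def _ingredients(self, name: str, grams: float):
        # age-group gram scaling mirrors standard portion-size tables:
        # smaller children get smaller portions, adolescents adult-sized ones
        scale = {"3-6": 0.6, "7-12": 0.8, "13-15": 1.0, "16-18": 1.0, "adult": 1.0}
        return {
            age: ((name, round(grams * s, 1)),) for age, s in scale.items()
        }

    def add_dish(
        self,
        name: str,
        groups: tuple[str, ...],
        kcal: float,
        color: str | None = None,
        role: str = "unspecified",
        fruit_salad: bool = False,
    ) -> int:
        self._dish_id += 1
        p_share = self.rng.uniform(*self.cfg.protein_kcal_share)
        f_share = self.rng.uniform(*self.cfg.fat_kcal_share)
        kept = self._keep(groups)
        colors = frozenset({color}) if color and kept & {"raw_vegetables", "cooked_vegetables"} else frozenset()
        dish = Dish(
            id=self._dish_id,
            name=name,
            groups=kept,
            colors=colors,
            nutrition=Nutrition(
                kcal=round(kcal, 2),
                protein_g=round(kcal * p_share / 4.0, 2),
                fat_g=round(kcal * f_share / 9.0, 2),
                carbs_g=round(kcal * max(0.0, 1 - p_share - f_share) / 4.0, 2),
            ),
            ingredients=self._ingredients(name, grams=float(self.rng.integers(40, 220))),
            recipe=f"Prepare {name.lower()}.",
            tip="Prefer seasonal, local produce.",
            role=role,
            fruit_salad=fruit_salad,
        )
        self.dishes[dish.id] = dish
        return dish.id

    def add_meal(
        self,
        name: str,
        type_: str,
        country: str,
        dish_ids: tuple[int, ...],
        program_snack: bool = False,
    ) -> int:
        self._meal_id += 1
        meal = Meal(
            id=self._meal_id,
            name=name,
            type=type_,
            country=country,
            seasons=frozenset(SEASONS),
            dish_ids=dish_ids,
            audience="both",
            program_snack=program_snack,
        )
        self.meals[meal.id] = meal
        return meal.id

    def _split_kcal(self, type_: str, n_parts: int) -> list[float]:
        lo, hi = self.cfg.kcal_ranges[type_]
        total = self.rng.uniform(lo, hi)
        weights = self.rng.dirichlet(np.ones(n_parts) * 3.0)
        return [total * w for w in weights]

    # -- meal archetypes -------------------------------------------------

    def breakfast(self, country: str, i: int, plant: bool) -> int:
        kcals = self._split_kcal("breakfast", 3)
        bev = "plant_beverage_yogurt" if plant else "milk_yogurt"
        carb = ("bread",) if i % 2 == 0 else ("cereals",)
        fruit = _FRUITS[i % len(_FRUITS)]
        d1 = self.add_dish(f"{'Soy drink' if plant else 'Milk'} {country} b{i}", (bev,), kcals[0])
        d2 = self.add_dish(
            f"{'Wholegrain bread' if carb == ('bread',) else 'Oat porridge'} b{i}",
            carb,
            kcals[1],
        )
        d3 = self.add_dish(f"{fruit} (breakfast {i})", ("fruit",), kcals[2])
        label = "plant " if plant else ""
        return self.add_meal(
            f"{label}breakfast {i} ({country})", "breakfast", country, (d1, d2, d3)
        )

    def snack(self, country: str, i: int, slot: str, plant: bool = False) -> int:
        if slot == "morning_snack":
            # odd snacks add a yogurt so the weekly dairy minimum keeps slack
            with_dairy = i % 2 == 1
            kcals = self._split_kcal(slot, 1 + int(with_dairy or plant))
            fs = i % 4 == 3  # every fourth snack is a fruit salad
            d = self.add_dish(
                f"{'Fruit salad' if fs else _FRUITS[(i + 3) % len(_FRUITS)]} ms{i} ({country})",
                ("fruit",),
                kcals[0],
                fruit_salad=fs,
            )
            ids = (d,)
            if plant:
                ids += (
                    self.add_dish(
                        f"Plant yogurt ms{i} ({country})",
                        ("plant_beverage_yogurt",),
                        kcals[1],
                    ),
                )
            elif with_dairy:
                ids += (
                    self.add_dish(
                        f"Yogurt ms{i} ({country})", ("milk_yogurt",), kcals[1]
                    ),
                )
            label = "plant " if plant else ""
            return self.add_meal(
                f"{label}morning snack {i} ({country})", slot, country, ids
            )
        kcals = self._split_kcal(slot, 2)
        bev = "plant_beverage_yogurt" if plant else "milk_yogurt"
        d1 = self.add_dish(
            f"{'Plant yogurt' if plant else 'Yogurt'} as{i} ({country})", (bev,), kcals[0]
        )
        d2 = self.add_dish(f"{_FRUITS[(i + 5) % len(_FRUITS)]} as{i}", ("fruit",), kcals[1])
        label = "plant " if plant else ""
        return self.add_meal(
            f"{label}afternoon snack {i} ({country})", slot, country, (d1, d2)
        )

    def main_meal(self, country: str, i: int, type_: str) -> int:
        proteins = _LUNCH_PROTEINS if type_ == "lunch" else _DINNER_PROTEINS
        carbs = _LUNCH_CARBS if type_ == "lunch" else _DINNER_CARBS
        protein = proteins[i % len(proteins)]
        carb = carbs[i % len(carbs)]
        with_fruit = type_ == "lunch"
        n = 3 + int(with_fruit)
        kcals = self._split_kcal(type_, n)
        adj = _ADJ[i % len(_ADJ)]
        d_protein = self.add_dish(
            f"{adj} {'/'.join(protein)} {type_} {i} ({country})",
            protein,
            kcals[0],
            role="main",
        )
        d_carb = self.add_dish(
            f"{'/'.join(carb)} side {type_} {i} ({country})", carb, kcals[1], role="side"
        )
        veg_kind = "raw_vegetables" if i % 2 == 0 else "cooked_vegetables"
        d_veg = self.add_dish(
            f"{'Salad' if veg_kind == 'raw_vegetables' else 'Sauteed vegetables'} {type_} {i} ({country})",
            (veg_kind,),
            kcals[2],
            color=_VEG_COLOR_CYCLE[i % len(_VEG_COLOR_CYCLE)],
            role="side",
        )
        ids = [d_protein, d_carb, d_veg]
        if with_fruit:
            ids.append(
                self.add_dish(f"{_FRUITS[i % len(_FRUITS)]} {type_} {i}", ("fruit",), kcals[3])
            )
        return self.add_meal(f"{type_} {i} ({country})", type_, country, tuple(ids))

    def program_snack(self, country: str) -> int:
        d = self.add_dish(
            f"Healthy project snack ({country})", ("nuts", "cereals"), 180.0
        )
        return self.add_meal(
            f"program snack ({country})", "afternoon_snack", country, (d,),
            program_snack=True,
        )


def generate_dataset(config: SynthConfig | None = None, seed: int = 0) -> Dataset:
    """Generate a referentially intact dataset attaining the child rules.

    Deterministic per seed; each meal owns its dishes so the weekly dish-ID
    repetition cap never binds through shared components.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    b = _Builder(cfg, rng)
    for country in cfg.countries:
        for i in range(cfg.n_breakfasts):
            b.breakfast(country, i, plant=False)
        for i in range(cfg.n_plant_breakfasts):
            b.breakfast(country, 100 + i, plant=True)
        for i in range(cfg.n_morning_snacks):
            b.snack(country, i, "morning_snack")
        for i in range(2):
            b.snack(country, 100 + i, "morning_snack", plant=True)
        for i in range(cfg.n_afternoon_snacks):
            b.snack(country, i, "afternoon_snack", plant=False)
        for i in range(cfg.n_plant_afternoon_snacks):
            b.snack(country, 100 + i, "afternoon_snack", plant=True)
        for i in range(cfg.n_lunches):
            b.main_meal(country, i, "lunch")
        for i in range(cfg.n_dinners):
            b.main_meal(country, i, "dinner")
        # plant-cheese dinners for milk-allergic weeks
        for i in range(2):
            kcals = b._split_kcal("dinner", 3)
            d1 = b.add_dish(f"Plant cheese platter {i} ({country})", ("plant_cheese",), kcals[0])
            d2 = b.add_dish(f"Bread side pc{i} ({country})", ("bread",), kcals[1], role="side")
            d3 = b.add_dish(
                f"Garden salad pc{i} ({country})",
                ("raw_vegetables",),
                kcals[2],
                color=_VEG_COLOR_CYCLE[i],
                role="side",
            )
            b.add_meal(f"plant dinner {i} ({country})", "dinner", country, (d1, d2, d3))
        b.program_snack(country)
    return Dataset(dishes=b.dishes, meals=b.meals)


def generate_school_menus(
    dataset: Dataset,
    config: SynthConfig | None = None,
    seed: int = 0,
    week_start: _dt.date = _dt.date(2025, 9, 8),
    cafeteria: bool = False,
) -> list[SchoolMenu | CafeteriaProposal]:
    """Dated menus per school (one per country round-robin), a configurable
    fraction of which deliberately holds two red-meat lunches to exercise
    the planner's budget clamping; optionally cafeteria proposals instead."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    menus: list[SchoolMenu | CafeteriaProposal] = []
    for s in range(cfg.n_schools):
        country = cfg.countries[s % len(cfg.countries)]
        lunches = dataset.meals_for(type="lunch", country=country, audience="child")
        if len(lunches) < 5:
            raise ValueError(f"dataset has too few lunches for {country}")
        name = f"school-{s}"
        if cafeteria:
            pool = rng.choice(lunches, size=min(6, len(lunches)), replace=False)
            menus.append(
                CafeteriaProposal(school=name, country=country, lunches=tuple(int(x) for x in pool))
            )
            continue
        chosen = [int(x) for x in rng.choice(lunches, size=5, replace=False)]
        if rng.random() < cfg.school_violation_fraction:
            red = [
                mid
                for mid in lunches
                if any(
                    "red_meat" in d.expanded_groups
                    for d in dataset.meal_dishes(mid)
                )
            ]
            if red:
                chosen[0] = red[0]
                chosen[2] = red[0]  # two red-meat lunches, non-adjacent days
        menus.append(
            SchoolMenu(
                school=name,
                country=country,
                week_start=week_start,
                lunches=dict(zip(WEEKDAYS[:5], chosen)),
            )
        )
    return menus


def generate_family_profiles(
    config: SynthConfig | None = None, seed: int = 0
) -> list[Family]:
    """Plausible families: 1-2 adults and 1-3 children each, PAL drawn from
    the five listed levels, allergy/snack flags at the configured rates."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    families = []
    for f in range(cfg.n_families):
        country = cfg.countries[f % len(cfg.countries)]
        n_adults = int(rng.integers(1, 3))
        n_children = int(rng.integers(1, 4))
        adults = []
        for a in range(n_adults):
            sex = "female" if rng.random() < 0.5 else "male"
            height = float(rng.normal(1.64 if sex == "female" else 1.76, 0.06))
            bmi = float(rng.uniform(19.0, 29.0))
            adults.append(
                AdultProfile(
                    name=f"family{f}-adult{a}",
                    sex=sex,
                    birth_year=int(rng.integers(1970, 1996)),
                    height_m=round(height, 2),
                    weight_kg=round(bmi * height**2, 1),
                    pal=float(rng.choice(PAL_LEVELS, p=PAL_WEIGHTS)),
                    milk_allergy=bool(rng.random() < cfg.allergy_rate),
                    country=country,
                )
            )
        children = []
        for c in range(n_children):
            age_group = str(rng.choice(["3-6", "7-12", "7-12", "13-15", "16-18"]))
            school_lunch = age_group in ("3-6", "7-12") and rng.random() < 0.7
            children.append(
                ChildProfile(
                    name=f"family{f}-child{c}",
                    age_group=age_group,
                    school=f"school-{int(rng.integers(0, cfg.n_schools))}"
                    if school_lunch
                    else None,
                    school_lunch=school_lunch,
                    milk_allergy=bool(rng.random() < cfg.allergy_rate),
                    snack=bool(rng.random() < cfg.snack_rate),
                    country=country,
                )
            )
        families.append(
            Family(name=f"family{f}", adults=tuple(adults), children=tuple(children))
        )
    return families
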