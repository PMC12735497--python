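import datetime as dt

import pytest

import mdplanner as mp
from mdplanner.model import Dish, Meal, Nutrition


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (both countries, all seasons)."""
    return mp.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def week_start():
    return dt.date(2025, 9, 8)  # a Monday


@pytest.fixture(scope="session")
def child_ruleset():
    return mp.load_ruleset("child")


@pytest.fixture(scope="session")
def adult_ruleset():
    return mp.load_ruleset("adult")


@pytest.fixture(scope="session")
def planner(dataset):
    return mp.ChildPlanner(dataset)


def build_dataset(meal_specs, country="Spain", meal_type=None, nutrition=True):
    """Tiny dataset from (meal_type, [flag sets or dicts]) specs.

    ``meal_specs`` is a list of (type, [dish spec, ...]) tuples; a dish
    spec is either a set of food-group flags or a dict with keys
    ``groups``, ``colors``, ``role``, ``fruit_salad``, ``kcal`` etc.
    Returns (Dataset, [meal ids in order]).
    """
    dishes, meals = {}, {}
    did, mid = 0, 100
    ids = []
    for mtype, dish_specs in meal_specs:
        dish_ids = []
        for spec in dish_specs:
            did += 1
            if isinstance(spec, (set, frozenset)):
                spec = {"groups": spec}
            nut = (
                Nutrition(
                    kcal=spec.get("kcal", 100.0),
                    fat_g=spec.get("fat_g", 3.0),
                    protein_g=spec.get("protein_g", 4.0),
                    carbs_g=spec.get("carbs_g", 12.0),
                )
                if nutrition
                else None
            )
            dishes[did] = Dish(
                id=did,
                name=spec.get("name", f"dish {did}"),
                groups=frozenset(spec.get("groups", ())),
                colors=frozenset(spec.get("colors", ())),
                nutrition=nut,
                role=spec.get("role", "unspecified"),
                fruit_salad=spec.get("fruit_salad", False),
                ingredients=spec.get("ingredients", {}),
            )
            dish_ids.append(did)
        mid += 1
        meals[mid] = Meal(
            id=mid,
            name=f"meal {mid}",
            type=mtype,
            country=country,
            seasons=frozenset({"winter", "spring", "summer", "autumn"}),
            dish_ids=tuple(dish_ids),
            audience="both" if nutrition else "child",
        )
        ids.append(mid)
    return mp.Dataset(dishes=dishes, meals=meals), ids
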