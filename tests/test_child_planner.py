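"""Child weekly planner: solver behavior, relaxation ladder, oracle checks."""

import dataclasses
import itertools

import numpy as np
import pytest

import mdplanner as mp
from mdplanner.child_planner import (
    ChildPlanner,
    ChildWeekRequest,
    Instance,
    is_valid_assignment,
    relax_ladder,
    resolve_lunch_source,
    scale_for_adolescent,
    ingredient_portions,
)
from mdplanner.model import MEAL_TYPES, Dish, Meal, ModelError
from mdplanner.rules import (
    DROPPED,
    LESS_RESTRICTIVE,
    PREFERRED,
    Constraint,
    RuleFamily,
    RuleSet,
    count_portions,
)
from collections import Counter

from conftest import build_dataset


def state_of(planner, result):
    return {
        f.id: (
            LESS_RESTRICTIVE if f.id in result.relaxations
            else DROPPED if f.id in result.dropped
            else PREFERRED
        )
        for f in planner.ruleset.families
    }


def plan_day_meals(plan, dataset):
    return [
        [dataset.meals[day.slots[t].meal_id] for t in MEAL_TYPES]
        for day in plan.days
    ]


# ---------------------------------------------------------------------------
# oracle equivalence on toy instances

TOY_GROUPS = ["fruit", "raw_vegetables", "milk_yogurt", "bread", "fish_seafood", "eggs"]


def toy_instance(rng):
    """Random tiny instance + random toy ruleset, small enough to enumerate."""
    n_days = int(rng.integers(1, 3))
    max_pool = 3 if n_days == 1 else 2
    dishes, meals, pools = {}, {}, {}
    mid = 0
    for slot in MEAL_TYPES:
        ids = []
        for _ in range(int(rng.integers(1, max_pool + 1))):
            mid += 1
            flags = frozenset(g for g in TOY_GROUPS if rng.random() < 0.45)
            dishes[mid] = Dish(id=mid, name=f"d{mid}", groups=flags)
            meals[mid] = Meal(
                id=mid, name=f"m{mid}", type=slot, country="Spain",
                seasons=frozenset({"autumn"}), dish_ids=(mid,), audience="child",
            )
            ids.append(mid)
        pools[slot] = ids
    dataset = mp.Dataset(dishes=dishes, meals=meals)

    families = []
    for i, g in enumerate(rng.choice(TOY_GROUPS, size=3, replace=False)):
        scope = "daily" if rng.random() < 0.5 else "weekly"
        if rng.random() < 0.5:
            c = Constraint(keys=(str(g),), max=int(rng.integers(0, 3)))
        else:
            c = Constraint(keys=(str(g),), min=int(rng.integers(1, 3)))
        families.append(
            RuleFamily(id=f"r{i}_{g}", scope=scope, preferred=(c,))
        )
    ruleset = RuleSet(version=1, audience="child", families=tuple(families))
    return dataset, pools, ruleset, n_days


def brute_force_feasible(dataset, pools, ruleset, n_days):
    slots = [(d, s) for d in range(n_days) for s in MEAL_TYPES]
    for combo in itertools.product(*[pools[s] for _, s in slots]):
        day_meals = [
            [dataset.meals[combo[i]] for i, (d, _) in enumerate(slots) if d == day]
            for day in range(n_days)
        ]
        if is_valid_assignment(day_meals, dataset, ruleset):
            return True
    return False


class TestOracleEquivalence:
    @pytest.mark.parametrize("block", range(4))
    def test_solver_matches_exhaustive_enumeration(self, block):
        """On enumerable instances the solver's feasibility verdict equals
        brute force, and returned assignments re-validate cleanly."""
        rng = np.random.default_rng(1000 + block)
        agree_feasible = agree_infeasible = 0
        for k in range(50):
            dataset, pools, ruleset, n_days = toy_instance(rng)
            planner = ChildPlanner(dataset, ruleset=ruleset)
            inst = Instance(n_days=n_days, pools=pools)
            assignment, _, _ = planner.solve_instance(inst, seed=int(rng.integers(2**31)))
            expected = brute_force_feasible(dataset, pools, ruleset, n_days)
            assert (assignment is not None) == expected, f"instance {block}/{k}"
            if assignment is not None:
                day_meals = [
                    [dataset.meals[assignment[(d, s)][0]] for s in MEAL_TYPES]
                    for d in range(n_days)
                ]
                assert is_valid_assignment(day_meals, dataset, ruleset)
                agree_feasible += 1
            else:
                agree_infeasible += 1
        # the mix must exercise both outcomes
        assert agree_feasible and agree_infeasible


class TestSolveWeek:
    def test_home_mode_plan_passes_independent_evaluation(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", seed=4)
        )
        assert res.feasible
        assert is_valid_assignment(
            plan_day_meals(res.plan, dataset), dataset, planner.ruleset,
            state_of(planner, res),
        )

    def test_seed_determinism_byte_identical_export(self, dataset, week_start, tmp_path):
        req = ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                               season="autumn", seed=42)
        for i in (0, 1):
            planner = ChildPlanner(dataset)
            res = planner.solve_week(req)
            mp.write_weekly_plan(res.plan, tmp_path / f"p{i}.json", dataset=dataset)
        assert (tmp_path / "p0.json").read_bytes() == (tmp_path / "p1.json").read_bytes()

    def test_no_fruit_dataset_infeasible_names_fruit_rule(self, week_start):
        cfg = mp.SynthConfig(flag_keep_probability={"fruit": 0.0})
        ds = mp.generate_dataset(cfg, seed=1)
        res = ChildPlanner(ds).solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", seed=1)
        )
        assert not res.feasible
        assert any("fruit" in r for r in res.failed_rules)

    def test_allergy_plans_contain_no_dairy_flagged_dish(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", milk_allergy=True, seed=5)
        )
        assert res.feasible
        for day in res.plan.days:
            for a in day.slots.values():
                assert not dataset.meal_has_dairy(a.meal_id)

    def test_snack_weeks_carry_exactly_three_program_snacks(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", snack=True, seed=6)
        )
        assert res.feasible
        snack_days = [
            d for d, day in enumerate(res.plan.days)
            for slot, a in day.slots.items()
            if a.provenance == "program_snack"
        ]
        assert len(snack_days) == 3
        assert len(set(snack_days)) == 3  # distinct days
        for day in res.plan.days:
            for slot, a in day.slots.items():
                if a.provenance == "program_snack":
                    assert slot in ("morning_snack", "afternoon_snack")

    def test_meal_repetition_within_cap_and_not_consecutive(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Türkiye",
                             season="spring", seed=8)
        )
        assert res.feasible
        seen: dict[int, list[int]] = {}
        for d, day in enumerate(res.plan.days):
            for a in day.slots.values():
                if not dataset.meals[a.meal_id].program_snack:
                    seen.setdefault(a.meal_id, []).append(d)
        for mid, days in seen.items():
            assert len(days) <= 2
            if len(days) == 2:
                assert abs(days[0] - days[1]) > 1


class TestSchoolModes:
    def test_dated_menu_pins_five_weekday_lunches(self, planner, dataset, week_start):
        menus = mp.generate_school_menus(dataset, mp.SynthConfig(), seed=2,
                                         week_start=week_start)
        menu = menus[0]
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country=menu.country,
                             season="autumn", school=menu.school, seed=2),
            menus,
        )
        assert res.feasible and res.lunch_source == "school"
        from mdplanner.model import WEEKDAYS
        for i, wd in enumerate(WEEKDAYS[:5]):
            slot = res.plan.days[i].slots["lunch"]
            assert slot.meal_id == menu.lunches[wd]
            assert slot.provenance == "school"

    def test_red_meat_heavy_menu_clamps_generated_meals(self, planner, dataset, week_start):
        cfg = mp.SynthConfig(school_violation_fraction=1.0)
        menus = mp.generate_school_menus(dataset, cfg, seed=2, week_start=week_start)
        menu = menus[0]
        fixed_red = sum(
            1
            for mid in menu.lunches.values()
            for d in dataset.meal_dishes(mid)
            if "red_meat" in d.expanded_groups
        )
        assert fixed_red >= 2  # the planted violation
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country=menu.country,
                             season="autumn", school=menu.school, seed=3),
            menus,
        )
        assert res.feasible
        generated_red = sum(
            1
            for day in res.plan.days
            for a in day.slots.values()
            if a.provenance != "school"
            for d in dataset.meal_dishes(a.meal_id)
            if d.expanded_groups & {"red_meat", "processed_meat"}
        )
        assert generated_red == 0

    def test_cafeteria_pool_fills_weekday_lunches(self, planner, dataset, week_start):
        cafs = mp.generate_school_menus(dataset, mp.SynthConfig(), seed=3, cafeteria=True)
        caf = cafs[0]
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country=caf.country,
                             season="autumn", school=caf.school, seed=4),
            cafs,
        )
        assert res.feasible and res.lunch_source == "cafeteria"
        for i in range(5):
            slot = res.plan.days[i].slots["lunch"]
            assert slot.meal_id in caf.lunches
            assert slot.provenance == "cafeteria"

    def test_unknown_school_falls_back_to_home_mode(self, week_start):
        req = ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                               season="autumn", school="atlantis", seed=1)
        source, menu = resolve_lunch_source(req, [])
        assert source == "home" and menu is None


class TestRelaxationLadder:
    def test_fixpoint_when_everything_relaxed(self, child_ruleset):
        state = {
            f.id: (DROPPED if f.droppable else
                   LESS_RESTRICTIVE if f.relaxable else PREFERRED)
            for f in child_ruleset.families
        }
        new, actions = relax_ladder(child_ruleset, state, Counter({"wk_fruit": 5}))
        assert actions == [] and new == state

    def test_limiting_cereals_rule_switched_to_less_restrictive(self, child_ruleset):
        state = child_ruleset.default_state()
        new, actions = relax_ladder(child_ruleset, state, Counter({"d_cereals": 9}))
        assert ("d_cereals", LESS_RESTRICTIVE) in actions
        assert new["d_cereals"] == LESS_RESTRICTIVE
        assert len(actions) <= 2

    def test_color_pressure_drops_all_color_rules(self, child_ruleset):
        state = child_ruleset.default_state()
        new, actions = relax_ladder(child_ruleset, state, Counter({"d_color_green": 3}))
        dropped = {rid for rid, kind in actions if kind == DROPPED}
        assert dropped == {
            f.id for f in child_ruleset.families if f.drop_group == "colors"
        }

    def test_monotone_relaxation_never_tightens(self, child_ruleset):
        """Walking the whole ladder only ever widens or removes bounds."""
        state = child_ruleset.default_state()
        rank = {PREFERRED: 0, LESS_RESTRICTIVE: 1, DROPPED: 2}
        for _ in range(40):
            new, actions = relax_ladder(child_ruleset, state, Counter())
            if not actions:
                break
            for rid in child_ruleset.by_id:
                assert rank[new.get(rid, PREFERRED)] >= rank[state.get(rid, PREFERRED)]
            state = new
        else:
            pytest.fail("ladder did not terminate")


class TestAdolescentScaling:
    def test_portions_follow_age_group_columns(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", seed=10, age_group="7-12")
        )
        scaled = scale_for_adolescent(res.plan, "13-15", dataset)
        assert scaled.age_group == "13-15"
        assert [d.meal_ids() for d in scaled.days] == [d.meal_ids() for d in res.plan.days]
        base = ingredient_portions(res.plan, dataset)
        teen = ingredient_portions(scaled, dataset)
        bumps = [
            (g2 > g1)
            for d in base
            for did in base[d]
            for (_, g1), (_, g2) in zip(base[d][did], teen[d][did])
        ]
        # synthetic portions scale 0.8 -> 1.0 from 7-12 to 13-15
        assert all(bumps) and bumps

    def test_same_age_group_is_identity(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", seed=10, age_group="7-12")
        )
        assert scale_for_adolescent(res.plan, "7-12", dataset) is res.plan

    def test_missing_age_column_names_dish(self, planner, dataset, week_start):
        res = planner.solve_week(
            ChildWeekRequest(owner="k", week_start=week_start, country="Spain",
                             season="autumn", seed=10)
        )
        # strip the 16-18 ingredient sets from one dish in the plan
        some_meal = res.plan.days[0].slots["lunch"].meal_id
        dish = dataset.meal_dishes(some_meal)[0]
        stripped = dataclasses.replace(
            dish,
            ingredients={k: v for k, v in dish.ingredients.items() if k != "16-18"},
        )
        dishes = dict(dataset.dishes)
        dishes[dish.id] = stripped
        broken = mp.Dataset(dishes=dishes, meals=dict(dataset.meals))
        with pytest.raises(ModelError, match=str(dish.id)):
            scale_for_adolescent(res.plan, "16-18", broken)
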