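"""Child weekly menu planner: constraint satisfaction over 7 days x 5 slots.

The week is a grid of 35 slot variables (Mon-Sun x breakfast, morning
snack, lunch, afternoon snack, dinner).  School-menu lunches pin the five
weekday lunch slots; cafeteria proposals supply an unordered pool for them;
in home mode all lunches are free.  The solver backtracks over slots in
(day, slot-type) order with forward checking against the remaining
daily/weekly food-group budgets, candidate order being a seeded shuffle.

School lunches that already break a rule are accepted, never altered: the
corresponding budget is clamped so the *generated* meals contribute zero
further portions of the offending category, and the excess surfaces only in
the audit report.

When no feasible assignment exists under the preferred rules, a relaxation
ladder first drops droppable rule groups tied to the limiting category
(vegetable colors, then pulse sub-categories, then white-meat
sub-categories), then switches the limiting rules to their less-restrictive
variants, one or two per step, until feasible or exhausted.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Dataset
from .model import (
    MEAL_TYPES,
    SNACK_SLOTS,
    CafeteriaProposal,
    DayPlan,
    Meal,
    ModelError,
    SchoolMenu,
    SlotAssignment,
    WeeklyPlan,
)
from .rules import (
    DROPPED,
    LESS_RESTRICTIVE,
    PREFERRED,
    RuleSet,
    RuleState,
    count_portions,
    evaluate_rules,
    evaluate_structure,
    load_ruleset,
)

log = logging.getLogger(__name__)

__all__ = [
    "ChildWeekRequest",
    "ChildPlanResult",
    "Instance",
    "ChildPlanner",
    "resolve_lunch_source",
    "relax_ladder",
    "is_valid_assignment",
    "scale_for_adolescent",
    "ingredient_portions",
]

#: Order in which droppable rule groups are excluded by the ladder.
DROP_ORDER = ("colors", "pulse_subcategories", "white_meat_subcategories")


@dataclass(frozen=True)
class ChildWeekRequest:
    owner: str
    week_start: _dt.date
    country: str
    season: str
    school: str | None = None
    milk_allergy: bool = False
    snack: bool = False
    seed: int = 0
    age_group: str = "7-12"


@dataclass
class ChildPlanResult:
    plan: WeeklyPlan | None
    feasible: bool
    relaxations: tuple[str, ...]
    dropped: tuple[str, ...]
    failed_rules: tuple[str, ...] = ()
    backtracks: int = 0
    lunch_source: str = "home"


@dataclass
class Instance:
    """A solvable instance: pools per slot type, optional pinned slots.

    ``n_days`` below 7 yields toy instances used for exhaustive-enumeration
    cross-checks; production planning always uses 7.
    """

    n_days: int
    pools: dict[str, list[int]]  # slot type -> candidate meal ids
    pinned: dict[tuple[int, str], tuple[int, str]] = field(default_factory=dict)
    # (day, slot) -> (meal id, provenance)
    milk_allergy: bool = False


def resolve_lunch_source(
    request: ChildWeekRequest,
    menus: list[SchoolMenu | CafeteriaProposal] | None,
) -> tuple[str, SchoolMenu | CafeteriaProposal | None]:
    """Pick the lunch source: dated school menu, cafeteria pool, or home.

    A dated menu matching the school and week pins the weekday lunches; an
    undated cafeteria proposal supplies a value pool; otherwise home mode
    (with a warning if a school was named but nothing matched).
    """
    if request.school and menus:
        for m in menus:
            if (
                isinstance(m, SchoolMenu)
                and m.school == request.school
                and m.week_start == request.week_start
            ):
                return "school", m
        for m in menus:
            if isinstance(m, CafeteriaProposal) and m.school == request.school:
                return "cafeteria", m
    if request.school:
        log.warning(
            "school %r named but no menu or cafeteria proposal found; "
            "falling back to home mode",
            request.school,
        )
    return "home", None


# ---------------------------------------------------------------------------
# validity semantics (shared by solver clamps, oracle tests and the auditor)

def is_valid_assignment(
    day_meals: list[list[Meal]],
    dataset: Dataset,
    ruleset: RuleSet,
    state: RuleState | None = None,
    milk_allergy: bool = False,
    fixed_day_meals: list[list[Meal]] | None = None,
) -> bool:
    """True iff the assignment satisfies the active ruleset.

    With ``fixed_day_meals`` (school/cafeteria lunches), a *maximum* bound
    already exceeded by the fixed meals alone is tolerated as long as the
    generated meals add nothing on top of the clamped budget; minima and
    every other violation still count.
    """
    if state is None:
        state = ruleset.default_state()
    day_ledgers = [count_portions(meals, dataset) for meals in day_meals]
    week = count_portions([m for meals in day_meals for m in meals], dataset)
    violations = evaluate_rules(day_ledgers, week, ruleset, state, milk_allergy)
    if fixed_day_meals is not None:
        fixed_days = [count_portions(meals, dataset) for meals in fixed_day_meals]
        fixed_week = count_portions(
            [m for meals in fixed_day_meals for m in meals], dataset
        )
        kept = []
        for v in violations:
            if v.direction == "below" or v.max is None:
                kept.append(v)
                continue
            if v.horizon == "week":
                full_ledger, fixed_ledger = week, fixed_week
            else:
                d = int(v.horizon.split(":")[1])
                full_ledger, fixed_ledger = day_ledgers[d], fixed_days[d]
            fam = ruleset.by_id[v.rule_id]
            tolerated = True
            for c in fam.constraints(state.get(v.rule_id, PREFERRED), milk_allergy):
                if c.max is None:
                    continue
                total = c.observed(full_ledger)
                if total <= c.max:
                    continue
                fixed_obs = c.observed(fixed_ledger)
                # excess acceptable only if it comes entirely from fixed meals
                if not (fixed_obs > c.max and total == fixed_obs):
                    tolerated = False
            if not tolerated:
                kept.append(v)
        violations = kept
    if violations:
        return False
    return not evaluate_structure(day_meals, dataset, ruleset, adult=False)


# ---------------------------------------------------------------------------
# relaxation ladder

def relax_ladder(
    ruleset: RuleSet,
    state: RuleState,
    evidence: Counter,
) -> tuple[RuleState, list[tuple[str, str]]]:
    """One ladder step: return the next state and the actions taken.

    Actions are ``(rule_id, "dropped" | "less_restrictive")`` pairs.  At the
    fixpoint (everything already relaxed) the state is returned unchanged
    with an empty action list.
    """
    state = dict(state)
    limiting = [rid for rid, _ in evidence.most_common() if rid in ruleset.by_id]

    # 1. drop a droppable group tied to the limiting categories
    for group in DROP_ORDER:
        members = [f.id for f in ruleset.families if f.drop_group == group]
        if not members or all(state.get(m) == DROPPED for m in members):
            continue
        if any(rid in members for rid in limiting):
            actions = []
            for m in members:
                if state.get(m) != DROPPED:
                    state[m] = DROPPED
                    actions.append((m, DROPPED))
            return state, actions

    # 2. switch limiting relaxable rules to less-restrictive, <=2 per step
    actions = []
    for rid in limiting:
        fam = ruleset.by_id[rid]
        if fam.relaxable and state.get(rid) == PREFERRED:
            state[rid] = LESS_RESTRICTIVE
            actions.append((rid, LESS_RESTRICTIVE))
            if len(actions) == 2:
                return state, actions
    if actions:
        return state, actions

    # 3. fallback when the evidence names nothing actionable: drop remaining
    #    droppable groups in order, then relax remaining relaxable families
    for group in DROP_ORDER:
        members = [f.id for f in ruleset.families if f.drop_group == group]
        todo = [m for m in members if state.get(m) != DROPPED]
        if todo:
            for m in todo:
                state[m] = DROPPED
            return state, [(m, DROPPED) for m in todo]
    for fam in ruleset.families:
        if fam.relaxable and state.get(fam.id) == PREFERRED:
            state[fam.id] = LESS_RESTRICTIVE
            actions.append((fam.id, LESS_RESTRICTIVE))
            if len(actions) == 2:
                break
    return state, actions


# ---------------------------------------------------------------------------
# the solver

_BIG = 10**6


class ChildPlanner:
    """Backtracking planner over the weekly slot grid.

    Parameters
    ----------
    dataset
        Loaded meal/dish dataset.
    ruleset
        Child frequency ruleset; defaults to the packaged one.
    backtrack_cap
        Backtracks allowed per ladder state before relaxing further.
    restart_backtracks
        Budget of one search run; a run cut off at this budget restarts
        with a fresh seeded candidate shuffle (within ``backtrack_cap``).
    snack_placement_tries
        Seeded placements of the 3 weekly program snacks attempted per
        ladder state before the ladder escalates.
    """

    def __init__(
        self,
        dataset: Dataset,
        ruleset: RuleSet | None = None,
        backtrack_cap: int = 50_000,
        restart_backtracks: int = 2_000,
        snack_placement_tries: int = 6,
    ) -> None:
        self.dataset = dataset
        self.ruleset = ruleset if ruleset is not None else load_ruleset("child")
        self.backtrack_cap = backtrack_cap
        self.restart_backtracks = restart_backtracks
        self.snack_placement_tries = snack_placement_tries
        self._compile_cache: dict = {}

    # -- public API ------------------------------------------------------

    def solve_week(
        self,
        request: ChildWeekRequest,
        menus: list[SchoolMenu | CafeteriaProposal] | None = None,
    ) -> ChildPlanResult:
        source, menu = resolve_lunch_source(request, menus)
        pools = self._build_pools(request, source, menu)
        pinned: dict[tuple[int, str], tuple[int, str]] = {}
        if source == "school":
            assert isinstance(menu, SchoolMenu)
            from .model import WEEKDAYS

            for i, wd in enumerate(WEEKDAYS[:5]):
                pinned[(i, "lunch")] = (menu.lunches[wd], "school")

        rng = np.random.default_rng(request.seed)
        snack_id = None
        if request.snack:
            snacks = self.dataset.program_snack_meals(request.country)
            if not snacks:
                raise ModelError(
                    "snack requested but the dataset has no program-snack meal "
                    f"for {request.country}"
                )
            snack_id = snacks[0]

        state = self.ruleset.default_state()
        relaxations: list[str] = []
        dropped: list[str] = []
        total_backtracks = 0
        evidence: Counter = Counter()

        while True:
            placements = self._snack_placements(rng, snack_id)
            for placement in placements:
                pin = dict(pinned)
                pin.update(placement)
                inst = Instance(
                    n_days=7,
                    pools=pools,
                    pinned=pin,
                    milk_allergy=request.milk_allergy,
                )
                assignment, ev, backtracks = self.solve_instance(
                    inst, state, seed=int(rng.integers(0, 2**31 - 1))
                )
                total_backtracks += backtracks
                evidence.update(ev)
                if assignment is not None:
                    plan = self._to_plan(request, assignment, relaxations, dropped)
                    return ChildPlanResult(
                        plan=plan,
                        feasible=True,
                        relaxations=tuple(relaxations),
                        dropped=tuple(dropped),
                        backtracks=total_backtracks,
                        lunch_source=source,
                    )
            new_state, actions = relax_ladder(self.ruleset, state, evidence)
            if not actions:
                failed = tuple(rid for rid, _ in evidence.most_common(5))
                return ChildPlanResult(
                    plan=None,
                    feasible=False,
                    relaxations=tuple(relaxations),
                    dropped=tuple(dropped),
                    failed_rules=failed,
                    backtracks=total_backtracks,
                    lunch_source=source,
                )
            for rid, kind in actions:
                (dropped if kind == DROPPED else relaxations).append(rid)
            log.info("relaxation ladder: %s", actions)
            state = new_state

    # -- internals -------------------------------------------------------

    def _build_pools(
        self,
        request: ChildWeekRequest,
        source: str,
        menu: SchoolMenu | CafeteriaProposal | None,
    ) -> dict[str, list[int]]:
        pools: dict[str, list[int]] = {}
        for slot in MEAL_TYPES:
            pools[slot] = self.dataset.meals_for(
                type=slot,
                country=request.country,
                season=request.season,
                audience="child",
                exclude_dairy=request.milk_allergy,
                include_program_snack=False,
            )
        if source == "cafeteria":
            assert isinstance(menu, CafeteriaProposal)
            pools = dict(pools)
            pools["weekday_lunch"] = list(menu.lunches)
        return pools

    def _snack_placements(self, rng, snack_id: int | None):
        """Seeded candidate placements of 3 weekly program snacks."""
        if snack_id is None:
            return [dict()]
        placements = []
        for _ in range(self.snack_placement_tries):
            days = sorted(rng.choice(7, size=3, replace=False).tolist())
            slots = rng.choice(len(SNACK_SLOTS), size=3).tolist()
            placements.append(
                {
                    (d, SNACK_SLOTS[s]): (snack_id, "program_snack")
                    for d, s in zip(days, slots)
                }
            )
        return placements

    def solve_instance(
        self,
        inst: Instance,
        state: RuleState | None = None,
        seed: int = 0,
    ) -> tuple[dict[tuple[int, str], tuple[int, str]] | None, Counter, int]:
        """Solve one instance under one ladder state.

        Returns ``(assignment, evidence, backtracks)``; assignment is None
        when the instance is infeasible within the backtrack cap, and
        evidence counts how often each rule pruned the search.
        """
        if state is None:
            state = self.ruleset.default_state()
        rng = np.random.default_rng(seed)
        ds, rs = self.dataset, self.ruleset

        variables = [
            (d, slot)
            for d in range(inst.n_days)
            for slot in MEAL_TYPES
            if (d, slot) not in inst.pinned
        ]
        pool_for = {}
        for d, slot in variables:
            if slot == "lunch" and d < 5 and "weekday_lunch" in inst.pools:
                pool_for[(d, slot)] = inst.pools["weekday_lunch"]
            else:
                pool_for[(d, slot)] = inst.pools[slot]
            if not pool_for[(d, slot)]:
                raise ModelError(f"empty candidate pool for slot type {slot!r}")

        # meal universe and per-constraint scalar contributions (cached per
        # ladder state + allergy flag; the dataset is immutable)
        meal_ids = sorted(
            {m for pool in pool_for.values() for m in pool}
            | {mid for mid, _ in inst.pinned.values()}
        )
        midx = {m: i for i, m in enumerate(meal_ids)}
        ckey = (tuple(sorted(state.items())), inst.milk_allergy)
        cache = self._compile_cache.setdefault(ckey, {"specs": None, "contrib": {}})
        if cache["specs"] is None:
            specs = []
            for fam in rs.families:
                for c in fam.constraints(
                    state.get(fam.id, PREFERRED), inst.milk_allergy
                ):
                    specs.append((fam.scope, fam.id, c))
            cache["specs"] = specs
        missing = [m for m in meal_ids if m not in cache["contrib"]]
        for m in missing:
            led = count_portions([ds.meals[m]], ds)
            cache["contrib"][m] = np.array(
                [c.observed(led) for _, _, c in cache["specs"]], dtype=np.int32
            )
        contrib_all = np.stack([cache["contrib"][m] for m in meal_ids], axis=1)

        daily, weekly = [], []  # (fam_id, contrib vector, min, max)
        for j, (scope, fam_id, c) in enumerate(cache["specs"]):
            entry = (
                fam_id,
                contrib_all[j],
                -_BIG if c.min is None else c.min,
                _BIG if c.max is None else c.max,
            )
            (daily if scope == "daily" else weekly).append(entry)

        nD, nW = len(daily), len(weekly)
        Dc = np.stack([e[1] for e in daily]) if nD else np.zeros((0, len(meal_ids)), np.int32)
        Wc = np.stack([e[1] for e in weekly]) if nW else np.zeros((0, len(meal_ids)), np.int32)
        dmin = np.array([e[2] for e in daily], np.int32)
        dmax = np.array([e[3] for e in daily], np.int64)
        wmin = np.array([e[2] for e in weekly], np.int32)
        wmax = np.array([e[3] for e in weekly], np.int64)

        # potentials: per slot variable, the max contribution any candidate adds
        pot_d = {}
        pot_w = {}
        for var in variables:
            cols = [midx[m] for m in pool_for[var]]
            pot_d[var] = Dc[:, cols].max(axis=1) if nD else np.zeros(0, np.int32)
            pot_w[var] = Wc[:, cols].max(axis=1) if nW else np.zeros(0, np.int32)

        # fixed (pinned) contributions; clamp max bounds so fixed excess is
        # tolerated while generated meals add nothing further
        fixed_day = np.zeros((inst.n_days, nD), np.int64)
        fixed_week = np.zeros(nW, np.int64)
        pin_meal_use: Counter = Counter()
        pin_dish_use: Counter = Counter()
        pin_day_of_meal: dict[int, list[int]] = {}
        for (d, slot), (mid, _prov) in inst.pinned.items():
            col = midx[mid]
            if nD:
                fixed_day[d] += Dc[:, col]
            if nW:
                fixed_week += Wc[:, col]
            meal = ds.meals[mid]
            if not meal.program_snack:
                pin_meal_use[mid] += 1
                pin_day_of_meal.setdefault(mid, []).append(d)
                for dish in ds.meal_dishes(mid):
                    pin_dish_use[dish.id] += 1
        dmax_eff = np.maximum(dmax[None, :], fixed_day) if nD else fixed_day
        wmax_eff = np.maximum(wmax, fixed_week) if nW else fixed_week
        meal_cap = {
            mid: max(rs.meal_repetition_max, n) for mid, n in pin_meal_use.items()
        }
        dish_cap_base = rs.dish_repetition_max
        dish_cap = {did: max(dish_cap_base or _BIG, n) for did, n in pin_dish_use.items()}

        # suffix potentials over the variable order, for weekly minima
        if nW:
            suffix_w = np.zeros((len(variables) + 1, nW), np.int64)
            for i in range(len(variables) - 1, -1, -1):
                suffix_w[i] = suffix_w[i + 1] + pot_w[variables[i]]

        # mutable search state (reset per restart)
        day_tot = np.zeros((inst.n_days, nD), np.int64)
        week_tot = np.zeros(nW, np.int64)
        meal_use: Counter = Counter()
        dish_use: Counter = Counter()
        day_of_meal: dict[int, list[int]] = {}
        shuffled: dict[tuple[int, str], list[int]] = {}
        evidence: Counter = Counter()
        backtracks = 0
        run_cap = 0
        capped = False
        assignment: dict[tuple[int, str], tuple[int, str]] = dict(inst.pinned)

        var_Dc: dict = {}
        var_Wc: dict = {}

        def reset() -> None:
            nonlocal week_tot, backtracks, capped, assignment
            day_tot[:] = fixed_day
            week_tot = fixed_week.copy()
            meal_use.clear()
            meal_use.update(pin_meal_use)
            dish_use.clear()
            dish_use.update(pin_dish_use)
            day_of_meal.clear()
            day_of_meal.update({k: list(v) for k, v in pin_day_of_meal.items()})
            assignment = dict(inst.pinned)
            backtracks = 0
            capped = False
            for var in variables:
                pool = list(pool_for[var])
                rng.shuffle(pool)
                shuffled[var] = pool
                cols = [midx[m] for m in pool]
                var_Dc[var] = Dc[:, cols] if nD else None
                var_Wc[var] = Wc[:, cols] if nW else None

        # per variable index, the daily potential still open in that day from
        # this variable onward (variables are day-major, so after the last
        # variable of a day nothing of it remains)
        day_suffix: list[np.ndarray] = []
        for i, var in enumerate(variables):
            rem = np.zeros(nD, np.int64)
            for j in range(i, len(variables)):
                if variables[j][0] == var[0]:
                    rem += pot_d[variables[j]]
            day_suffix.append(rem)
        day_suffix.append(np.zeros(nD, np.int64))

        # evidence accumulators: one slot per constraint, flushed to the
        # rule-id Counter at the end (cheap vectorized add per prune)
        ev_daily = np.zeros(nD, np.int64)
        ev_weekly = np.zeros(nW, np.int64)

        def valid_candidates(i: int, var) -> np.ndarray:
            """Mask over the slot's (shuffled) pool passing budget checks."""
            nonlocal ev_daily, ev_weekly
            d = var[0]
            ok = np.ones(len(shuffled[var]), bool)
            nxt = i + 1
            if nD:
                nd = day_tot[d][:, None] + var_Dc[var]
                last_of_day = nxt >= len(variables) or variables[nxt][0] != d
                rem = day_suffix[nxt] if not last_of_day else day_suffix[-1]
                bad = (nd > dmax_eff[d][:, None]) | (nd + rem[:, None] < dmin[:, None])
                if bad.any():
                    ev_daily += bad.sum(axis=1)
                    ok &= ~bad.any(axis=0)
            if nW:
                nw = week_tot[:, None] + var_Wc[var]
                bad = (nw > wmax_eff[:, None]) | (
                    nw + suffix_w[nxt][:, None] < wmin[:, None]
                )
                if bad.any():
                    ev_weekly += bad.sum(axis=1)
                    ok &= ~bad.any(axis=0)
            return ok

        dishes_of = {m: tuple(d.id for d in ds.meal_dishes(m)) for m in meal_ids}
        is_snack = {m: ds.meals[m].program_snack for m in meal_ids}

        def ok_repetition(var, mid: int) -> bool:
            if is_snack[mid]:
                return True
            if meal_use[mid] >= meal_cap.get(mid, rs.meal_repetition_max):
                evidence["wk_meal_repetition"] += 1
                return False
            if not rs.meal_repetition_consecutive:
                for dd in day_of_meal.get(mid, ()):
                    if abs(dd - var[0]) == 1:
                        evidence["wk_meal_consecutive"] += 1
                        return False
            if dish_cap_base is not None:
                for did in dishes_of[mid]:
                    if dish_use[did] >= dish_cap.get(did, dish_cap_base):
                        evidence["wk_dish_repetition"] += 1
                        return False
            return True

        def assign(var, mid: int) -> None:
            nonlocal week_tot
            col = midx[mid]
            if nD:
                day_tot[var[0]] += Dc[:, col]
            if nW:
                week_tot += Wc[:, col]
            if not is_snack[mid]:
                meal_use[mid] += 1
                day_of_meal.setdefault(mid, []).append(var[0])
                for did in dishes_of[mid]:
                    dish_use[did] += 1
            assignment[var] = (mid, "generated")

        def unassign(var, mid: int) -> None:
            nonlocal week_tot
            col = midx[mid]
            if nD:
                day_tot[var[0]] -= Dc[:, col]
            if nW:
                week_tot -= Wc[:, col]
            if not is_snack[mid]:
                meal_use[mid] -= 1
                day_of_meal[mid].remove(var[0])
                for did in dishes_of[mid]:
                    dish_use[did] -= 1
            del assignment[var]

        def search(i: int) -> bool:
            nonlocal backtracks, capped, ev_weekly
            if i == len(variables):
                if nW:
                    under = week_tot < wmin
                    if under.any():
                        ev_weekly += under
                        return False
                return True
            var = variables[i]
            pool = shuffled[var]
            ok = valid_candidates(i, var)
            for j in np.nonzero(ok)[0]:
                mid = pool[j]
                if not ok_repetition(var, mid):
                    continue
                assign(var, mid)
                if search(i + 1):
                    return True
                unassign(var, mid)
                backtracks += 1
                if backtracks > run_cap:
                    capped = True
                    return False
            return False

        # Restarts: a thrashing search is cut at a modest backtrack budget
        # and retried with a fresh seeded shuffle, within the total cap; a
        # run that terminates *without* hitting its budget has explored its
        # whole subtree, so the instance is genuinely infeasible.
        def flush_evidence() -> None:
            for j, e in enumerate(daily):
                if ev_daily[j]:
                    evidence[e[0]] += int(ev_daily[j])
            for j, e in enumerate(weekly):
                if ev_weekly[j]:
                    evidence[e[0]] += int(ev_weekly[j])

        total_backtracks = 0
        chunk = min(self.restart_backtracks, self.backtrack_cap)
        while True:
            reset()
            run_cap = min(chunk, self.backtrack_cap - total_backtracks)
            found = search(0)
            total_backtracks += backtracks
            if found:
                flush_evidence()
                out = dict(assignment)
                if "weekday_lunch" in inst.pools:
                    for d in range(min(5, inst.n_days)):
                        key = (d, "lunch")
                        if key in out and key not in inst.pinned:
                            out[key] = (out[key][0], "cafeteria")
                return out, evidence, total_backtracks
            if not capped or total_backtracks >= self.backtrack_cap:
                flush_evidence()
                return None, evidence, total_backtracks

    def _to_plan(
        self,
        request: ChildWeekRequest,
        assignment: dict[tuple[int, str], tuple[int, str]],
        relaxations: list[str],
        dropped: list[str],
    ) -> WeeklyPlan:
        days = []
        for d in range(7):
            slots = {
                slot: SlotAssignment(
                    meal_id=assignment[(d, slot)][0],
                    provenance=assignment[(d, slot)][1],
                )
                for slot in MEAL_TYPES
            }
            days.append(
                DayPlan(date=request.week_start + _dt.timedelta(days=d), slots=slots)
            )
        return WeeklyPlan(
            owner=request.owner,
            week_start=request.week_start,
            country=request.country,
            season=request.season,
            days=tuple(days),
            relaxations=tuple(relaxations),
            dropped_rules=tuple(dropped),
            feasible=True,
            seed=request.seed,
            age_group=request.age_group,
            milk_allergy=request.milk_allergy,
        )


# ---------------------------------------------------------------------------
# adolescent portion scaling

def scale_for_adolescent(
    plan: WeeklyPlan, age_group: str, dataset: Dataset
) -> WeeklyPlan:
    """Re-issue a child plan for an adolescent sibling.

    Meal IDs are identical; only the age group changes, which selects the
    age-appropriate ingredient gram column of every dish.  Raises when any
    dish lacks an ingredient set for the requested age group.
    """
    if age_group not in ("3-6", "7-12", "13-15", "16-18"):
        raise ModelError(f"unknown child/adolescent age group {age_group!r}")
    if not plan.feasible:
        raise ModelError("cannot rescale an infeasible plan")
    if age_group == plan.age_group:
        return plan
    for day in plan.days:
        for assign in day.slots.values():
            for dish in dataset.meal_dishes(assign.meal_id):
                if dish.ingredients and age_group not in dish.ingredients:
                    raise ModelError(
                        f"dish {dish.id} ({dish.name!r}) has no ingredient "
                        f"portions for age group {age_group}"
                    )
    return replace(plan, age_group=age_group)


def ingredient_portions(
    plan: WeeklyPlan, dataset: Dataset
) -> dict[int, dict[int, tuple[tuple[str, float], ...]]]:
    """day index -> dish id -> (ingredient, grams) at the plan's age group."""
    out: dict[int, dict[int, tuple[tuple[str, float], ...]]] = {}
    for i, day in enumerate(plan.days):
        day_map: dict[int, tuple[tuple[str, float], ...]] = {}
        for assign in day.slots.values():
            for dish in dataset.meal_dishes(assign.meal_id):
                if dish.ingredients:
                    if plan.age_group not in dish.ingredients:
                        raise ModelError(
                            f"dish {dish.id} lacks portions for {plan.age_group}"
                        )
                    day_map[dish.id] = dish.ingredients[plan.age_group]
        out[i] = day_map
    return out
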