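"""Adult family recommender: sample, score and assemble weekly plans.

Around the meals the children share with the family (seven dinners and the
two weekend lunches, fixed by the child plan), each adult's remaining slots
are filled by sampling daily combinations from the filtered meal pools,
scoring each daily plan against the adult's energy needs, and assembling
one candidate per day into a week that satisfies the Mediterranean-diet and
diversity rules.

The daily score (DNPS, 0-4) is the sum of four partial scores in [0, 1]:

* caloric score   CS  = max(0, 1 - |kcal - DER| / (0.3 DER))
* protein score   PS  = 1 inside 15-20% of DER, linear ramp over 10 pp
* fat score       FS  = 1 inside 25-40% of DER, linear ramp over 10 pp
* fruit&veg score FVS = 1 inside 5-10 servings, linear ramp over 5 servings

Protein and fat energy use the 4 / 9 kcal/g Atwater factors.  The in-band
plateaus are the expert guidance; the ramp widths are package constants
(:data:`ScoreConfig`) and the audit metrics do not depend on them inside
the bands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dataset import Dataset
from .model import MEAL_TYPES, ModelError, WeeklyPlan
from .profiles import AdultProfile, energy_requirements
from .rules import (
    PREFERRED,
    RuleSet,
    RuleViolation,
    count_portions,
    evaluate_rules,
    evaluate_structure,
    load_ruleset,
)

__all__ = [
    "ScoreConfig",
    "ScoreBreakdown",
    "DailyCandidate",
    "DailyCandidateSet",
    "FamilyWeeklyPlan",
    "filter_meals",
    "fixed_child_meals",
    "generate_daily_candidates",
    "score_daily_plan",
    "build_weekly_plan",
    "plan_family_week",
]

WEEKEND_DAYS = (5, 6)
FREE_WEEKDAY_SLOTS = ("breakfast", "morning_snack", "lunch", "afternoon_snack")
FREE_WEEKEND_SLOTS = ("breakfast", "morning_snack", "afternoon_snack")

PROTEIN_KCAL_PER_G = 4.0
FAT_KCAL_PER_G = 9.0


@dataclass(frozen=True)
class ScoreConfig:
    """Bands (expert guidance) and ramp widths (package constants)."""

    cs_ramp_frac: float = 0.3  # CS hits 0 at a 30% caloric deviation
    protein_band: tuple[float, float] = (15.0, 20.0)  # % of DER
    fat_band: tuple[float, float] = (25.0, 40.0)  # % of DER
    macro_ramp_pp: float = 10.0  # percentage points to score 0
    fv_band: tuple[int, int] = (5, 10)  # servings/day
    fv_ramp: float = 5.0  # servings to score 0


DEFAULT_SCORES = ScoreConfig()


@dataclass(frozen=True)
class ScoreBreakdown:
    cs: float
    ps: float
    fs: float
    fvs: float
    kcal_total: float
    protein_pct: float
    fat_pct: float
    fv_servings: int

    @property
    def dnps(self) -> float:
        return self.cs + self.ps + self.fs + self.fvs


@dataclass(frozen=True)
class DailyCandidate:
    day: int
    meal_ids: tuple[int, ...]  # slot order: breakfast ... dinner
    fixed_slots: frozenset[str]
    breakdown: ScoreBreakdown


@dataclass
class FamilyWeeklyPlan:
    owner: str
    days: tuple[DailyCandidate, ...]
    md_ok: bool
    violations: list[RuleViolation]
    der: float
    nodes_visited: int = 0

    def dinners(self) -> tuple[int, ...]:
        i = MEAL_TYPES.index("dinner")
        return tuple(d.meal_ids[i] for d in self.days)


# ---------------------------------------------------------------------------
# step 1-2: filtering and fixed child meals

def filter_meals(
    dataset: Dataset, profile: AdultProfile, season: str
) -> dict[str, list[int]]:
    """Per-slot candidate pools: adult-audience meals of the profile's
    cuisine and the season, dairy-free when the adult is milk-allergic."""
    pools: dict[str, list[int]] = {}
    for slot in MEAL_TYPES:
        pool = dataset.meals_for(
            type=slot,
            country=profile.country,
            season=season,
            audience="adult",
            exclude_dairy=profile.milk_allergy,
            include_program_snack=False,
        )
        if not pool:
            raise ModelError(
                f"no adult {slot} meals for {profile.country}/{season}"
                + (" without dairy" if profile.milk_allergy else "")
            )
        pools[slot] = pool
    return pools


def fixed_child_meals(child_plan: WeeklyPlan) -> dict[int, dict[str, int]]:
    """Extract the 9 shared family meals from a feasible child plan:
    seven daily dinners plus the Saturday and Sunday lunches."""
    if not child_plan.feasible:
        raise ModelError("child plan is infeasible; no shared meals to extract")
    fixed: dict[int, dict[str, int]] = {}
    for d, day in enumerate(child_plan.days):
        fixed[d] = {"dinner": day.slots["dinner"].meal_id}
        if d in WEEKEND_DAYS:
            fixed[d]["lunch"] = day.slots["lunch"].meal_id
    return fixed


# ---------------------------------------------------------------------------
# step 3: daily candidates

def _meal_nutrition_table(dataset: Dataset, meal_ids: list[int]) -> dict[int, tuple]:
    """meal id -> (kcal, protein_g, fat_g, fv servings)."""
    out = {}
    for mid in meal_ids:
        kcal = protein = fat = 0.0
        fv = 0
        for dish in dataset.meal_dishes(mid):
            if dish.nutrition is None:
                raise ModelError(f"meal {mid}: dish {dish.id} has no nutrition")
            kcal += dish.nutrition.kcal
            protein += dish.nutrition.protein_g
            fat += dish.nutrition.fat_g
            fv += sum(
                1
                for g in ("fruit", "raw_vegetables", "cooked_vegetables")
                if g in dish.expanded_groups
            )
        out[mid] = (kcal, protein, fat, fv)
    return out


def _score_arrays(kcal, protein_g, fat_g, fv, der: float, cfg: ScoreConfig):
    kcal = np.asarray(kcal, float)
    protein_pct = 100.0 * protein_g * PROTEIN_KCAL_PER_G / der
    fat_pct = 100.0 * fat_g * FAT_KCAL_PER_G / der
    cs = np.maximum(0.0, 1.0 - np.abs(kcal - der) / (cfg.cs_ramp_frac * der))

    def band_score(pct, lo, hi, ramp):
        gap = np.where(pct < lo, lo - pct, np.where(pct > hi, pct - hi, 0.0))
        return np.maximum(0.0, 1.0 - gap / ramp)

    ps = band_score(protein_pct, *cfg.protein_band, cfg.macro_ramp_pp)
    fs = band_score(fat_pct, *cfg.fat_band, cfg.macro_ramp_pp)
    fvs = band_score(np.asarray(fv, float), *cfg.fv_band, cfg.fv_ramp)
    return cs, ps, fs, fvs, protein_pct, fat_pct


def score_daily_plan(
    meal_ids: tuple[int, ...],
    dataset: Dataset,
    der: float,
    config: ScoreConfig = DEFAULT_SCORES,
) -> ScoreBreakdown:
    """Score one daily plan (5 meal ids) against an adult's DER."""
    table = _meal_nutrition_table(dataset, list(meal_ids))
    kcal = sum(table[m][0] for m in meal_ids)
    protein = sum(table[m][1] for m in meal_ids)
    fat = sum(table[m][2] for m in meal_ids)
    fv = sum(table[m][3] for m in meal_ids)
    cs, ps, fs, fvs, ppct, fpct = _score_arrays(
        np.array([kcal]), np.array([protein]), np.array([fat]), np.array([fv]),
        der, config,
    )
    return ScoreBreakdown(
        cs=float(cs[0]),
        ps=float(ps[0]),
        fs=float(fs[0]),
        fvs=float(fvs[0]),
        kcal_total=float(kcal),
        protein_pct=float(ppct[0]),
        fat_pct=float(fpct[0]),
        fv_servings=int(fv),
    )


@dataclass
class DailyCandidateSet:
    """Deduplicated, DNPS-sorted daily candidates for one day (array form)."""

    day: int
    fixed_slots: frozenset[str]
    meal_ids: np.ndarray  # (n, 5) int, slot order
    cs: np.ndarray
    ps: np.ndarray
    fs: np.ndarray
    fvs: np.ndarray
    kcal: np.ndarray
    protein_pct: np.ndarray
    fat_pct: np.ndarray
    fv: np.ndarray

    def __len__(self) -> int:
        return len(self.meal_ids)

    @property
    def dnps(self) -> np.ndarray:
        return self.cs + self.ps + self.fs + self.fvs

    def candidate(self, i: int) -> DailyCandidate:
        return DailyCandidate(
            day=self.day,
            meal_ids=tuple(int(m) for m in self.meal_ids[i]),
            fixed_slots=self.fixed_slots,
            breakdown=ScoreBreakdown(
                cs=float(self.cs[i]),
                ps=float(self.ps[i]),
                fs=float(self.fs[i]),
                fvs=float(self.fvs[i]),
                kcal_total=float(self.kcal[i]),
                protein_pct=float(self.protein_pct[i]),
                fat_pct=float(self.fat_pct[i]),
                fv_servings=int(self.fv[i]),
            ),
        )


def generate_daily_candidates(
    pools: dict[str, list[int]],
    fixed: dict[str, int],
    day: int,
    dataset: Dataset,
    der: float,
    n: int = 100_000,
    seed: int = 0,
    config: ScoreConfig = DEFAULT_SCORES,
) -> DailyCandidateSet:
    """Create, score and sort the day's candidate plans.

    Free slots draw uniformly with replacement from their pools (``n``
    samples, deduplicated); when the full Cartesian product of the free
    pools is no larger than ``n`` it is enumerated exhaustively instead.
    Sorting is by DNPS descending, ties broken by caloric distance to DER
    and then by the meal-ID tuple so the order is deterministic.
    """
    free_slots = [s for s in MEAL_TYPES if s not in fixed]
    for s in free_slots:
        if not pools.get(s):
            raise ModelError(f"empty candidate pool for slot {s!r}")
    pool_arrays = {s: np.asarray(sorted(pools[s]), dtype=np.int64) for s in free_slots}

    sizes = [len(pool_arrays[s]) for s in free_slots]
    product = int(np.prod(sizes)) if sizes else 1
    rng = np.random.default_rng(seed)
    if product <= n:
        grids = np.meshgrid(*[pool_arrays[s] for s in free_slots], indexing="ij")
        free_cols = [g.reshape(-1) for g in grids]
    else:
        free_cols = [rng.choice(pool_arrays[s], size=n, replace=True) for s in free_slots]

    n_rows = len(free_cols[0]) if free_cols else 1
    cols = []
    for slot in MEAL_TYPES:
        if slot in fixed:
            cols.append(np.full(n_rows, fixed[slot], dtype=np.int64))
        else:
            cols.append(free_cols[free_slots.index(slot)])
    ids = np.stack(cols, axis=1)
    ids = np.unique(ids, axis=0)

    all_ids = sorted(set(ids.reshape(-1).tolist()))
    table = _meal_nutrition_table(dataset, all_ids)
    lookup_idx = {m: i for i, m in enumerate(all_ids)}
    nut = np.array([table[m] for m in all_ids], float)  # (m, 4)
    flat = np.vectorize(lookup_idx.get, otypes=[np.int64])(ids)
    per_meal = nut[flat]  # (n, 5, 4)
    kcal, protein, fat, fv = (per_meal[:, :, k].sum(axis=1) for k in range(4))

    cs, ps, fs, fvs, ppct, fpct = _score_arrays(kcal, protein, fat, fv, der, config)
    dnps = cs + ps + fs + fvs
    kdist = np.abs(kcal - der)
    order = np.lexsort(
        tuple(ids[:, j] for j in range(4, -1, -1)) + (kdist, -dnps)
    )
    return DailyCandidateSet(
        day=day,
        fixed_slots=frozenset(fixed),
        meal_ids=ids[order],
        cs=cs[order],
        ps=ps[order],
        fs=fs[order],
        fvs=fvs[order],
        kcal=kcal[order],
        protein_pct=ppct[order],
        fat_pct=fpct[order],
        fv=fv[order].astype(int),
    )


# ---------------------------------------------------------------------------
# step 4: weekly assembly under the adult ruleset

def _day_meals(dataset: Dataset, row: np.ndarray):
    return [dataset.meals[int(m)] for m in row]


def _day_is_compliant(
    dataset: Dataset, ruleset: RuleSet, row: np.ndarray
) -> bool:
    """Daily-horizon adult rules (frequency + structural) for one candidate."""
    meals = _day_meals(dataset, row)
    ledger = count_portions(meals, dataset)
    if evaluate_rules([ledger], None, ruleset):
        return False
    return not evaluate_structure([meals], dataset, ruleset, adult=True)


def build_weekly_plan(
    candidate_sets: list[DailyCandidateSet],
    dataset: Dataset,
    owner: str,
    der: float,
    ruleset: RuleSet | None = None,
    node_cap: int = 1_000_000,
    seed: int = 0,
    sample_budget: int = 100_000,
) -> FamilyWeeklyPlan:
    """Select one candidate per day so the assembled week is compliant.

    Weekly food-group caps, meal repetition (<=2/week, never on consecutive
    days) and the daily diversity rules constrain the choice.  Enumerable
    spaces are searched exhaustively in DNPS rank order; larger spaces get
    a narrow rank-ordered pass, then seeded uniform sampling over the
    day-compliant candidates followed by a rank-improving polish.  If no
    compliant week is found (typically because the fixed child meals
    already violate a rule) the top-ranked candidate of each day is
    returned with ``md_ok=False`` and the violations listed.
    """
    if ruleset is None:
        ruleset = load_ruleset("adult")
    if len(candidate_sets) != 7:
        raise ModelError("weekly assembly needs exactly 7 daily candidate lists")

    # compile weekly frequency caps into per-meal scalar contributions
    all_ids = sorted(
        {int(m) for cs_ in candidate_sets for m in cs_.meal_ids.reshape(-1)}
    )
    midx = {m: i for i, m in enumerate(all_ids)}
    ledgers = [count_portions([dataset.meals[m]], dataset) for m in all_ids]
    weekly = []
    for fam in ruleset.families_in("weekly"):
        for c in fam.constraints(PREFERRED, False):
            if c.max is None:
                continue
            contrib = np.array([c.observed(led) for led in ledgers], np.int32)
            weekly.append((fam.id, contrib, c.max))
    Wc = np.stack([w[1] for w in weekly]) if weekly else np.zeros((0, len(all_ids)), np.int32)
    wmax = np.array([w[2] for w in weekly], np.int64)

    day_vectors = []
    day_valid: list[list[int]] = []
    for cs_ in candidate_sets:
        flat = np.vectorize(midx.get, otypes=[np.int64])(cs_.meal_ids)
        vecs = Wc[:, flat].sum(axis=2).T if len(weekly) else np.zeros((len(cs_), 0), np.int64)
        day_vectors.append(vecs)
        day_valid.append(
            [
                i
                for i, row in enumerate(cs_.meal_ids)
                if _day_is_compliant(dataset, ruleset, row)
            ]
        )

    nodes = 0
    chosen: list[int] = []
    meal_use: Counter = Counter()
    last_day: dict[int, int] = {}

    # fixed child meals sit in every candidate of their day, so if they
    # alone blow a weekly cap, or a day has no compliant candidate at all,
    # no assembled week can comply — bail out to best effort immediately
    infeasible = any(not v for v in day_valid)
    if not infeasible and len(weekly):
        fixed_floor = np.zeros(len(weekly), np.int64)
        for d, cs_ in enumerate(candidate_sets):
            fixed_cols = [
                MEAL_TYPES.index(s) for s in cs_.fixed_slots
            ]
            if fixed_cols:
                row = cs_.meal_ids[0]
                fixed_floor += Wc[:, [midx[int(row[j])] for j in fixed_cols]].sum(axis=1)
        if (fixed_floor > wmax).any():
            infeasible = True

    def rep_ok(d: int, row: np.ndarray) -> tuple[bool, list[tuple[int, int]]]:
        added = []
        local = Counter(int(m) for m in row)
        for mid, k in local.items():
            if meal_use[mid] + k > ruleset.meal_repetition_max or k > ruleset.meal_repetition_max:
                return False, []
            if not ruleset.meal_repetition_consecutive and last_day.get(mid) == d - 1:
                return False, []
            added.append((mid, k))
        return True, added

    week_tot = np.zeros(len(weekly), np.int64)

    def dfs(d: int, width: int) -> bool:
        nonlocal nodes, week_tot
        if d == 7:
            return True
        cs_ = candidate_sets[d]
        for i in day_valid[d][:width]:
            nodes += 1
            if nodes > node_cap:
                return False
            new_tot = week_tot + day_vectors[d][i]
            if len(weekly) and (new_tot > wmax).any():
                continue
            ok, added = rep_ok(d, cs_.meal_ids[i])
            if not ok:
                continue
            saved_last = {}
            for mid, k in added:
                meal_use[mid] += k
                saved_last[mid] = last_day.get(mid)
                last_day[mid] = d
            old_tot = week_tot
            week_tot = new_tot
            chosen.append(i)
            if dfs(d + 1, width):
                return True
            chosen.pop()
            week_tot = old_tot
            for mid, k in added:
                meal_use[mid] -= k
                if saved_last[mid] is None:
                    del last_day[mid]
                else:
                    last_day[mid] = saved_last[mid]
        return False

    def run_dfs(width: int) -> bool:
        nonlocal week_tot
        chosen.clear()
        meal_use.clear()
        last_day.clear()
        week_tot = np.zeros(len(weekly), np.int64)
        return dfs(0, width)

    def week_ok(picks: list[int]) -> bool:
        tot = np.zeros(len(weekly), np.int64)
        use: Counter = Counter()
        last: dict[int, int] = {}
        for d, i in enumerate(picks):
            tot += day_vectors[d][i]
            for m in candidate_sets[d].meal_ids[i]:
                m = int(m)
                use[m] += 1
                if use[m] > ruleset.meal_repetition_max:
                    return False
                if not ruleset.meal_repetition_consecutive and last.get(m) == d - 1:
                    return False
                last[m] = d
        return not (len(weekly) and (tot > wmax).any())

    found = False
    if not infeasible:
        sizes = [len(v) for v in day_valid]
        product = 1
        for s in sizes:
            product *= s
        if product <= node_cap:
            # enumerable space: complete depth-first search, exact answer
            found = run_dfs(max(sizes))
        else:
            # large space: the top-ranked candidates of different days are
            # highly correlated, which makes pure rank-order DFS thrash, so
            # (a) a narrow complete pass over the top ranks,
            found = run_dfs(4)
            if not found:
                # (b) seeded uniform sampling over the day-valid candidates;
                # keep the best-scoring compliant week among the first hits
                rng = np.random.default_rng(seed)
                dnps_by_day = [cs_.dnps for cs_ in candidate_sets]
                hits: list[tuple[float, list[int]]] = []
                for _ in range(sample_budget // 256):
                    batch = np.stack(
                        [rng.choice(v, size=256) for v in day_valid], axis=1
                    )  # (256, 7) candidate indices
                    tots = np.zeros((256, len(weekly)), np.int64)
                    for d in range(7):
                        tots += day_vectors[d][batch[:, d]]
                    survivors = np.nonzero(~(tots > wmax).any(axis=1))[0]
                    for b in survivors:
                        picks = [int(batch[b, d]) for d in range(7)]
                        if week_ok(picks):
                            score = sum(
                                float(dnps_by_day[d][picks[d]]) for d in range(7)
                            )
                            hits.append((score, picks))
                    if len(hits) >= 20:
                        break
                if hits:
                    picks_found = max(hits)[1]
                    # (c) polish to a fixpoint: per day, swap in the best-
                    # ranked candidate that keeps the whole week compliant
                    for _ in range(3):
                        changed = False
                        for d in range(7):
                            for i in day_valid[d]:
                                if i == picks_found[d]:
                                    break
                                trial = list(picks_found)
                                trial[d] = i
                                if week_ok(trial):
                                    picks_found = trial
                                    changed = True
                                    break
                        if not changed:
                            break
                    chosen[:] = picks_found
                    found = True
    if found:
        days = tuple(candidate_sets[d].candidate(chosen[d]) for d in range(7))
        return FamilyWeeklyPlan(
            owner=owner, days=days, md_ok=True, violations=[], der=der,
            nodes_visited=nodes,
        )

    # best effort: top-ranked candidate per day, with violations reported
    days = tuple(cs_.candidate(0) for cs_ in candidate_sets)
    day_meals = [_day_meals(dataset, np.asarray(day.meal_ids)) for day in days]
    day_ledgers = [count_portions(m, dataset) for m in day_meals]
    week_ledger = count_portions([m for ms in day_meals for m in ms], dataset)
    violations = evaluate_rules(day_ledgers, week_ledger, ruleset)
    violations += evaluate_structure(day_meals, dataset, ruleset, adult=True)
    return FamilyWeeklyPlan(
        owner=owner,
        days=days,
        md_ok=False,
        violations=violations,
        der=der,
        nodes_visited=nodes,
    )


# ---------------------------------------------------------------------------
# JSON export

def write_family_plan(plan: FamilyWeeklyPlan, path, seed: int | None = None,
                      ruleset_version: int | None = None) -> None:
    import json
    from pathlib import Path

    payload = {
        "schema_version": 1,
        "owner": plan.owner,
        "der": plan.der,
        "md_ok": plan.md_ok,
        "seed": seed,
        "ruleset_version": ruleset_version,
        "violations": [
            {"rule_id": v.rule_id, "horizon": v.horizon, "observed": v.observed}
            for v in plan.violations
        ],
        "days": [
            {
                "day": day.day,
                "meal_ids": list(day.meal_ids),
                "fixed_slots": sorted(day.fixed_slots),
                "dnps": day.breakdown.dnps,
            }
            for day in plan.days
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_family_plan(path, dataset: Dataset) -> FamilyWeeklyPlan:
    """Load an exported family plan; score breakdowns are recomputed."""
    import json
    from pathlib import Path

    p = json.loads(Path(path).read_text(encoding="utf-8"))
    days = tuple(
        DailyCandidate(
            day=d["day"],
            meal_ids=tuple(d["meal_ids"]),
            fixed_slots=frozenset(d["fixed_slots"]),
            breakdown=score_daily_plan(tuple(d["meal_ids"]), dataset, p["der"]),
        )
        for d in p["days"]
    )
    return FamilyWeeklyPlan(
        owner=p["owner"],
        days=days,
        md_ok=p["md_ok"],
        violations=[],
        der=p["der"],
    )


# ---------------------------------------------------------------------------
# one-call driver

def plan_family_week(
    dataset: Dataset,
    profile: AdultProfile,
    child_plan: WeeklyPlan,
    season: str,
    reference_year: int,
    n_candidates: int = 100_000,
    seed: int = 0,
    config: ScoreConfig = DEFAULT_SCORES,
    ruleset: RuleSet | None = None,
) -> FamilyWeeklyPlan:
    """Filter, fix the shared child meals, sample+score, assemble the week."""
    pools = filter_meals(dataset, profile, season)
    fixed = fixed_child_meals(child_plan)
    der = energy_requirements(profile, reference_year).der
    sets = [
        generate_daily_candidates(
            pools,
            fixed[d],
            d,
            dataset,
            der,
            n=n_candidates,
            seed=seed + d,
            config=config,
        )
        for d in range(7)
    ]
    return build_weekly_plan(
        sets, dataset, profile.name, der, ruleset=ruleset, seed=seed
    )
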