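"""Compliance auditing: per-rule child compliance and adult accuracy.

The auditor re-counts portions and re-evaluates every rule directly from
finished plans, independently of how the planners searched for them, so
planner-vs-auditor agreement is a meaningful cross-check rather than a
tautology.

Child reports: for every rule family, the share of daily plans (daily
rules) or weekly plans (weekly rules) that satisfy it, under the preferred
variant and under the less-restrictive variant, with the delta between the
two.  Dairy rules are skipped for milk-allergic owners (their plans carry
the plant-based alternative rules instead), mirroring how such menus are
validated in practice.

Adult reports: per daily plan, caloric agreement = 100*(1 - |kcal-DER|/DER)
averaged over plans, plus the share of daily plans whose fat, protein and
fruit-and-vegetable intake fall inside the recommended bands.  Because
"accuracy" can reasonably mean either the mean agreement or a
share-above-threshold, both are computed; the mean is the headline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import Dataset
from .family_planner import (
    DEFAULT_SCORES,
    FamilyWeeklyPlan,
    ScoreConfig,
    score_daily_plan,
)
from .model import WeeklyPlan
from .rules import (
    LESS_RESTRICTIVE,
    PREFERRED,
    RuleSet,
    count_portions,
    evaluate_rules,
    load_ruleset,
)

__all__ = [
    "ComplianceReport",
    "AdultAccuracyReport",
    "audit_child_compliance",
    "audit_adult_accuracy",
]


@dataclass
class ComplianceReport:
    """Per rule x country x variant compliance percentages."""

    table: pd.DataFrame  # columns: rule_id, scope, country, variant, n, n_compliant, percent
    n_daily: int = 0
    n_weekly: int = 0

    def percent(self, rule_id: str, variant: str, country: str = "Overall") -> float:
        t = self.table
        row = t[
            (t.rule_id == rule_id) & (t.variant == variant) & (t.country == country)
        ]
        if row.empty or row.n.iloc[0] == 0:
            return float("nan")
        return float(row.percent.iloc[0])

    def mean_compliance(self, scope: str, variant: str, country: str = "Overall") -> float:
        """Mean of per-rule compliance percentages at one horizon.

        For the less-restrictive column, rules without a variant keep their
        preferred percentage (relaxed and unchanged rules applied together).
        """
        t = self.table
        sub = t[(t.scope == scope) & (t.country == country) & (t.n > 0)]
        vals = []
        for rid in sub.rule_id.unique():
            rows = sub[sub.rule_id == rid]
            pick = rows[rows.variant == variant]
            if pick.empty and variant == LESS_RESTRICTIVE:
                pick = rows[rows.variant == PREFERRED]
            if not pick.empty:
                vals.append(float(pick.percent.iloc[0]))
        return sum(vals) / len(vals) if vals else float("nan")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self, country: str = "Overall") -> str:
        """Row-per-rule rendering: preferred vs. less-restrictive percent."""
        t = self.table
        lines = [f"Compliance ({country}; {self.n_weekly} weekly plans)"]
        for scope in ("daily", "weekly"):
            lines.append(f"-- {scope} rules " + "-" * 30)
            sub = t[(t.scope == scope) & (t.country == country) & (t.n > 0)]
            for rid in sorted(sub.rule_id.unique()):
                rows = sub[sub.rule_id == rid]
                pref = rows[rows.variant == PREFERRED]
                lr = rows[rows.variant == LESS_RESTRICTIVE]
                p = f"{pref.percent.iloc[0]:6.2f}%" if len(pref) else "     —"
                l = f"{lr.percent.iloc[0]:6.2f}%" if len(lr) else "  (not to be changed)"
                lines.append(f"{rid:<28} preferred {p}  less restrictive {l}")
        return "\n".join(lines)


@dataclass
class AdultAccuracyReport:
    weekly_np_count: int
    daily_np_count: int
    mean_caloric_agreement: float
    fat_within_range_pct: float
    protein_within_range_pct: float
    fv_within_range_pct: float
    caloric_agreement_over_90_pct: float = 0.0
    md_pass_count: int = 0
    per_plan: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "weekly_nps": self.weekly_np_count,
                    "daily_nps": self.daily_np_count,
                    "mean_caloric_agreement": self.mean_caloric_agreement,
                    "fat_within_range": self.fat_within_range_pct,
                    "protein_within_range": self.protein_within_range_pct,
                    "fruit_veg_within_range": self.fv_within_range_pct,
                }
            ]
        )

    def to_text(self) -> str:
        return (
            f"Weekly NPs {self.weekly_np_count} | Daily NPs {self.daily_np_count} | "
            f"Mean Caloric Agreement {self.mean_caloric_agreement:.2f}% | "
            f"Fat Within Range {self.fat_within_range_pct:.2f}% | "
            f"Protein Within Range {self.protein_within_range_pct:.2f}% | "
            f"Fruit and Veg Within Range {self.fv_within_range_pct:.2f}%"
        )


def audit_child_compliance(
    plans: list[WeeklyPlan],
    dataset: Dataset,
    ruleset: RuleSet | None = None,
) -> ComplianceReport:
    """Evaluate every rule family over every plan, both variants.

    A daily plan complies with a daily rule iff re-evaluation raises no
    violation of it on that day; a weekly plan complies with a weekly rule
    iff the week ledger satisfies it.  Aggregated per country and overall.
    """
    if ruleset is None:
        ruleset = load_ruleset("child")
    counters: dict[tuple[str, str, str, str], list[int]] = {}

    def bump(rule_id, scope, country, variant, ok: bool) -> None:
        for c in (country, "Overall"):
            key = (rule_id, scope, c, variant)
            n = counters.setdefault(key, [0, 0])
            n[0] += 1
            n[1] += int(ok)

    for plan in plans:
        day_meals = [
            [dataset.meals[day.slots[t].meal_id] for t in day.slots]
            for day in plan.days
        ]
        day_ledgers = [count_portions(m, dataset) for m in day_meals]
        week_ledger = count_portions([m for ms in day_meals for m in ms], dataset)
        for variant in (PREFERRED, LESS_RESTRICTIVE):
            state = {f.id: variant if f.relaxable else PREFERRED for f in ruleset.families}
            violations = evaluate_rules(
                day_ledgers, week_ledger, ruleset, state, plan.milk_allergy
            )
            bad_daily = {(v.rule_id, v.horizon) for v in violations}
            bad_weekly = {v.rule_id for v in violations if v.horizon == "week"}
            for fam in ruleset.families:
                if variant == LESS_RESTRICTIVE and not fam.relaxable:
                    continue
                if fam.allergy_only and not plan.milk_allergy:
                    continue
                if fam.dairy and plan.milk_allergy:
                    continue  # dairy rules skipped for milk-allergy plans
                if fam.scope == "daily":
                    for i in range(7):
                        ok = (fam.id, f"day:{i}") not in bad_daily
                        bump(fam.id, "daily", plan.country, variant, ok)
                else:
                    bump(fam.id, "weekly", plan.country, variant, fam.id not in bad_weekly)

    rows = [
        {
            "rule_id": rid,
            "scope": scope,
            "country": country,
            "variant": variant,
            "n": n,
            "n_compliant": k,
            "percent": 100.0 * k / n if n else float("nan"),
        }
        for (rid, scope, country, variant), (n, k) in sorted(counters.items())
    ]
    return ComplianceReport(
        table=pd.DataFrame(rows),
        n_daily=7 * len(plans),
        n_weekly=len(plans),
    )


def audit_adult_accuracy(
    plans: list[FamilyWeeklyPlan],
    dataset: Dataset,
    config: ScoreConfig = DEFAULT_SCORES,
) -> AdultAccuracyReport:
    """Re-score every daily plan of every adult week from scratch.

    Caloric agreement per daily plan is 100*(1 - |kcal - DER|/DER); the
    within-range shares use the protein/fat/fruit-and-vegetable bands of
    the scoring configuration.
    """
    records = []
    for plan in plans:
        for day in plan.days:
            b = score_daily_plan(day.meal_ids, dataset, plan.der, config)
            records.append(
                {
                    "owner": plan.owner,
                    "day": day.day,
                    "kcal": b.kcal_total,
                    "der": plan.der,
                    "caloric_agreement": 100.0 * (1.0 - abs(b.kcal_total - plan.der) / plan.der),
                    "protein_pct": b.protein_pct,
                    "fat_pct": b.fat_pct,
                    "fv": b.fv_servings,
                }
            )
    df = pd.DataFrame(records)
    if df.empty:
        return AdultAccuracyReport(0, 0, float("nan"), float("nan"), float("nan"), float("nan"))
    p_lo, p_hi = config.protein_band
    f_lo, f_hi = config.fat_band
    v_lo, v_hi = config.fv_band
    fat_ok = df.fat_pct.between(f_lo, f_hi)
    protein_ok = df.protein_pct.between(p_lo, p_hi)
    fv_ok = df.fv.between(v_lo, v_hi)
    return AdultAccuracyReport(
        weekly_np_count=len(plans),
        daily_np_count=len(df),
        mean_caloric_agreement=float(df.caloric_agreement.mean()),
        fat_within_range_pct=100.0 * float(fat_ok.mean()),
        protein_within_range_pct=100.0 * float(protein_ok.mean()),
        fv_within_range_pct=100.0 * float(fv_ok.mean()),
        caloric_agreement_over_90_pct=100.0 * float((df.caloric_agreement > 90).mean()),
        md_pass_count=sum(1 for p in plans if p.md_ok),
        per_plan=df,
    )
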