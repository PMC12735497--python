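# Plan export schemas

## Child weekly plan (`plan-child --out`, `write_weekly_plan`)

JSON object, UTF-8:

```json
{
  "schema_version": 1,
  "owner": "child-0",
  "week_start": "2025-09-08",
  "country": "Spain",
  "season": "autumn",
  "age_group": "7-12",
  "milk_allergy": false,
  "seed": 7,
  "feasible": true,
  "relaxations": ["d_cereals"],
  "dropped_rules": [],
  "days": [
    {
      "date": "2025-09-08",
      "slots": {
        "breakfast":       {"meal_id": 1001, "provenance": "generated"},
        "morning_snack":   {"meal_id": 1013, "provenance": "generated"},
        "lunch":           {"meal_id": 1030, "provenance": "school"},
        "afternoon_snack": {"meal_id": 1018, "provenance": "program_snack"},
        "dinner":          {"meal_id": 1044, "provenance": "generated"}
      }
    }
  ]
}
```

* `days` has exactly 7 entries, dated Monday through Sunday.
* `provenance` ∈ `school`, `cafeteria`, `child_fixed`, `generated`,
  `program_snack`.
* `relaxations` / `dropped_rules` list rule-family IDs from the shipped
  ruleset (`d_*` daily, `wk_*` weekly), in ladder order.
* `write_weekly_plan` re-validates before writing when given the dataset:
  school-provenance lunches must match the menu verbatim, every meal must
  match the plan's country/season and slot type, and milk-allergy plans
  must be dairy-free.  `read_weekly_plan(write_weekly_plan(p)) == p`.

## Adult weekly plan (`plan-family --out`, `write_family_plan`)

```json
{
  "schema_version": 1,
  "owner": "family0-adult0",
  "der": 2210.4,
  "md_ok": true,
  "seed": 7,
  "ruleset_version": 1,
  "violations": [],
  "days": [
    {"day": 0, "meal_ids": [1001, 1013, 1030, 1018, 1044],
     "fixed_slots": ["dinner"], "dnps": 3.82}
  ]
}
```

* `meal_ids` are in slot order (breakfast, morning snack, lunch, afternoon
  snack, dinner).
* `violations` is non-empty only when `md_ok` is false; entries carry the
  rule ID, horizon (`week` or `day:<i>`) and observed count.
* Score breakdowns are recomputed from the dataset on load, so the file
  stays small and cannot drift from the meals it names.

## Dataset tables

`dishes.csv` columns: `id`, `name`, `groups` (`;`-separated flags),
`colors`, `kcal`, `fat_g`, `protein_g`, `carbs_g` (blank when the dish has
no adult nutrition), `role` (`main`/`side`/`unspecified`), `fruit_salad`
(0/1), `recipe`, `tip`, and one `ingredients_<age>` column per age group
(`3_6`, `7_12`, `13_15`, `16_18`, `adult`) holding `name:grams` pairs
joined by `;`.

`meals.csv` columns: `id`, `name`, `type`, `country`, `seasons`,
`dish_ids`, `audience`, `program_snack`.

`school_menus.csv` columns: `school`, `country`, `week_start`, `weekday`,
`meal_id`; cafeteria proposals leave `week_start`/`weekday` empty.

A JSON mirror (`{"dishes": [...], "meals": [...]}` with the same field
names) is accepted by `load_dataset`.
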