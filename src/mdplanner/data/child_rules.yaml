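# Expert-validated child food-frequency ruleset (weekly + daily horizons).
# Each family carries a preferred bound and, where flexibility is allowed,
# a less-restrictive variant; "less_restrictive" omitted = not to be changed.
# drop_group marks sub-category/color families that may be excluded entirely
# when too restrictive.  dairy families are zeroed for milk-allergic users,
# allergy_only families (plant-based alternatives) then apply the same bounds.
version: 1
audience: child
meal_repetition_max: 2
meal_repetition_consecutive: false
dish_repetition_max: 3
families:
  # -- weekly ---------------------------------------------------------------
  - id: wk_pulses
    scope: weekly
    preferred: [{keys: [pulses], min: 4, max: 5}]
    less_restrictive: [{keys: [pulses], min: 4, max: 6}]
    note: if the pulse sub-categories are too restrictive, only this macro
      category is kept
  - id: wk_white_red_beans
    scope: weekly
    drop_group: pulse_subcategories
    preferred: [{keys: [white_red_beans], min: 1, max: 1}]
    less_restrictive: [{keys: [white_red_beans], min: 1, max: 2}]
  - id: wk_other_pulses
    scope: weekly
    drop_group: pulse_subcategories
    preferred: [{keys: [other_pulses], min: 1, max: 1}]
    less_restrictive: [{keys: [other_pulses], min: 1, max: 2}]
  - id: wk_lentils
    scope: weekly
    drop_group: pulse_subcategories
    preferred: [{keys: [lentils], min: 1, max: 2}]
    less_restrictive: [{keys: [lentils], min: 1, max: 3}]
  - id: wk_chickpeas
    scope: weekly
    drop_group: pulse_subcategories
    preferred: [{keys: [chickpeas], min: 1, max: 2}]
    less_restrictive: [{keys: [chickpeas], min: 1, max: 3}]
  - id: wk_milk_yogurt
    scope: weekly
    dairy: true
    preferred: [{keys: [milk_yogurt], min: 14, max: 21}]
  - id: wk_cheese
    scope: weekly
    dairy: true
    preferred: [{keys: [cheese], min: 2, max: 3}]
    less_restrictive: [{keys: [cheese], min: 2, max: 4}]
  - id: wk_plant_beverage_yogurt
    scope: weekly
    allergy_only: true
    preferred: [{keys: [plant_beverage_yogurt], min: 14, max: 21}]
  - id: wk_plant_cheese
    scope: weekly
    allergy_only: true
    preferred: [{keys: [plant_cheese], min: 2, max: 3}]
    less_restrictive: [{keys: [plant_cheese], min: 2, max: 4}]
  - id: wk_fish_seafood
    scope: weekly
    preferred: [{keys: [fish_seafood], min: 2, max: 4}]
    less_restrictive: [{keys: [fish_seafood], min: 2, max: 5}]
  - id: wk_white_meat
    scope: weekly
    preferred: [{keys: [white_meat], max: 2}]
    note: if the white-meat sub-categories are too restrictive, only this
      macro category is kept
  - id: wk_turkey
    scope: weekly
    drop_group: white_meat_subcategories
    preferred: [{keys: [turkey], max: 1}]
  - id: wk_rabbit
    scope: weekly
    drop_group: white_meat_subcategories
    preferred: [{keys: [rabbit], max: 1}]
  - id: wk_chicken
    scope: weekly
    drop_group: white_meat_subcategories
    preferred: [{keys: [chicken], max: 2}]
  - id: wk_red_processed_meat
    scope: weekly
    preferred:
      - {keys: [red_meat], max: 1}
      - {keys: [processed_meat], max: 1}
    less_restrictive:
      - {keys: [red_meat, processed_meat], max: 2}
  - id: wk_eggs
    scope: weekly
    preferred: [{keys: [eggs], min: 1, max: 3}]
  - id: wk_carbohydrates
    scope: weekly
    preferred: [{keys: [bread, pasta, rice, tubers, cereals], min: 21, max: 35}]
  - id: wk_bread
    scope: weekly
    preferred: [{keys: [bread], max: 14}]
  - id: wk_tubers
    scope: weekly
    preferred: [{keys: [tubers], max: 7}]
    less_restrictive: [{keys: [tubers], max: 14}]
  - id: wk_rice
    scope: weekly
    preferred: [{keys: [rice], max: 7}]
    less_restrictive: [{keys: [rice], max: 14}]
  - id: wk_cereals
    scope: weekly
    preferred: [{keys: [cereals], max: 7}]
    less_restrictive: [{keys: [cereals], max: 14}]
  - id: wk_pasta
    scope: weekly
    preferred: [{keys: [pasta], max: 7}]
  - id: wk_fruit
    scope: weekly
    preferred: [{keys: [fruit], min: 21, max: 28}]
  - id: wk_vegetables
    scope: weekly
    preferred: [{keys: [raw_vegetables, cooked_vegetables], min: 14, max: 21}]
    less_restrictive: [{keys: [raw_vegetables, cooked_vegetables], min: 14, max: 28}]
  # -- daily ----------------------------------------------------------------
  - id: d_pulses
    scope: daily
    preferred: [{keys: [pulses], max: 2}]
  - id: d_milk_yogurt
    scope: daily
    dairy: true
    preferred: [{keys: [milk_yogurt], max: 3}]
  - id: d_cheese
    scope: daily
    dairy: true
    preferred: [{keys: [cheese], max: 1}]
  - id: d_plant_beverage_yogurt
    scope: daily
    allergy_only: true
    preferred: [{keys: [plant_beverage_yogurt], max: 3}]
  - id: d_plant_cheese
    scope: daily
    allergy_only: true
    preferred: [{keys: [plant_cheese], max: 1}]
  - id: d_fish_seafood
    scope: daily
    preferred: [{keys: [fish_seafood], max: 1}]
  - id: d_all_meat
    scope: daily
    preferred: [{keys: [white_meat, red_meat, processed_meat], max: 1}]
  - id: d_eggs
    scope: daily
    preferred: [{keys: [eggs], max: 1}]
  - id: d_bread
    scope: daily
    preferred: [{keys: [bread], max: 3}]
  - id: d_tubers
    scope: daily
    preferred: [{keys: [tubers], max: 1}]
    less_restrictive: [{keys: [tubers], max: 2}]
  - id: d_rice
    scope: daily
    preferred: [{keys: [rice], max: 1}]
    less_restrictive: [{keys: [rice], max: 2}]
  - id: d_cereals
    scope: daily
    preferred: [{keys: [cereals], max: 1}]
    less_restrictive: [{keys: [cereals], max: 2}]
  - id: d_pasta
    scope: daily
    preferred: [{keys: [pasta], max: 1}]
  - id: d_fruit
    scope: daily
    preferred: [{keys: [fruit], min: 3}]
  - id: d_vegetables
    scope: daily
    preferred: [{keys: [raw_vegetables, cooked_vegetables], min: 2}]
  - id: d_color_red
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:red"], max: 2}]
    less_restrictive: [{keys: ["color:red"], max: 3}]
  - id: d_color_green
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:green"], max: 2}]
    less_restrictive: [{keys: ["color:green"], max: 3}]
  - id: d_color_white
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:white"], max: 2}]
    less_restrictive: [{keys: ["color:white"], max: 3}]
  - id: d_color_yellow
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:yellow"], max: 2}]
    less_restrictive: [{keys: ["color:yellow"], max: 3}]
  - id: d_color_purple
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:purple"], max: 2}]
    less_restrictive: [{keys: ["color:purple"], max: 3}]
  - id: d_color_multicolor
    scope: daily
    drop_group: colors
    preferred: [{keys: ["color:multicolor"], max: 2}]
    less_restrictive: [{keys: ["color:multicolor"], max: 3}]
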