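# Adult Mediterranean-diet + diversity/food-group-variety ruleset.
# All bounds are maxima (minimum intake enters through the fruit-and-
# vegetable partial score, not through frequency rules) and none of them
# is relaxable.  Beyond these frequency families, the structural checks
# (repeating dishes <=1/day, white/red meat, pork, fish and pasta <=1/day
# across lunch+dinner, repeating meals <=2/week) are evaluated from the
# day/slot structure by the rules engine.
version: 1
audience: adult
meal_repetition_max: 2
meal_repetition_consecutive: false
families:
  - id: d_eggs
    scope: daily
    preferred: [{keys: [eggs], max: 1}]
  - id: wk_turkey
    scope: weekly
    preferred: [{keys: [turkey], max: 1}]
  - id: wk_rabbit
    scope: weekly
    preferred: [{keys: [rabbit], max: 1}]
  - id: wk_red_meat
    scope: weekly
    preferred: [{keys: [red_meat], max: 2}]
  - id: wk_chicken
    scope: weekly
    preferred: [{keys: [chicken], max: 2}]
  - id: wk_white_red_beans
    scope: weekly
    preferred: [{keys: [white_red_beans], max: 2}]
  - id: wk_other_pulses
    scope: weekly
    preferred: [{keys: [other_pulses], max: 2}]
  - id: wk_processed_meat
    scope: weekly
    preferred: [{keys: [processed_meat], max: 2}]
  - id: wk_chickpeas
    scope: weekly
    preferred: [{keys: [chickpeas], max: 3}]
  - id: wk_lentils
    scope: weekly
    preferred: [{keys: [lentils], max: 3}]
  - id: wk_rice
    scope: weekly
    preferred: [{keys: [rice], max: 3}]
  - id: wk_pasta
    scope: weekly
    preferred: [{keys: [pasta], max: 3}]
  - id: wk_red_white_meat
    scope: weekly
    preferred: [{keys: [red_meat, white_meat], max: 4}]
  - id: wk_pulses
    scope: weekly
    preferred: [{keys: [pulses], max: 6}]
  - id: wk_fish_seafood
    scope: weekly
    preferred: [{keys: [fish_seafood], max: 6}]
  - id: wk_fish_main
    scope: weekly
    preferred: [{keys: [fish_main], max: 3}]
    note: fish at most three times per week as a main dish
  - id: wk_fish_side
    scope: weekly
    preferred: [{keys: [fish_side], max: 4}]
    note: fish at most four times per week as a side dish
  - id: d_fruit_salad
    scope: daily
    preferred: [{keys: [fruit_salad], max: 1}]
  - id: wk_fruit_salad
    scope: weekly
    preferred: [{keys: [fruit_salad], max: 2}]
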