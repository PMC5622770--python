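# Table schemas

All interchange files are comma-delimited text with a header row.

## participants.csv

| column | type | notes |
| --- | --- | --- |
| participant_id | string | opaque key, unique |
| age_years | int >= 1 | ages below 1 are rejected |
| sex | `male` / `female` | |
| race_eth | `NHWhite` / `NHBlack` / `MexAmerican` / `OtherHispanic` / `OtherMixed` | |
| wic_flag | bool | WIC program participation in the past year |
| stratum_id | string | design stratum; must contain exactly 2 PSUs |
| psu_id | int | primary sampling unit within stratum |
| weight_day1 | float >= 0 | day-1 dietary weight |
| weight_2day | float >= 0 | two-day dietary weight; > 0 iff n_recalls = 2 |
| n_recalls | 1 or 2 | |

`age_group` is always derived from `age_years` on read
(1-3, 4-8, 9-13, 14-19, 20-30, 31-50, 51-70, 71+); a column of that name
in the file is ignored.

## food_records.csv

| column | type | notes |
| --- | --- | --- |
| participant_id | string | must exist in participants.csv |
| recall_day | 1 or 2 | must not exceed the participant's n_recalls |
| line_id | string | unique within person-day |
| food_code | string | 8-digit convention; prefixes 571-574 mark ready-to-eat cereal |
| occasion | string | normalized on read to: breakfast, desayuno, brunch, lunch, dinner, snack, beverage_occasion, other |
| grams | float > 0 | |
| energy_kcal | float >= 0 | |
| fiber_g, vitaminD_ug, calcium_mg, potassium_mg, magnesium_mg, iron_mg, folic_acid_ug, vitaminB12_ug, sodium_mg, sfa_g, mufa_g, pufa_g, alcohol_g | float >= 0 | nutrient amounts for the record |
| whole_grain_ozeq, refined_grain_ozeq, dairy_cupeq, total_fruit_cupeq, whole_fruit_cupeq, total_veg_cupeq, greens_beans_cupeq, protein_ozeq, seafood_plant_ozeq, solid_fat_g, added_sugar_tspeq | float >= 0 | food-pattern equivalents |
| price_per_100g | float >= 0 | USD per 100 g edible portion |
| is_beverage | bool | input flag (beverage identification is code-list based upstream) |
| is_beverage_addition | bool | e.g. sugar added to coffee; requires a beverage at the same person-day occasion |
| is_rtec | bool | recomputed from the food-code prefix on read |
| is_milk | bool | input flag |

Substituted outputs add `model_id` (`observed`/`model1`/`model2`) and
`synthetic` (true for inserted composite records).

## prices.csv

| column | type |
| --- | --- |
| food_code | string |
| price_per_100g | float >= 0 |
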