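# HEI-2010 component scoring standards.
#
# density_basis:
#   per_1000kcal  - constituent amount per 1000 kcal of energy
#   fatty_acid_ratio - (MUFA + PUFA) / SFA
#   pct_energy    - percent of total energy
# direction: adequacy (more is better) or moderation (less is better).
# Points interpolate linearly between zero_threshold and max_threshold,
# clamped to [0, max_points].  Every value here is overridable.
components:
  total_fruit:
    constituent: total_fruit_cupeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 0.8
    max_points: 5
  whole_fruit:
    constituent: whole_fruit_cupeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 0.4
    max_points: 5
  total_vegetables:
    constituent: total_veg_cupeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 1.1
    max_points: 5
  greens_and_beans:
    constituent: greens_beans_cupeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 0.2
    max_points: 5
  whole_grains:
    constituent: whole_grain_ozeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 1.5
    max_points: 10
  dairy:
    constituent: dairy_cupeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 1.3
    max_points: 10
  total_protein_foods:
    constituent: protein_ozeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 2.5
    max_points: 5
  seafood_plant_proteins:
    constituent: seafood_plant_ozeq
    density_basis: per_1000kcal
    direction: adequacy
    zero_threshold: 0.0
    max_threshold: 0.8
    max_points: 5
  fatty_acids:
    constituent: fatty_acid_ratio
    density_basis: fatty_acid_ratio
    direction: adequacy
    zero_threshold: 1.2
    max_threshold: 2.5
    max_points: 10
  refined_grains:
    constituent: refined_grain_ozeq
    density_basis: per_1000kcal
    direction: moderation
    zero_threshold: 4.3
    max_threshold: 1.8
    max_points: 10
  sodium:
    constituent: sodium_mg
    density_basis: per_1000kcal
    direction: moderation
    zero_threshold: 2000.0
    max_threshold: 1100.0
    max_points: 10
  empty_calories:
    constituent: sofaas_kcal
    density_basis: pct_energy
    direction: moderation
    zero_threshold: 50.0
    max_threshold: 19.0
    max_points: 20
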