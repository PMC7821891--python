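# Dietary reference intakes for healthy, non-pregnant, non-lactating women
# aged 19-30 years (U.S. Institute of Medicine / National Academies DRI
# tables).  Amounts are per day.  Lower bounds are EARs; upper bounds are
# ULs, except sodium where the 2019 CDRR (2300 mg/day) serves as the upper
# bound.  Magnesium has no upper bound here because the IOM UL applies to
# supplemental magnesium only.  The vitamin A EAR applies to total vitamin A
# in retinol activity equivalents; the UL applies to preformed retinol and
# is carried on a separate "retinol" row.  Edit and reload with
# RequirementSet.from_yaml to change any of these roles.
reference: "women 19-30 y, 57 kg, 163 cm, low-active physical activity"
energy:
  eer:
    sex: female
    age_years: 24.5
    weight_kg: 57.0
    height_m: 1.63
    pal: low_active
amdr:
  protein:      {lower: 0.10, upper: 0.35}
  carbohydrate: {lower: 0.45, upper: 0.65}
  lipid:        {lower: 0.20, upper: 0.35}
nutrients:
  # macronutrients (g/day); protein EAR = 0.66 g/kg x 57 kg
  protein:       {lower: 37.62, unit: g}
  carbohydrate:  {lower: 100.0, unit: g}
  lipid:         {unit: g}                       # bounded via AMDR only
  # minerals
  calcium:       {lower: 800.0, upper: 2500.0, unit: mg}
  iron:          {lower: 8.1,   upper: 45.0,   unit: mg}
  magnesium:     {lower: 255.0,                unit: mg}
  phosphorus:    {lower: 580.0, upper: 4000.0, unit: mg}
  zinc:          {lower: 6.8,   upper: 40.0,   unit: mg}
  copper:        {lower: 0.7,   upper: 10.0,   unit: mg}
  selenium:      {lower: 45.0,  upper: 400.0,  unit: ug}
  sodium:        {upper: 2300.0,               unit: mg}   # CDRR
  # vitamins
  vitamin_c:     {lower: 60.0,  upper: 2000.0, unit: mg}
  thiamin:       {lower: 0.9,                  unit: mg}
  riboflavin:    {lower: 0.9,                  unit: mg}
  niacin:        {lower: 11.0,  upper: 35.0,   unit: mg}
  vitamin_b6:    {lower: 1.1,   upper: 100.0,  unit: mg}
  folate:        {lower: 320.0, upper: 1000.0, unit: ug}
  vitamin_b12:   {lower: 2.0,                  unit: ug}
  vitamin_a_rae: {lower: 500.0,                unit: ug}
  retinol:       {upper: 3000.0,               unit: ug}
  vitamin_e:     {lower: 12.0,  upper: 1000.0, unit: mg}
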