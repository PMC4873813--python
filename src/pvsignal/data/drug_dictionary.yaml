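# Built-in drug synonym dictionary: lowercased name variants (trade names,
# salts, abbreviations) -> unified generic name.  Every generic also resolves
# to itself automatically.  Salt-form suffixes listed here are stripped from
# the end of a name before the second lookup attempt.
#
# This ships as a small, documented starting point covering the drugs the
# package's examples use; real analyses should supply a comprehensive mapping.

salt_suffixes:
  - fumarate
  - hydrochloride
  - hcl
  - maleate
  - besylate
  - mesylate
  - succinate
  - tartrate
  - citrate
  - sodium
  - potassium
  - calcium
  - carbonate
  - sulfate
  - acetate
  - dihydrate
  - monohydrate

mapping:
  seroquel: quetiapine
  seroquel xr: quetiapine
  quetiapin: quetiapine
  zyprexa: olanzapine
  zyprexa zydis: olanzapine
  risperdal: risperidone
  risperdal consta: risperidone
  abilify: aripiprazole
  geodon: ziprasidone
  zeldox: ziprasidone
  clozaril: clozapine
  leponex: clozapine
  haldol: haloperidol
  lyrica: pregabalin
  lamictal: lamotrigine
  eskalith: lithium
  lithobid: lithium
  glucophage: metformin
  rocaltrol: calcitriol
  calcijex: calcitriol
  one-alpha: alfacalcidol
  hectorol: doxercalciferol
  zemplar: paricalcitol
  dovonex: calcipotriol
  vitamin d3: cholecalciferol
  colecalciferol: cholecalciferol
  vitamin d2: ergocalciferol
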