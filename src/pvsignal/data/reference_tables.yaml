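# Reference contingency counts from a published disproportionality analysis of
# a large spontaneous-report database (FAERS, 2004Q1-2014Q2; 4,547,841
# deduplicated reports) on antipsychotic-associated diabetes-related adverse
# events.  Counts are event/total marginals per arm; the published odds ratio
# and 95% CI (2 dp, Wald) are kept alongside so recomputations can be checked
# against the printed values.
#
# Schema per row: a (exposed with event), n_exposed (= a+b),
#                 c (unexposed with event), n_unexposed (= c+d),
#                 or/ci_low/ci_high: published values at 2 dp.

population:
  raw_reports: 5821354
  deduplicated_reports: 4547841

# Full-population reporting odds ratios for diabetes-related events.
antipsychotic_risk:
  - {drug: quetiapine,   a: 10809, n_exposed: 65453, c: 37373, n_unexposed: 4482388, or: 23.53, ci_low: 22.99, ci_high: 24.07, tier: strong}
  - {drug: olanzapine,   a: 6514,  n_exposed: 32483, c: 41668, n_unexposed: 4515358, or: 26.93, ci_low: 26.17, ci_high: 27.72, tier: strong}
  - {drug: risperidone,  a: 3800,  n_exposed: 34262, c: 44382, n_unexposed: 4513579, or: 12.56, ci_low: 12.13, ci_high: 13.01, tier: intermediate}
  - {drug: aripiprazole, a: 2175,  n_exposed: 28894, c: 46007, n_unexposed: 4518947, or: 7.91,  ci_low: 7.57,  ci_high: 8.28,  tier: intermediate}
  - {drug: ziprasidone,  a: 1613,  n_exposed: 12974, c: 46569, n_unexposed: 4534867, or: 13.68, ci_low: 12.98, ci_high: 14.43, tier: intermediate}
  - {drug: clozapine,    a: 1058,  n_exposed: 30021, c: 47124, n_unexposed: 4517820, or: 3.47,  ci_low: 3.26,  ci_high: 3.69,  tier: low}

# Confounder-stratified ORs for the quetiapine / diabetes association.
quetiapine_strata:
  - {dimension: event_term, label: diabetes mellitus,     a: 7668, n_exposed: 65453, c: 20092, n_unexposed: 4482388, or: 29.47, ci_low: 28.67, ci_high: 30.30}
  - {dimension: event_term, label: diabetic ketoacidosis, a: 1258, n_exposed: 65453, c: 2897,  n_unexposed: 4482388, or: 30.30, ci_low: 28.35, ci_high: 32.39}
  - {dimension: event_term, label: diabetic coma,         a: 876,  n_exposed: 65453, c: 885,   n_unexposed: 4482388, or: 68.69, ci_low: 62.55, ci_high: 75.44}
  - {dimension: age, label: "<40 years",   a: 2229, n_exposed: 16317, c: 3622, n_unexposed: 657664, or: 28.57, ci_low: 27.03, ci_high: 30.20}
  - {dimension: age, label: "40–49 years", a: 2813, n_exposed: 11828, c: 3982, n_unexposed: 391629, or: 30.38, ci_low: 28.82, ci_high: 32.02}
  - {dimension: age, label: "50–59 years", a: 1690, n_exposed: 10574, c: 5929, n_unexposed: 547124, or: 17.36, ci_low: 16.39, ci_high: 18.40}
  - {dimension: age, label: "60–69 years", a: 409,  n_exposed: 4932,  c: 5170, n_unexposed: 536481, or: 9.29,  ci_low: 8.37,  ci_high: 10.32}
  - {dimension: age, label: "≥70 years",   a: 175,  n_exposed: 5067,  c: 4100, n_unexposed: 616472, or: 5.34,  ci_low: 4.58,  ci_high: 6.23}
  - {dimension: sex, label: male,   a: 4512, n_exposed: 24882, c: 14129, n_unexposed: 1572620, or: 24.43, ci_low: 23.56, ci_high: 25.33}
  - {dimension: sex, label: female, a: 6010, n_exposed: 37798, c: 18996, n_unexposed: 2537316, or: 25.06, ci_low: 24.30, ci_high: 25.85}
  - {dimension: indication, label: schizophrenia,    a: 1398, n_exposed: 4160,  c: 1060, n_unexposed: 27277, or: 12.52, ci_low: 11.45, ci_high: 13.68}
  - {dimension: indication, label: bipolar disorder, a: 2459, n_exposed: 10676, c: 649,  n_unexposed: 23332, or: 10.46, ci_low: 9.56,  ci_high: 11.45}
  - {dimension: co_drug, label: haloperidol, a: 1219, n_exposed: 2712, c: 308, n_unexposed: 12393, or: 32.04, ci_low: 27.96, ci_high: 36.71}
  - {dimension: co_drug, label: lithium,     a: 785,  n_exposed: 3771, c: 351, n_unexposed: 13116, or: 9.56,  ci_low: 8.38,  ci_high: 10.91}

# Mitigation screen within the quetiapine cohort: the three concomitant drugs
# published as significantly associated with decreased event occurrence.
quetiapine_cohort_mitigation:
  - {drug: pregabalin,  a: 184, n_exposed: 1377, c: 10625, n_unexposed: 64076, or: 0.78, ci_low: 0.66, ci_high: 0.91}
  - {drug: lamotrigine, a: 422, n_exposed: 4055, c: 10387, n_unexposed: 61398, or: 0.57, ci_low: 0.51, ci_high: 0.63}
  - {drug: vitamin d,   a: 66,  n_exposed: 1171, c: 10743, n_unexposed: 64282, or: 0.30, ci_low: 0.23, ci_high: 0.38}

# Published standalone (full-population) ORs for the screen hits; no raw
# counts were printed for these, so they are context, not recomputation input.
standalone_or:
  pregabalin:  {or: 1.33, ci_low: 1.25, ci_high: 1.41}
  lamotrigine: {or: 1.41, ci_low: 1.30, ci_high: 1.52}
  vitamin d:   {or: 1.01, ci_low: 0.94, ci_high: 1.07, p_value: 0.86}

# Co-occurrence among diabetes event cases exposed to ziprasidone.
ziprasidone_cooccurrence:
  event_cases_with_ziprasidone: 1613
  also_received_quetiapine: 1368
  quetiapine_primary_suspect: 1250
  ziprasidone_primary_suspect: 91

# Published relative-expression fold changes of insulin-resistance pathway
# genes (rat liver, drug vs vehicle), used as scenario parameters for the
# expression-overlay generator.  "unchanged" lists the remaining pathway
# genes measured but not significantly altered.
insulin_resistance_overlay:
  pathway_id: map04931
  downregulated:
    Pik3r1: 0.39
    Cpt1b: 0.46
    Mapk9: 0.46
    Prkab1: 0.50
    Gsk3b: 0.63
    Frap1: 0.66
    Gys2: 0.67
    Ptpn11: 0.70
    Ikbkb: 0.70
    Prkaa2: 0.74
  upregulated:
    Mapk8: 1.30
  unchanged:
    - Insr
    - Irs1
    - Akt2
    - Slc2a4
    - Pygl
    - Ppp1ca
    - Pten
    - Rps6kb1
    - Prkcd
    - Socs3
    - Stat3
    - Il6
    - Tnf
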