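# Methods

## The problem

Spontaneous adverse-event reporting systems (such as the FDA's FAERS)
collect self-reports of suspected drug harms. Because there is no
denominator of drug users, association is measured by *disproportionality*:
does an event appear more often among reports mentioning a drug than among
reports that do not?  `pvsignal` implements this analysis end to end for
the motivating use case — quantifying the diabetes-related risk of atypical
antipsychotics and screening for co-medications that mitigate it — and an
accompanying toxicogenomics step that overlays a treated-vs-vehicle
expression matrix onto a pathway gene set to suggest a mechanism.

## Report model and preprocessing

A *case* is one spontaneous report, possibly resubmitted several times with
an increasing version ordinal.  Deduplication keeps the highest version per
case id (ties keep the last-seen record, with a warning, since "most
recent" does not order equal versions); one deduplicated case is counted as
one individual, the only interpretation a spontaneous-report database
supports.  Reports whose source dialect supplies dates rather than version
ordinals should map date → ordinal at load time.

Drug names are normalized by dictionary lookup after lowercasing, trimming
punctuation/whitespace, and stripping a configurable list of trailing
salt-form words ("fumarate", "hydrochloride", …).  Unmatched names are kept
under their cleaned verbatim form and counted — an unmatched name is an
outcome, not an error.  Free-text mining beyond dictionary lookup is out of
scope.  Event and drug-class membership is exact string matching of
lowercased preferred-term-style strings against configurable term sets;
substring matching is deliberately not used so that counts are
reproducible.  The shipped diabetes and vitamin-D term sets are documented
approximations and are meant to be replaced for production use.

Reports with missing age or sex are retained in overall analyses and
excluded from the corresponding stratum analyses only, which is why stratum
totals need not sum to the overall total.

## Reporting odds ratio

With reports cross-classified as a (drug & event), b (drug, no event),
c (event, no drug), d (neither):

    OR  = (a/b) / (c/d)
    CI  = exp( ln OR ± z · √(1/a + 1/b + 1/c + 1/d) ),  z = 1.96 by default
    p   = two-sided normal tail of  ln OR / √(1/a + 1/b + 1/c + 1/d)

The Wald z-test is used for the p-value because it is the test consistent
with the Wald interval; Fisher's exact test is available as an option
(`fisher_p`) but is never the default.  Zero cells raise an error by
default; an optional Haldane–Anscombe correction adds 0.5 to every cell and
flags the result.  The mitigation screen uses the flagged continuity mode
internally so that a rare candidate with an empty cell is comparable rather
than fatal.

Signals: lower CI bound > 1 is a *risk* signal, upper bound < 1 is
*protective*, anything else is no signal.  Risk signals are tiered by the
point estimate — strong (> 20), intermediate (> 5), low (≤ 5) — with
boundary values assigned to the lower tier (the published tier wording uses
strict inequalities and leaves exactly 5 and 20 unassigned).

Display values are rounded half-even at 2 decimal places, and the packaged
reference counts reproduce all 23 published OR/CI pairs at that precision
(6 antipsychotic rows, 14 confounder strata, 3 within-cohort mitigation
rows), which is the validation of this formula choice.

## Mitigation screen

Within the cohort of reports exposed to drug A, every other drug B
co-occurring on at least `min_exposed` cohort reports (default 1000 —
odds ratios fluctuate badly below that) is tested for association with the
event inside the cohort.  Candidates with upper CI bound < 1 are returned
sorted ascending by OR (most protective first, ties broken by name) with
1-based ranks.  Co-exposure counts any role code.  Two annotations are
attached to each hit rather than used as filters: the drug's standalone
full-population OR (a hit whose solo effect is itself a risk signal is
suspect — the published screen discarded two such candidates), and the
fraction of its cohort users whose recorded indication falls in the event
domain (indication bias: a drug prescribed *for* the event domain will look
associated with it, the reason a metformin-style hit is untrustworthy).
Only significantly protective candidates are ranked; non-significant ones
are not reported.

## Stratified analyses

Five stratification dimensions are supported.  `event_term` narrows the
event definition to a single term without restricting the population;
`age`, `sex` and `indication` restrict the analysed population to the
stratum (missing stratum variables exclude a report from that dimension
only; unknown sex is excluded from both arms); `co_drug` restricts **both**
the exposed and unexposed arms to users of the co-medication — the only
reading consistent with published drug-combination stratum totals that are
far smaller than the full database.  Age bins are half-open `[lo, hi)` with
the published edges <40, 40–49, 50–59, 60–69, ≥70 as defaults.  A stratum
with an empty contingency cell yields a flagged not-estimable record, not
an error, and no pooling (Mantel–Haenszel or otherwise) is attempted —
strata are reported side by side.

The suspect-fraction computation takes the deduplicated event reports
exposed to a cohort drug as denominator and reports (i) the fraction also
exposed to a second drug and (ii) the fraction in which that second drug
carries the primary-suspect role; the second can never exceed the first.

## Expression overlay

The input is a probes × samples matrix of log2 intensities with a two-level
group factor and a pathway gene set.  Per probe mapping into the pathway:
values are back-transformed (2^x), each treated sample is divided by the
vehicle-group mean, and those ratios are summarised as mean ± SEM — the SEM
is that of the treated-group ratios, with the vehicle group entering only
through its mean, the only definition consistent with a "±" column under
heavily unequal group sizes.  Significance uses Welch's two-sample t-test
on the log2 scale by default (original-scale testing by flag); probes with
p < α are reported sorted ascending by relative expression and classified
down (< 1) or up.  Duplicate probes per gene are reported per probe.  No
multiple-testing correction is applied by default, matching the screening
character of the published analysis; a Benjamini–Hochberg option exists.

**Known limitation — small-sample size distortion.**  With 3 samples in the
treated group the Satterthwaite degrees-of-freedom approximation is
anti-conservative: the true size of the Welch test at α = 0.05, measured
here over 10⁵ null replicates, is ≈ 0.075 at 20-vs-3 (0.056 at 20-vs-5,
nominal at balanced sizes).  The test suite therefore calibrates the
machinery on a balanced null design and pins the 20-vs-3 inflation in its
own test; borderline p-values from 3-sample groups should be read
accordingly.  Degenerate zero-variance probes: identical groups give p = 1
with a warning; separated constant groups give p = 0 (the package reports
the trivially correct answer rather than a fixed p = 1 for any degenerate
input).

## Synthetic data generators

The report generator draws, per report: age (five bins with the published
edges plus a missing-age mass; defaults give ≈ 61% age completeness,
matching large spontaneous-report databases), sex (35% male / 57% female /
8% unknown, the female skew of such databases), indications (independent
Bernoulli), drug exposures (independent Bernoulli, except that an
indication linked to a drug multiplies its exposure probability — the
mechanism that produces indication bias on demand), and the event from a
logistic model: `logit P(event) = baseline + Σ solo effects + Σ interaction
effects` over drugs present.  The default baseline is a 1% event rate, the
order observed for the diabetes event family in the motivating database.
Event reports receive a diabetes-set term, others a neutral term.  The
primary-suspect role goes to the present drug with the largest total
log-odds contribution.  Duplicate submissions (earlier-version copies of
sampled cases) and verbatim-name variants (drawn from the dictionary's
inverse map) are injected at configured rates with exact bookkeeping.

Ground-truth marginal and within-cohort odds ratios are computed by exact
enumeration over indication × drug presence patterns weighted by their
probabilities — a closed form, not a simulation average — so
non-collapsibility of the OR is handled exactly.

Two named scenarios fix the calibration-study conditions:

* `solo_effect_scenario`: one drug, prevalence 0.10, solo OR 20, baseline
  1%, 200,000 reports — CI-coverage calibration.  Measured: the 95% Wald
  interval covers the generating OR in ≈ 95–96% of replicates.
* `protective_interaction_scenario`: a risk drug A (prevalence 0.20, solo
  OR 20 — sized so the A-cohort is ~40,000 reports, the order of the real
  drug-of-interest cohort, and a 5%-prevalence candidate B clears the
  1000-report co-exposure floor), B acting only through a protective
  interaction with A (OR 0.3), and three decoy co-medications (two null,
  one with a mild solo risk of 1.4).  The screen must return B at rank 1
  with a truth-covering CI.

The expression generator writes `baseline + log2(FC if treated) + N(0, sd)`
per probe and sample.  Defaults are 20 vehicle vs 3 treated samples (the
published design) and a within-group log2 s.d. of 0.1 — the replicate
precision implied by the reported SEMs of the well-measured pathway genes
on this class of array (several imply per-sample log2 s.d. ≈ 0.08–0.2); it
is a per-config parameter, and tests of estimator behaviour under heavier
noise use 0.2.  The pathway scenario plants the eleven published fold
changes (ten between 0.39 and 0.74, one at 1.30) and thirteen unchanged
pathway genes.

### What the generators do *not* emulate

Reporting dynamics over time, stimulated reporting and Weber effects,
correlated polypharmacy beyond the indication-link mechanism, MedDRA
hierarchy structure, per-gene variance heterogeneity, and probe-level
cross-hybridisation.  Passing tests therefore demonstrate that the
statistics recover what this generative model injects — they do not certify
performance on real reporting streams, whose biases are broader.

## Problem sizes and numerical choices

Calibration studies use 500 replicates (CI coverage) and 100 replicates
(screen recovery) of 200,000-report populations, drawn through a vectorised
path that materialises only exposure and event arrays; full report objects
are built only where the ingestion pipeline itself is under test.  Multi-
stratum consistency checks use a 99.9% per-stratum band so the joint error
rate across five strata stays near 0.5%.  Recovery of a fold-change
estimate with 3 treated samples is judged against `t(0.975, df=2) · SEM`
(≈ 4.30 · SEM), the correct 95% interval for an SEM carrying 2 degrees of
freedom.  Seeds fix every stream end to end: identical seed and config give
byte-identical written files.

## Out of scope

Downloading real quarterly report archives or public expression accessions;
licence-dependent terminology hierarchies; probabilistic record linkage;
Bayesian shrinkage signal scores (EBGM, IC) and the proportional reporting
ratio; propensity or regression adjustment (the published method is
restriction plus stratification only); microarray preprocessing and pathway
diagram rendering.
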