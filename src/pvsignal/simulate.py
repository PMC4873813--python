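"""Synthetic data with known ground truth for both pipeline arms.

Spontaneous reports are generated from a logistic event model: each report
draws demographics, indications and drug exposures, and the event occurs
with probability ``expit(baseline + Σ solo effects + Σ interaction
effects)`` over the drugs present.  Exposures are independent Bernoulli
draws except where an indication is linked to a drug, which multiplies that
drug's exposure probability on reports carrying the indication — the
mechanism behind indication bias.  Duplicate submissions and verbatim-name
variants are injected at configurable rates so that deduplication and
dictionary normalization can be validated against generator bookkeeping.

Ground-truth marginal and within-cohort odds ratios are computed exactly by
enumeration over indication × drug presence patterns weighted by their
probabilities — an independent closed form, not a simulation average.

Expression matrices are generated as ``baseline + log2(fold change if
treated) + N(0, sd)`` per probe and sample, emulating a two-group rat
toxicogenomics microarray with heavily unbalanced groups (default 20
vehicle vs 3 treated).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .faers_io import write_faers_files  # noqa: F401  (re-exported)
from .overlay import ExpressionMatrix
from .reports import CaseReport, DrugDictionary, DrugExposure, Role, Sex
from .ror import ContingencyTable, odds_ratio
from .screen import MitigationScreen

# Five age bins (<40, 40-49, 50-59, 60-69, >=70) plus a missing-age mass;
# defaults follow the completeness and shape of a large spontaneous-report
# database (~61% of reports carry an age).
DEFAULT_AGE_BIN_PROBS = (0.147, 0.087, 0.122, 0.120, 0.138, 0.386)
AGE_EDGES = (0.0, 40.0, 50.0, 60.0, 70.0, 100.0)

# (male, female, unknown); spontaneous reporting skews female.
DEFAULT_SEX_PROBS = (0.351, 0.566, 0.083)

DEFAULT_EVENT_TERMS = ("diabetes mellitus", "diabetic ketoacidosis", "diabetic coma")
DEFAULT_NEUTRAL_TERMS = ("nausea", "headache", "dizziness", "rash")

_ENUMERATION_LIMIT = 22  # 2^(drugs+indications) patterns


def _check_prob(p: float, what: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{what} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class DrugSpec:
    """One simulated drug: marginal exposure prevalence and its solo
    log-odds effect on the event (0 = null)."""

    name: str
    prevalence: float
    effect: float = 0.0

    def __post_init__(self):
        _check_prob(self.prevalence, f"prevalence of {self.name}")


@dataclass(frozen=True)
class Interaction:
    """Extra log-odds effect when both drugs are on the same report."""

    drug_a: str
    drug_b: str
    effect: float


@dataclass(frozen=True)
class IndicationSpec:
    """An indication term with its prevalence; when ``linked_drug`` is set,
    that drug's exposure probability is multiplied by ``exposure_multiplier``
    on reports carrying the indication (capped at 1)."""

    term: str
    prevalence: float
    linked_drug: str | None = None
    exposure_multiplier: float = 1.0

    def __post_init__(self):
        _check_prob(self.prevalence, f"prevalence of indication {self.term}")
        if self.exposure_multiplier < 0:
            raise ConfigError("exposure_multiplier must be >= 0")


@dataclass(frozen=True)
class ReportSimConfig:
    n_reports: int = 10_000
    drugs: tuple[DrugSpec, ...] = ()
    interactions: tuple[Interaction, ...] = ()
    # logit of a 1% background event rate, the order observed for a broad
    # event family in a large spontaneous-report database
    baseline_event_logit: float = math.log(0.01 / 0.99)
    age_bin_probs: tuple[float, ...] = DEFAULT_AGE_BIN_PROBS
    sex_probs: tuple[float, float, float] = DEFAULT_SEX_PROBS
    indications: tuple[IndicationSpec, ...] = ()
    event_term_pool: tuple[str, ...] = DEFAULT_EVENT_TERMS
    neutral_term_pool: tuple[str, ...] = DEFAULT_NEUTRAL_TERMS
    duplicate_rate: float = 0.05
    name_variant_rate: float = 0.0
    dictionary: DrugDictionary | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        names = [d.name for d in self.drugs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate drug names in config")
        for inter in self.interactions:
            for drug in (inter.drug_a, inter.drug_b):
                if drug not in names:
                    raise ConfigError(f"interaction references unknown drug {drug!r}")
        for spec in self.indications:
            if spec.linked_drug is not None and spec.linked_drug not in names:
                raise ConfigError(f"indication links unknown drug {spec.linked_drug!r}")
        _check_prob(self.duplicate_rate, "duplicate_rate")
        _check_prob(self.name_variant_rate, "name_variant_rate")
        if abs(sum(self.age_bin_probs) - 1.0) > 1e-9 or len(self.age_bin_probs) != 6:
            raise ConfigError("age_bin_probs must be 6 probabilities summing to 1")
        if abs(sum(self.sex_probs) - 1.0) > 1e-9:
            raise ConfigError("sex_probs must sum to 1")
        if self.name_variant_rate > 0 and self.dictionary is None:
            raise ConfigError("name_variant_rate > 0 requires a dictionary")

    @property
    def drug_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.drugs)


# ---------------------------------------------------------------------------
# Closed-form ground truth


def _exposure_probs_given_ind(config: ReportSimConfig, ind_pattern: tuple[bool, ...]) -> list[float]:
    probs = [d.prevalence for d in config.drugs]
    idx = {d.name: i for i, d in enumerate(config.drugs)}
    for spec, present in zip(config.indications, ind_pattern):
        if present and spec.linked_drug is not None:
            i = idx[spec.linked_drug]
            probs[i] = min(probs[i] * spec.exposure_multiplier, 1.0)
    return probs


def _event_logit(config: ReportSimConfig, pattern: tuple[bool, ...]) -> float:
    idx = {d.name: i for i, d in enumerate(config.drugs)}
    logit = config.baseline_event_logit
    for d, present in zip(config.drugs, pattern):
        if present:
            logit += d.effect
    for inter in config.interactions:
        if pattern[idx[inter.drug_a]] and pattern[idx[inter.drug_b]]:
            logit += inter.effect
    return logit


def _enumerate_masses(config: ReportSimConfig):
    """Yield (drug pattern, probability mass, event probability) exactly."""
    k, m = len(config.drugs), len(config.indications)
    if k + m > _ENUMERATION_LIMIT:
        raise ConfigError(
            f"closed-form enumeration supports at most {_ENUMERATION_LIMIT} "
            f"drugs+indications, got {k + m}")
    for ind_pattern in itertools.product((False, True), repeat=m):
        p_ind = 1.0
        for spec, present in zip(config.indications, ind_pattern):
            p_ind *= spec.prevalence if present else 1.0 - spec.prevalence
        if p_ind == 0.0:
            continue
        probs = _exposure_probs_given_ind(config, ind_pattern)
        for pattern in itertools.product((False, True), repeat=k):
            mass = p_ind
            for p, present in zip(probs, pattern):
                mass *= p if present else 1.0 - p
            if mass == 0.0:
                continue
            yield pattern, mass, float(expit(_event_logit(config, pattern)))


def generating_odds_ratio(
    config: ReportSimConfig, drug: str, within: str | None = None
) -> float:
    """Exact marginal OR for ``drug`` under the generating model, optionally
    restricted to the cohort of reports exposed to ``within``.

    Computed by exhaustive enumeration over exposure patterns — the
    independent oracle against which simulation estimates are judged.
    Marginal ORs differ in general from the conditional (log-odds) effects
    because the odds ratio is non-collapsible.
    """
    names = list(config.drug_names)
    if drug not in names:
        raise ConfigError(f"unknown drug {drug!r}")
    j = names.index(drug)
    w = names.index(within) if within is not None else None
    a = b = c = d = 0.0
    for pattern, mass, p_ev in _enumerate_masses(config):
        if w is not None and not pattern[w]:
            continue
        if pattern[j]:
            a += mass * p_ev
            b += mass * (1.0 - p_ev)
        else:
            c += mass * p_ev
            d += mass * (1.0 - p_ev)
    if min(a, b, c, d) == 0.0:
        raise ConfigError("generating OR undefined: an expected cell is zero")
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Vectorized population draw


def draw_population(
    config: ReportSimConfig, rng: np.random.Generator, n: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw exposure (reports × drugs boolean frame) and event vector only —
    the fast path for replication studies that never needs report objects."""
    n = config.n_reports if n is None else n
    k, m = len(config.drugs), len(config.indications)
    base = np.array([d.prevalence for d in config.drugs])
    probs = np.broadcast_to(base, (n, k)).copy()
    ind = np.zeros((n, m), dtype=bool)
    if m:
        ind = rng.random((n, m)) < np.array([s.prevalence for s in config.indications])
        idx = {d.name: i for i, d in enumerate(config.drugs)}
        for jm, spec in enumerate(config.indications):
            if spec.linked_drug is not None:
                ji = idx[spec.linked_drug]
                rows = ind[:, jm]
                probs[rows, ji] = np.minimum(probs[rows, ji] * spec.exposure_multiplier, 1.0)
    exposure = rng.random((n, k)) < probs
    logit = np.full(n, config.baseline_event_logit)
    effects = np.array([d.effect for d in config.drugs])
    logit += exposure @ effects
    if config.interactions:
        idx = {d.name: i for i, d in enumerate(config.drugs)}
        for inter in config.interactions:
            both = exposure[:, idx[inter.drug_a]] & exposure[:, idx[inter.drug_b]]
            logit += inter.effect * both
    events = rng.random(n) < expit(logit)
    frame = pd.DataFrame(exposure, columns=list(config.drug_names))
    frame.attrs["indications"] = ind
    return frame, events


def contingency_from_arrays(exposure: np.ndarray, events: np.ndarray) -> ContingencyTable:
    """2x2 table from a boolean exposure column and an event vector."""
    exposure = np.asarray(exposure, dtype=bool)
    events = np.asarray(events, dtype=bool)
    a = int((exposure & events).sum())
    b = int(exposure.sum()) - a
    c = int(events.sum()) - a
    d = len(events) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# Full report-stream generation


@dataclass(frozen=True)
class SimTruth:
    """Generator bookkeeping: what was actually injected."""

    drug_names: tuple[str, ...]
    exposure: np.ndarray            # unique reports × drugs
    events: np.ndarray              # unique reports
    duplicated_case_ids: tuple[str, ...]
    n_name_variants: int
    config: ReportSimConfig

    def realized_table(self, drug: str) -> ContingencyTable:
        j = self.drug_names.index(drug)
        return contingency_from_arrays(self.exposure[:, j], self.events)

    def marginal_or(self, drug: str) -> float:
        return generating_odds_ratio(self.config, drug)

    def conditional_or(self, drug_b: str, within: str) -> float:
        return generating_odds_ratio(self.config, drug_b, within=within)


def simulate_reports(
    config: ReportSimConfig, seed: int | None = None
) -> tuple[list[CaseReport], SimTruth]:
    """Generate a spontaneous-report stream plus ground truth.

    ``config.n_reports`` counts emitted reports *including* injected
    duplicates: ``round(duplicate_rate * n)`` of them are earlier-version
    resubmissions of other cases, so deduplication should recover exactly
    ``n - round(duplicate_rate * n)`` unique cases.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_total = config.n_reports
    n_dup = int(round(config.duplicate_rate * n_total))
    n_unique = n_total - n_dup
    if n_unique < 1:
        raise ConfigError("duplicate_rate too high for n_reports")
    if n_dup > n_unique:
        raise ConfigError("cannot inject more duplicates than unique cases")

    exposure_df, events = draw_population(config, rng, n=n_unique)
    exposure = exposure_df.to_numpy(dtype=bool)
    ind = exposure_df.attrs["indications"]

    age_cat = rng.choice(6, size=n_unique, p=np.array(config.age_bin_probs))
    age_u = rng.random(n_unique)
    sex_cat = rng.choice(3, size=n_unique, p=np.array(config.sex_probs))
    event_terms = rng.choice(len(config.event_term_pool), size=n_unique)
    neutral_terms = rng.choice(len(config.neutral_term_pool), size=n_unique)

    # Per-exposure verbatim-name variant draws (consumed only where needed,
    # but drawn as a block for determinism).
    variant_u = rng.random(exposure.sum()) if config.name_variant_rate > 0 else None
    variants_by_drug = {}
    if config.dictionary is not None:
        variants_by_drug = {d.name: config.dictionary.variants_of(d.name)
                            for d in config.drugs}

    # Solo-plus-interaction contribution of each present drug decides the
    # primary suspect on a report (largest contribution; ties by drug order).
    idx = {d.name: i for i, d in enumerate(config.drugs)}
    effects = np.array([d.effect for d in config.drugs])

    sexes = (Sex.MALE, Sex.FEMALE, Sex.UNKNOWN)
    reports: list[CaseReport] = []
    n_variants = 0
    vpos = 0
    for i in range(n_unique):
        present = np.flatnonzero(exposure[i])
        contrib = {}
        for j in present:
            c = effects[j]
            for inter in config.interactions:
                ja, jb = idx[inter.drug_a], idx[inter.drug_b]
                if j in (ja, jb) and exposure[i, ja] and exposure[i, jb]:
                    c += inter.effect
            contrib[j] = c
        ps_j = max(present, key=lambda j: (contrib[j], -j)) if len(present) else None

        drugs = []
        for j in present:
            generic = config.drug_names[j]
            raw = generic
            variants = variants_by_drug.get(generic, ())
            if variant_u is not None:
                u = variant_u[vpos]
                vpos += 1
                if variants and u < config.name_variant_rate:
                    raw = variants[int(u / config.name_variant_rate * len(variants))]
                    n_variants += 1
            role = Role.PRIMARY_SUSPECT if j == ps_j else Role.CONCOMITANT
            drugs.append(DrugExposure(raw_name=raw, role=role))

        if age_cat[i] == 5:
            age = None
        else:
            lo, hi = AGE_EDGES[age_cat[i]], AGE_EDGES[age_cat[i] + 1]
            age = float(lo + age_u[i] * (hi - lo))
        if events[i]:
            reaction = config.event_term_pool[event_terms[i]]
        else:
            reaction = config.neutral_term_pool[neutral_terms[i]]
        indications = frozenset(
            spec.term for jm, spec in enumerate(config.indications) if ind[i, jm]
        )
        reports.append(CaseReport(
            case_id=f"C{i:08d}", version=2, age_years=age, sex=sexes[sex_cat[i]],
            drugs=tuple(drugs), reactions=frozenset([reaction]),
            indications=indications,
        ))

    dup_idx = rng.choice(n_unique, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    dup_ids = []
    for i in sorted(int(x) for x in dup_idx):
        original = reports[i]
        reports.append(dataclasses.replace(original, version=1))
        dup_ids.append(original.case_id)

    truth = SimTruth(
        drug_names=tuple(config.drug_names), exposure=exposure, events=events,
        duplicated_case_ids=tuple(dup_ids), n_name_variants=n_variants,
        config=config,
    )
    return reports, truth


# ---------------------------------------------------------------------------
# Named study scenarios


def solo_effect_scenario(
    solo_or: float = 20.0,
    n_reports: int = 200_000,
    prevalence: float = 0.10,
    baseline_rate: float = 0.01,
    seed: int = 0,
) -> ReportSimConfig:
    """One drug with a multiplicative solo effect on the event odds — the
    scenario for CI-coverage calibration of the Wald interval."""
    return ReportSimConfig(
        n_reports=n_reports,
        drugs=(DrugSpec("anchor", prevalence, math.log(solo_or)),),
        baseline_event_logit=math.log(baseline_rate / (1 - baseline_rate)),
        duplicate_rate=0.0,
        seed=seed,
    )


def protective_interaction_scenario(
    interaction_or: float = 0.3,
    n_reports: int = 200_000,
    a_prevalence: float = 0.20,
    b_prevalence: float = 0.05,
    a_solo_or: float = 20.0,
    baseline_rate: float = 0.01,
    seed: int = 0,
) -> ReportSimConfig:
    """A risk drug A, a candidate B whose only action is a protective
    interaction with A, and three decoy co-medications (two null, one with a
    mild solo risk).  Sized so the A-cohort is of the order of a real
    drug-of-interest cohort and B clears a 1000-report co-exposure floor."""
    return ReportSimConfig(
        n_reports=n_reports,
        drugs=(
            DrugSpec("drug_a", a_prevalence, math.log(a_solo_or)),
            DrugSpec("drug_b", b_prevalence, 0.0),
            DrugSpec("decoy_one", 0.08, 0.0),
            DrugSpec("decoy_two", 0.06, 0.0),
            DrugSpec("decoy_risk", 0.08, math.log(1.4)),
        ),
        interactions=(Interaction("drug_a", "drug_b", math.log(interaction_or)),),
        baseline_event_logit=math.log(baseline_rate / (1 - baseline_rate)),
        duplicate_rate=0.0,
        seed=seed,
    )


def ci_coverage(
    config: ReportSimConfig,
    drug: str,
    n_replicates: int = 500,
    seed: int = 0,
    z_quantile: float = 1.96,
) -> float:
    """Fraction of replicates whose Wald CI covers the generating marginal OR."""
    truth = generating_odds_ratio(config, drug)
    j = list(config.drug_names).index(drug)
    covered = 0
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        frame, events = draw_population(config, rng)
        table = contingency_from_arrays(frame.to_numpy(dtype=bool)[:, j], events)
        res = odds_ratio(table, z_quantile=z_quantile)
        covered += res.ci_low <= truth <= res.ci_high
    return covered / n_replicates


def screen_recovery(
    config: ReportSimConfig,
    drug_a: str,
    drug_b: str,
    n_replicates: int = 100,
    seed: int = 0,
    min_exposed: int = 1000,
) -> float:
    """Fraction of replicates in which ``drug_b`` is the top mitigation hit
    *and* its estimated CI covers the generating within-cohort OR."""
    truth = generating_odds_ratio(config, drug_b, within=drug_a)
    recovered = 0
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        frame, events = draw_population(config, rng)
        results = MitigationScreen.from_arrays(
            frame, events, drug_a, min_exposed=min_exposed).fit()
        if results.hits and results.hits[0].drug_b == drug_b:
            top = results.hits[0].result
            if top.ci_low <= truth <= top.ci_high:
                recovered += 1
    return recovered / n_replicates


# ---------------------------------------------------------------------------
# Expression simulation


@dataclass(frozen=True)
class ProbeSpec:
    probe_id: str
    symbol: str
    baseline_log2: float = 8.0
    fold_change: float = 1.0

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ConfigError(f"fold change must be > 0 for {self.probe_id}")


@dataclass(frozen=True)
class ExprSimConfig:
    """Two-group log2 expression matrix generator.

    The default group sizes (20 vehicle vs 3 treated) and within-group noise
    (log2 s.d. 0.1, the replicate precision implied by the reported SEMs of
    well-measured genes on this class of array) emulate a pooled-control rat
    toxicogenomics design.
    """

    probes: tuple[ProbeSpec, ...]
    n_vehicle: int = 20
    n_treated: int = 3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.probes:
            raise ConfigError("at least one probe is required")
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate probe ids")
        if self.n_vehicle < 2 or self.n_treated < 2:
            raise ConfigError("each group needs >= 2 samples")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def null_probes(n: int, prefix: str = "NULL", baseline_log2: float = 8.0) -> tuple[ProbeSpec, ...]:
    width = max(4, len(str(n)))
    return tuple(
        ProbeSpec(probe_id=f"{prefix}{i:0{width}d}_PROBE1", symbol=f"{prefix}{i:0{width}d}",
                  baseline_log2=baseline_log2)
        for i in range(1, n + 1)
    )


def simulate_expression(
    config: ExprSimConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Generate the matrix; truth maps probe id → injected fold change."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_s = config.n_vehicle + config.n_treated
    baselines = np.array([p.baseline_log2 for p in config.probes])
    shifts = np.array([math.log2(p.fold_change) for p in config.probes])
    values = baselines[:, None] + rng.normal(0.0, config.noise_sd,
                                             size=(len(config.probes), n_s))
    values[:, config.n_vehicle:] += shifts[:, None]
    samples = ([f"vehicle_{i:02d}" for i in range(1, config.n_vehicle + 1)]
               + [f"treated_{i:02d}" for i in range(1, config.n_treated + 1)])
    groups = pd.Series(["vehicle"] * config.n_vehicle + ["treated"] * config.n_treated,
                       index=samples)
    probe_ids = [p.probe_id for p in config.probes]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        symbols=pd.Series([p.symbol for p in config.probes], index=probe_ids),
        groups=groups,
    )
    truth = {p.probe_id: p.fold_change for p in config.probes}
    return matrix, truth
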