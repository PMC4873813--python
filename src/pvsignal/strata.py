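"""Confounder-stratified odds ratios and suspect-drug co-occurrence.

A stratification dimension is one of:

* ``event_term`` — the event definition is narrowed to a single preferred
  term; the analysed population is unchanged.
* ``age`` / ``sex`` / ``indication`` — the analysed population is restricted
  to the stratum (reports missing the stratum variable are excluded from
  that dimension).
* ``co_drug`` — both the exposed and the unexposed arm are restricted to
  users of the co-medication, so the stratum total is the co-drug cohort.

Strata are reported side by side; no pooling across strata is attempted.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, EmptyInputError
from .reports import CaseReport, Sex, TermSet, Role
from .ror import ContingencyTable, OddsRatioResult, contingency, odds_ratio

DIMENSIONS = ("event_term", "age", "sex", "indication", "co_drug")


@dataclass(frozen=True)
class StratumBin:
    """One stratum: a label plus the dimension-specific selector.

    ``selector`` is an (lo, hi) pair for age (half-open [lo, hi)), a
    :class:`~pvsignal.reports.Sex` or code string for sex, a term collection
    for indication, a generic drug name for co_drug, and a single event term
    for event_term.
    """

    label: str
    selector: object


@dataclass(frozen=True)
class StratumSpec:
    dimension: str
    bins: tuple[StratumBin, ...]

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ConfigError(f"dimension must be one of {DIMENSIONS}")
        object.__setattr__(self, "bins", tuple(self.bins))
        if not self.bins:
            raise ConfigError("a stratum spec needs at least one bin")
        if self.dimension == "age":
            intervals = sorted(tuple(b.selector) for b in self.bins)
            for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
                if lo1 >= hi1 or lo2 < hi1:
                    raise ConfigError("age bins must be non-overlapping [lo, hi)")


def age_spec(edges: Sequence[float] = (0, 40, 50, 60, 70)) -> StratumSpec:
    """Half-open age bins; the last bin is unbounded above."""
    bins = []
    for lo, hi in zip(edges, edges[1:]):
        bins.append(StratumBin(label=f"{int(lo)}–{int(hi) - 1} years" if lo else f"<{int(hi)} years",
                               selector=(float(lo), float(hi))))
    bins.append(StratumBin(label=f"≥{int(edges[-1])} years",
                           selector=(float(edges[-1]), float("inf"))))
    return StratumSpec(dimension="age", bins=tuple(bins))


def sex_spec() -> StratumSpec:
    return StratumSpec(dimension="sex", bins=(
        StratumBin("male", Sex.MALE), StratumBin("female", Sex.FEMALE)))


def event_term_spec(terms: Iterable[str]) -> StratumSpec:
    return StratumSpec(dimension="event_term",
                       bins=tuple(StratumBin(t, t) for t in terms))


def indication_spec(groups: dict[str, Iterable[str]]) -> StratumSpec:
    return StratumSpec(dimension="indication", bins=tuple(
        StratumBin(label, frozenset(t.lower() for t in terms))
        for label, terms in groups.items()))


def co_drug_spec(drugs: Iterable[str]) -> StratumSpec:
    return StratumSpec(dimension="co_drug",
                       bins=tuple(StratumBin(d, d.lower()) for d in drugs))


def spec_from_yaml(path: str) -> StratumSpec:
    """Build a StratumSpec from a YAML file.

    Schema by dimension::

        dimension: age          # edges: [0, 40, 50, 60, 70]
        dimension: sex          # no options
        dimension: event_term   # terms: [diabetes mellitus, ...]
        dimension: indication   # groups: {label: [term, ...], ...}
        dimension: co_drug      # drugs: [haloperidol, ...]
    """
    import yaml

    raw = yaml.safe_load(open(path, encoding="utf-8"))
    if not isinstance(raw, dict) or "dimension" not in raw:
        raise ConfigError(f"{path}: stratum spec needs a 'dimension' key")
    dim = raw["dimension"]
    try:
        if dim == "age":
            return age_spec(tuple(raw.get("edges", (0, 40, 50, 60, 70))))
        if dim == "sex":
            return sex_spec()
        if dim == "event_term":
            return event_term_spec(raw["terms"])
        if dim == "indication":
            return indication_spec(raw["groups"])
        if dim == "co_drug":
            return co_drug_spec(raw["drugs"])
    except KeyError as exc:
        raise ConfigError(f"{path}: missing key {exc} for dimension {dim!r}")
    raise ConfigError(f"{path}: unknown dimension {dim!r}")


@dataclass(frozen=True)
class NotEstimable:
    """Placeholder for a stratum whose 2x2 table has an empty cell."""

    table: ContingencyTable
    reason: str


@dataclass(frozen=True)
class StratumResult:
    label: str
    n: int
    result: OddsRatioResult | NotEstimable

    @property
    def estimable(self) -> bool:
        return isinstance(self.result, OddsRatioResult)


def _in_stratum(report: CaseReport, dimension: str, bin_: StratumBin) -> bool:
    if dimension == "age":
        lo, hi = bin_.selector
        return report.age_years is not None and lo <= report.age_years < hi
    if dimension == "sex":
        want = bin_.selector if isinstance(bin_.selector, Sex) else Sex.from_code(str(bin_.selector))
        return report.sex is want
    if dimension == "indication":
        return not frozenset(bin_.selector).isdisjoint(report.indications)
    if dimension == "co_drug":
        return report.has_drug(str(bin_.selector))
    raise ConfigError(f"no population restriction for dimension {dimension!r}")


def stratify(
    reports: Iterable[CaseReport],
    drug_a: str,
    event_terms: TermSet,
    spec: StratumSpec,
    z_quantile: float = 1.96,
) -> list[StratumResult]:
    """Per-stratum odds ratios for ``drug_a`` against ``event_terms``.

    A stratum with an empty contingency cell yields a flagged
    :class:`NotEstimable` record rather than an error.
    """
    reports = list(reports)
    if not reports:
        raise EmptyInputError("no reports to stratify")
    out = []
    for bin_ in spec.bins:
        if spec.dimension == "event_term":
            population = reports
            terms = TermSet(name=str(bin_.selector), terms=frozenset([str(bin_.selector)]))
        else:
            population = [r for r in reports if _in_stratum(r, spec.dimension, bin_)]
            terms = event_terms
        if not population:
            out.append(StratumResult(bin_.label, 0, NotEstimable(
                ContingencyTable(0, 0, 0, 0), "empty stratum")))
            continue
        table = contingency(population, drug_a, terms)
        if min(table.cells()) == 0:
            out.append(StratumResult(bin_.label, len(population),
                                     NotEstimable(table, "zero contingency cell")))
        else:
            out.append(StratumResult(bin_.label, len(population),
                                     odds_ratio(table, z_quantile=z_quantile)))
    return out


def suspect_fraction(
    reports: Iterable[CaseReport],
    drug: str,
    event_terms: TermSet,
    cohort_drug: str,
) -> tuple[float, float]:
    """Co-occurrence of ``drug`` among event cases exposed to ``cohort_drug``.

    Denominator: deduplicated reports containing ``cohort_drug`` with an
    event-term match.  Returns (fraction also containing ``drug``, fraction
    in which ``drug`` carries the primary-suspect role).  The second is
    never larger than the first.
    """
    drug = drug.lower()
    denominator = [
        r for r in reports
        if r.has_drug(cohort_drug) and not event_terms.terms.isdisjoint(r.reactions)
    ]
    if not denominator:
        raise EmptyInputError(
            f"no event reports exposed to cohort drug {cohort_drug!r}")
    n = len(denominator)
    overlap = sum(1 for r in denominator if r.has_drug(drug))
    suspect = sum(
        1 for r in denominator
        if any(e.name == drug and e.role is Role.PRIMARY_SUSPECT for e in r.drugs)
    )
    return overlap / n, suspect / n


class StrataResults:
    """Side-by-side stratum results with tabular and text summaries."""

    def __init__(self, strata: list[StratumResult], dimension: str, drug_a: str):
        self.strata = strata
        self.dimension = dimension
        self.drug_a = drug_a

    def __iter__(self):
        return iter(self.strata)

    def __len__(self):
        return len(self.strata)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            row = {"stratum": s.label, "n": s.n, "estimable": s.estimable}
            t = s.result.table
            row.update({"a": t.a, "b": t.b, "c": t.c, "d": t.d})
            if s.estimable:
                row.update({"or": s.result.or_value, "ci_low": s.result.ci_low,
                            "ci_high": s.result.ci_high, "p_value": s.result.p_value})
            else:
                row.update({"or": float("nan"), "ci_low": float("nan"),
                            "ci_high": float("nan"), "p_value": float("nan")})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        header = f"{self.drug_a}: ORs stratified by {self.dimension}"
        lines = [header, "=" * len(header)]
        for s in self.strata:
            if s.estimable:
                lines.append(f"{s.label}: OR {s.result.or_value:.2f} "
                             f"({s.result.ci_low:.2f}–{s.result.ci_high:.2f}), n={s.n}")
            else:
                lines.append(f"{s.label}: not estimable ({s.result.reason}), n={s.n}")
        return "\n".join(lines)


class StratifiedAnalysis:
    """Model object: per-stratum reporting odds ratios for one drug/event."""

    def __init__(self, reports, drug_a: str, event_terms: TermSet, spec: StratumSpec,
                 z_quantile: float = 1.96):
        self.reports = list(reports)
        self.drug_a = drug_a
        self.event_terms = event_terms
        self.spec = spec
        self.z_quantile = z_quantile

    def fit(self) -> StrataResults:
        strata = stratify(self.reports, self.drug_a, self.event_terms, self.spec,
                          z_quantile=self.z_quantile)
        return StrataResults(strata, dimension=self.spec.dimension, drug_a=self.drug_a)
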