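"""Mitigation screen: concomitant drugs associated with a lower event rate.

Within the cohort of reports exposed to drug A, every other drug B with at
least ``min_exposed`` co-exposed reports is tested for association with the
event; candidates whose within-cohort OR has an upper CI bound below 1 are
returned ranked most-protective-first (ascending OR, ties broken by name).
The minimum-exposure restriction guards against the instability of odds
ratios at small sample sizes.

A hit's within-cohort OR is not a standalone effect: the screen annotates
each hit with the drug's full-population OR (a candidate whose solo effect
is itself risk-increasing is suspect) and with the fraction of its users
whose recorded indication falls in the event domain (indication bias: a
drug prescribed *for* the event domain will look associated with it).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, EmptyInputError
from .reports import CaseReport, TermSet
from .ror import ContingencyTable, OddsRatioResult, contingency, odds_ratio


@dataclass(frozen=True)
class MitigationHit:
    """One screened drug B: its within-cohort result and rank (1 = lowest OR)."""

    drug_b: str
    result: OddsRatioResult
    n_exposed: int
    rank: int
    solo_result: OddsRatioResult | None = None
    indication_match_fraction: float | None = None


def rank_candidates(
    tables: Mapping[str, ContingencyTable],
    min_exposed: int = 1000,
    top_k: int | None = 10,
    z_quantile: float = 1.96,
) -> list[MitigationHit]:
    """Shared ranking core: filter by exposure, keep significantly protective
    candidates (upper CI bound < 1), sort ascending by OR then name."""
    scored = []
    for drug_b, table in tables.items():
        if table.n_exposed < min_exposed:
            continue
        # Zero cells are possible for rare candidates even past the exposure
        # floor; the continuity-corrected estimate keeps them comparable.
        result = odds_ratio(table, z_quantile=z_quantile, zero_cell="haldane")
        if result.ci_high < 1.0:
            scored.append((result.or_value, drug_b, result, table.n_exposed))
    scored.sort(key=lambda t: (t[0], t[1]))
    if top_k is not None:
        scored = scored[:top_k]
    return [
        MitigationHit(drug_b=drug_b, result=result, n_exposed=n_exp, rank=i)
        for i, (_, drug_b, result, n_exp) in enumerate(scored, start=1)
    ]


def _cohort_tables(
    cohort: list[CaseReport], drug_a: str, event_terms: TermSet
) -> dict[str, ContingencyTable]:
    """Within-cohort 2x2 tables for every candidate drug (any role code)."""
    drug_a = drug_a.lower()
    events = np.array([not event_terms.terms.isdisjoint(r.reactions) for r in cohort])
    names = [r.drug_names() for r in cohort]
    candidates = sorted(set().union(*names) - {drug_a}) if names else []
    n, n_event = len(cohort), int(events.sum())
    tables = {}
    for drug_b in candidates:
        mask = np.array([drug_b in s for s in names])
        a = int((mask & events).sum())
        b = int(mask.sum()) - a
        c = n_event - a
        d = n - n_event - b
        tables[drug_b] = ContingencyTable(a=a, b=b, c=c, d=d)
    return tables


def screen(
    reports: Iterable[CaseReport],
    drug_a: str,
    event_terms: TermSet,
    min_exposed: int = 1000,
    top_k: int | None = 10,
    z_quantile: float = 1.96,
    annotate: bool = True,
) -> list[MitigationHit]:
    """Rank concomitant drugs associated with decreased event occurrence
    among users of ``drug_a``.

    Reports must be deduplicated and name-normalized.  Co-exposure counts
    any role code.  Returns an empty list (not an error) when no candidate
    reaches ``min_exposed``.
    """
    reports = list(reports)
    cohort = [r for r in reports if r.has_drug(drug_a)]
    if not cohort:
        raise EmptyInputError(f"no reports exposed to {drug_a!r}")
    tables = _cohort_tables(cohort, drug_a, event_terms)
    hits = rank_candidates(tables, min_exposed=min_exposed, top_k=top_k,
                           z_quantile=z_quantile)
    if annotate:
        hits = [
            MitigationHit(
                drug_b=h.drug_b, result=h.result, n_exposed=h.n_exposed,
                rank=h.rank,
                solo_result=standalone_effect(reports, h.drug_b, event_terms,
                                              z_quantile=z_quantile),
                indication_match_fraction=_indication_fraction(cohort, h.drug_b,
                                                               event_terms),
            )
            for h in hits
        ]
    return hits


def _indication_fraction(cohort: list[CaseReport], drug_b: str, event_terms: TermSet) -> float:
    users = [r for r in cohort if r.has_drug(drug_b)]
    if not users:
        return 0.0
    n = sum(1 for r in users if not event_terms.terms.isdisjoint(r.indications))
    return n / len(users)


def standalone_effect(
    reports: Iterable[CaseReport],
    drug_b: str,
    event_terms: TermSet,
    z_quantile: float = 1.96,
) -> OddsRatioResult:
    """Full-population OR for ``drug_b`` (no cohort restriction), used to
    flag screen hits whose solo effect is itself risk-increasing."""
    table = contingency(reports, drug_b, event_terms)
    return odds_ratio(table, z_quantile=z_quantile)


class ScreenResults:
    """Ranked mitigation hits with tabular and text summaries."""

    def __init__(self, hits: list[MitigationHit], drug_a: str, min_exposed: int):
        self.hits = hits
        self.drug_a = drug_a
        self.min_exposed = min_exposed

    def __len__(self):
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            t = h.result.table
            rows.append({
                "rank": h.rank, "drug_b": h.drug_b,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "or": h.result.or_value,
                "ci_low": h.result.ci_low, "ci_high": h.result.ci_high,
                "p_value": h.result.p_value, "n_exposed": h.n_exposed,
                "solo_or": h.solo_result.or_value if h.solo_result else math.nan,
                "solo_ci_low": h.solo_result.ci_low if h.solo_result else math.nan,
                "solo_ci_high": h.solo_result.ci_high if h.solo_result else math.nan,
                "indication_match_fraction": (
                    math.nan if h.indication_match_fraction is None
                    else h.indication_match_fraction),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        header = (f"Mitigation screen within the {self.drug_a} cohort "
                  f"(min co-exposure {self.min_exposed})")
        lines = [header, "=" * len(header)]
        if not self.hits:
            lines.append("no significantly protective concomitant drug found")
        for h in self.hits:
            solo = (f"  solo OR {h.solo_result.or_value:.2f}"
                    if h.solo_result else "")
            lines.append(
                f"{h.rank}. {h.drug_b}: OR {h.result.or_value:.2f} "
                f"({h.result.ci_low:.2f}–{h.result.ci_high:.2f}), "
                f"n={h.n_exposed}{solo}"
            )
        return "\n".join(lines)


class MitigationScreen:
    """Model object for the within-cohort mitigation screen.

    Build from reports (``MitigationScreen(reports, drug_a, event_terms)``),
    from per-candidate contingency tables (``from_tables``, the
    count-preserving fixture mode for published tables), or from a boolean
    exposure matrix plus event vector (``from_arrays``, the fast path used
    by simulation studies).  ``fit()`` returns :class:`ScreenResults`.
    """

    def __init__(self, reports=None, drug_a: str = "", event_terms: TermSet | None = None,
                 min_exposed: int = 1000, top_k: int | None = 10,
                 z_quantile: float = 1.96, annotate: bool = True):
        self._reports = list(reports) if reports is not None else None
        self._tables: dict[str, ContingencyTable] | None = None
        self.drug_a = drug_a
        self.event_terms = event_terms
        self.min_exposed = min_exposed
        self.top_k = top_k
        self.z_quantile = z_quantile
        self.annotate = annotate

    @classmethod
    def from_tables(cls, tables: Mapping[str, ContingencyTable], drug_a: str = "",
                    min_exposed: int = 1000, top_k: int | None = 10,
                    z_quantile: float = 1.96) -> "MitigationScreen":
        model = cls(drug_a=drug_a, min_exposed=min_exposed, top_k=top_k,
                    z_quantile=z_quantile, annotate=False)
        model._tables = dict(tables)
        return model

    @classmethod
    def from_arrays(cls, exposure: pd.DataFrame, events: np.ndarray, drug_a: str,
                    min_exposed: int = 1000, top_k: int | None = 10,
                    z_quantile: float = 1.96) -> "MitigationScreen":
        """``exposure``: reports x drugs boolean frame; ``events``: boolean
        vector.  Restricts to the drug-A cohort and builds per-candidate
        tables vectorially."""
        if drug_a not in exposure.columns:
            raise DataError(f"{drug_a!r} not among exposure columns")
        in_cohort = exposure[drug_a].to_numpy(dtype=bool)
        if not in_cohort.any():
            raise EmptyInputError(f"no reports exposed to {drug_a!r}")
        ev = np.asarray(events, dtype=bool)[in_cohort]
        sub = exposure.loc[in_cohort, exposure.columns != drug_a].to_numpy(dtype=bool)
        names = [c for c in exposure.columns if c != drug_a]
        n, n_event = len(ev), int(ev.sum())
        a_vec = (sub & ev[:, None]).sum(axis=0)
        n_b = sub.sum(axis=0)
        tables = {
            name: ContingencyTable(a=int(a), b=int(nb - a),
                                   c=int(n_event - a), d=int(n - n_event - (nb - a)))
            for name, a, nb in zip(names, a_vec, n_b)
        }
        model = cls(drug_a=drug_a, min_exposed=min_exposed, top_k=top_k,
                    z_quantile=z_quantile, annotate=False)
        model._tables = tables
        return model

    def fit(self) -> ScreenResults:
        if self._tables is not None:
            hits = rank_candidates(self._tables, min_exposed=self.min_exposed,
                                   top_k=self.top_k, z_quantile=self.z_quantile)
        else:
            if self._reports is None or self.event_terms is None:
                raise DataError("MitigationScreen needs reports+event_terms or tables")
            hits = screen(self._reports, self.drug_a, self.event_terms,
                          min_exposed=self.min_exposed, top_k=self.top_k,
                          z_quantile=self.z_quantile, annotate=self.annotate)
        return ScreenResults(hits, drug_a=self.drug_a, min_exposed=self.min_exposed)
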