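"""Spontaneous adverse-event report model: ingestion, deduplication,
drug-name normalization and term matching.

The unit of analysis is the *case*: one spontaneous report identified by an
opaque ``case_id``, possibly submitted several times (follow-ups) with an
increasing ``version`` ordinal.  Counting rules downstream treat one
deduplicated case as one individual, which is the only interpretation a
spontaneous-reporting database supports (no cross-report patient linkage).
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import ConfigError, DataError, EmptyInputError

logger = logging.getLogger(__name__)

MAX_PLAUSIBLE_AGE = 130.0


class Role(enum.Enum):
    """Reported role of a drug on a case, following FAERS role codes."""

    PRIMARY_SUSPECT = "PS"
    SECONDARY_SUSPECT = "SS"
    CONCOMITANT = "C"
    INTERACTING = "I"
    UNKNOWN = ""

    @classmethod
    def from_code(cls, code: str) -> "Role":
        code = (code or "").strip().upper()
        for role in cls:
            if role.value == code:
                return role
        return cls.UNKNOWN


class Sex(enum.Enum):
    MALE = "M"
    FEMALE = "F"
    UNKNOWN = ""

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        code = (code or "").strip().upper()
        if code in ("M", "MALE"):
            return cls.MALE
        if code in ("F", "FEMALE"):
            return cls.FEMALE
        return cls.UNKNOWN


_PUNCT_RE = re.compile(r"[^\w\s-]")
_WS_RE = re.compile(r"\s+")


def clean_drug_name(raw: str) -> str:
    """Lowercase a verbatim drug name, drop punctuation, collapse whitespace."""
    cleaned = _PUNCT_RE.sub(" ", raw.lower())
    return _WS_RE.sub(" ", cleaned).strip()


@dataclass(frozen=True)
class DrugExposure:
    """One drug record on a case: the verbatim name, the resolved generic
    name (``None`` until :func:`normalize_drug_names` runs), and the role."""

    raw_name: str
    generic_name: str | None = None
    role: Role = Role.UNKNOWN

    def __post_init__(self):
        if not self.raw_name or not self.raw_name.strip():
            raise DataError("DrugExposure.raw_name must be non-empty")

    @property
    def name(self) -> str:
        """The analysis name: generic if resolved, else the cleaned verbatim."""
        return self.generic_name if self.generic_name else clean_drug_name(self.raw_name)


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous report (one submission version of one case)."""

    case_id: str
    version: int = 1
    age_years: float | None = None
    sex: Sex = Sex.UNKNOWN
    drugs: tuple[DrugExposure, ...] = ()
    reactions: frozenset[str] = frozenset()
    indications: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.case_id:
            raise DataError("case_id must be non-empty")
        if self.version < 0:
            raise DataError(f"case {self.case_id}: version must be >= 0")
        if self.age_years is not None and not (0 <= self.age_years < MAX_PLAUSIBLE_AGE):
            raise DataError(
                f"case {self.case_id}: implausible age {self.age_years}"
            )
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "reactions", frozenset(t.lower() for t in self.reactions))
        object.__setattr__(self, "indications", frozenset(t.lower() for t in self.indications))

    def drug_names(self) -> frozenset[str]:
        return frozenset(d.name for d in self.drugs)

    def has_drug(self, generic: str) -> bool:
        return generic.lower() in self.drug_names()


_DEFAULT_SALT_SUFFIXES = (
    "fumarate", "hydrochloride", "hcl", "maleate", "besylate", "mesylate",
    "succinate", "tartrate", "citrate", "sodium", "potassium", "calcium",
    "carbonate", "sulfate", "acetate", "dihydrate", "monohydrate",
)


@dataclass(frozen=True)
class DrugDictionary:
    """Many-to-one map from lowercased name variants to a generic name.

    Every generic (every value) also maps to itself, so resolving an
    already-generic name is a hit.  Lookup first tries the cleaned verbatim
    name, then the name with trailing salt-form words stripped.
    """

    mapping: Mapping[str, str]
    salt_suffixes: tuple[str, ...] = _DEFAULT_SALT_SUFFIXES

    def __post_init__(self):
        norm: dict[str, str] = {}
        for variant, generic in self.mapping.items():
            v, g = clean_drug_name(variant), clean_drug_name(generic)
            if not v or not g:
                raise ConfigError(f"empty dictionary entry: {variant!r} -> {generic!r}")
            if v in norm and norm[v] != g:
                raise ConfigError(
                    f"dictionary maps {v!r} to both {norm[v]!r} and {g!r}"
                )
            norm[v] = g
        for generic in list(norm.values()):
            norm.setdefault(generic, generic)
        object.__setattr__(self, "mapping", norm)
        object.__setattr__(
            self, "salt_suffixes", tuple(s.lower() for s in self.salt_suffixes)
        )

    def strip_salt(self, cleaned: str) -> str:
        words = cleaned.split()
        while len(words) > 1 and words[-1] in self.salt_suffixes:
            words = words[:-1]
        return " ".join(words)

    def resolve(self, raw_name: str) -> str | None:
        """Generic name for a verbatim name, or ``None`` if unmatched."""
        cleaned = clean_drug_name(raw_name)
        hit = self.mapping.get(cleaned)
        if hit is not None:
            return hit
        return self.mapping.get(self.strip_salt(cleaned))

    def variants_of(self, generic: str) -> tuple[str, ...]:
        """Non-identity variants mapping to ``generic`` (for simulation)."""
        g = clean_drug_name(generic)
        return tuple(sorted(v for v, t in self.mapping.items() if t == g and v != g))


@dataclass(frozen=True)
class TermSet:
    """A named set of lowercased terms (adverse-event preferred terms, drug
    generics or indication terms).  Matching downstream is exact-string on
    these normalized terms, never substring search, so that counts are
    reproducible."""

    name: str
    terms: frozenset[str]

    def __post_init__(self):
        terms = frozenset(t.strip().lower() for t in self.terms if t.strip())
        if not terms:
            raise ConfigError(f"term set {self.name!r} is empty")
        object.__setattr__(self, "terms", terms)

    def __contains__(self, term: str) -> bool:
        return term.lower() in self.terms

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Operations


def load_reports(paths: Iterable[str], dialect: str = "faers_dollar") -> list[CaseReport]:
    """Read spontaneous reports from disk.

    dialect ``faers_dollar``: a set of $-delimited DEMO/DRUG/REAC/INDI files
    joined on (case_id, version); dialect ``csv``: one flat CSV with
    semicolon-joined list columns.  Reports with no reactions are dropped
    (with a logged count): a spontaneous report without an event term is not
    analysable.
    """
    from . import faers_io  # local import to avoid a cycle

    paths = [str(p) for p in paths]
    if dialect == "faers_dollar":
        reports, n_skipped = faers_io.read_faers_files(paths)
    elif dialect == "csv":
        reports, n_skipped = faers_io.read_flat_csv(paths)
    else:
        raise ConfigError(f"unknown dialect {dialect!r}")

    kept = [r for r in reports if r.reactions]
    dropped = len(reports) - len(kept)
    if dropped:
        logger.warning("dropped %d report(s) with no reaction terms", dropped)
    if n_skipped:
        logger.warning("skipped %d unparseable row(s)", n_skipped)
    if not kept:
        raise EmptyInputError(f"no valid reports in {paths}")
    return kept


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep the most recent version of each case.

    Follow-up submissions share a case_id; the regulator's deduplication
    recommendation is to retain the most recent one.  Ties on (case_id,
    version) keep the last-seen record, with a warning.  Output is sorted by
    case_id for determinism.
    """
    best: dict[str, CaseReport] = {}
    for report in reports:
        prev = best.get(report.case_id)
        if prev is None or report.version > prev.version:
            best[report.case_id] = report
        elif report.version == prev.version and report is not prev:
            logger.warning(
                "case %s: duplicate version %d, keeping last-seen record",
                report.case_id, report.version,
            )
            best[report.case_id] = report
    return [best[cid] for cid in sorted(best)]


def normalize_drug_names(
    reports: Iterable[CaseReport], dictionary: DrugDictionary
) -> list[CaseReport]:
    """Resolve every exposure's verbatim name to a generic via the dictionary.

    Unmatched names are kept with ``generic_name`` set to the cleaned
    verbatim name (an unmatched name is a logged outcome, not an error); the
    number of reports and exposures is never changed.
    """
    out: list[CaseReport] = []
    n_unmatched = 0
    for report in reports:
        new_drugs = []
        for exp in report.drugs:
            generic = dictionary.resolve(exp.raw_name)
            if generic is None:
                generic = dictionary.strip_salt(clean_drug_name(exp.raw_name))
                n_unmatched += 1
            new_drugs.append(dataclasses.replace(exp, generic_name=generic))
        out.append(dataclasses.replace(report, drugs=tuple(new_drugs)))
    if n_unmatched:
        logger.info("%d drug exposure(s) left unresolved by the dictionary", n_unmatched)
    return out


_MATCH_FIELDS = ("reactions", "drugs", "indications")


def match_terms(report: CaseReport, term_set: TermSet, field: str = "reactions") -> bool:
    """True iff any of the report's terms in ``field`` is in ``term_set``.

    For ``drugs`` the analysis name (generic if resolved) is matched.
    Exact-string, case-insensitive.
    """
    if field not in _MATCH_FIELDS:
        raise ConfigError(f"field must be one of {_MATCH_FIELDS}, got {field!r}")
    if field == "reactions":
        values = report.reactions
    elif field == "indications":
        values = report.indications
    else:
        values = report.drug_names()
    return not term_set.terms.isdisjoint(values)
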