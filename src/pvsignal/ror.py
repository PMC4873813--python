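"""Reporting odds ratio (ROR) disproportionality statistics.

Reports are cross-classified by exposure to a drug of interest and
occurrence of an event of interest:

    a  exposed, event        b  exposed, no event
    c  unexposed, event      d  unexposed, no event

The reporting odds ratio is OR = (a/b)/(c/d) with the Wald confidence
interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and a two-sided Wald z-test on
ln OR.  A signal is *risk* when the lower CI bound exceeds 1 and
*protective* when the upper bound is below 1; risk signals are tiered by
the point estimate (strong > 20, intermediate > 5, low otherwise).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from collections.abc import Iterable
from dataclasses import dataclass

from scipy import stats

from .errors import DataError, EmptyInputError, ZeroCellError
from .reports import CaseReport, TermSet


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 exposure-by-event report counts a, b, c, d."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            v = getattr(self, cell)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                if isinstance(v, float) and v.is_integer():
                    object.__setattr__(self, cell, int(v))
                    continue
                raise DataError(f"cell {cell} must be an integer, got {v!r}")
            if v < 0:
                raise DataError(f"cell {cell} must be >= 0, got {v}")

    @classmethod
    def from_marginals(cls, a: int, n_exposed: int, c: int, n_unexposed: int) -> "ContingencyTable":
        """Build from event counts and group totals, the form in which
        published disproportionality tables are usually printed."""
        if a > n_exposed or c > n_unexposed:
            raise DataError("event count exceeds its group total")
        return cls(a=a, b=n_exposed - a, c=c, d=n_unexposed - c)

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class Direction(enum.Enum):
    RISK = "risk"
    PROTECTIVE = "protective"
    NONE = "none"


class Tier(enum.Enum):
    STRONG = "strong"
    INTERMEDIATE = "intermediate"
    LOW = "low"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class SignalClass:
    direction: Direction
    tier: Tier

    def __post_init__(self):
        if self.tier is not Tier.NOT_APPLICABLE and self.direction is not Direction.RISK:
            raise DataError("tiers apply to risk signals only")

    def __str__(self):
        if self.direction is Direction.RISK:
            return f"risk ({self.tier.value})"
        return self.direction.value


@dataclass(frozen=True)
class OddsRatioResult:
    """Point estimate, Wald CI and p-value for one 2x2 table.

    The CI is symmetric around the estimate on the log scale.  When the
    Haldane–Anscombe continuity correction was applied (a zero cell with
    ``zero_cell='haldane'``), ``continuity_corrected`` is True and the
    statistics come from the +0.5-adjusted table while ``table`` keeps the
    raw counts.
    """

    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    table: ContingencyTable
    z_quantile: float = 1.96
    continuity_corrected: bool = False

    @property
    def log_or(self) -> float:
        return math.log(self.or_value)

    @property
    def se_log_or(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * self.z_quantile)

    @property
    def signal(self) -> SignalClass:
        return classify(self)

    def summary(self) -> str:
        row = format_row(self)
        lines = [
            "Reporting odds ratio",
            "====================",
            f"exposed    {row['exposed_summary']:>24}",
            f"unexposed  {row['unexposed_summary']:>24}",
            f"OR (95% CI)  {row['or_ci']}",
            f"p-value      {self.p_value:.3g}   signal: {self.signal}",
        ]
        if self.continuity_corrected:
            lines.append("(Haldane–Anscombe +0.5 continuity correction applied)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.table.a, "b": self.table.b,
            "c": self.table.c, "d": self.table.d,
            "or": self.or_value, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "z_quantile": self.z_quantile,
            "continuity_corrected": self.continuity_corrected,
            "direction": self.signal.direction.value, "tier": self.signal.tier.value,
        }


def contingency(reports: Iterable[CaseReport], drug: str, event_terms: TermSet) -> ContingencyTable:
    """Cross-classify deduplicated, name-normalized reports for one drug and
    one event term set.  Every report lands in exactly one cell."""
    drug = drug.lower()
    a = b = c = d = 0
    n = 0
    for report in reports:
        n += 1
        exposed = report.has_drug(drug)
        event = not event_terms.terms.isdisjoint(report.reactions)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    if n == 0:
        raise EmptyInputError("no reports to classify")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(
    table: ContingencyTable,
    z_quantile: float = 1.96,
    zero_cell: str = "error",
) -> OddsRatioResult:
    """Reporting odds ratio with Wald CI and two-sided Wald z p-value.

    ``zero_cell='error'`` (default) raises on any empty cell;
    ``zero_cell='haldane'`` adds 0.5 to every cell instead and flags the
    result.  Fisher's exact p-value is available via :func:`fisher_p`.
    """
    a, b, c, d = (float(x) for x in table.cells())
    if min(a, b, c, d) == 0:
        if zero_cell == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        elif zero_cell == "error":
            raise ZeroCellError(
                f"zero cell in table {table.cells()}; pass zero_cell='haldane' "
                "for the +0.5 continuity correction"
            )
        else:
            raise DataError(f"unknown zero_cell mode {zero_cell!r}")
    else:
        corrected = False
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OddsRatioResult(
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z_quantile * se),
        ci_high=math.exp(log_or + z_quantile * se),
        p_value=float(min(p, 1.0)),
        table=table,
        z_quantile=z_quantile,
        continuity_corrected=corrected,
    )


def fisher_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (optional alternative to the Wald test)."""
    return float(stats.fisher_exact([[table.a, table.b], [table.c, table.d]])[1])


def classify(result: OddsRatioResult) -> SignalClass:
    """Signal direction from the CI, risk tier from the point estimate.

    Boundary estimates of exactly 20 (or 5) fall in the lower tier.
    """
    if result.ci_low > 1.0:
        if result.or_value > 20.0:
            tier = Tier.STRONG
        elif result.or_value > 5.0:
            tier = Tier.INTERMEDIATE
        else:
            tier = Tier.LOW
        return SignalClass(Direction.RISK, tier)
    if result.ci_high < 1.0:
        return SignalClass(Direction.PROTECTIVE, Tier.NOT_APPLICABLE)
    return SignalClass(Direction.NONE, Tier.NOT_APPLICABLE)


def _round2(x: float) -> float:
    return round(x, 2)


def format_row(result: OddsRatioResult) -> dict[str, object]:
    """Display record mirroring the published table layout:
    ``event/total (percent)`` per arm and ``OR (lo–hi)`` at 2 dp."""
    t = result.table
    pct_exposed = _round2(100.0 * t.a / t.n_exposed) if t.n_exposed else 0.0
    pct_unexposed = _round2(100.0 * t.c / t.n_unexposed) if t.n_unexposed else 0.0
    return {
        "exposed_summary": f"{t.a}/{t.n_exposed} ({pct_exposed:.2f})",
        "unexposed_summary": f"{t.c}/{t.n_unexposed} ({pct_unexposed:.2f})",
        "pct_exposed": pct_exposed,
        "pct_unexposed": pct_unexposed,
        "or": _round2(result.or_value),
        "ci_low": _round2(result.ci_low),
        "ci_high": _round2(result.ci_high),
        "or_ci": f"{_round2(result.or_value):.2f} "
                 f"({_round2(result.ci_low):.2f}–{_round2(result.ci_high):.2f})",
    }


class ReportingOddsRatio:
    """Model object for one drug/event disproportionality analysis.

    Construct from a contingency table (``from_counts`` /
    ``from_marginals`` for published counts) or from a report collection
    (``from_reports``), then call :meth:`fit` for an
    :class:`OddsRatioResult`.
    """

    def __init__(self, table: ContingencyTable, zero_cell: str = "error"):
        self.table = table
        self.zero_cell = zero_cell

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int, **kw) -> "ReportingOddsRatio":
        return cls(ContingencyTable(a=a, b=b, c=c, d=d), **kw)

    @classmethod
    def from_marginals(cls, a: int, n_exposed: int, c: int, n_unexposed: int, **kw):
        return cls(ContingencyTable.from_marginals(a, n_exposed, c, n_unexposed), **kw)

    @classmethod
    def from_reports(cls, reports, drug: str, event_terms: TermSet, **kw):
        return cls(contingency(reports, drug, event_terms), **kw)

    def fit(self, z_quantile: float = 1.96) -> OddsRatioResult:
        return odds_ratio(self.table, z_quantile=z_quantile, zero_cell=self.zero_cell)
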