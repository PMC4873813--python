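"""Pathway overlay of a treated-vs-vehicle expression matrix.

The input is a probes × samples matrix of log2 microarray intensities with
a two-level group factor (vehicle / treated) and a pathway gene set.  For
each probe mapping to a pathway gene the procedure

1. back-transforms to the original scale (2**x),
2. expresses each treated sample relative to the vehicle-group mean and
   summarises those ratios as mean ± SEM,
3. tests treated vs vehicle with Welch's two-sample t-test on the log2
   scale (the default; original-scale testing is available by flag), and
4. reports probes significant at ``alpha``, sorted ascending by relative
   expression, classified *down* (< 1) or *up*.

No multiple-testing correction is applied by default; a Benjamini–Hochberg
option exists but is off, matching the screening character of the analysis.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

GROUPS = ("vehicle", "treated")


@dataclass
class ExpressionMatrix:
    """Probes × samples log2 intensities, probe→symbol map, group labels."""

    values: pd.DataFrame            # index: probe ids, columns: sample ids
    symbols: pd.Series              # index: probe ids -> gene symbol
    groups: pd.Series               # index: sample ids -> 'vehicle' | 'treated'

    def __post_init__(self):
        self.values = pd.DataFrame(self.values)
        self.symbols = pd.Series(self.symbols).reindex(self.values.index)
        self.groups = pd.Series(self.groups).reindex(self.values.columns)
        if self.symbols.isna().any():
            missing = list(self.symbols.index[self.symbols.isna()])[:5]
            raise ConfigError(f"probes without a gene symbol: {missing}")
        if self.groups.isna().any() or not set(self.groups) <= set(GROUPS):
            raise ConfigError(f"every sample needs a group label in {GROUPS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError("expression values must be finite")
        for g in GROUPS:
            if (self.groups == g).sum() < 2:
                raise DataError(f"need >= 2 samples in group {g!r}")

    def samples_in(self, group: str) -> pd.Index:
        return self.groups.index[self.groups == group]

    @property
    def n_vehicle(self) -> int:
        return int((self.groups == "vehicle").sum())

    @property
    def n_treated(self) -> int:
        return int((self.groups == "treated").sum())

    @classmethod
    def from_tsv(cls, matrix_path: str, groups_path: str) -> "ExpressionMatrix":
        """matrix TSV: columns ``probe``, ``symbol``, then one column per
        sample; groups TSV: columns ``sample``, ``group``."""
        mat = pd.read_csv(matrix_path, sep="\t")
        for col in ("probe", "symbol"):
            if col not in mat.columns:
                raise DataError(f"{matrix_path}: missing column {col!r}")
        mat = mat.set_index("probe")
        grp = pd.read_csv(groups_path, sep="\t")
        for col in ("sample", "group"):
            if col not in grp.columns:
                raise DataError(f"{groups_path}: missing column {col!r}")
        groups = grp.set_index("sample")["group"]
        return cls(values=mat.drop(columns="symbol").astype(float),
                   symbols=mat["symbol"], groups=groups)

    def to_tsv(self, matrix_path: str, groups_path: str) -> None:
        out = self.values.copy()
        out.insert(0, "symbol", self.symbols)
        out.index.name = "probe"
        out.to_csv(matrix_path, sep="\t")
        grp = self.groups.rename("group").to_frame()
        grp.index.name = "sample"
        grp.to_csv(groups_path, sep="\t")


@dataclass(frozen=True)
class GeneSet:
    """A pathway gene set: an identifier and its member gene symbols."""

    pathway_id: str
    symbols: frozenset[str]

    def __post_init__(self):
        symbols = frozenset(s.strip() for s in self.symbols if s.strip())
        if not symbols:
            raise ConfigError(f"gene set {self.pathway_id!r} is empty")
        object.__setattr__(self, "symbols", symbols)

    @classmethod
    def from_file(cls, path: str, pathway_id: str | None = None) -> "GeneSet":
        """Plain-text list, one symbol per line; ``#`` comments ignored."""
        symbols = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
        return cls(pathway_id=pathway_id or Path(path).stem, symbols=frozenset(symbols))


class ExprDirection(enum.Enum):
    DOWN = "down"
    UP = "up"


@dataclass(frozen=True)
class OverlayRow:
    probe: str
    symbol: str
    relative_expression_mean: float
    sem: float
    p_value: float
    direction: ExprDirection


def back_transform(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise 2**x: log2 intensities back to the original scale."""
    return np.power(2.0, matrix.values)


def relative_expression(matrix: ExpressionMatrix, probe: str) -> tuple[float, float]:
    """Treated-group expression relative to the vehicle mean, as mean ± SEM.

    Original-scale values of the treated samples are divided by the
    vehicle-group mean; the SEM is that of the treated-group ratios (the
    vehicle group enters only through its mean).
    """
    if probe not in matrix.values.index:
        raise DataError(f"probe {probe!r} not in matrix")
    orig = np.power(2.0, matrix.values.loc[probe])
    vehicle_mean = float(orig[matrix.samples_in("vehicle")].mean())
    ratios = orig[matrix.samples_in("treated")] / vehicle_mean
    n = len(ratios)
    return float(ratios.mean()), float(ratios.std(ddof=1) / math.sqrt(n))


def test_probe(matrix: ExpressionMatrix, probe: str, scale: str = "log2") -> float:
    """Two-sided Welch two-sample t-test for one probe.

    ``scale='log2'`` (default) tests the log2 values; ``scale='original'``
    tests 2**x.  Degenerate zero-variance groups: identical groups give
    p = 1 with a warning; separated constant groups give p = 0.
    """
    if scale not in ("log2", "original"):
        raise ConfigError(f"scale must be 'log2' or 'original', got {scale!r}")
    if probe not in matrix.values.index:
        raise DataError(f"probe {probe!r} not in matrix")
    row = matrix.values.loc[probe]
    if scale == "original":
        row = np.power(2.0, row)
    x = row[matrix.samples_in("treated")].to_numpy(dtype=float)
    y = row[matrix.samples_in("vehicle")].to_numpy(dtype=float)
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        logger.warning("probe %s: zero variance in both groups", probe)
        return 1.0 if x.mean() == y.mean() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
    return float(p)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adjusted = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, pvals[i] * m / (rank_idx + 1))
        adjusted[i] = running
    return adjusted


def overlay(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = 0.05,
    scale: str = "log2",
    fdr: bool = False,
) -> list[OverlayRow]:
    """Significantly altered pathway probes, sorted ascending by relative
    expression.  Raises if no matrix symbol is in the gene set, naming the
    missing symbols."""
    mask = matrix.symbols.isin(gene_set.symbols)
    probes = list(matrix.values.index[mask])
    if not probes:
        missing = sorted(gene_set.symbols)
        raise DataError(
            f"no probe maps to gene set {gene_set.pathway_id!r}; "
            f"missing symbols: {missing}"
        )
    pvals = np.array([test_probe(matrix, p, scale=scale) for p in probes])
    shown = _bh_adjust(pvals) if fdr else pvals
    rows = []
    for probe, p in zip(probes, shown):
        if p < alpha:
            mean, sem = relative_expression(matrix, probe)
            rows.append(OverlayRow(
                probe=probe, symbol=str(matrix.symbols[probe]),
                relative_expression_mean=mean, sem=sem, p_value=float(p),
                direction=ExprDirection.DOWN if mean < 1.0 else ExprDirection.UP,
            ))
    rows.sort(key=lambda r: (r.relative_expression_mean, r.probe))
    return rows


class OverlayResults:
    """Overlay rows with down/up counts and a published-table-style frame."""

    def __init__(self, rows: list[OverlayRow], gene_set: GeneSet, alpha: float):
        self.rows = rows
        self.gene_set = gene_set
        self.alpha = alpha

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    @property
    def n_down(self) -> int:
        return sum(1 for r in self.rows if r.direction is ExprDirection.DOWN)

    @property
    def n_up(self) -> int:
        return sum(1 for r in self.rows if r.direction is ExprDirection.UP)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "probe": r.probe, "symbol": r.symbol,
            "relative_expression": r.relative_expression_mean,
            "sem": r.sem, "p_value": r.p_value, "direction": r.direction.value,
        } for r in self.rows])

    def summary(self) -> str:
        header = (f"Pathway overlay: {self.gene_set.pathway_id} "
                  f"(alpha={self.alpha:g})")
        lines = [header, "=" * len(header),
                 f"{self.n_down} downregulated, {self.n_up} upregulated"]
        for r in self.rows:
            lines.append(f"{r.probe}  {r.symbol}: "
                         f"{r.relative_expression_mean:.2f} ± {r.sem:.2f}  "
                         f"p={r.p_value:.4f} ({r.direction.value})")
        return "\n".join(lines)


class PathwayOverlay:
    """Model object: overlay one expression matrix onto one pathway set."""

    def __init__(self, matrix: ExpressionMatrix, gene_set: GeneSet,
                 alpha: float = 0.05, scale: str = "log2", fdr: bool = False):
        self.matrix = matrix
        self.gene_set = gene_set
        self.alpha = alpha
        self.scale = scale
        self.fdr = fdr

    def fit(self) -> OverlayResults:
        rows = overlay(self.matrix, self.gene_set, alpha=self.alpha,
                       scale=self.scale, fdr=self.fdr)
        return OverlayResults(rows, gene_set=self.gene_set, alpha=self.alpha)
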