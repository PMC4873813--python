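"""Readers and writers for the supported report dialects.

``faers_dollar`` mirrors the quarterly ASCII distribution of a spontaneous
reporting system: four $-delimited tables (demographics, drugs, reactions,
indications) sharing a (case_id, version) key.  ``csv`` is a single flat
file with semicolon-joined list columns, convenient for small fixtures.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import defaultdict
from pathlib import Path

from .errors import ReportFormatError
from .reports import CaseReport, DrugExposure, Role, Sex

logger = logging.getLogger(__name__)

DELIM = "$"

DEMO_COLS = ("case_id", "version", "age", "sex")
DRUG_COLS = ("case_id", "version", "drug_seq", "role", "drugname")
REAC_COLS = ("case_id", "version", "pt")
INDI_COLS = ("case_id", "version", "indi_pt")

_KIND_BY_COLS = {
    frozenset(DEMO_COLS): "demo",
    frozenset(DRUG_COLS): "drug",
    frozenset(REAC_COLS): "reac",
    frozenset(INDI_COLS): "indi",
}


def _read_dollar_table(path: str) -> tuple[str, list[dict[str, str]], int]:
    """Return (kind, rows, n_skipped) for one $-delimited file."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=DELIM)
        try:
            header = next(reader)
        except StopIteration:
            raise ReportFormatError(path, "empty file (no header)")
        cols = [c.strip().lower() for c in header]
        kind = _KIND_BY_COLS.get(frozenset(cols))
        if kind is None:
            for want in (DEMO_COLS, DRUG_COLS, REAC_COLS, INDI_COLS):
                missing = set(want) - set(cols)
                if len(missing) == 1 and len(set(cols) & set(want)) >= 2:
                    raise ReportFormatError(
                        path, f"missing mandatory column {missing.pop()!r}"
                    )
            raise ReportFormatError(path, f"unrecognised header {header!r}")
        rows, skipped = [], 0
        for lineno, values in enumerate(reader, start=2):
            if not values or all(not v.strip() for v in values):
                continue
            if len(values) != len(cols):
                logger.warning("%s:%d: wrong field count, row skipped", path, lineno)
                skipped += 1
                continue
            rows.append(dict(zip(cols, values)))
    return kind, rows, skipped


def _parse_key(row: dict[str, str], path: str) -> tuple[str, int] | None:
    case_id = row["case_id"].strip()
    try:
        version = int(row["version"])
    except ValueError:
        return None
    if not case_id or version < 0:
        return None
    return case_id, version


def read_faers_files(paths: list[str]) -> tuple[list[CaseReport], int]:
    """Assemble CaseReports from $-delimited DEMO/DRUG/REAC/INDI files.

    One report is built per (case_id, version) row of the demographics
    table; drug, reaction and indication rows attach by the same key.
    Returns (reports, number of skipped rows).
    """
    tables: dict[str, list[tuple[str, list[dict[str, str]]]]] = defaultdict(list)
    n_skipped = 0
    for path in paths:
        kind, rows, skipped = _read_dollar_table(str(path))
        tables[kind].append((str(path), rows))
        n_skipped += skipped
    if "demo" not in tables:
        raise ReportFormatError(paths, "no demographics table among the inputs")

    drugs = defaultdict(list)
    for path, rows in tables.get("drug", []):
        for row in rows:
            key = _parse_key(row, path)
            if key is None or not row["drugname"].strip():
                n_skipped += 1
                continue
            try:
                seq = int(row["drug_seq"])
            except ValueError:
                n_skipped += 1
                continue
            drugs[key].append(
                (seq, DrugExposure(raw_name=row["drugname"].strip(),
                                   role=Role.from_code(row["role"])))
            )
    reacs = defaultdict(set)
    for path, rows in tables.get("reac", []):
        for row in rows:
            key = _parse_key(row, path)
            if key is None or not row["pt"].strip():
                n_skipped += 1
                continue
            reacs[key].add(row["pt"].strip().lower())
    indis = defaultdict(set)
    for path, rows in tables.get("indi", []):
        for row in rows:
            key = _parse_key(row, path)
            if key is None or not row["indi_pt"].strip():
                n_skipped += 1
                continue
            indis[key].add(row["indi_pt"].strip().lower())

    reports: list[CaseReport] = []
    for path, rows in tables["demo"]:
        for row in rows:
            key = _parse_key(row, path)
            if key is None:
                n_skipped += 1
                continue
            age_raw = row["age"].strip()
            try:
                age = float(age_raw) if age_raw else None
            except ValueError:
                logger.warning("%s: case %s: unparseable age %r treated as missing",
                               path, key[0], age_raw)
                age = None
            if age is not None and not (0 <= age < 130):
                logger.warning("%s: case %s: implausible age %s treated as missing",
                               path, key[0], age)
                age = None
            exposures = tuple(exp for _, exp in sorted(drugs.get(key, []), key=lambda t: t[0]))
            reports.append(CaseReport(
                case_id=key[0], version=key[1], age_years=age,
                sex=Sex.from_code(row["sex"]), drugs=exposures,
                reactions=frozenset(reacs.get(key, ())),
                indications=frozenset(indis.get(key, ())),
            ))
    return reports, n_skipped


def write_faers_files(reports: list[CaseReport], directory: str) -> dict[str, str]:
    """Write reports as the four $-delimited tables; lossless round-trip.

    Set-valued fields are written sorted so that write → load → write is
    byte-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {kind: directory / f"{kind}.txt" for kind in ("demo", "drug", "reac", "indi")}

    def _age(r: CaseReport) -> str:
        # shortest round-trip float representation keeps reload lossless
        return "" if r.age_years is None else repr(r.age_years)

    with open(paths["demo"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=DELIM)
        w.writerow(DEMO_COLS)
        for r in reports:
            w.writerow([r.case_id, r.version, _age(r), r.sex.value])
    with open(paths["drug"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=DELIM)
        w.writerow(DRUG_COLS)
        for r in reports:
            for seq, exp in enumerate(r.drugs, start=1):
                w.writerow([r.case_id, r.version, seq, exp.role.value, exp.raw_name])
    with open(paths["reac"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=DELIM)
        w.writerow(REAC_COLS)
        for r in reports:
            for pt in sorted(r.reactions):
                w.writerow([r.case_id, r.version, pt])
    with open(paths["indi"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=DELIM)
        w.writerow(INDI_COLS)
        for r in reports:
            for pt in sorted(r.indications):
                w.writerow([r.case_id, r.version, pt])
    return {k: str(v) for k, v in paths.items()}


FLAT_COLS = ("case_id", "version", "age", "sex", "drugs", "reactions", "indications")
_ITEM_SEP = ";"
_ROLE_SEP = "|"


def read_flat_csv(paths: list[str]) -> tuple[list[CaseReport], int]:
    """Read the flat one-row-per-report CSV dialect."""
    reports: list[CaseReport] = []
    n_skipped = 0
    for path in paths:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            cols = [c.strip().lower() for c in reader.fieldnames or []]
            missing = set(FLAT_COLS) - set(cols)
            if missing:
                raise ReportFormatError(
                    path, f"missing mandatory column {sorted(missing)[0]!r}"
                )
            for row in reader:
                row = {k.strip().lower(): (v or "") for k, v in row.items()}
                key = _parse_key(row, path)
                if key is None:
                    n_skipped += 1
                    continue
                try:
                    age = float(row["age"]) if row["age"].strip() else None
                except ValueError:
                    age = None
                exposures = []
                for item in row["drugs"].split(_ITEM_SEP):
                    item = item.strip()
                    if not item:
                        continue
                    name, _, role = item.partition(_ROLE_SEP)
                    if not name.strip():
                        continue
                    exposures.append(DrugExposure(raw_name=name.strip(),
                                                  role=Role.from_code(role)))
                split = lambda s: frozenset(t.strip().lower()
                                            for t in s.split(_ITEM_SEP) if t.strip())
                reports.append(CaseReport(
                    case_id=key[0], version=key[1], age_years=age,
                    sex=Sex.from_code(row["sex"]), drugs=tuple(exposures),
                    reactions=split(row["reactions"]),
                    indications=split(row["indications"]),
                ))
    return reports, n_skipped


def write_flat_csv(reports: list[CaseReport], path: str) -> str:
    """Write reports as the flat CSV dialect."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(FLAT_COLS)
        for r in reports:
            drugs = _ITEM_SEP.join(f"{e.raw_name}{_ROLE_SEP}{e.role.value}" for e in r.drugs)
            age = "" if r.age_years is None else repr(r.age_years)
            w.writerow([r.case_id, r.version, age, r.sex.value, drugs,
                        _ITEM_SEP.join(sorted(r.reactions)),
                        _ITEM_SEP.join(sorted(r.indications))])
    return path
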