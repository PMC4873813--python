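"""Loading of term sets, drug dictionaries and packaged reference data.

Term sets: YAML (``{name: ..., terms: [...]}``, or a mapping of several such
entries) or a one-column CSV/plain list.  Drug dictionaries: YAML with
``salt_suffixes`` and ``mapping`` keys, or a two-column CSV
(variant,generic).
"""

from __future__ import annotations

import csv
import functools
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigError
from .reports import DrugDictionary, TermSet


def _read_packaged_yaml(name: str) -> dict:
    with resources.files("pvsignal.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def builtin_term_sets() -> dict[str, TermSet]:
    raw = _read_packaged_yaml("term_sets.yaml")
    return {key: TermSet(name=entry["name"], terms=frozenset(entry["terms"]))
            for key, entry in raw.items()}


def builtin_term_set(key: str) -> TermSet:
    """One of the shipped term sets: ``dm_core``, ``dm_extended``, ``vitamin_d``."""
    sets = builtin_term_sets()
    if key not in sets:
        raise ConfigError(f"unknown builtin term set {key!r}; have {sorted(sets)}")
    return sets[key]


def load_term_set(path: str, key: str | None = None) -> TermSet:
    """Read a term set from YAML or a plain one-term-per-line file."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        if "terms" in raw:
            entry = raw
        else:
            if key is None:
                if len(raw) != 1:
                    raise ConfigError(
                        f"{path}: multiple term sets {sorted(raw)}; pass key=")
                key = next(iter(raw))
            if key not in raw:
                raise ConfigError(f"{path}: no term set {key!r}")
            entry = raw[key]
        return TermSet(name=entry.get("name", key or path.stem),
                       terms=frozenset(entry["terms"]))
    terms = [line.strip() for line in path.read_text(encoding="utf-8").splitlines()
             if line.strip() and not line.lstrip().startswith("#")]
    return TermSet(name=path.stem, terms=frozenset(terms))


@functools.lru_cache(maxsize=None)
def default_drug_dictionary() -> DrugDictionary:
    raw = _read_packaged_yaml("drug_dictionary.yaml")
    return DrugDictionary(mapping=raw["mapping"],
                          salt_suffixes=tuple(raw.get("salt_suffixes", ())))


def load_drug_dictionary(path: str) -> DrugDictionary:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        if "mapping" not in raw:
            raise ConfigError(f"{path}: YAML dictionary needs a 'mapping' key")
        kwargs = {}
        if "salt_suffixes" in raw:
            kwargs["salt_suffixes"] = tuple(raw["salt_suffixes"])
        return DrugDictionary(mapping=raw["mapping"], **kwargs)
    mapping = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 2:
                raise ConfigError(f"{path}: dictionary CSV needs 2 columns per row")
            mapping[row[0]] = row[1]
    return DrugDictionary(mapping=mapping)


@functools.lru_cache(maxsize=None)
def reference_tables() -> dict:
    """Packaged published contingency counts and scenario parameters."""
    return _read_packaged_yaml("reference_tables.yaml")
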