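"""Convenience builders over the packaged reference counts.

The package ships the contingency counts of a published spontaneous-report
disproportionality analysis (see ``data/reference_tables.yaml``).  These
helpers turn them into ready-made model objects and synthetic fixtures so
that the pipeline's statistics can be exercised — and checked against the
published OR/CI values — without any external data.
"""

from __future__ import annotations

from .config import reference_tables
from .overlay import GeneSet
from .reports import CaseReport, DrugExposure, Role
from .ror import ContingencyTable, ReportingOddsRatio
from .simulate import ExprSimConfig, ProbeSpec


def _table(row: dict) -> ContingencyTable:
    return ContingencyTable.from_marginals(
        a=row["a"], n_exposed=row["n_exposed"],
        c=row["c"], n_unexposed=row["n_unexposed"])


def risk_models() -> dict[str, ReportingOddsRatio]:
    """Full-population disproportionality models, one per antipsychotic."""
    return {row["drug"]: ReportingOddsRatio(_table(row))
            for row in reference_tables()["antipsychotic_risk"]}


def strata_models() -> list[tuple[str, str, ReportingOddsRatio]]:
    """(dimension, stratum label, model) triples for the confounder table."""
    return [(row["dimension"], row["label"], ReportingOddsRatio(_table(row)))
            for row in reference_tables()["quetiapine_strata"]]


def mitigation_tables() -> dict[str, ContingencyTable]:
    """Within-cohort candidate tables for the published mitigation screen."""
    return {row["drug"]: _table(row)
            for row in reference_tables()["quetiapine_cohort_mitigation"]}


def expected_values() -> dict:
    """Published OR/CI values (2 dp) keyed like the builders above."""
    ref = reference_tables()
    return {
        "risk": {row["drug"]: row for row in ref["antipsychotic_risk"]},
        "strata": {(row["dimension"], row["label"]): row
                   for row in ref["quetiapine_strata"]},
        "mitigation": {row["drug"]: row for row in ref["quetiapine_cohort_mitigation"]},
    }


def cooccurrence_fixture() -> list[CaseReport]:
    """Synthetic report fixture reproducing the published co-occurrence
    counts among diabetes event cases exposed to a second antipsychotic.

    Every report carries the second antipsychotic (ziprasidone) and a
    diabetes event term; the published overlap and primary-suspect counts
    for quetiapine (and the primary-suspect count for ziprasidone itself)
    are laid out exactly, so the suspect-fraction computation can be checked
    against the published percentages.
    """
    co = reference_tables()["ziprasidone_cooccurrence"]
    n = co["event_cases_with_ziprasidone"]
    n_overlap = co["also_received_quetiapine"]
    n_quet_ps = co["quetiapine_primary_suspect"]
    n_zip_ps = co["ziprasidone_primary_suspect"]
    assert n_quet_ps + n_zip_ps <= n and n_quet_ps <= n_overlap

    reports = []
    for i in range(n):
        if i < n_quet_ps:                # quetiapine primary suspect
            drugs = (DrugExposure("quetiapine", role=Role.PRIMARY_SUSPECT),
                     DrugExposure("ziprasidone", role=Role.CONCOMITANT))
        elif i < n_quet_ps + n_zip_ps:   # ziprasidone primary suspect, quetiapine concomitant
            drugs = (DrugExposure("ziprasidone", role=Role.PRIMARY_SUSPECT),
                     DrugExposure("quetiapine", role=Role.CONCOMITANT))
        elif i < n_overlap:              # remaining overlap, another drug suspect
            drugs = (DrugExposure("haloperidol", role=Role.PRIMARY_SUSPECT),
                     DrugExposure("ziprasidone", role=Role.CONCOMITANT),
                     DrugExposure("quetiapine", role=Role.CONCOMITANT))
        else:                            # ziprasidone without quetiapine
            drugs = (DrugExposure("haloperidol", role=Role.PRIMARY_SUSPECT),
                     DrugExposure("ziprasidone", role=Role.CONCOMITANT))
        reports.append(CaseReport(
            case_id=f"Z{i:05d}", version=1, drugs=drugs,
            reactions=frozenset(["diabetes mellitus"]),
        ))
    return reports


def insulin_resistance_scenario(
    noise_sd: float = 0.1,
    n_vehicle: int = 20,
    n_treated: int = 3,
    seed: int = 0,
) -> tuple[ExprSimConfig, GeneSet]:
    """Expression-overlay scenario shaped like the published pathway table:
    ten downregulated genes (fold changes 0.39–0.74), one upregulated (1.30)
    and the remaining pathway genes unchanged, with unbalanced groups."""
    ref = reference_tables()["insulin_resistance_overlay"]
    probes = []
    for symbol, fc in {**ref["downregulated"], **ref["upregulated"]}.items():
        probes.append(ProbeSpec(probe_id=f"{symbol.upper()}_PROBE1",
                                symbol=symbol, fold_change=float(fc)))
    for symbol in ref["unchanged"]:
        probes.append(ProbeSpec(probe_id=f"{symbol.upper()}_PROBE1", symbol=symbol))
    gene_set = GeneSet(pathway_id=ref["pathway_id"],
                       symbols=frozenset(p.symbol for p in probes))
    config = ExprSimConfig(probes=tuple(probes), n_vehicle=n_vehicle,
                           n_treated=n_treated, noise_sd=noise_sd, seed=seed)
    return config, gene_set
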