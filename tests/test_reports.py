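"""Report ingestion, deduplication, name normalization and term matching."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal import faers_io
from pvsignal.errors import EmptyInputError, ReportFormatError

from conftest import make_report


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


class TestLoadFaers:
    def test_joins_four_files_per_case_version(self, tmp_path):
        # two cases, three (case_id, version) groups
        demo = _write(tmp_path / "demo.txt",
                      "case_id$version$age$sex\n"
                      "X$1$45$M\nX$2$46$M\nY$1$$F\n")
        drug = _write(tmp_path / "drug.txt",
                      "case_id$version$drug_seq$role$drugname\n"
                      "X$1$1$PS$SEROQUEL\nX$2$1$PS$SEROQUEL\n"
                      "X$2$2$C$lithium\nY$1$1$C$haloperidol\n")
        reac = _write(tmp_path / "reac.txt",
                      "case_id$version$pt\n"
                      "X$1$Diabetes Mellitus\nX$2$diabetic coma\nY$1$nausea\n")
        indi = _write(tmp_path / "indi.txt",
                      "case_id$version$indi_pt\nX$2$bipolar disorder\n")
        reports = pv.load_reports([demo, drug, reac, indi])
        assert len(reports) == 3
        by_key = {(r.case_id, r.version): r for r in reports}
        assert by_key[("X", 1)].reactions == frozenset({"diabetes mellitus"})
        x2 = by_key[("X", 2)]
        assert [d.raw_name for d in x2.drugs] == ["SEROQUEL", "lithium"]
        assert x2.drugs[0].role is pv.Role.PRIMARY_SUSPECT
        assert x2.indications == frozenset({"bipolar disorder"})
        assert by_key[("Y", 1)].age_years is None
        assert by_key[("Y", 1)].sex is pv.Sex.FEMALE

    def test_reports_without_reactions_are_dropped(self, tmp_path, caplog):
        demo = _write(tmp_path / "demo.txt",
                      "case_id$version$age$sex\nX$1$45$M\nY$1$30$F\n")
        reac = _write(tmp_path / "reac.txt", "case_id$version$pt\nX$1$nausea\n")
        reports = pv.load_reports([demo, reac])
        assert [r.case_id for r in reports] == ["X"]

    def test_all_reports_invalid_is_an_error(self, tmp_path):
        demo = _write(tmp_path / "demo.txt", "case_id$version$age$sex\nX$1$45$M\n")
        reac = _write(tmp_path / "reac.txt", "case_id$version$pt\n")
        with pytest.raises(EmptyInputError):
            pv.load_reports([demo, reac])

    def test_missing_column_names_file_and_column(self, tmp_path):
        demo = _write(tmp_path / "demo.txt", "case_id$version$age\nX$1$45\n")
        with pytest.raises(ReportFormatError) as err:
            pv.load_reports([demo])
        assert "sex" in str(err.value) and "demo.txt" in str(err.value)

    def test_malformed_rows_are_skipped_not_fatal(self, tmp_path):
        demo = _write(tmp_path / "demo.txt",
                      "case_id$version$age$sex\nX$1$45$M\nbroken row\nY$oops$30$F\n")
        reac = _write(tmp_path / "reac.txt",
                      "case_id$version$pt\nX$1$nausea\n")
        reports = pv.load_reports([demo, reac])
        assert [r.case_id for r in reports] == ["X"]


@pytest.fixture(scope="module")
def synthetic_reports():
    config = pv.ReportSimConfig(
        n_reports=300,
        drugs=(pv.DrugSpec("quetiapine", 0.2, 2.0), pv.DrugSpec("lithium", 0.1)),
        indications=(pv.IndicationSpec("bipolar disorder", 0.2,
                                       linked_drug="quetiapine",
                                       exposure_multiplier=2.0),),
        duplicate_rate=0.1, seed=42)
    reports, _ = pv.simulate_reports(config)
    return reports


class TestRoundTrip:
    def test_faers_write_then_load_reproduces_reports(self, tmp_path, synthetic_reports):
        paths = pv.write_faers_files(synthetic_reports, tmp_path)
        loaded = pv.load_reports(list(paths.values()))
        assert sorted(loaded, key=lambda r: (r.case_id, r.version)) == \
               sorted(synthetic_reports, key=lambda r: (r.case_id, r.version))

    def test_faers_write_is_byte_stable(self, tmp_path, synthetic_reports):
        paths1 = pv.write_faers_files(synthetic_reports, tmp_path / "one")
        loaded = pv.load_reports(list(paths1.values()))
        paths2 = pv.write_faers_files(loaded, tmp_path / "two")
        for kind in paths1:
            b1 = open(paths1[kind], "rb").read()
            b2 = open(paths2[kind], "rb").read()
            assert b1 == b2, f"{kind} table not byte-identical after round trip"

    def test_flat_csv_round_trip(self, tmp_path, synthetic_reports):
        path = faers_io.write_flat_csv(synthetic_reports, tmp_path / "flat.csv")
        loaded = pv.load_reports([path], dialect="csv")
        assert sorted(loaded, key=lambda r: (r.case_id, r.version)) == \
               sorted(synthetic_reports, key=lambda r: (r.case_id, r.version))

    def test_empty_report_list_writes_headers_only(self, tmp_path):
        paths = pv.write_faers_files([], tmp_path)
        for kind, path in paths.items():
            lines = open(path).read().splitlines()
            assert len(lines) == 1 and "case_id" in lines[0]

    def test_missing_age_and_sex_round_trip_as_missing(self, tmp_path):
        report = make_report("m1", drugs=["quetiapine"], reactions=["nausea"])
        # writer represents unknown demographics as blank fields
        paths = pv.write_faers_files([report], tmp_path)
        demo_rows = open(paths["demo"]).read().splitlines()
        assert demo_rows[1] == "m1$1$$"
        (loaded,) = pv.load_reports(list(paths.values()))
        assert loaded.age_years is None and loaded.sex is pv.Sex.UNKNOWN


class TestDeduplicate:
    def test_keeps_maximal_version(self):
        reports = [make_report("X", version=1), make_report("X", version=2)]
        (survivor,) = pv.deduplicate(reports)
        assert survivor.version == 2

    def test_idempotent_and_sorted(self):
        reports = [make_report(cid, version=v)
                   for cid, v in [("b", 1), ("a", 3), ("a", 1), ("c", 2)]]
        once = pv.deduplicate(reports)
        assert pv.deduplicate(once) == once
        assert [r.case_id for r in once] == ["a", "b", "c"]

    def test_version_tie_keeps_last_seen_with_warning(self, caplog):
        first = make_report("X", version=2, reactions=["nausea"])
        second = make_report("X", version=2, reactions=["rash"])
        with caplog.at_level("WARNING"):
            (kept,) = pv.deduplicate([first, second])
        assert kept.reactions == frozenset({"rash"})
        assert any("duplicate version" in m for m in caplog.messages)

    def test_removes_exactly_injected_duplicates(self):
        config = pv.ReportSimConfig(
            n_reports=1000, drugs=(pv.DrugSpec("quetiapine", 0.1, 1.0),),
            duplicate_rate=0.1, seed=7)
        reports, truth = pv.simulate_reports(config)
        assert len(reports) == 1000 and len(truth.duplicated_case_ids) == 100
        survivors = pv.deduplicate(reports)
        assert len(survivors) == 900
        ids = [r.case_id for r in survivors]
        assert len(set(ids)) == len(ids)
        assert all(r.version == 2 for r in survivors)

    @given(st.lists(st.tuples(st.sampled_from("abcde"), st.integers(0, 5)), max_size=30))
    def test_output_never_larger_and_unique(self, pairs):
        reports = [make_report(cid, version=v) for cid, v in pairs]
        out = pv.deduplicate(reports)
        assert len(out) <= len(reports)
        ids = [r.case_id for r in out]
        assert len(set(ids)) == len(ids)
        if len({r.case_id for r in reports}) == len(reports):
            assert sorted(out, key=lambda r: r.case_id) == \
                   sorted(reports, key=lambda r: r.case_id)


@pytest.fixture(scope="module")
def dictionary():
    return pv.default_drug_dictionary()


class TestNormalize:
    @pytest.mark.parametrize("raw, generic", [
        ("SEROQUEL", "quetiapine"),
        ("quetiapine fumarate", "quetiapine"),
        ("  Zyprexa ", "olanzapine"),
        ("lithium carbonate", "lithium"),
        ("Vitamin D3", "cholecalciferol"),
    ])
    def test_dictionary_lookup(self, dictionary, raw, generic):
        assert dictionary.resolve(raw) == generic

    def test_unmatched_kept_with_cleaned_name(self, dictionary):
        reports = [make_report("u1", reactions=["nausea"])]
        reports[0] = pv.CaseReport(
            case_id="u1", drugs=(pv.DrugExposure(raw_name="Obscurol 500mg!"),),
            reactions=frozenset(["nausea"]))
        (out,) = pv.normalize_drug_names(reports, dictionary)
        assert out.drugs[0].generic_name == "obscurol 500mg"

    def test_counts_preserved_and_variants_all_resolved(self, dictionary):
        config = pv.ReportSimConfig(
            n_reports=2000, drugs=(pv.DrugSpec("quetiapine", 0.3, 1.0),
                                   pv.DrugSpec("olanzapine", 0.2)),
            duplicate_rate=0.0, name_variant_rate=0.1, dictionary=dictionary,
            seed=11)
        reports, truth = pv.simulate_reports(config)
        out = pv.normalize_drug_names(reports, dictionary)
        assert len(out) == len(reports)
        assert [len(r.drugs) for r in out] == [len(r.drugs) for r in reports]
        n_variant = sum(1 for r in reports for e in r.drugs
                        if e.raw_name not in config.drug_names)
        assert n_variant == truth.n_name_variants > 0
        # every exposure, variant or not, resolves to its generating generic
        for before, after in zip(reports, out):
            for e_before, e_after in zip(before.drugs, after.drugs):
                assert e_after.generic_name in config.drug_names


class TestMatchTerms:
    def test_exact_match_on_reactions(self, dm_terms):
        hit = make_report("x", reactions=["diabetic coma"])
        miss = make_report("y", reactions=["nausea"])
        assert pv.match_terms(hit, dm_terms, "reactions")
        assert not pv.match_terms(miss, dm_terms, "reactions")

    def test_drug_field_uses_generic_names(self):
        vitd = pv.builtin_term_set("vitamin_d")
        report = make_report("x", drugs=["cholecalciferol"], reactions=["rash"])
        assert pv.match_terms(report, vitd, "drugs")

    def test_indications_field(self):
        ts = pv.TermSet(name="psych", terms=frozenset(["schizophrenia"]))
        report = make_report("x", reactions=["rash"], indications=["schizophrenia"])
        assert pv.match_terms(report, ts, "indications")

    def test_invalid_field_rejected(self, dm_terms):
        with pytest.raises(pv.ConfigError):
            pv.match_terms(make_report("x"), dm_terms, "ages")

    @given(st.frozensets(st.sampled_from(
        ["diabetes mellitus", "diabetic coma", "nausea", "rash"]), min_size=1),
        st.frozensets(st.sampled_from(
            ["diabetes mellitus", "diabetic coma", "hyperglycaemia"]), min_size=1))
    def test_monotone_in_term_set(self, reactions, base_terms):
        report = make_report("x", reactions=reactions)
        small = pv.TermSet(name="s", terms=base_terms)
        large = pv.TermSet(name="l", terms=base_terms | {"nausea", "rash"})
        if pv.match_terms(report, small, "reactions"):
            assert pv.match_terms(report, large, "reactions")
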