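"""Expression back-transform, relative expression, Welch testing and overlay."""

import math

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal import reference
from pvsignal.overlay import ExpressionMatrix


def matrix_from_original(vehicle, treated, probe="P1", symbol="GeneX"):
    """Build a one-probe matrix from original-scale values."""
    values = [math.log2(v) for v in list(vehicle) + list(treated)]
    samples = [f"v{i}" for i in range(len(vehicle))] + \
              [f"t{i}" for i in range(len(treated))]
    groups = pd.Series(["vehicle"] * len(vehicle) + ["treated"] * len(treated),
                       index=samples)
    return ExpressionMatrix(values=pd.DataFrame([values], index=[probe], columns=samples),
                            symbols=pd.Series([symbol], index=[probe]),
                            groups=groups)


class TestBackTransform:
    def test_log2_zero_and_three(self):
        m = matrix_from_original([1, 8], [1, 8])
        orig = pv.back_transform(m)
        assert orig.iloc[0].tolist() == pytest.approx([1, 8, 1, 8])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        config = pv.ExprSimConfig(probes=pv.null_probes(20), seed=4)
        m, _ = pv.simulate_expression(config)
        orig = pv.back_transform(m)
        assert np.allclose(np.log2(orig.to_numpy()), m.values.to_numpy())


class TestRelativeExpression:
    def test_hand_computed_two_sample_matrix(self):
        # vehicle {4, 4}, treated {1, 3} on the original scale:
        # vehicle mean 4, ratios {0.25, 0.75} -> mean 0.5
        m = matrix_from_original([4, 4], [1, 3])
        mean, sem = pv.relative_expression(m, "P1")
        assert mean == pytest.approx(0.5)
        ratios_sd = np.std([0.25, 0.75], ddof=1)
        assert sem == pytest.approx(ratios_sd / math.sqrt(2))

    def test_treated_at_vehicle_mean_is_unity_with_zero_sem(self):
        m = matrix_from_original([2, 6], [4, 4, 4])
        mean, sem = pv.relative_expression(m, "P1")
        assert (mean, sem) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_missing_probe_is_an_error(self):
        m = matrix_from_original([4, 4], [1, 3])
        with pytest.raises(pv.DataError):
            pv.relative_expression(m, "nope")

    def test_fold_change_recovery_under_noise(self):
        # injected FC 0.40, noise sd 0.2 log2 units, 20 vs 3 samples: the
        # estimate recovers the truth within its own 95% uncertainty in
        # >= 90% of replicates.  With 3 treated samples the SEM carries
        # df=2, so the correct 95% multiplier is t(0.975, 2) = 4.30, not 2.
        from scipy import stats
        tq = stats.t.ppf(0.975, df=2)
        probe = pv.ProbeSpec("FC_PROBE1", "Fc", fold_change=0.40)
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            config = pv.ExprSimConfig(probes=(probe,), noise_sd=0.2, seed=1000 + s)
            m, _ = pv.simulate_expression(config)
            mean, sem = pv.relative_expression(m, "FC_PROBE1")
            hits += abs(mean - 0.40) <= tq * sem
        assert hits / n_rep >= 0.90


class TestWelchTest:
    def test_identical_groups_give_p_one(self, caplog):
        m = matrix_from_original([4, 4], [4, 4])
        with caplog.at_level("WARNING"):
            assert pv.test_probe(m, "P1") == 1.0
        assert any("zero variance" in msg for msg in caplog.messages)

    def test_type_one_error_calibrated_on_balanced_null(self):
        # balanced groups: Welch's t holds its nominal size
        config = pv.ExprSimConfig(probes=pv.null_probes(1000),
                                  n_vehicle=20, n_treated=20, seed=8)
        m, _ = pv.simulate_expression(config)
        pvals = np.array([pv.test_probe(m, p) for p in m.values.index])
        rate = float((pvals < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_known_anticonservatism_at_three_treated_samples(self):
        # with only 3 treated samples the Satterthwaite approximation is
        # anti-conservative: the true size at alpha=0.05 is ~0.075, a
        # documented limitation of the default design
        config = pv.ExprSimConfig(probes=pv.null_probes(1000),
                                  n_vehicle=20, n_treated=3, seed=8)
        m, _ = pv.simulate_expression(config)
        pvals = np.array([pv.test_probe(m, p) for p in m.values.index])
        rate = float((pvals < 0.05).mean())
        assert 0.05 <= rate <= 0.10

    def test_power_against_strong_fold_change(self):
        # FC 0.4, sd 0.2 log2 units, 20 vs 3: detected in a majority of reps
        probe = pv.ProbeSpec("FC_PROBE1", "Fc", fold_change=0.40)
        detected = sum(
            pv.test_probe(pv.simulate_expression(
                pv.ExprSimConfig(probes=(probe,), noise_sd=0.2, seed=2000 + s))[0],
                "FC_PROBE1") < 0.05
            for s in range(60))
        assert detected / 60 > 0.5

    def test_original_scale_option(self):
        m = matrix_from_original([4, 4, 5], [1, 2, 1])
        p_log = pv.test_probe(m, "P1", scale="log2")
        p_orig = pv.test_probe(m, "P1", scale="original")
        assert 0 < p_log < 1 and 0 < p_orig < 1 and p_log != p_orig


@pytest.fixture(scope="module")
def scenario():
    config, gene_set = reference.insulin_resistance_scenario(seed=0)
    matrix, truth = pv.simulate_expression(config)
    return matrix, gene_set, truth


class TestOverlay:
    def test_alpha_zero_returns_nothing(self, scenario):
        matrix, gene_set, _ = scenario
        assert pv.overlay(matrix, gene_set, alpha=0.0) == []

    def test_alpha_one_returns_every_pathway_probe(self, scenario):
        matrix, gene_set, _ = scenario
        rows = pv.overlay(matrix, gene_set, alpha=1.0)
        assert len(rows) == len(matrix.values.index)

    def test_disjoint_gene_set_is_an_error_naming_symbols(self, scenario):
        matrix, _, _ = scenario
        missing = pv.GeneSet(pathway_id="none", symbols=frozenset(["Nosuchgene"]))
        with pytest.raises(pv.DataError) as err:
            pv.overlay(matrix, missing)
        assert "Nosuchgene" in str(err.value)

    def test_rows_sorted_ascending_and_directions_consistent(self, scenario):
        matrix, gene_set, _ = scenario
        rows = pv.overlay(matrix, gene_set, alpha=1.0)
        means = [r.relative_expression_mean for r in rows]
        assert means == sorted(means)
        for r in rows:
            assert (r.direction is pv.ExprDirection.DOWN) == \
                   (r.relative_expression_mean < 1.0)

    def test_down_up_split_recovered_across_seeds(self):
        # pathway-table-shaped scenario: 10 down, 1 up, 13 null probes
        for seed in range(5):
            config, gene_set = reference.insulin_resistance_scenario(seed=seed)
            matrix, truth = pv.simulate_expression(config)
            results = pv.PathwayOverlay(matrix, gene_set).fit()
            assert abs(results.n_down - 10) <= 1, f"seed {seed}"
            assert abs(results.n_up - 1) <= 1, f"seed {seed}"
            assert results.n_down + results.n_up == len(results.rows)

    def test_strongest_downregulation_ranked_first(self, scenario):
        matrix, gene_set, truth = scenario
        results = pv.PathwayOverlay(matrix, gene_set).fit()
        assert results.rows[0].symbol == "Pik3r1"  # injected FC 0.39 is the lowest

    def test_fdr_never_adds_rows(self, scenario):
        matrix, gene_set, _ = scenario
        raw = pv.overlay(matrix, gene_set, alpha=0.05, fdr=False)
        adj = pv.overlay(matrix, gene_set, alpha=0.05, fdr=True)
        assert {r.probe for r in adj} <= {r.probe for r in raw}

    def test_tsv_round_trip(self, scenario, tmp_path):
        matrix, _, _ = scenario
        matrix.to_tsv(tmp_path / "m.tsv", tmp_path / "g.tsv")
        loaded = ExpressionMatrix.from_tsv(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert np.allclose(loaded.values.to_numpy(), matrix.values.to_numpy())
        assert list(loaded.groups) == list(matrix.groups)


class TestMatrixValidation:
    def test_group_needs_two_samples(self):
        with pytest.raises(pv.DataError):
            matrix_from_original([4, 4], [1])

    def test_unknown_group_label_rejected(self):
        values = pd.DataFrame([[1.0, 2.0, 1.5, 1.0]], index=["P1"],
                              columns=list("abcd"))
        groups = pd.Series(["vehicle", "vehicle", "treated", "mystery"],
                           index=list("abcd"))
        with pytest.raises(pv.ConfigError):
            ExpressionMatrix(values=values, symbols=pd.Series(["G"], index=["P1"]),
                             groups=groups)
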