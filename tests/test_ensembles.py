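"""Conformational-ensemble figures of merit."""

import numpy as np
import pandas as pd
import pytest

from qdrcharges import (
    EnsembleChargeTable,
    conformation_average,
    conformational_sensitivity,
    make_ensemble,
    merit_report,
    method_correlations,
    pareto_table,
    rms_charge_transfer,
)
from qdrcharges.errors import ValidationError


def _table(values, methods=None):
    values = np.asarray(values, dtype=float)
    m, c, _ = values.shape
    return EnsembleChargeTable(
        methods=methods or [f"m{i}" for i in range(m)],
        conformations=[f"c{i}" for i in range(c)],
        values=values,
    )


class TestConformationAverage:
    def test_single_conformation_is_identity(self):
        t = _table(np.array([[[0.1, -0.1, 0.4]]]))
        np.testing.assert_array_equal(conformation_average(t), [[0.1, -0.1, 0.4]])

    def test_two_conformation_mean(self):
        t = _table(np.array([[[0.1, 0.0], [0.3, 0.0]]]))
        np.testing.assert_allclose(conformation_average(t)[0, 0], 0.2)

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((3, 7, 11))
        t = _table(vals)
        avg = conformation_average(t)
        for m in range(3):
            for a in range(11):
                assert avg[m, a] == pytest.approx(
                    sum(vals[m, c, a] for c in range(7)) / 7, abs=1e-14
                )


class TestRmsChargeTransfer:
    def test_symmetric_pair(self):
        sigma, qbar = rms_charge_transfer(np.array([[0.5, -0.5]]))
        assert sigma[0] == pytest.approx(0.5) and qbar[0] == pytest.approx(0.0)

    def test_constant_charges_give_zero(self):
        sigma, qbar = rms_charge_transfer(np.full((1, 9), 0.3))
        assert sigma[0] == 0.0 and qbar[0] == pytest.approx(0.3)

    def test_population_rms_oracle(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((1, 50))
        sigma, _ = rms_charge_transfer(q)
        assert sigma[0] == pytest.approx(np.std(q[0]), abs=1e-14)  # population std


class TestSensitivity:
    def test_constant_over_conformations_gives_zero(self):
        t = _table(np.tile(np.array([0.4, -0.4])[None, None, :], (1, 5, 1)))
        sens, _ = conformational_sensitivity(t, "m0")
        assert sens == 0.0

    def test_pooled_rms_matches_direct_loop(self):
        vals = np.array([[[0.1, 0.4], [0.3, 0.4]]])  # one atom varies
        t = _table(vals)
        sens, _ = conformational_sensitivity(t, "m0")
        devs = []
        for a in range(2):
            avg = vals[0, :, a].mean()
            devs.extend((vals[0, c, a] - avg) ** 2 for c in range(2))
        assert sens == pytest.approx(np.sqrt(np.mean(devs)), abs=1e-14)

    def test_homogeneity_under_charge_scaling(self):
        base = make_ensemble(n_atoms=20, n_conformations=6, n_methods=1, seed=3)
        doubled = _table(2.0 * base.values, methods=base.methods)
        s1, n1 = conformational_sensitivity(base, base.methods[0])
        s2, n2 = conformational_sensitivity(doubled, base.methods[0])
        assert s2 == pytest.approx(2 * s1, rel=1e-12)
        assert n2 == pytest.approx(n1, rel=1e-12)

    def test_single_conformation_rejected(self):
        t = _table(np.zeros((1, 1, 3)))
        with pytest.raises(ValidationError):
            conformational_sensitivity(t, "m0")

    def test_zero_sigma_rejected(self):
        t = _table(np.full((1, 3, 4), 0.2))
        with pytest.raises(ValidationError, match="zero rms"):
            conformational_sensitivity(t, "m0")


class TestCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        q = rng.standard_normal(30)
        rep = method_correlations(np.stack([q, q]), ["a", "b"])
        np.testing.assert_allclose(rep.correlation, 1.0, atol=1e-12)

    def test_negated_recentered_method_correlates_minus_one(self):
        rng = np.random.default_rng(6)
        q = rng.standard_normal(30)
        rep = method_correlations(np.stack([q, -q + 0.7]), ["a", "b"])
        assert rep.correlation[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(7)
        q = rng.standard_normal((3, 100))
        rep = method_correlations(q, ["a", "b", "c"])
        np.testing.assert_allclose(rep.correlation, np.corrcoef(q), atol=1e-12)
        # symmetry and unit diagonal
        np.testing.assert_allclose(rep.correlation, rep.correlation.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(rep.correlation), 1.0, atol=1e-12)
        assert np.all(np.abs(rep.correlation) <= 1.0 + 1e-12)

    def test_mean_profile_is_most_confluent(self):
        rng = np.random.default_rng(8)
        profiles = rng.standard_normal((4, 60))
        mean_method = profiles.mean(axis=0)[None, :]
        q = np.concatenate([profiles, mean_method])
        rep = method_correlations(q, ["a", "b", "c", "d", "mean"])
        assert np.argmax(rep.summed_correlations) == 4

    def test_strong_count_uses_inclusive_threshold(self):
        base = np.linspace(-1, 1, 40)
        exact = 0.9 * base + np.sqrt(1 - 0.81) * np.linspace(1, -1, 40)[::-1]
        # construct two identical methods (corr 1) and check self excluded
        rep = method_correlations(np.stack([base, base.copy()]), ["a", "b"])
        assert list(rep.n_strong) == [1, 1]


class TestReportAndPareto:
    def test_law_of_total_variance_decomposition(self):
        table = make_ensemble(n_atoms=40, n_conformations=30, n_methods=2,
                              perturbation=0.03, seed=9)
        rep = merit_report(table)
        for mi, m in enumerate(table.methods):
            pooled_var = float(np.var(table.values[mi]))
            avg_var = float(np.var(table.values[mi].mean(axis=0)))
            assert rep.sensitivity[mi] ** 2 + avg_var == pytest.approx(
                pooled_var, rel=1e-10
            )

    def test_normalized_sensitivity_definition(self):
        table = make_ensemble(n_atoms=25, n_conformations=10, seed=10)
        rep = merit_report(table)
        np.testing.assert_allclose(
            rep.normalized_sensitivity, rep.sensitivity / rep.sigma, atol=1e-14
        )

    def test_sensitivity_recovers_generator_jitter(self):
        # with many conformations the pooled rms approaches the jitter sd
        table = make_ensemble(n_atoms=50, n_conformations=1000, n_methods=2,
                              perturbation=0.05, seed=11)
        rep = merit_report(table)
        for s in rep.sensitivity:
            assert s == pytest.approx(0.05, rel=0.05)

    def test_zero_perturbation_gives_zero_sensitivity(self):
        table = make_ensemble(n_atoms=10, n_conformations=5, perturbation=0.0, seed=12)
        rep = merit_report(table)
        np.testing.assert_allclose(rep.sensitivity, 0.0, atol=1e-15)

    def test_pareto_single_method_single_row(self):
        table = make_ensemble(n_atoms=10, n_conformations=4, n_methods=2, seed=13)
        rep = merit_report(table)
        df = pareto_table(rep, {m: 0.3 for m in rep.methods})
        assert len(df) == 2

    def test_pareto_tie_broken_by_sensitivity(self):
        table = make_ensemble(n_atoms=30, n_conformations=8, n_methods=3, seed=14)
        rep = merit_report(table)
        df = pareto_table(rep, {m: 0.25 for m in rep.methods})
        assert list(df["sensitivity"]) == sorted(df["sensitivity"])

    def test_pareto_rows_match_individually_computed_statistics(self):
        table = make_ensemble(n_atoms=30, n_conformations=8, n_methods=4, seed=15)
        rep = merit_report(table)
        df = pareto_table(rep, {m: 0.2 for m in rep.methods}).set_index("method")
        for mi, m in enumerate(table.methods):
            sens, nsens = conformational_sensitivity(table, m)
            assert df.loc[m, "sensitivity"] == pytest.approx(sens, abs=1e-14)
            sigma, _ = rms_charge_transfer(conformation_average(table)[mi][None, :])
            assert df.loc[m, "rms_charge_transfer"] == pytest.approx(sigma[0], abs=1e-14)


class TestLongFormat:
    def test_long_round_trip(self):
        table = make_ensemble(n_atoms=6, n_conformations=3, n_methods=2, seed=16)
        back = EnsembleChargeTable.from_long(table.to_long())
        np.testing.assert_allclose(back.values, table.values, atol=1e-14)

    def test_ragged_table_rejected(self):
        df = pd.DataFrame(
            {
                "method": ["a", "a", "b"],
                "conformation": ["c0", "c0", "c0"],
                "atom": [0, 1, 0],
                "charge": [0.1, 0.2, 0.3],
            }
        )
        with pytest.raises(ValidationError, match="rectangular"):
            EnsembleChargeTable.from_long(df)
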