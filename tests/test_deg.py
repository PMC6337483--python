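"""Moderated-t differential expression: worked examples, oracles, invariants.

The empirical-Bayes fit is cross-checked against frozen output of an
independent reference implementation (limma's lmFit/eBayes, run once on the
two fixtures under tests/data and stored as TSV).
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddipipe.deg import adjust_bh, call_degs, fit_moderated_t
from ddipipe.integration import IntegratedDataset, integrate_studies
from ddipipe.synthetic import SimulationConfig, simulate_collection

from conftest import make_integrated

DATA = Path(__file__).parent / "data"


def load_fixture(matrix_name, n_case):
    values = pd.read_csv(DATA / matrix_name, sep="\t", index_col=0)
    n = values.shape[1]
    info = pd.DataFrame(
        {"study": "S1", "group": ["case"] * n_case + ["control"] * (n - n_case)},
        index=values.columns,
    )
    return IntegratedDataset(values=values, sample_info=info, provenance=["S1"])


class TestModeratedT:
    def test_equal_group_means_give_t_zero_p_one(self):
        data = make_integrated(
            [[1.0, 2.0, 1.0, 2.0], [3.0, 5.0, 4.0, 4.0]],
            ["case", "case", "control", "control"],
        )
        table = fit_moderated_t(data, ebayes=False)
        row = table.loc["g1"]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_classical_pooled_t_worked_example(self):
        # case [3, 4] vs control [1, 2]: logFC 2, t = 2.828, df 2, p = 0.1056
        data = make_integrated(
            [[3.0, 4.0, 1.0, 2.0], [0.0, 1.0, 0.5, 0.2]],
            ["case", "case", "control", "control"],
        )
        row = fit_moderated_t(data, ebayes=False).loc["g1"]
        assert row["logFC"] == pytest.approx(2.0)
        assert row["t"] == pytest.approx(2.828, abs=5e-4)
        assert row["df_resid"] == 2
        assert row["p"] == pytest.approx(0.1056, abs=5e-5)

    def test_full_shrinkage_with_common_variance_equals_classical_t(self):
        # when every gene has the same sample variance, d0 -> inf and
        # s0_sq = s2, so the moderated t equals the classical pooled t
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=4)
        x = np.array([base + shift for shift in rng.normal(0, 2, size=12)])
        data = make_integrated(x, ["case", "case", "control", "control"])
        classical = fit_moderated_t(data, ebayes=False)
        moderated = fit_moderated_t(data, d0_override=float("inf"))
        np.testing.assert_allclose(
            moderated["t"].sort_index(), classical["t"].sort_index(), atol=1e-9
        )

    def test_small_group_rejected(self):
        data = make_integrated([[1.0, 2.0, 3.0]], ["case", "case", "control"])
        with pytest.raises(ValueError, match="2 samples per group"):
            fit_moderated_t(data)

    @pytest.mark.parametrize(
        "matrix,expected,n_case",
        [
            ("limma_fixture.tsv", "limma_expected.tsv", 5),
            ("limma_fixture2.tsv", "limma_expected2.tsv", 4),
        ],
    )
    def test_matches_independent_reference_fit(self, matrix, expected, n_case):
        """Frozen lmFit/eBayes output (limma 3.58.1) on the same fixture."""
        data = load_fixture(matrix, n_case)
        mine = fit_moderated_t(data)
        ref = pd.read_csv(DATA / expected, sep="\t", index_col=0)
        mine = mine.loc[ref.index]
        np.testing.assert_allclose(mine["logFC"], ref["logFC"], atol=1e-9)
        np.testing.assert_allclose(mine["t"], ref["t"], atol=1e-8)
        np.testing.assert_allclose(mine["p"], ref["p"], atol=1e-10)


def brute_force_bh(p):
    """Literal step-up definition: p_adj(i) = min over j >= i of min(1, p(j)*m/j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    for rank_idx, i in enumerate(order):
        candidates = [
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(rank_idx, m)
        ]
        adjusted[i] = min(candidates)
    return adjusted


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_and_boundary(self):
        np.testing.assert_allclose(adjust_bh([0.3]), [0.3])
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_matches_brute_force_oracle_on_1000_random_vectors(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.uniform(0, 1, size=m)
            np.testing.assert_allclose(adjust_bh(p), brute_force_bh(list(p)), atol=1e-12)


class TestCallDegs:
    @staticmethod
    def table_from(logfc, p_adj):
        return pd.DataFrame(
            {
                "logFC": logfc,
                "p": p_adj,
                "p_adj": p_adj,
                "s2": 1.0,
                "df_resid": 10.0,
                "t": 1.0,
            },
            index=[f"g{i}" for i in range(len(logfc))],
        )

    def test_dual_threshold(self):
        # 0.78 > log2(1.5) ~ 0.585 -> in; 0.5 -> out despite tiny p
        table = self.table_from([0.78, 0.5], [0.03, 0.001])
        assert call_degs(table) == ["g0"]

    def test_invalid_thresholds_rejected(self):
        table = self.table_from([1.0], [0.01])
        with pytest.raises(ValueError, match="fc_threshold"):
            call_degs(table, fc_threshold=1.0)
        with pytest.raises(ValueError, match="alpha"):
            call_degs(table, alpha=0.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_nestedness_under_tightened_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        m = 50
        table = self.table_from(rng.normal(0, 1, m), rng.uniform(0, 0.2, m))
        tight = set(call_degs(table, fc_threshold=2.0, alpha=0.01))
        loose = set(call_degs(table, fc_threshold=1.5, alpha=0.05))
        assert tight <= loose

    def test_sign_recovery_on_simulation(self):
        """Recovered true DEGs carry the simulated effect sign (>= 99%)."""
        agreements, total = 0, 0
        for seed in range(10):
            studies, truth = simulate_collection(
                SimulationConfig(n_genes=400, seed=seed)
            )
            data = integrate_studies(studies)
            table = fit_moderated_t(data)
            recovered = set(call_degs(table)) & truth.deg_genes
            for gene in recovered:
                total += 1
                agreements += np.sign(table.loc[gene, "logFC"]) == np.sign(
                    truth.effects[gene]
                )
        assert total > 50
        assert agreements / total >= 0.99
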