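"""Per-array z-scoring, probe collapse, outlier screening, multi-study merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddipipe.integration import (
    collapse_probes,
    detect_outlier_arrays,
    integrate_studies,
    zscore_transform,
)
from ddipipe.synthetic import SEVEN_STUDY_SIZES, SimulationConfig, simulate_collection

from conftest import make_study


class TestZscore:
    def test_symmetric_column(self):
        study = make_study([[1.0], [2.0], [3.0]], ["case"])
        z = zscore_transform(study)
        np.testing.assert_allclose(z.values.iloc[:, 0], [-1.0, 0.0, 1.0])

    def test_columns_have_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(5, 3, size=(50, 6)), ["case"] * 3 + ["control"] * 3)
        z = zscore_transform(study).values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_constant_array_rejected(self):
        study = make_study([[5.0], [5.0], [5.0]], ["case"])
        with pytest.raises(ValueError, match="zero variance"):
            zscore_transform(study)

    @settings(max_examples=50, deadline=None)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(123)
        x = rng.normal(0, 1, size=(20, 3))
        base = zscore_transform(make_study(x, ["case"] * 3)).values.to_numpy()
        transformed = zscore_transform(
            make_study(x * scale + shift, ["case"] * 3)
        ).values.to_numpy()
        np.testing.assert_allclose(transformed, base, atol=1e-9)


class TestCollapseProbes:
    def test_multi_probe_gene_averaged(self):
        study = make_study([[2.0, 4.0], [4.0, 6.0]], ["case", "control"], genes=["p1", "p2"])
        collapsed = collapse_probes(study, {"p1": "gA", "p2": "gA"})
        assert collapsed.gene_ids == ["gA"]
        np.testing.assert_allclose(collapsed.values.loc["gA"], [3.0, 5.0])

    def test_single_probe_identity(self):
        study = make_study([[1.0, 2.0]], ["case", "control"], genes=["p1"])
        collapsed = collapse_probes(study, {"p1": "gA"})
        np.testing.assert_allclose(collapsed.values.loc["gA"], [1.0, 2.0])

    def test_unmapped_probe_dropped(self):
        study = make_study(
            [[1.0], [2.0], [3.0]], ["case"], genes=["p1", "p2", "p3"]
        )
        collapsed = collapse_probes(study, {"p1": "gA", "p3": "gB"})
        assert sorted(collapsed.gene_ids) == ["gA", "gB"]

    def test_empty_mapping_rejected(self):
        study = make_study([[1.0]], ["case"], genes=["p1"])
        with pytest.raises(ValueError, match="no probes left"):
            collapse_probes(study, {"px": "gA"})


class TestOutliers:
    def test_identical_arrays_no_outlier(self):
        study = make_study(np.tile([[1.0], [2.0], [3.0]], (1, 3)), ["case"] * 3)
        assert detect_outlier_arrays(study) == []

    def test_noise_array_flagged(self):
        rng = np.random.default_rng(77)
        profile = rng.normal(0, 2, size=100)
        arrays = [profile + rng.normal(0, 0.1, size=100) for _ in range(9)]
        arrays.append(rng.normal(0, 2, size=100))  # unrelated noise array
        study = make_study(np.column_stack(arrays), ["case"] * 10)
        assert detect_outlier_arrays(study) == [study.sample_ids[-1]]

    def test_two_sample_study_returns_empty(self):
        study = make_study([[1.0, 2.0], [2.0, 1.0]], ["case", "control"])
        assert detect_outlier_arrays(study) == []


class TestIntegrate:
    @staticmethod
    def collection(seed=0, sizes=SEVEN_STUDY_SIZES, n_genes=40):
        studies, _ = simulate_collection(
            SimulationConfig(n_genes=n_genes, study_sizes=sizes, seed=seed)
        )
        return studies

    def test_five_study_dataset_has_60_cases_12_controls(self):
        sizes = [(13, 0), (14, 9), (10, 0), (16, 0), (7, 3)]
        data = integrate_studies(self.collection(sizes=sizes))
        assert (data.n_case, data.n_control) == (60, 12)

    def test_seven_study_dataset_has_68_cases_16_controls(self):
        data = integrate_studies(self.collection())
        assert (data.n_case, data.n_control) == (68, 16)

    def test_single_study_is_just_zscoring(self):
        study = self.collection(sizes=[(3, 3)])[0]
        data = integrate_studies([study])
        assert data.gene_ids == study.gene_ids
        np.testing.assert_allclose(data.values.to_numpy().mean(axis=0), 0.0, atol=1e-9)

    def test_columns_standardized_after_merge(self):
        data = integrate_studies(self.collection())
        x = data.values.to_numpy()
        np.testing.assert_allclose(x.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(x.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_order_invariance(self):
        studies = self.collection(sizes=[(3, 2), (4, 3), (2, 2)])
        a = integrate_studies(studies)
        b = integrate_studies(studies[::-1])
        shared_gene = a.gene_ids[0]
        for sample in a.values.columns:
            assert a.values.loc[shared_gene, sample] == pytest.approx(
                b.values.loc[shared_gene, sample]
            )

    def test_gene_intersection_monotone(self):
        studies = self.collection(sizes=[(3, 2), (4, 3)])
        # knock a gene out of a third study
        extra = self.collection(sizes=[(3, 2), (4, 3), (3, 3)])[2]
        extra = make_study(
            extra.values.iloc[1:].to_numpy(),
            list(extra.groups),
            study_id="S9",
            genes=extra.gene_ids[1:],
            samples=[f"S9_s{i}" for i in range(len(extra.sample_ids))],
        )
        small = integrate_studies(studies + [extra])
        assert set(small.gene_ids) <= set(integrate_studies(studies).gene_ids)
        assert len(small.gene_ids) == len(studies[0].gene_ids) - 1

    def test_empty_intersection_reports_counts(self):
        a = make_study([[1.0, 2.0], [0.0, 1.0]], ["case", "control"], genes=["g1", "g2"])
        b = make_study(
            [[1.0, 2.0], [0.0, 1.0]],
            ["case", "control"],
            study_id="S2",
            genes=["g3", "g4"],
            samples=["S2_s1", "S2_s2"],
        )
        with pytest.raises(ValueError, match="empty gene intersection"):
            integrate_studies([a, b])

    def test_array_scale_factor_removed_by_standardization(self):
        cfg = SimulationConfig(n_genes=60, study_sizes=[(4, 4)], seed=5, array_scale=True)
        scaled, _ = simulate_collection(cfg)
        # scale factors multiply before noise, so the z-scores are not identical,
        # but the per-column standardization must still hold exactly
        z = integrate_studies(scaled).values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)
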