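import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from silicofem import meshing
from silicofem.atlas import AtlasTopology, assemble_vector, build_atlas, vector_length
from silicofem.sampler import (
    SamplingConfig,
    empirical_inverse_cdf,
    qc_mesh,
    sample_component_weights,
    synthesize_cohort,
)


class TestInverseCDF:
    def test_median_of_symmetric_sample(self):
        assert empirical_inverse_cdf(np.array([1, 2, 3, 4, 5]), 0.5) == 3.0

    def test_two_point_hand_interpolation(self):
        scores = np.array([0.0, 10.0])  # plotting positions 0.25, 0.75
        assert empirical_inverse_cdf(scores, 0.25) == 0.0
        assert empirical_inverse_cdf(scores, 0.5) == 5.0
        assert empirical_inverse_cdf(scores, 0.1) == 0.0  # clamp below p_1

    def test_endpoint_clamping(self, rng):
        scores = rng.normal(size=37)
        assert empirical_inverse_cdf(scores, 0.0) == scores.min()
        assert empirical_inverse_cdf(scores, 1.0) == scores.max()

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            empirical_inverse_cdf(np.array([]), 0.5)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30),
           st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_u(self, scores, u1, u2):
        s = np.asarray(scores)
        lo, hi = sorted([u1, u2])
        assert empirical_inverse_cdf(s, lo) <= empirical_inverse_cdf(s, hi)


@pytest.fixture(scope="module")
def toy_atlas():
    topo = AtlasTopology(5, 4, 6)
    rng = np.random.default_rng(17)
    X = np.empty((40, vector_length(topo)))
    for i in range(40):
        X[i] = assemble_vector(
            rng.normal(size=(5, 3)),
            rng.normal(size=(4, 3)),
            rng.lognormal(size=6),
            topo,
        )
    return build_atlas(X, topo)


class TestSampleWeights:
    def test_determinism(self, toy_atlas):
        cfg = SamplingConfig(n_synthetic=50, seed=4)
        assert np.array_equal(
            sample_component_weights(toy_atlas, cfg),
            sample_component_weights(toy_atlas, cfg),
        )

    def test_central_band_bounds(self, toy_atlas):
        cfg = SamplingConfig(n_synthetic=2000, u_range=(0.025, 0.975), seed=0)
        W = sample_component_weights(toy_atlas, cfg)
        for k in range(toy_atlas.n_components):
            s = toy_atlas.training_scores[:, k]
            lo = empirical_inverse_cdf(s, 0.025)
            hi = empirical_inverse_cdf(s, 0.975)
            assert W[:, k].min() >= lo and W[:, k].max() <= hi

    def test_support_bound_never_exceeded(self, toy_atlas):
        cfg = SamplingConfig(n_synthetic=2000, u_range=(0.0, 1.0), seed=1)
        W = sample_component_weights(toy_atlas, cfg)
        for k in range(toy_atlas.n_components):
            s = toy_atlas.training_scores[:, k]
            assert W[:, k].min() >= s.min() and W[:, k].max() <= s.max()

    def test_marginal_fidelity_ks(self, toy_atlas):
        cfg = SamplingConfig(n_synthetic=10_000, u_range=(0.0, 1.0), seed=2)
        W = sample_component_weights(toy_atlas, cfg)
        D = sps.ks_2samp(W[:, 0], toy_atlas.training_scores[:, 0]).statistic
        assert D < 0.03

    def test_component_independence(self, toy_atlas):
        cfg = SamplingConfig(n_synthetic=10_000, u_range=(0.0, 1.0), seed=3)
        W = sample_component_weights(toy_atlas, cfg)
        corr = np.corrcoef(W[:, :5], rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 0.05


class TestQC:
    def test_template_passes(self, coarse_template):
        res = qc_mesh(coarse_template.node_coords, coarse_template.tets)
        assert res.passed and res.status == "pass"

    def test_inverted_element_fails_with_reason(self, coarse_template):
        coords = coarse_template.node_coords.copy()
        tet0 = coarse_template.tets[0]
        # reflect one node through the opposite face centroid to invert
        coords[tet0[0]] = 2 * coords[tet0[1:]].mean(axis=0) - coords[tet0[0]]
        res = qc_mesh(coords, coarse_template.tets)
        assert not res.passed
        assert "non-positive volume" in res.reasons

    def test_needle_tet_fails_aspect_ratio(self):
        # hand-computed: edge 1 equilateral base, height 100 -> huge ratio
        coords = np.array(
            [
                [0.0, 0.0, 0.0],
                [1.0, 0.0, 0.0],
                [0.5, np.sqrt(3) / 2, 0.0],
                [0.5, np.sqrt(3) / 6, 100.0],
            ]
        )
        ratios = meshing.aspect_ratios(coords, np.array([[0, 1, 2, 3]]))
        assert ratios[0] > 20
        res = qc_mesh(coords, np.array([[0, 1, 2, 3]]), aspect_threshold=20)
        assert not res.passed and "aspect ratio" in res.reasons


class TestSynthesize:
    def test_training_column_reproduces_training_subject(self, small_cohort):
        subjects, _, tpl = small_cohort
        topo = AtlasTopology(tpl.n_nodes, 4, tpl.n_elements)
        X = np.array(
            [
                assemble_vector(
                    s.geometry.node_coords,
                    s.geometry.landmark_coords,
                    s.materials.young_modulus,
                    topo,
                )
                for s in subjects
            ]
        )
        atlas = build_atlas(X, topo)
        out, table = synthesize_cohort(
            atlas,
            atlas.training_scores[2][None, :],
            tpl,
            covariate_models=None,
            config=SamplingConfig(n_synthetic=1, seed=0),
        )
        ref = subjects[2].geometry.node_coords
        err = np.abs(out[0].geometry.node_coords - ref).max()
        assert err < 1e-6 * np.abs(ref).max()
        assert table["qc_status"].iloc[0] == "pass"

    def test_zero_scores_give_mean_subject(self, small_cohort):
        subjects, _, tpl = small_cohort
        topo = AtlasTopology(tpl.n_nodes, 4, tpl.n_elements)
        X = np.array(
            [
                assemble_vector(
                    s.geometry.node_coords,
                    s.geometry.landmark_coords,
                    s.materials.young_modulus,
                    topo,
                )
                for s in subjects
            ]
        )
        atlas = build_atlas(X, topo)
        out, table = synthesize_cohort(
            atlas,
            np.zeros((1, atlas.n_components)),
            tpl,
            covariate_models=None,
            config=SamplingConfig(n_synthetic=1, seed=0),
        )
        mean_coords = X.mean(axis=0)[: 3 * tpl.n_nodes].reshape(-1, 3)
        assert np.allclose(out[0].geometry.node_coords, mean_coords)
        assert table["qc_status"].iloc[0] == "pass"

    def test_sampled_rows_mostly_pass_qc(self, small_cohort):
        subjects, _, tpl = small_cohort
        topo = AtlasTopology(tpl.n_nodes, 4, tpl.n_elements)
        X = np.array(
            [
                assemble_vector(
                    s.geometry.node_coords,
                    s.geometry.landmark_coords,
                    s.materials.young_modulus,
                    topo,
                )
                for s in subjects
            ]
        )
        atlas = build_atlas(X, topo)
        cfg = SamplingConfig(n_synthetic=100, seed=5)
        W = sample_component_weights(atlas, cfg)
        _, table = synthesize_cohort(atlas, W, tpl, None, cfg)
        assert (table["qc_status"] == "pass").mean() >= 0.9
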