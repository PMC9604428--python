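"""Unit and property tests for the bilateral noise decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from fanoise import (
    BilateralMatrix,
    DegenerateSampleWarning,
    LOG2_TO_NATURAL_VARIANCE,
    center_genewise,
    convert_variance_scale,
    eigen2x2,
    individual_intrinsic_noise,
    log_transform_counts,
    pairwise_reference_free_intrinsic_noise,
    per_gene_noise_components,
    pooled_noise,
    SimulationConfig,
    simulate_bilateral_expression,
    simulate_qpcr_dataset,
)

from conftest import exact_cov_matrix


# ---------------------------------------------------------------------------
# per-gene partition
# ---------------------------------------------------------------------------


class TestPerGeneNoiseComponents:
    def test_perfect_symmetry_has_zero_fa(self, rng):
        u = rng.normal(0, 1, 50)
        u = (u - u.mean()) / u.std(ddof=1)  # Var exactly 1
        nc = per_gene_noise_components(u, u)
        assert nc.eta2_int == 0.0
        assert nc.eta2_ext == pytest.approx(4.0, rel=1e-12)
        assert nc.rho == pytest.approx(1.0)

    def test_mirror_pair_hand_arithmetic(self):
        with pytest.warns(DegenerateSampleWarning):
            nc = per_gene_noise_components([0.0, 2.0], [2.0, 0.0])
        assert nc.eta2_ext == 0.0
        assert nc.eta2_int == pytest.approx(8.0)

    def test_closed_form_recovery_monte_carlo(self, rng):
        # shared variance 0.03 + side variance 0.01 -> eta^2 = 0.04, rho = 0.75
        n = 10_000
        s = rng.normal(0, np.sqrt(0.03), n)
        u = s + rng.normal(0, 0.1, n)
        v = s + rng.normal(0, 0.1, n)
        nc = per_gene_noise_components(u, v)
        assert nc.eta2_ext == pytest.approx(0.14, rel=0.05)
        assert nc.eta2_int == pytest.approx(0.02, rel=0.05)
        assert nc.rho == pytest.approx(0.75, abs=0.02)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            per_gene_noise_components([1.0, 2.0, 3.0], [1.0, 2.0])

    def test_zero_variance_flags_undefined_rho(self):
        with pytest.warns(DegenerateSampleWarning):
            nc = per_gene_noise_components([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert np.isnan(nc.rho)
        assert nc.eta2_int == 0.0

    @given(
        u=hnp.arrays(np.float64, st.integers(3, 40),
                     elements=st.floats(-50, 50, allow_nan=False)),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_identity_property(self, u, data):
        """(eta2_ext + eta2_int)/4 equals the mean side variance exactly."""
        v = data.draw(hnp.arrays(np.float64, u.shape[0],
                                 elements=st.floats(-50, 50, allow_nan=False)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nc = per_gene_noise_components(u, v)
        assert 0.25 * (nc.eta2_ext + nc.eta2_int) == pytest.approx(
            nc.sigma2_w, abs=1e-10, rel=1e-10
        )


# ---------------------------------------------------------------------------
# eigen decomposition
# ---------------------------------------------------------------------------


class TestEigen2x2:
    def test_closed_form_eigenvalues(self):
        X = exact_cov_matrix([[2.0, 1.0], [1.0, 2.0]])
        res = eigen2x2(X, centered=True)
        assert res.lambda_ext == pytest.approx(3.0, abs=1e-12)
        assert res.lambda_int == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(np.abs(res.evec_ext), 1 / np.sqrt(2))
        assert not res.assignment_conflict

    def test_identical_sides_give_zero_intrinsic(self, rng):
        u = rng.normal(0, 1, 20)
        res = eigen2x2(np.column_stack([u, u]), centered=True)
        assert res.lambda_int == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_asymmetry_cancelled(self, rng):
        # v = 2u is rank one: the second eigenvalue is null even though the
        # naive difference variance Var(u - v) = Var(u) is large
        u = rng.normal(0, 1, 10_000)
        res = eigen2x2(np.column_stack([u, 2 * u]), centered=True)
        assert res.lambda_int == pytest.approx(0.0, abs=1e-10)
        assert np.var(u - 2 * u, ddof=1) > 0.9

    def test_orientation_based_assignment_with_conflict(self):
        # intrinsic (anti-diagonal) variance dominating extrinsic: magnitude
        # ordering would mislabel, orientation must win and flag the conflict
        X = exact_cov_matrix([[2.0, -1.5], [-1.5, 2.0]])
        res = eigen2x2(X, centered=True)
        assert res.lambda_ext == pytest.approx(0.5, abs=1e-12)
        assert res.lambda_int == pytest.approx(3.5, abs=1e-12)
        assert res.assignment_conflict

    def test_rank_zero_warns(self):
        with pytest.warns(DegenerateSampleWarning, match="rank-0"):
            eigen2x2(np.ones((5, 2)), centered=True)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            eigen2x2(np.ones((2, 2)))

    def test_noncentered_flags_extrinsic_unusable(self, rng):
        X = rng.normal(10, 2, (8, 2))
        res = eigen2x2(X, centered=False)
        assert not res.lambda_ext_valid

    @given(st.integers(0, 1000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_trace_conservation_property(self, seed):
        """lambda_ext + lambda_int equals Var(u) + Var(v) to machine precision."""
        r = np.random.default_rng(seed)
        X = r.normal(r.normal(0, 5), np.exp(r.normal(0, 1)), (r.integers(3, 50), 2))
        res = eigen2x2(X, centered=True)
        trace = np.var(X[:, 0], ddof=1) + np.var(X[:, 1], ddof=1)
        assert res.lambda_ext + res.lambda_int == pytest.approx(trace, rel=1e-10, abs=1e-12)
        # score variances reproduce the eigenvalues with the same divisor
        assert np.var(res.scores_pc1, ddof=1) == pytest.approx(res.lambda_ext, abs=1e-10)
        assert np.var(res.scores_pc2, ddof=1) == pytest.approx(res.lambda_int, abs=1e-10)
        assert abs(res.evec_ext @ res.evec_int) < 1e-10


# ---------------------------------------------------------------------------
# gene-wise centering
# ---------------------------------------------------------------------------


class TestCenterGenewise:
    def test_pooled_means_zero(self, small_matrix):
        c = center_genewise(small_matrix)
        pooled_mean = (c.left.sum(axis=1) + c.right.sum(axis=1)) / (2 * c.n_individuals)
        assert np.allclose(pooled_mean, 0.0, atol=1e-12)

    def test_hand_arithmetic(self):
        M = BilateralMatrix(gene_ids=["g"], left=[[1.0, 3.0]], right=[[2.0, 2.0]])
        c = center_genewise(M)
        assert np.allclose(c.left, [[-1.0, 1.0]])
        assert np.allclose(c.right, [[0.0, 0.0]])
        assert c.gene_means[0] == pytest.approx(2.0)

    def test_differences_invariant(self, small_matrix):
        c = center_genewise(small_matrix)
        assert np.allclose(
            small_matrix.left - small_matrix.right, c.left - c.right, atol=1e-12
        )


# ---------------------------------------------------------------------------
# pooled estimation
# ---------------------------------------------------------------------------


class TestPooledNoise:
    def test_symmetric_input_zero_intrinsic(self, rng):
        u = rng.normal(10, 2, (6, 5))
        M = BilateralMatrix(gene_ids=list("abcdef"), left=u, right=u.copy())
        comps, eig = pooled_noise(M)
        assert comps.eta2_int == pytest.approx(0.0, abs=1e-12)

    def test_per_side_constant_invariance(self, small_matrix):
        base, _ = pooled_noise(small_matrix)
        shifted = BilateralMatrix(
            gene_ids=small_matrix.gene_ids,
            left=small_matrix.left + 3.7,
            right=small_matrix.right - 1.2,
            log_base=small_matrix.log_base,
        )
        moved, _ = pooled_noise(shifted)
        assert moved.eta2_ext == pytest.approx(base.eta2_ext, rel=1e-10)
        assert moved.eta2_int == pytest.approx(base.eta2_int, rel=1e-10)

    def test_group_stratum_selection(self, small_matrix):
        comps_a, _ = pooled_noise(small_matrix, stratum="A")
        comps_all, _ = pooled_noise(small_matrix)
        assert comps_a.n_pairs == small_matrix.n_genes * 3
        assert comps_all.n_pairs == small_matrix.n_genes * 6

    @pytest.mark.filterwarnings("ignore::fanoise.UnequalSideVarianceWarning")
    def test_parameter_recovery_13_genes(self):
        """Pooled intrinsic noise tracks the generative truth at cohort scale."""
        ratios = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, n_individuals_per_group=(12,),
                                   group_names=("only",), group_scale_multipliers=(1.0,))
            M, truth = simulate_bilateral_expression(cfg)
            comps, _ = pooled_noise(M)
            ratios.append(comps.eta2_int / truth["eta2_int_pooled_per_group"]["only"])
        assert abs(np.median(ratios) - 1.0) < 0.15

    def test_too_small_stratum_rejected(self):
        M = BilateralMatrix(gene_ids=["g"], left=[[1.0, 2.0]], right=[[1.5, 2.5]])
        with pytest.raises(ValueError, match="at least 3"):
            pooled_noise(M)


# ---------------------------------------------------------------------------
# per-individual estimates
# ---------------------------------------------------------------------------


class TestIndividualIntrinsicNoise:
    def test_symmetric_individual_is_zero(self, rng):
        u = rng.normal(10, 3, 8)
        M = BilateralMatrix(gene_ids=[f"g{i}" for i in range(8)],
                            left=u[:, None], right=u[:, None].copy())
        assert individual_intrinsic_noise(M, 0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_difference_variance_without_asymmetry(self, rng):
        # additive per-gene offsets of zero mean: 2*lambda_int tracks Var(u-v)
        u = rng.normal(10, 3, 200)
        d = rng.normal(0, 0.3, 200)
        d -= d.mean()
        M = BilateralMatrix(gene_ids=[f"g{i}" for i in range(200)],
                            left=u[:, None], right=(u + d)[:, None])
        eta = individual_intrinsic_noise(M, 0)
        assert eta**2 == pytest.approx(np.var(d, ddof=1), rel=0.05)

    def test_rank_correlates_with_generative_noise(self):
        """Per-individual estimates rank individuals by their true side noise."""
        from scipy.stats import spearmanr

        rs = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_genes=100, n_individuals_per_group=(50,),
                group_names=("c",), group_scale_multipliers=(1.0,),
                individual_dispersion=0.3,
            )
            M, truth = simulate_bilateral_expression(cfg)
            est = [individual_intrinsic_noise(M, j) for j in range(50)]
            rs.append(spearmanr(est, truth["side_noise_sd_per_individual"])[0])
        assert np.median(rs) > 0.8

    def test_too_few_genes_rejected(self):
        M = BilateralMatrix(gene_ids=["a", "b"], left=[[1.0], [2.0]], right=[[1.0], [2.0]])
        with pytest.raises(ValueError, match="at least 3 genes"):
            individual_intrinsic_noise(M, 0)


class TestPairwiseReferenceFree:
    def test_shared_shift_gives_zero(self, rng):
        ct = rng.normal(25, 3, 10)
        assert pairwise_reference_free_intrinsic_noise(ct, ct + 1.3) == pytest.approx(0.0, abs=1e-9)

    def test_identical_sides_give_zero(self, rng):
        ct = rng.normal(25, 3, 10)
        assert pairwise_reference_free_intrinsic_noise(ct, ct) == pytest.approx(0.0, abs=1e-9)

    def test_correlates_with_reference_normalized_estimate(self):
        """Both per-individual estimators rank a synthetic qPCR cohort alike."""
        cfg = SimulationConfig(
            seed=3, n_individuals_per_group=(50,), group_names=("c",),
            group_scale_multipliers=(1.0,), individual_dispersion=0.3,
        )
        table, _ = simulate_qpcr_dataset(cfg)
        avg = (table.groupby(["gene_id", "individual_id", "side"], as_index=False)["ct"].mean())
        ref = avg[avg.gene_id == "18S"].set_index(["individual_id", "side"])["ct"]
        panel = avg[avg.gene_id != "18S"].copy()
        inds = sorted(panel.individual_id.unique())
        eta_ref, eta_pair = [], []
        for ind in inds:
            sub = panel[panel.individual_id == ind].pivot(
                index="gene_id", columns="side", values="ct")
            dct = sub.sub([ref[(ind, "L")], ref[(ind, "R")]], axis=1)
            M = BilateralMatrix(gene_ids=list(sub.index),
                                left=dct["L"].to_numpy()[:, None],
                                right=dct["R"].to_numpy()[:, None], log_base="2")
            eta_ref.append(individual_intrinsic_noise(M, 0))
            eta_pair.append(pairwise_reference_free_intrinsic_noise(
                sub["L"].to_numpy(), sub["R"].to_numpy()))
        r = np.corrcoef(eta_ref, eta_pair)[0, 1]
        assert r >= 0.9

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pairwise_reference_free_intrinsic_noise([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# input transformation and scale conversion
# ---------------------------------------------------------------------------


class TestLogTransformCounts:
    def test_zero_containing_gene_dropped_and_counted(self):
        L = np.array([[1.0, 2.0], [3.0, 0.0]])
        R = np.array([[1.5, 2.5], [3.5, 4.0]])
        M, report = log_transform_counts(L, R, ["g1", "g2"])
        assert M.gene_ids == ["g1"]
        assert report.n_dropped == 1
        assert np.allclose(M.left, np.log(L[:1]))

    def test_all_positive_matrix_log_transformed(self):
        L = np.array([[1.0, np.e], [2.0, 4.0]])
        M, report = log_transform_counts(L, L.copy(), ["a", "b"])
        assert M.left.shape == (2, 2)
        assert report.n_dropped == 0
        assert M.log_base == "natural"
        assert M.left[0, 1] == pytest.approx(1.0)

    def test_ct_passthrough(self):
        M, _ = log_transform_counts(np.array([[15.0]]), np.array([[15.0]]),
                                    ["g"], mode="ct-passthrough")
        assert M.log_base == "2"
        assert M.left[0, 0] == 15.0

    def test_all_filtered_rejected(self):
        with pytest.raises(ValueError, match="all genes filtered"):
            log_transform_counts(np.zeros((2, 2)), np.ones((2, 2)), ["a", "b"])


def test_log_base_conversion_round_trip():
    v = 0.59**2
    nat = convert_variance_scale(v, "2", "natural")
    assert nat == pytest.approx(v * LOG2_TO_NATURAL_VARIANCE)
    assert convert_variance_scale(nat, "natural", "2") == pytest.approx(v)
    assert LOG2_TO_NATURAL_VARIANCE == pytest.approx(2.081, rel=1e-3)


def test_side_swap_leaves_variance_outputs_unchanged(small_matrix):
    """Sides are exchangeable labels: swapping L and R changes nothing."""
    swapped = BilateralMatrix(
        gene_ids=small_matrix.gene_ids,
        left=small_matrix.right.copy(),
        right=small_matrix.left.copy(),
        log_base=small_matrix.log_base,
    )
    a, ea = pooled_noise(small_matrix)
    b, eb = pooled_noise(swapped)
    assert a.eta2_ext == pytest.approx(b.eta2_ext, rel=1e-10)
    assert a.eta2_int == pytest.approx(b.eta2_int, rel=1e-10)
    for j in range(small_matrix.n_individuals):
        assert individual_intrinsic_noise(small_matrix, j) == pytest.approx(
            individual_intrinsic_noise(swapped, j), rel=1e-10
        )
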