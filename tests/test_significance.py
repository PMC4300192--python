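"""Population z-normalization, p-values, and Benjamini-Hochberg FDR."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from fastgcn.correlation import PackedTriangular
from fastgcn.significance import (
    compute_edge_statistics,
    fdr_qvalues,
    fisher_z,
    normalize_coefficients,
    z_to_p,
)
from helpers import bh_step_up_oracle


def packed(values):
    """Coefficient population for the normalization tests; plain arrays
    are accepted alongside packed storage."""
    return np.asarray(values, dtype=float)


class TestNormalizeCoefficients:
    def test_two_coefficient_hand_computation(self):
        z, rho_bar, s = normalize_coefficients(packed([0.9, 0.1]))
        assert rho_bar == pytest.approx(0.5)
        assert s == pytest.approx(0.565685, abs=1e-6)  # sqrt(2*0.4^2/1)
        np.testing.assert_allclose(z, [0.707107, -0.707107], atol=1e-6)

    def test_standardization_identities(self):
        rng = np.random.default_rng(5)
        for t in (2, 10, 4950):
            z, _, _ = normalize_coefficients(packed(rng.uniform(-1, 1, size=t)))
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_population_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            normalize_coefficients(packed([0.3, 0.3, 0.3]))

    def test_single_coefficient_is_an_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            normalize_coefficients(PackedTriangular(k=2, values=np.array([0.5])))


class TestZToP:
    def test_reference_points(self):
        assert z_to_p(np.array([0.0]))[0] == pytest.approx(1.0)
        assert z_to_p(np.array([1.959964]))[0] == pytest.approx(0.05, abs=1e-6)

    def test_two_sided_symmetry(self):
        z = np.linspace(-4, 4, 33)
        np.testing.assert_array_equal(z_to_p(z), z_to_p(-z))

    def test_right_tail(self):
        assert z_to_p(np.array([0.0]), tail="right")[0] == pytest.approx(0.5)
        p = z_to_p(np.array([2.0, -2.0]), tail="right")
        assert p[0] < 0.05 < p[1]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            z_to_p(np.array([np.nan]))


class TestFisherZ:
    def test_matches_closed_form(self):
        rho = np.array([0.5, -0.3, 0.0])
        z = fisher_z(rho, n_samples=28)
        np.testing.assert_allclose(z, np.arctanh(rho) * 5.0, atol=1e-12)

    def test_perfect_correlation_stays_finite(self):
        assert np.isfinite(fisher_z(packed([1.0, -1.0, 0.2]), n_samples=10)).all()


class TestFdrQvalues:
    def test_single_test_q_equals_p(self):
        assert fdr_qvalues(np.array([0.037]))[0] == 0.037

    def test_stepup_examples(self):
        np.testing.assert_allclose(
            fdr_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4, atol=1e-15
        )
        np.testing.assert_allclose(
            fdr_qvalues(np.array([0.05, 0.05])), [0.05, 0.05], atol=1e-15
        )

    def test_matches_loop_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for t in (1, 2, 37, 1000, 100_000):
            # beta-skewed mix resembling a signal + null population
            p = np.concatenate(
                [rng.beta(0.2, 5.0, size=t // 3), rng.uniform(size=t - t // 3)]
            )
            q = fdr_qvalues(p)
            np.testing.assert_array_equal(q, bh_step_up_oracle(p))

    def test_cross_check_against_statsmodels(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=5000)
        np.testing.assert_allclose(
            fdr_qvalues(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(size=500)
        q = fdr_qvalues(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_ties_share_a_q_value(self):
        q = fdr_qvalues(np.array([0.2, 0.01, 0.2, 0.6]))
        assert q[0] == q[2]

    def test_invalid_p_rejected(self):
        for bad in ([-0.1], [1.1], [np.nan]):
            with pytest.raises(ValueError):
                fdr_qvalues(np.array(bad))


class TestComputeEdgeStatistics:
    def test_full_pass_is_consistent(self):
        rng = np.random.default_rng(31)
        rho = PackedTriangular(k=10, values=rng.uniform(-0.9, 0.9, size=45))
        stats = compute_edge_statistics(rho)
        assert stats.k == 10
        np.testing.assert_array_equal(stats.q, fdr_qvalues(stats.p))
        np.testing.assert_array_equal(stats.p, z_to_p(stats.z))

    def test_fisher_method_requires_sample_count(self):
        rho = PackedTriangular(k=10, values=np.linspace(-0.5, 0.5, 45))
        with pytest.raises(ValueError, match="n_samples"):
            compute_edge_statistics(rho, method="fisher")
        stats = compute_edge_statistics(rho, method="fisher", n_samples=50)
        np.testing.assert_allclose(stats.z, fisher_z(rho, 50), atol=1e-12)
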