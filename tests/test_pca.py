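import numpy as np
import pandas as pd
import pytest

from molsim import (
    DescriptorTable,
    PCAError,
    RetentionRule,
    fit_pca,
    k_from_variance,
    reduce_descriptors,
    scale,
    scatter_scores,
    top_loadings,
)


def scaled_from_matrix(values, names=None):
    n, d = values.shape
    names = names or [f"x{j}" for j in range(d)]
    df = pd.DataFrame(values, index=[f"M{i}" for i in range(n)], columns=names)
    return scale(DescriptorTable(df, pd.Series("OTHER", index=df.columns, dtype=object)))


def factor_table(rng, n=40, n_factors=5, per_factor=4, noise=0.05):
    """Descriptors built from a few latent factors: correlation structure of
    known rank, so the leading PCs carry almost all the variance."""
    factors = rng.normal(size=(n, n_factors))
    cols = []
    for f in range(n_factors):
        for _ in range(per_factor):
            cols.append(factors[:, f] * rng.uniform(0.8, 1.2) + noise * rng.normal(size=n))
    return scaled_from_matrix(np.column_stack(cols))


class TestFitPCA:
    def test_rank2_data_has_two_nonzero_ratios(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=20)
        values = np.column_stack([u, v, u + v, u - v])
        pca = fit_pca(scaled_from_matrix(values))
        assert pca.explained_variance_ratio[:2].sum() == pytest.approx(1.0, abs=1e-9)
        assert pca.explained_variance_ratio[2:].sum() == pytest.approx(0.0, abs=1e-9)

    def test_reconstruction_round_trip(self, rng):
        scaled = scaled_from_matrix(rng.normal(size=(15, 6)))
        pca = fit_pca(scaled)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T + scaled.values.mean(axis=0)
        np.testing.assert_allclose(recon, scaled.values, atol=1e-9)

    def test_isotropic_gaussian_ratios_flat(self):
        rng = np.random.default_rng(0)
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(10_000, 4))))
        np.testing.assert_allclose(pca.explained_variance_ratio, 0.25, atol=0.02)

    def test_loadings_orthonormal_and_ratio_sums_to_one(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(12, 5))))
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sign_convention_largest_entry_positive(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(12, 5))))
        L = pca.loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0

    def test_matches_correlation_matrix_eigendecomposition(self, rng):
        scaled = scaled_from_matrix(rng.normal(size=(10, 4)))
        pca = fit_pca(scaled)
        corr = np.corrcoef(scaled.values, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        ratios = eigvals / eigvals.sum()
        np.testing.assert_allclose(
            pca.explained_variance_ratio, ratios[: pca.component_count], atol=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]},
                          index=["A", "B", "C"])
        from molsim.descriptors import ScaledTable
        fake = ScaledTable(df, pd.Series({"a": "OTHER", "b": "OTHER"}),
                           mu=df.mean(), sigma=df.std(ddof=0))
        with pytest.raises(PCAError, match="b"):
            fit_pca(fake)


class TestKFromVariance:
    def test_rank2_data_needs_two_components(self, rng):
        u, v = rng.normal(size=(2, 20))
        pca = fit_pca(scaled_from_matrix(np.column_stack([u, v, u + v, 2 * u - v])))
        assert k_from_variance(pca, 0.99) == 2

    def test_threshold_one_needs_full_rank(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(20, 4))))
        assert k_from_variance(pca, 1.0) == pca.component_count

    def test_five_factor_structure_gives_five(self, rng):
        pca = fit_pca(factor_table(rng))
        assert k_from_variance(pca, 0.95) == 5

    def test_non_decreasing_in_threshold(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(15, 8))))
        ks = [k_from_variance(pca, t) for t in (0.2, 0.5, 0.8, 0.95, 1.0)]
        assert ks == sorted(ks)

    def test_bad_threshold_rejected(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(6, 3))))
        with pytest.raises(PCAError):
            k_from_variance(pca, 0.0)


class TestTopLoadings:
    def test_lone_independent_descriptor_dominates_a_component(self, rng):
        factors = rng.normal(size=(60, 1))
        correlated = factors @ rng.uniform(0.9, 1.1, size=(1, 4)) \
            + 0.05 * rng.normal(size=(60, 4))
        lone = rng.normal(size=(60, 1))
        scaled = scaled_from_matrix(
            np.column_stack([correlated, lone]),
            names=["c1", "c2", "c3", "c4", "lone"])
        tops = top_loadings(fit_pca(scaled), 2)
        winners = {name for names, _ in tops for name in names}
        assert "lone" in winners
        lone_mag = next(mag for names, mag in tops if "lone" in names)
        assert lone_mag == pytest.approx(1.0, abs=0.01)

    def test_duplicated_descriptor_reported_jointly(self, rng):
        base = rng.normal(size=30)
        other = rng.normal(size=(30, 2))
        scaled = scaled_from_matrix(
            np.column_stack([base, base, other]), names=["twinA", "twinB", "o1", "o2"])
        tops = top_loadings(fit_pca(scaled), 1)
        assert set(tops[0][0]) >= {"twinA", "twinB"}

    def test_agreement_with_brute_force_max(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(15, 6))))
        tops = top_loadings(pca, 4, tie_tol=0.0)
        L = np.abs(pca.loadings.to_numpy())
        for j, (names, mag) in enumerate(tops):
            assert mag == pytest.approx(L[:, j].max())
            assert pca.loadings.index[L[:, j].argmax()] in names


class TestReduceDescriptors:
    def test_zero_cutoff_retains_everything(self, rng):
        scaled = scaled_from_matrix(rng.normal(size=(12, 5)))
        pca = fit_pca(scaled)
        retained, sub = reduce_descriptors(pca, RetentionRule(n_components=3, cutoff=0.0))
        assert retained == scaled.descriptor_names
        assert sub.n_descriptors == 5

    def test_impossible_cutoff_errors(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(12, 5))))
        with pytest.raises(PCAError, match="cutoff"):
            reduce_descriptors(pca, RetentionRule(n_components=3, cutoff=1.01))

    def test_retained_subtable_holds_raw_values(self, rng):
        values = rng.normal(size=(12, 5)) * 10 + 3
        scaled = scaled_from_matrix(values)
        pca = fit_pca(scaled)
        retained, sub = reduce_descriptors(pca, RetentionRule(n_components=3, cutoff=0.0))
        np.testing.assert_allclose(sub.values, values, atol=1e-9)

    def test_planted_high_loading_set_is_retained(self, rng):
        """A block of strongly correlated descriptors plus diffuse noise
        descriptors: the rule keeps the block, drops the diffuse ones."""
        factor = rng.normal(size=(80, 1))
        strong = factor @ np.ones((1, 3)) + 0.05 * rng.normal(size=(80, 3))
        # many exchangeable noise descriptors share their loading mass thinly
        noise = rng.normal(size=(80, 12))
        scaled = scaled_from_matrix(
            np.column_stack([strong, noise]),
            names=[f"strong{j}" for j in range(3)] + [f"noise{j}" for j in range(12)])
        pca = fit_pca(scaled)
        retained, _ = reduce_descriptors(pca, RetentionRule(n_components=1, cutoff=0.45))
        assert set(retained) == {"strong0", "strong1", "strong2"}


class TestScatterScores:
    def test_shape_and_label_echo(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(30, 8))))
        labels = rng.integers(0, 5, size=30)
        out = scatter_scores(pca, 3, labels)
        assert out.shape == (30, 4)
        np.testing.assert_array_equal(out["cluster"].to_numpy(), labels)

    def test_scores_stable_under_molecule_reordering(self, rng):
        values = rng.normal(size=(20, 6))
        perm = rng.permutation(20)
        s1 = fit_pca(scaled_from_matrix(values)).scores.to_numpy()
        s2 = fit_pca(scaled_from_matrix(values[perm])).scores.to_numpy()
        # same molecules end up with the same scores up to component sign
        np.testing.assert_allclose(np.abs(s2), np.abs(s1[perm]), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        pca = fit_pca(scaled_from_matrix(rng.normal(size=(6, 3))))
        with pytest.raises(PCAError):
            scatter_scores(pca, 10)
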