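"""LOWESS mean-decoupling, noise tests, medoids, and phenotypic potential."""

import numpy as np
import pytest
from scipy import stats

import phenonoise as pn
from conftest import make_noise_table


class TestLowessDecouple:
    def test_constant_cv_gives_zero_residuals(self, rng):
        m = np.sort(rng.uniform(1, 10, 60))
        r = pn.lowess_decouple(m, np.full(60, 0.3))
        assert np.abs(r).max() < 1e-8

    def test_linear_trend_reproduced_exactly(self, rng):
        m = np.sort(rng.uniform(1, 10, 120))
        cv = 0.6 - 0.04 * m
        r = pn.lowess_decouple(m, cv)
        assert np.abs(r).max() < 1e-6 * np.ptp(cv)

    def test_planted_outlier_recovered(self, rng):
        m = np.sort(rng.uniform(1, 10, 150))
        cv = 0.5 - 0.03 * m + 0.002 * m**2
        delta = 0.2
        cv2 = cv.copy()
        cv2[70] += delta
        r = pn.lowess_decouple(m, cv2)
        assert r[70] == pytest.approx(delta, rel=0.1)
        assert np.abs(np.delete(r, 70)).max() < 0.1 * delta

    def test_degenerate_means_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pn.lowess_decouple(np.ones(50), np.linspace(0, 1, 50))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            pn.lowess_decouple(np.arange(5.0), np.arange(5.0))


class TestBuildNoiseTable:
    def test_one_noise_trait_per_pair_and_decoupled(self, small_traits, small_ds):
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        assert nt.values.shape[1] == len(small_ds.catalogue.pairs())
        # decoupling: residuals uncorrelated with means, per trait
        for cv_id in nt.values.columns[:10]:
            m = small_traits.values[nt.mean_param[cv_id]]
            rho = stats.spearmanr(nt.values[cv_id], m).statistic
            assert abs(rho) < 0.25  # loose at n = 60; tight check in acceptance

    def test_noise_strain_test_recovers_planted(self, small_traits, small_ds):
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        kw = pn.noise_strain_test(nt)
        found = set(kw.loc[kw["significant_0.05"], "param_id"])
        planted = set(small_ds.truth.noise_traits)
        assert len(found & planted) / len(planted) >= 0.5

    def test_unequal_groups_rejected(self, small_traits, small_ds):
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        short = pn.noise.NoiseTable(nt.values.iloc[1:], nt.span, nt.iters)
        with pytest.raises(ValueError, match="equal size"):
            pn.noise_strain_test(short)


class TestSelectMedoids:
    def test_k_equals_traits_returns_all(self, rng):
        nt = make_noise_table(rng.normal(size=(20, 6)))
        assert pn.select_medoids(nt, k=6) == list(nt.values.columns)

    def test_k_one_matches_exhaustive_search(self, rng):
        vals = rng.normal(size=(20, 5))
        nt = make_noise_table(vals)
        got = pn.select_medoids(nt, k=1)
        R = np.abs(stats.spearmanr(vals).statistic)
        D = 1 - R
        np.fill_diagonal(D, 0)
        best = int(np.argmin(D.sum(axis=1)))
        assert got == [nt.values.columns[best]]

    def test_duplicate_trait_never_co_selected(self, rng):
        vals = rng.normal(size=(20, 5))
        vals[:, 4] = vals[:, 3]  # exact duplicate, dissimilarity 0
        nt = make_noise_table(vals)
        med = pn.select_medoids(nt, k=4)
        names = list(nt.values.columns)
        assert not {names[3], names[4]} <= set(med)

    def test_bad_k_rejected(self, rng):
        nt = make_noise_table(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError):
            pn.select_medoids(nt, k=0)


class TestPhenotypicPotential:
    def test_all_equal_gives_that_value(self):
        nt = make_noise_table(np.full((10, 70), 0.25), n_reps=5)
        res = pn.phenotypic_potential(nt, list(nt.values.columns))
        assert res.top_count == 35
        assert np.allclose(res.per_sample, 0.25)

    def test_values_1_to_70_give_53(self):
        vals = np.tile(np.arange(1.0, 71.0), (10, 1))
        nt = make_noise_table(vals, n_reps=5)
        res = pn.phenotypic_potential(nt, list(nt.values.columns))
        assert np.allclose(res.per_sample, 53.0)  # mean of 36..70

    def test_translation_equivariance(self, rng):
        vals = rng.normal(size=(20, 30))
        nt = make_noise_table(vals)
        base = pn.phenotypic_potential(nt, list(nt.values.columns))
        shifted = pn.phenotypic_potential(
            make_noise_table(vals + 1.7), list(nt.values.columns)
        )
        assert np.allclose(shifted.per_sample, base.per_sample + 1.7)

    def test_invariant_to_replicate_order(self, rng):
        vals = rng.normal(size=(20, 30))
        nt = make_noise_table(vals)
        res = pn.phenotypic_potential(nt, list(nt.values.columns))
        perm = np.concatenate([np.arange(i, 20, 5) for i in range(5)])
        shuffled = pn.noise.NoiseTable(nt.values.iloc[perm], 0.4, 3)
        res2 = pn.phenotypic_potential(shuffled, list(nt.values.columns))
        assert res2.kw_p == pytest.approx(res.kw_p)
        assert sorted(res2.per_sample) == pytest.approx(sorted(res.per_sample))

    def test_missing_medoid_rejected(self, rng):
        nt = make_noise_table(rng.normal(size=(20, 5)))
        with pytest.raises(ValueError, match="absent"):
            pn.phenotypic_potential(nt, ["nope_A", "CCV0_A"])

    def test_monotone_in_noise_values(self, rng):
        vals = rng.normal(size=(20, 30))
        nt = make_noise_table(vals)
        base = pn.phenotypic_potential(nt, list(nt.values.columns))
        bumped = vals.copy()
        bumped[3, 7] += 2.0
        res = pn.phenotypic_potential(make_noise_table(bumped), list(nt.values.columns))
        assert (res.per_sample >= base.per_sample - 1e-12).all()


class TestNoisePcaLoadings:
    def test_pvalues_match_pearson_oracle(self, small_traits, small_ds):
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        traits = list(nt.values.columns[:12])
        lt = pn.noise_pca_loadings(nt, traits, n_retained=3)
        rs = pn.ranksum_transform(nt.as_trait_table().subset_params(traits))
        for trait in traits[:5]:
            for npc in lt.T.columns:
                r_ref, p_ref = stats.pearsonr(
                    rs.values[trait], lt.pca.scores[npc]
                )
                assert lt.loading_R.loc[trait, npc] == pytest.approx(r_ref)
                assert lt.pvalues.loc[trait, npc] == pytest.approx(p_ref, abs=1e-12)

    def test_family_size_is_product(self, rng):
        nt = make_noise_table(rng.normal(size=(185, 76)), n_reps=5)
        lt = pn.noise_pca_loadings(nt, list(nt.values.columns), n_retained=7)
        assert lt.family_size == 532

    def test_perfect_loading_is_boundary_significant(self):
        """A trait identical to another gives |R| = 1 against the shared nPC."""
        base = np.linspace(-1, 1, 40)
        vals = np.column_stack([base, base, -base, np.linspace(0.5, -0.5, 40) ** 3])
        nt = make_noise_table(vals, n_reps=5)
        lt = pn.noise_pca_loadings(nt, list(nt.values.columns), n_retained=1)
        assert np.isinf(lt.T.iloc[0, 0]) or abs(lt.T.iloc[0, 0]) > 50
        assert lt.significant.iloc[0, 0]

    def test_empty_traits_rejected(self, small_traits, small_ds):
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        with pytest.raises(ValueError, match="nonempty"):
            pn.noise_pca_loadings(nt, [])


class TestGlobalNoiseRecovery:
    def test_global_noisy_strains_have_top_potentials(self):
        """Strains with a 2-fold global CV multiplier rank top in potential."""
        cfg = pn.SimConfig(
            n_strains=12, n_reps=5, n_cells=60, n_base_traits=24, n_other=7,
            n_sites=100, n_subpopulations=3, global_noise_fold=2.0, seed=21,
        )
        ds = pn.generate(cfg)
        traits = pn.summarize_cells(ds.cells, ds.catalogue)
        nt = pn.build_noise_table(traits, ds.catalogue)
        med = pn.select_medoids(nt, k=12)
        pot = pn.phenotypic_potential(nt, med)
        ranking = pot.per_strain.mean(axis=1).sort_values(ascending=False)
        assert set(ranking.index[:3]) == set(ds.truth.global_noisy_strains)

    def test_first_npc_separates_global_from_specific(self, small_traits, small_ds):
        """With a planted global effect, the leading noise PC orders strains
        by their global noise status."""
        nt = pn.build_noise_table(small_traits, small_ds.catalogue)
        kw = pn.noise_strain_test(nt)
        sig = list(kw.loc[kw["significant_0.05"], "param_id"])
        lt = pn.noise_pca_loadings(nt, sig, n_retained=2)
        scores = lt.pca.scores.iloc[:, 0]
        noisy = [s in small_ds.truth.global_noisy_strains for s in scores.index]
        _, p = stats.mannwhitneyu(scores[noisy], scores[np.logical_not(noisy)])
        assert p < 0.05
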