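"""Rank-sum transform, PCA, angle distances, AU clustering, and LDA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenonoise as pn
from phenonoise.io import TraitTable
from phenonoise.morphospace import (
    RankSumMatrix,
    _angles_deg,
    fit_au,
    null_ranksum_matrix,
)


def _table(values: np.ndarray, n_reps: int = 2) -> TraitTable:
    n = values.shape[0]
    ids = [f"S{i // n_reps + 1}.{i % n_reps + 1}" for i in range(n)]
    cols = [f"t{j}" for j in range(values.shape[1])]
    return TraitTable(pd.DataFrame(values, index=pd.Index(ids, name="sample"), columns=cols))


class TestRankSum:
    def test_two_strain_toy(self):
        table = _table(np.array([[10.0], [20.0], [30.0], [40.0]]))
        rs = pn.ranksum_transform(table)
        assert rs.values["t0"].tolist() == [3.0, 7.0]

    def test_smallest_five_values_give_15(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        col = small_traits.values.iloc[:, 0]
        lowest_strain = col.nsmallest(5).index[0].rpartition(".")[0]
        doctored = small_traits.values.copy()
        hit = [s.startswith(lowest_strain + ".") for s in doctored.index]
        doctored.loc[hit, doctored.columns[0]] = -np.inf
        rs2 = pn.ranksum_transform(pn.TraitTable(doctored))
        assert rs2.values.loc[lowest_strain, doctored.columns[0]] == 15.0

    def test_columns_sum_to_n_n_plus_1_over_2(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        n = len(small_traits.sample_ids)
        assert np.allclose(rs.values.sum(axis=0), n * (n + 1) / 2)

    def test_invariant_under_monotone_transform(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        mono = pn.TraitTable(np.log1p(small_traits.values * 3.0))
        rs2 = pn.ranksum_transform(mono)
        pd.testing.assert_frame_equal(rs.values, rs2.values)


class TestPca:
    def test_single_varying_column_is_pc1(self):
        vals = np.ones((6, 3))
        vals[:, 1] = [1, 2, 3, 4, 5, 6]
        rs = RankSumMatrix(pd.DataFrame(vals, index=list("abcdef")), n_samples=12)
        res = pn.pca_ranksum(rs)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_two_identical_columns_closed_form(self):
        """Two equal columns, nothing else: PC1 carries all variance with
        symmetric loadings 1/sqrt(2)."""
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        vals = np.column_stack([x, x])
        rs = RankSumMatrix(pd.DataFrame(vals, index=list("abcde")), n_samples=10)
        res = pn.pca_ranksum(rs)
        assert res.proportions[0] == pytest.approx(1.0)
        assert np.abs(res.loadings.iloc[:, 0]).to_numpy() == pytest.approx(
            np.full(2, 1 / np.sqrt(2))
        )

    def test_constant_matrix_rejected(self):
        rs = RankSumMatrix(pd.DataFrame(np.ones((4, 3)), index=list("abcd")), 8)
        with pytest.raises(ValueError, match="constant"):
            pn.pca_ranksum(rs)

    def test_proportions_sum_to_one_and_cumulative_monotone(self, small_traits):
        res = pn.pca_ranksum(pn.ranksum_transform(small_traits))
        assert res.proportions.sum() == pytest.approx(1.0)
        assert (np.diff(res.cumulative) >= -1e-12).all()

    def test_scores_recover_planted_structure(self, small_traits, small_ds):
        """Strain scores correlate with the planted per-strain mean offsets."""
        rs = pn.ranksum_transform(small_traits)
        res = pn.pca_ranksum(rs)
        offs = small_ds.truth.mean_offsets
        best = 0.0
        for trait in small_ds.truth.strain_effect_traits[:8]:
            planted = np.array([offs[trait][s] for s in rs.strains])
            for j in range(3):
                r = abs(np.corrcoef(planted, res.scores.iloc[:, j])[0, 1])
                best = max(best, r)
        assert best > 0.5


class TestChanceThreshold:
    def test_single_param_chance_is_one(self, rng):
        M = null_ranksum_matrix(8, 5, 1, rng)
        res = pn.pc_chance_threshold(M, B=100, seed=0)
        assert res.expected_max == pytest.approx(1.0)

    def test_more_params_do_not_raise_chance_max(self, rng):
        a = pn.pc_chance_threshold(null_ranksum_matrix(10, 5, 40, rng), B=150, seed=1)
        b = pn.pc_chance_threshold(null_ranksum_matrix(10, 5, 80, rng), B=150, seed=2)
        assert b.expected_max <= a.expected_max * 1.05


class TestAngleDissimilarity:
    def test_identical_orthogonal_and_pi_over_4(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        D = pn.angle_dissimilarity(S).to_numpy()
        assert D[0, 0] == 0.0
        assert D[0, 1] == pytest.approx(np.pi / 2)
        assert D[0, 2] == pytest.approx(np.pi / 4)
        assert np.allclose(D, D.T)

    def test_zero_norm_vector_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            pn.angle_dissimilarity(np.array([[1.0, 0.0], [0.0, 0.0]]))

    def test_triangle_inequality_on_random_instances(self, rng):
        X = rng.normal(size=(12, 5))
        D = pn.angle_dissimilarity(X).to_numpy()
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestAuFit:
    def test_recovers_generating_parameters(self):
        v, c = 1.0, 0.5
        r = np.arange(0.5, 1.41, 0.1)
        sigma = np.sqrt(r)
        bp = 1 - stats.norm.cdf(v * sigma + c / sigma)
        vf, cf, au, degen = fit_au(bp, r, B=10_000)
        assert not degen
        assert vf == pytest.approx(v, abs=1e-3)
        assert cf == pytest.approx(c, abs=1e-3)
        assert au == pytest.approx(1 - stats.norm.cdf(v - c), abs=1e-3)

    def test_c_zero_makes_au_equal_bp_at_sigma_one(self):
        v = 0.7
        r = np.arange(0.5, 1.41, 0.1)
        bp = 1 - stats.norm.cdf(v * np.sqrt(r))
        _, _, au, _ = fit_au(bp, r, B=10_000)
        bp_at_1 = 1 - stats.norm.cdf(v)
        assert au == pytest.approx(bp_at_1, abs=1e-3)

    def test_v_equals_c_gives_half(self):
        v = c = 0.8
        r = np.arange(0.5, 1.41, 0.1)
        sigma = np.sqrt(r)
        bp = 1 - stats.norm.cdf(v * sigma + c / sigma)
        _, _, au, _ = fit_au(bp, r, B=10_000)
        assert au == pytest.approx(0.5, abs=1e-6)

    def test_degenerate_bp_clamped_and_flagged(self):
        r = np.arange(0.5, 1.41, 0.1)
        _, _, au_hi, degen_hi = fit_au(np.ones_like(r), r, B=100)
        _, _, au_lo, degen_lo = fit_au(np.zeros_like(r), r, B=100)
        assert degen_hi and degen_lo
        assert au_hi == 1.0 and au_lo == 0.0


def _blocked_table(rng, n_strains=16, n_reps=5, n_block_traits=8, n_noise_traits=8,
                   shift=7.0, strain_sd=1.2):
    """Three labelled strain groups each shifting a disjoint trait block,
    plus unlabelled ("other") strains; strains carry their own random
    offsets (within-class heterogeneity) on every trait."""
    n = n_strains * n_reps
    classes = np.arange(n_strains) % 4  # class 3 = other
    p = 3 * n_block_traits + n_noise_traits
    strain_jitter = rng.normal(size=(n_strains, p)) * strain_sd
    names, blocks = [], {}
    for c in range(3):
        blocks[c] = [f"blk{c}_{t}" for t in range(n_block_traits)]
        names += blocks[c]
    names += [f"noise{t}" for t in range(n_noise_traits)]
    cols = {}
    for jcol, name in enumerate(names):
        base = rng.normal(size=n) + np.repeat(strain_jitter[:, jcol], n_reps)
        if name.startswith("blk"):
            c = int(name[3])
            base += np.repeat((classes == c).astype(float), n_reps) * shift
        cols[name] = base
    ids = [f"S{i // n_reps + 1:02d}.{i % n_reps + 1}" for i in range(n)]
    table = TraitTable(pd.DataFrame(cols, index=pd.Index(ids, name="sample")))
    roman = {0: "I", 1: "II", 2: "III"}
    labels = {f"S{i + 1:02d}": roman[classes[i]]
              for i in range(n_strains) if classes[i] in roman}
    return table, labels, blocks


class TestAuCluster:
    def test_planted_groups_get_high_au(self, rng):
        table, labels, _ = _blocked_table(rng, n_strains=9, shift=8.0, strain_sd=0.5)
        rs = pn.ranksum_transform(table)
        dend = pn.au_cluster(rs, B=400, seed=3, cheap=True)
        sig_sets = {c.members for c in dend.significant_clusters()}
        for cls in ("I", "II", "III"):
            group = tuple(sorted(s for s, l in labels.items() if l == cls))
            assert any(set(group) <= set(m) and len(m) <= len(group) + 1 for m in sig_sets), (
                cls, sig_sets)

    def test_au_in_unit_interval_and_root_certain(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        dend = pn.au_cluster(rs, B=150, seed=4, cheap=True)
        aus = np.array([c.au for c in dend.clusters])
        assert ((aus >= 0) & (aus <= 1)).all()
        root = max(dend.clusters, key=lambda c: len(c.members))
        assert root.au == 1.0  # the full strain set is in every replicate tree

    def test_newick_contains_all_strains(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        dend = pn.au_cluster(rs, B=100, seed=5, cheap=True)
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for s in rs.strains:
            assert s in nwk

    def test_bad_scales_rejected(self, small_traits):
        rs = pn.ranksum_transform(small_traits)
        with pytest.raises(ValueError, match="scales"):
            pn.au_cluster(rs, scales=[0.0, 1.0], B=100)


class TestLda:
    def test_angle_helper_parallel_and_orthogonal(self):
        b = np.array([1.0, 2.0, 3.0])
        A = np.stack([2 * b, [3.0, 0.0, -1.0], -b])
        ang = _angles_deg(A, b)
        assert ang[0] == pytest.approx(0.0, abs=1e-9)
        assert ang[1] == pytest.approx(90.0)
        assert ang[2] == pytest.approx(180.0)

    def test_discriminating_params_recover_planted_blocks(self):
        """Across 20 seeds, discriminating sets recover the planted blocks
        and resubstitution is almost always exact."""
        jaccards, consistent = [], 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, labels, blocks = _blocked_table(rng)
            rs = pn.ranksum_transform(table)
            K, p = pn.kw_statistics(table.values.to_numpy(), table.strain_codes())
            pvals = pd.Series(p, index=table.values.columns)
            model = pn.lda_classes(rs, labels, pvals, alpha=0.05)
            consistent += model.self_consistent
            for cls, c in (("I", 0), ("II", 1), ("III", 2)):
                got = set(model.discriminating[cls])
                want = set(blocks[c])
                jaccards.append(len(got & want) / len(got | want))
        assert np.mean(jaccards) >= 0.8
        assert consistent >= 18

    def test_resubstitution_matches_labels_on_benchmark(self):
        """On a well-separated benchmark, every labelled strain is predicted
        back into its own class."""
        rng = np.random.default_rng(0)
        table, labels, _ = _blocked_table(rng)
        rs = pn.ranksum_transform(table)
        K, p = pn.kw_statistics(table.values.to_numpy(), table.strain_codes())
        pvals = pd.Series(p, index=table.values.columns)
        model = pn.lda_classes(rs, labels, pvals, alpha=0.05)
        assert model.self_consistent

    def test_null_parameter_not_selected(self, rng):
        """A trait with no between-class signal sits far from every center."""
        table, labels, blocks = _blocked_table(rng)
        rs = pn.ranksum_transform(table)
        preselected = [c for c in table.values.columns]
        model = pn.lda_classes(rs, labels, preselected=preselected)
        noise_params = [c for c in table.values.columns if c.startswith("noise")]
        angles = model.contribution_angles.loc[noise_params].to_numpy()
        assert np.median(angles) > 60.0
        block_params = [c for c in table.values.columns if c.startswith("blk")]
        block_angles = np.array(
            [model.contribution_angles.loc[blocks[c], cls].to_numpy()
             for cls, c in (("I", 0), ("II", 1), ("III", 2))]
        )
        assert np.median(block_angles) < np.median(angles)

    def test_singleton_class_rejected(self, rng):
        table, labels, _ = _blocked_table(rng)
        labels = dict(labels)
        lone = list(labels)[0]
        labels[lone] = "IV"
        rs = pn.ranksum_transform(table)
        with pytest.raises(ValueError, match="single strain"):
            pn.lda_classes(rs, labels, preselected=list(table.values.columns))

    def test_too_few_classes_rejected(self, rng):
        table, labels, _ = _blocked_table(rng)
        two = {s: ("I" if l == "I" else "II") for s, l in labels.items()}
        rs = pn.ranksum_transform(table)
        with pytest.raises(ValueError, match="classes"):
            pn.lda_classes(rs, two, preselected=list(table.values.columns))
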