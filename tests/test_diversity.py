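import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from lakemicro import alpha_diversity, anosim, bray_curtis, group_tests, pcoa, spearman_screen
from lakemicro.io import read_tree

from conftest import make_cm

count_tables = st.lists(
    st.lists(st.integers(0, 50), min_size=4, max_size=4),
    min_size=3, max_size=8,
).filter(lambda rows: all(sum(r) > 0 for r in rows))


class TestAlphaDiversity:
    def test_equal_abundances(self):
        cm = make_cm([[25, 25, 25, 25]])
        a = alpha_diversity(cm)
        assert a["Shannon"].iloc[0] == pytest.approx(np.log(4))
        assert a["Simpson"].iloc[0] == pytest.approx(0.75)
        assert a["Pielou"].iloc[0] == pytest.approx(1.0)

    def test_chao1_hand_value(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        counts = [1] * 4 + [2] * 2 + [5] * 4
        a = alpha_diversity(make_cm([counts]))
        assert a["Chao1"].iloc[0] == pytest.approx(14.0)

    def test_faith_pd_star_tree_additivity(self):
        tree = read_tree("((A:1,B:1,C:1,D:1):0.0,(E:1,F:1,G:1,H:1):0.0);")
        cm = make_cm([[1, 1, 1, 1, 1, 1, 1, 0]], otu_ids=list("ABCDEFGH"))
        a = alpha_diversity(cm, tree)
        assert a["Faith_PD"].iloc[0] == pytest.approx(7.0)

    def test_single_taxon_pielou_is_nan(self):
        a = alpha_diversity(make_cm([[7, 0, 0]]))
        assert np.isnan(a["Pielou"].iloc[0])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(count_tables)
    def test_shannon_maximal_iff_equal(self, rows):
        cm = make_cm(rows)
        a = alpha_diversity(cm)
        for (_, row), h in zip(cm.counts.iterrows(), a["Shannon"]):
            s = (row > 0).sum()
            assert h <= np.log(s) + 1e-12
            nz = row[row > 0]
            if nz.nunique() > 1:
                assert h < np.log(s) - 1e-12


class TestBrayCurtis:
    def test_hand_value(self):
        bc = bray_curtis(make_cm([[6, 0, 2], [2, 2, 0]]))
        assert bc.iloc[0, 1] == pytest.approx(8 / 12)

    def test_identical_and_disjoint(self):
        bc = bray_curtis(make_cm([[3, 1, 0, 0], [3, 1, 0, 0], [0, 0, 2, 5]]))
        assert bc.iloc[0, 1] == pytest.approx(0.0)
        assert bc.iloc[0, 2] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(count_tables)
    def test_bounded_symmetric_zero_diagonal(self, rows):
        bc = bray_curtis(make_cm(rows)).to_numpy()
        assert np.allclose(bc, bc.T)
        assert np.allclose(np.diag(bc), 0)
        assert (bc >= -1e-12).all() and (bc <= 1 + 1e-12).all()


class TestPcoa:
    def test_two_samples_single_axis(self):
        d = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"], columns=["a", "b"])
        coords, evals, prop = pcoa(d)
        assert coords.shape[1] == 1
        assert prop.iloc[0] == pytest.approx(1.0)

    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        coords, _, _ = pcoa(d, n_axes=2)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, coords.to_numpy())
        assert disparity < 1e-8

    def test_doubling_distances_scales_coordinates(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        d = pd.DataFrame(squareform(pdist(pts)))
        c1, _, p1 = pcoa(d)
        c2, _, p2 = pcoa(2 * d)
        assert np.allclose(np.abs(c2.to_numpy()), 2 * np.abs(c1.to_numpy()), atol=1e-8)
        assert np.allclose(p1.to_numpy(), p2.to_numpy())

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            pcoa(d)

    def test_agrees_with_skbio(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        ours, _, prop = pcoa(pd.DataFrame(d), n_axes=2)
        ref = skbio_pcoa(d, method="eigh", number_of_dimensions=2)
        assert np.allclose(np.abs(ours.to_numpy()),
                           np.abs(ref.samples.to_numpy()[:, :2]), atol=1e-8)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # two tight blocks far apart: all between-ranks above within-ranks
        x = np.concatenate([np.zeros(4), np.full(4, 100.0)]) + np.arange(8) * 0.01
        d = pd.DataFrame(squareform(pdist(x[:, None])))
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=d.index)
        r, p = anosim(d, groups, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_null_r_centred_on_zero(self):
        rng = np.random.default_rng(2)
        rs = []
        for i in range(200):
            x = rng.normal(size=(12, 3))
            d = pd.DataFrame(squareform(pdist(x)))
            groups = pd.Series(["a"] * 6 + ["b"] * 6, index=d.index)
            r, _ = anosim(d, groups, n_perm=49, seed=i)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_seeded_p_reproducible(self):
        rng = np.random.default_rng(5)
        d = pd.DataFrame(squareform(pdist(rng.normal(size=(10, 2)))))
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=d.index)
        assert anosim(d, groups, seed=7) == anosim(d, groups, seed=7)

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="singleton"):
            anosim(d, pd.Series(["a", "a", "b"], index=d.index))

    def test_r_statistic_matches_skbio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(8)
        d = squareform(pdist(rng.normal(size=(12, 4))))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours, _ = anosim(pd.DataFrame(d), pd.Series(groups), n_perm=49, seed=0)
        ref = sk_anosim(DistanceMatrix(d), grouping=groups, permutations=0)
        assert ours == pytest.approx(ref["test statistic"], abs=1e-12)


class TestGroupTests:
    def test_identical_values_give_zero_h(self):
        tab = group_tests([1.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert tab.loc[tab.test == "kruskal", "statistic"].iloc[0] == 0.0

    def test_extreme_two_group_mannwhitney(self):
        tab = group_tests([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        mw = tab[tab.test == "mannwhitney"].iloc[0]
        assert min(mw.statistic, 9 - mw.statistic) == 0  # U = 0 at one extreme
        assert mw.p < 0.1

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1, 2, 3], ["a", "a", "a"])


class TestSpearmanScreen:
    def test_monotone_and_inverse(self):
        idx = [f"S{i}" for i in range(8)]
        x = pd.DataFrame({"x": np.arange(8.0)}, index=idx)
        y = pd.DataFrame({"up": np.exp(np.arange(8.0)), "down": -np.arange(8.0)},
                         index=idx)
        out = spearman_screen(x, y).set_index("right")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_hand_ranked_value(self):
        idx = list("abcde")
        out = spearman_screen(
            pd.DataFrame({"x": [1, 2, 3, 4, 5]}, index=idx),
            pd.DataFrame({"y": [3, 1, 4, 2, 5]}, index=idx),
        )
        assert out["rho"].iloc[0] == pytest.approx(0.5)

    def test_constant_column_gives_nan(self):
        idx = list("abcdef")
        out = spearman_screen(
            pd.DataFrame({"x": np.arange(6.0)}, index=idx),
            pd.DataFrame({"c": np.ones(6)}, index=idx),
        )
        assert np.isnan(out["rho"].iloc[0])
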