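import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lakemicro import (
    SimulationConfig,
    beta_mntd,
    beta_nti,
    bnti_env_correlation,
    classify_processes,
    fit_neutral,
    raup_crick_bray,
    simulate_metacommunity,
    simulate_tree,
)
from lakemicro.assembly import classify_pair
from lakemicro.io import read_tree

from conftest import make_cm


def brute_force_bmntd(cm, tree, weighted=True):
    """Naive double-loop oracle over sample pairs and taxa."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    d = {a: {b: dm[(a, b)] for b in ids} for a in ids}
    rel = cm.relative_abundance()
    out = np.zeros((cm.n_samples, cm.n_samples))
    for k in range(cm.n_samples):
        for l in range(cm.n_samples):
            if k == l:
                continue
            sk = [o for o in cm.otu_ids if cm.counts.iloc[k][o] > 0]
            sl = [o for o in cm.otu_ids if cm.counts.iloc[l][o] > 0]
            tot = 0.0
            for o in sk:
                w = rel.iloc[k][o] if weighted else 1 / len(sk)
                tot += w * min(d[o][p] for p in sl)
            for o in sl:
                w = rel.iloc[l][o] if weighted else 1 / len(sl)
                tot += w * min(d[o][p] for p in sk)
            out[k, l] = tot / 2
    return out


class TestBetaMntd:
    def test_identical_samples_zero(self, small_tree):
        cm = make_cm([[3, 1, 2], [3, 1, 2]], otu_ids=["A", "B", "C"])
        b = beta_mntd(cm, small_tree)
        assert b.iloc[0, 1] == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, small_tree):
        cm = make_cm([[5, 0, 0], [0, 7, 0]], otu_ids=["A", "B", "C"])
        b = beta_mntd(cm, small_tree)
        assert b.iloc[0, 1] == pytest.approx(3.0)  # path A-B

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tree = simulate_tree(20, seed=seed)
            otus = sorted(t.name for t in tree.tips())
            counts = rng.integers(0, 8, size=(5, 20))
            counts[:, 0] += 1
            cm = make_cm(counts, otu_ids=otus)
            ours = beta_mntd(cm, tree, abundance_weighted=weighted).to_numpy()
            oracle = brute_force_bmntd(cm, tree, weighted)
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_missing_otu_is_error(self, small_tree):
        cm = make_cm([[1, 1], [1, 1]], otu_ids=["A", "Z"])
        with pytest.raises(ValueError, match="Z"):
            beta_mntd(cm, small_tree)


class TestBetaNti:
    def test_star_tree_degenerate_null_gives_nan(self):
        tree = read_tree("((A:1,B:1):0.0,(C:1,D:1):0.0);")
        cm = make_cm([[1, 1, 0, 0], [0, 0, 1, 1]], otu_ids=list("ABCD"))
        z = beta_nti(cm, tree, n_null=29, seed=0)
        assert np.isnan(z.iloc[0, 1])

    def test_relabelling_invariance(self):
        tree = simulate_tree(12, seed=3)
        otus = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 6, size=(4, 12))
        counts[:, 0] += 1
        cm = make_cm(counts, otu_ids=otus)
        z1 = beta_nti(cm, tree, n_null=99, seed=5)
        # jointly permute OTU labels in matrix and tree
        perm = rng.permutation(12)
        relabel = {otus[i]: otus[perm[i]] for i in range(12)}
        tree2 = tree.copy()
        for tip in tree2.tips():
            tip.name = relabel[tip.name]
        cm2 = make_cm(counts, otu_ids=[relabel[o] for o in otus])
        z2 = beta_nti(cm2, tree2, n_null=99, seed=5)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), equal_nan=True)

    def test_seeded_reproducibility(self, neutral_survey):
        cm, tree, _, _ = neutral_survey
        a = beta_nti(cm, tree, n_null=19, seed=9)
        b = beta_nti(cm, tree, n_null=19, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_selection_regime_pushes_bnti_negative(self):
        cfg = SimulationConfig(n_groups=3, samples_per_group=3,
                               regime="homogeneous_selection",
                               migration_rate=0.02, env_gradient_strength=15.0,
                               niche_conservatism=0.05, seed=8)
        cm, tree, _, _ = simulate_metacommunity(cfg)
        z = beta_nti(cm, tree, n_null=199, seed=0)
        iu = np.triu_indices(cm.n_samples, 1)
        assert np.nanmedian(z.to_numpy()[iu]) < -2


class TestRaupCrick:
    def test_identical_samples_hit_minus_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, size=(3, 40)) + 1
        counts[2] = rng.integers(0, 10, size=40) + 1
        cm = make_cm(np.vstack([counts[0], counts[0], counts[2]]))
        rc = raup_crick_bray(cm, n_null=199, seed=1)
        assert rc.iloc[0, 1] == pytest.approx(-1.0)

    def test_disjoint_samples_over_shared_pool_hit_plus_one(self):
        # two samples with private halves of a large shared pool
        rng = np.random.default_rng(1)
        a = np.concatenate([rng.integers(1, 20, 40), np.zeros(40, int)])
        b = np.concatenate([np.zeros(40, int), rng.integers(1, 20, 40)])
        filler = rng.integers(1, 5, 80)
        cm = make_cm(np.vstack([a, b, filler, filler + 1]))
        rc = raup_crick_bray(cm, n_null=999, seed=2)
        assert rc.iloc[0, 1] > 0.95

    def test_bounded_and_symmetric(self, neutral_survey):
        cm = neutral_survey[0].subset_samples(neutral_survey[0].sample_ids[:5])
        rc = raup_crick_bray(cm, n_null=99, seed=0).to_numpy()
        assert np.allclose(rc, rc.T)
        assert (rc >= -1).all() and (rc <= 1).all()

    def test_seeded_reproducibility(self, neutral_survey):
        cm = neutral_survey[0].subset_samples(neutral_survey[0].sample_ids[:4])
        a = raup_crick_bray(cm, n_null=49, seed=3)
        b = raup_crick_bray(cm, n_null=49, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestNeutralFit:
    def test_dominant_taxon_predicted_everywhere(self, neutral_survey):
        cm = neutral_survey[0]
        fit = fit_neutral(cm)
        dominant = fit.table["p"].idxmax()
        assert fit.table.loc[dominant, "predicted_freq"] > 0.99
        assert fit.table["predicted_freq"].between(0, 1).all()

    def test_predicted_frequency_monotone_in_abundance(self, neutral_survey):
        fit = fit_neutral(neutral_survey[0])
        tab = fit.table.sort_values("p")
        assert (np.diff(tab["predicted_freq"]) >= -1e-9).all()

    def test_partitions_exhaustive(self, neutral_survey):
        fit = fit_neutral(neutral_survey[0])
        assert set(fit.table["partition"]) <= {"above", "within", "below"}

    def test_monotone_recovery_of_migration_rate(self):
        fitted = []
        for m in (0.05, 0.2):
            cfg = SimulationConfig(n_groups=5, samples_per_group=4, n_taxa=600,
                                   library_size=5000, migration_rate=m,
                                   regime="neutral", seed=21)
            cm, *_ = simulate_metacommunity(cfg)
            fitted.append(fit_neutral(cm).m)
        assert fitted[0] < fitted[1]

    def test_unidentifiable_fit_rejected(self):
        cm = make_cm([[5, 5, 5], [5, 5, 5]])
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_neutral(cm)


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (-3.0, 0.99, "homogeneous_selection"),   # selection checked first
        (3.0, -0.99, "heterogeneous_selection"),
        (1.0, 0.99, "dispersal_limitation"),
        (0.0, -0.99, "homogeneous_dispersal"),
        (2.0, 0.0, "undominated"),               # strict boundary
        (-2.0, 0.95, "undominated"),
        (0.0, -0.95, "undominated"),
    ])
    def test_pair_labels(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-1, 1)),
                    min_size=3, max_size=10))
    def test_fractions_sum_to_hundred(self, vals):
        n = len(vals)
        ids = [f"S{i}" for i in range(n + 1)]
        b = np.zeros((n + 1, n + 1))
        r = np.zeros((n + 1, n + 1))
        k = 0
        for i in range(n + 1):
            for j in range(i + 1, n + 1):
                bv, rv = vals[k % n]
                b[i, j] = b[j, i] = bv
                r[i, j] = r[j, i] = rv
                k += 1
        res = classify_processes(pd.DataFrame(b, index=ids, columns=ids),
                                 pd.DataFrame(r, index=ids, columns=ids))
        assert res.fractions.sum() == pytest.approx(100.0, abs=0.01)

    def test_nan_pairs_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        b = pd.DataFrame([[0, np.nan, -3], [np.nan, 0, 0], [-3, 0, 0]],
                         index=ids, columns=ids)
        r = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        res = classify_processes(b, r)
        assert res.n_na == 1
        assert res.n_pairs == 2


class TestBntiEnvCorrelation:
    def test_monotone_delta_gives_rho_one(self):
        ids = [f"S{i}" for i in range(6)]
        v = np.array([0.0, 1.0, 2.5, 4.0, 7.0, 11.0])
        delta = np.abs(v[:, None] - v[None, :])
        bnti = pd.DataFrame(np.sqrt(delta), index=ids, columns=ids)
        env = pd.DataFrame({"pH": v}, index=ids)
        out = bnti_env_correlation(bnti, env, n_perm=49, seed=0)
        assert out["rho"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 0.05

    def test_matches_allpairs_spearman_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = 7
            ids = [f"S{i}" for i in range(n)]
            m = rng.normal(size=(n, n))
            bnti = pd.DataFrame((m + m.T) / 2, index=ids, columns=ids)
            np.fill_diagonal(bnti.values, 0)
            v = rng.normal(size=n)
            env = pd.DataFrame({"x": v}, index=ids)
            out = bnti_env_correlation(bnti, env, n_perm=9, seed=0)
            iu = np.triu_indices(n, 1)
            expect, _ = stats.spearmanr(bnti.to_numpy()[iu],
                                        np.abs(v[:, None] - v[None, :])[iu])
            assert out["rho"].iloc[0] == pytest.approx(expect, abs=1e-12)

    def test_constant_variable_gives_nan(self):
        ids = list("abcd")
        bnti = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=ids, columns=ids)
        env = pd.DataFrame({"c": np.ones(4)}, index=ids)
        out = bnti_env_correlation(bnti, env, n_perm=9, seed=0)
        assert np.isnan(out["rho"].iloc[0])
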