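"""Alpha/beta diversity, ordination, group tests and correlation screens.

Alpha indices are Shannon (nats by default), Gini–Simpson, Chao1,
Faith's phylogenetic diversity, Pielou evenness and observed richness.
Beta diversity is Bray–Curtis; ordination is classical PCoA with the
proportion explained computed over positive eigenvalues only (negative
eigenvalues are reported but excluded from the denominator). Group
structure is tested with ANOSIM (seeded permutations), Kruskal–Wallis
and Mann–Whitney U; alpha-vs-environment screens use Spearman rank
correlation with optional Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1, faith_pd, shannon, simpson
from statsmodels.stats.multitest import multipletests

from .io import CommunityMatrix

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "anosim",
    "group_tests",
    "spearman_screen",
]


def alpha_diversity(cm: CommunityMatrix, tree=None, base: float = np.e) -> pd.DataFrame:
    """Per-sample alpha diversity table.

    Shannon uses log base ``base`` (natural log by default). Pielou is
    Shannon / log(S_obs) and is NaN for single-taxon samples. Faith's PD
    (requires ``tree``) is the total branch length of the subtree
    spanning the sample's taxa including the path to the root.
    """
    rows = {}
    otu_ids = cm.otu_ids
    for sid, counts in cm.counts.iterrows():
        c = counts.to_numpy()
        s_obs = int((c > 0).sum())
        h = shannon(c, base=base)
        pielou = h / (np.log(s_obs) / np.log(base)) if s_obs > 1 else np.nan
        row = {
            "Richness": s_obs,
            "Shannon": h,
            "Simpson": simpson(c),
            "Chao1": chao1(c, bias_corrected=False),
            "Pielou": pielou,
        }
        if tree is not None:
            row["Faith_PD"] = faith_pd(c, otu_ids, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(cm: CommunityMatrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity, samples × samples."""
    if cm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dm = beta_diversity("braycurtis", cm.counts.to_numpy(), ids=cm.sample_ids)
    return pd.DataFrame(dm.data, index=cm.sample_ids, columns=cm.sample_ids)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    return a - row - row.T + a.mean()


def pcoa(d: pd.DataFrame, n_axes: int | None = None):
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Returns ``(coordinates, eigenvalues, proportion_explained)``.
    Eigenvalues are reported with sign; proportions are computed over the
    positive eigenvalues only, so axes from semi-metric dissimilarities
    (like Bray–Curtis) are comparable across studies using the same
    convention.
    """
    dd = np.asarray(d, dtype=float)
    if dd.shape[0] != dd.shape[1] or not np.allclose(dd, dd.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    ids = list(d.index) if isinstance(d, pd.DataFrame) else list(range(len(dd)))
    evals, evecs = np.linalg.eigh(_gower_center(dd))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    prop = np.where(pos, evals / evals[pos].sum(), 0.0) if n_pos else np.zeros_like(evals)
    axes = [f"PCo{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(coords, index=ids, columns=axes),
        pd.Series(evals, index=[f"PCo{i + 1}" for i in range(len(evals))]),
        pd.Series(prop[:k], index=axes),
    )


def _rank_matrix(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(d, k=1)
    ranks = stats.rankdata(d[iu])
    r = np.zeros_like(d)
    r[iu] = ranks
    return r + r.T


def anosim(d: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0):
    """Analysis of similarity on a dissimilarity matrix.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2; p is the fraction of label permutations (plus the
    observed labelling) with R at least as large.
    """
    dd = np.asarray(d, dtype=float)
    labels = np.asarray(pd.Series(groups).loc[list(d.index)] if isinstance(d, pd.DataFrame) else groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"singleton group(s): {uniq[counts < 2].tolist()}")
    n = len(labels)
    ranks = _rank_matrix(dd)
    iu = np.triu_indices(n, k=1)
    m = n * (n - 1) / 2

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[iu][~within].mean() - ranks[iu][within].mean()) / (m / 2)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    perm_r = np.array([r_stat(rng.permutation(labels)) for _ in range(n_perm)])
    p = (1 + (perm_r >= r_obs).sum()) / (n_perm + 1)
    return r_obs, p


def group_tests(values, groups) -> pd.DataFrame:
    """Kruskal–Wallis across all groups plus pairwise Mann–Whitney U.

    ``values`` is a Series (or per-sample array) of a diversity index or
    an environmental factor; ``groups`` the matching labels. Returns a
    one-row table for the omnibus test and one row per group pair.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by = [values[groups == g].to_numpy() for g in uniq]
    if np.ptp(np.concatenate(by)) == 0:
        h, p_kw = 0.0, 1.0
    else:
        h, p_kw = stats.kruskal(*by)
    rows = [{"test": "kruskal", "group1": "all", "group2": "all",
             "statistic": h, "p": p_kw}]
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            u, p = stats.mannwhitneyu(
                by[i], by[j], alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            rows.append({"test": "mannwhitney", "group1": uniq[i],
                         "group2": uniq[j], "statistic": u, "p": p})
    return pd.DataFrame(rows)


def spearman_screen(
    left: pd.DataFrame,
    right: pd.DataFrame,
    adjust: bool = False,
) -> pd.DataFrame:
    """All-pairs Spearman screen between two aligned sample tables.

    Returns a long table (left variable, right variable, rho, p, stars).
    Constant columns yield NaN rho. With ``adjust=True`` the p-values are
    Benjamini–Hochberg corrected over the whole screen before starring
    (* 0.05, ** 0.01, *** 0.001).
    """
    common = left.index.intersection(right.index)
    if len(common) < 5:
        raise ValueError("need at least 5 aligned samples")
    L, R = left.loc[common], right.loc[common]
    rows = []
    for lcol in L.columns:
        for rcol in R.columns:
            x, y = L[lcol].to_numpy(float), R[rcol].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 5 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            rows.append({"left": lcol, "right": rcol, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    ok = ~np.isnan(pvals)
    padj = np.full_like(pvals, np.nan)
    if ok.any():
        padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["p_adj"] = padj
    basis = out["p_adj"] if adjust else out["p"]
    out["stars"] = [
        "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        for p in basis.fillna(1.0)
    ]
    return out
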