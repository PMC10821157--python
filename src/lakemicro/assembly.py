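"""Community-assembly process quantification.

Three complementary instruments:

* **Sloan neutral community model** (:func:`fit_neutral`) — fits the
  immigration rate ``m`` that best predicts each OTU's occurrence
  frequency from its mean metacommunity relative abundance ``p``; the
  prediction is the upper tail, above the detection limit ``d = 1/N_T``,
  of ``Beta(N_T*m*p, N_T*m*(1-p))``.

* **Phylogenetic null model** (:func:`beta_mntd`, :func:`beta_nti`) —
  the between-community mean nearest taxon distance and its standardized
  effect size against ``n_null`` shuffles of taxon labels across all
  tree tips. |βNTI| > 2 flags deterministic turnover: βNTI < −2
  homogeneous selection, βNTI > 2 heterogeneous selection.

* **Abundance-based Raup–Crick** (:func:`raup_crick_bray`) — compares
  observed Bray–Curtis against pairs of null assemblies that preserve
  each sample's richness and total abundance while drawing taxa by
  metacommunity occurrence frequency and filling individuals by
  metacommunity relative abundance. RCbray > 0.95 flags dispersal
  limitation, RCbray < −0.95 homogeneous dispersal.

:func:`classify_processes` combines the two null models into the
five-way partition (selection first, then dispersal, else undominated;
all thresholds strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CommunityMatrix

logger = logging.getLogger("lakemicro")

__all__ = [
    "NeutralFit",
    "AssemblyResult",
    "fit_neutral",
    "beta_mntd",
    "beta_nti",
    "raup_crick_bray",
    "null_assemblage",
    "metacommunity_weights",
    "classify_processes",
    "bnti_env_correlation",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogeneous_dispersal",
    "undominated",
)


# --------------------------------------------------------------------------
# Sloan neutral community model
# --------------------------------------------------------------------------

@dataclass
class NeutralFit:
    """Result of the neutral-model fit.

    ``table`` has one row per OTU: mean relative abundance ``p``,
    observed occurrence frequency, predicted frequency, Wilson 95% CI
    bounds and the partition label (above/within/below the band).
    """

    m: float
    r2: float
    n_t: float
    table: pd.DataFrame


def _sloan_freq(p: np.ndarray, m: float, n_t: float, d: float) -> np.ndarray:
    a = n_t * m * p
    b = n_t * m * (1.0 - p)
    return stats.beta.sf(d, a, b)


def fit_neutral(cm: CommunityMatrix, ci_z: float = 1.959964) -> NeutralFit:
    """Fit the Sloan neutral model to occurrence frequency vs abundance.

    ``N_T`` is the mean library size and the detection limit is
    ``1/N_T``. ``m`` is fitted by bounded least squares of predicted
    against observed frequencies; R² = 1 − SSE/SST.
    """
    rel = cm.relative_abundance().to_numpy()
    p = rel.mean(axis=0)
    freq = (cm.counts.to_numpy() > 0).mean(axis=0)
    n_t = float(cm.counts.sum(axis=1).mean())
    d = 1.0 / n_t

    intermediate = (freq > 0) & (freq < 1)
    if intermediate.sum() < 5:
        raise ValueError(
            "fewer than 5 OTUs with intermediate occurrence frequency; "
            "the neutral fit is unidentifiable"
        )

    def sse(m: float) -> float:
        resid = freq - _sloan_freq(p, m, n_t, d)
        return float(resid @ resid)

    res = optimize.minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    m_hat = float(res.x)
    pred = _sloan_freq(p, m_hat, n_t, d)
    sst = float(((freq - freq.mean()) ** 2).sum())
    r2 = 1.0 - res.fun / sst if sst > 0 else np.nan

    # Wilson score 95% band around the predicted frequency at n = #samples
    n = cm.n_samples
    z2 = ci_z**2
    center = (pred + z2 / (2 * n)) / (1 + z2 / n)
    half = (ci_z / (1 + z2 / n)) * np.sqrt(pred * (1 - pred) / n + z2 / (4 * n**2))
    lower, upper = center - half, center + half
    partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))

    table = pd.DataFrame(
        {
            "p": p,
            "observed_freq": freq,
            "predicted_freq": pred,
            "ci_lower": lower,
            "ci_upper": upper,
            "partition": partition,
        },
        index=cm.otu_ids,
    )
    return NeutralFit(m=m_hat, r2=r2, n_t=n_t, table=table)


# --------------------------------------------------------------------------
# betaMNTD / betaNTI
# --------------------------------------------------------------------------

def _patristic_and_profiles(cm: CommunityMatrix, tree, abundance_weighted: bool):
    """Full tip-tip distance matrix plus per-sample tip indices/weights."""
    tip_names = [t.name for t in tree.tips()]
    missing = sorted(set(cm.otu_ids) - set(tip_names))
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}")
    dm = tree.tip_tip_distances()
    order = {name: i for i, name in enumerate(dm.ids)}
    D = dm.data
    counts = cm.counts.to_numpy()
    idxs, freqs = [], []
    for row in counts:
        present = np.flatnonzero(row > 0)
        ix = np.array([order[cm.otu_ids[j]] for j in present])
        if abundance_weighted:
            f = row[present] / row[present].sum()
        else:
            f = np.full(len(present), 1.0 / len(present))
        idxs.append(ix)
        freqs.append(f)
    return D, idxs, freqs


def _bmntd_from_profiles(D: np.ndarray, idxs, freqs) -> np.ndarray:
    s = len(idxs)
    # min patristic distance from *every* tip to each sample's taxa
    mins = [D[:, ix].min(axis=1) for ix in idxs]
    out = np.zeros((s, s))
    for k in range(s):
        for l in range(k + 1, s):
            v = 0.5 * (freqs[k] @ mins[l][idxs[k]] + freqs[l] @ mins[k][idxs[l]])
            out[k, l] = out[l, k] = v
    return out


def beta_mntd(cm: CommunityMatrix, tree, abundance_weighted: bool = True) -> pd.DataFrame:
    """Between-sample mean nearest taxon distance (patristic).

    βMNTD(k,l) = ½[Σ_i f_ik·min_j d(i,j∈l) + Σ_j f_jl·min_i d(j,i∈k)]
    with f the relative abundances (weighted) or 1/S (unweighted).
    """
    D, idxs, freqs = _patristic_and_profiles(cm, tree, abundance_weighted)
    out = _bmntd_from_profiles(D, idxs, freqs)
    return pd.DataFrame(out, index=cm.sample_ids, columns=cm.sample_ids)


def beta_nti(
    cm: CommunityMatrix,
    tree,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Standardized effect size of βMNTD under taxon-label shuffling.

    For each pair, βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)
    with the null built from ``n_null`` independent permutations of tip
    labels across the whole tree. Pairs with a degenerate null
    (sd = 0, e.g. a star phylogeny) are NaN with a warning.
    """
    D, idxs, freqs = _patristic_and_profiles(cm, tree, abundance_weighted)
    obs = _bmntd_from_profiles(D, idxs, freqs)
    n_tips = D.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        null = _bmntd_from_profiles(D, [perm[ix] for ix in idxs], freqs)
        acc += null
        acc2 += null**2
    mean = acc / n_null
    var = acc2 / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    degenerate = (sd <= 1e-12) & ~np.eye(len(z), dtype=bool)
    if degenerate.any():
        logger.warning(
            "null betaMNTD has zero variance for %d pair(s); betaNTI set to NaN",
            int(degenerate.sum() // 2),
        )
        z[degenerate] = np.nan
    return pd.DataFrame(z, index=cm.sample_ids, columns=cm.sample_ids)


# --------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# --------------------------------------------------------------------------

def null_assemblage(occ_w: np.ndarray, ab_w: np.ndarray, richness: int, total: int,
                    rng, scratch: np.ndarray | None = None) -> np.ndarray:
    """One null community of ``total`` individuals over ``richness`` taxa.

    Taxa are picked without replacement with probability proportional to
    their metacommunity occurrence frequency (``occ_w``); each receives
    one individual and the remainder is filled multinomially by
    metacommunity relative abundance (``ab_w``). This is the null that
    the Raup–Crick index integrates over.
    """
    t = len(occ_w)
    if scratch is None:
        scratch = np.zeros(t)
    # Efraimidis-Spirakis weighted sampling without replacement
    keys = rng.random(t) ** (1.0 / occ_w)
    chosen = np.argpartition(keys, t - richness)[t - richness:]
    pvals = ab_w[chosen] / ab_w[chosen].sum()
    fill = rng.multinomial(total - richness, pvals)
    scratch[:] = 0
    scratch[chosen] = 1 + fill
    return scratch


def metacommunity_weights(cm: CommunityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence-frequency and total-abundance weights per OTU."""
    counts = cm.counts.to_numpy()
    occ = (counts > 0).sum(axis=0).astype(float)
    ab = counts.sum(axis=0).astype(float)
    if (occ == 0).any():
        raise ValueError("community matrix contains all-zero OTU columns")
    return occ, ab


def raup_crick_bray(
    cm: CommunityMatrix,
    n_null: int = 999,
    seed: int = 0,
    reference: CommunityMatrix | None = None,
) -> pd.DataFrame:
    """Abundance-based Raup–Crick index on Bray–Curtis, in [−1, 1].

    RCbray = 2·[(#{BC_null < BC_obs} + ½·#{BC_null = BC_obs}) / n_null] − 1,
    with null pairs drawn independently per pair of samples (richness and
    library size preserved; taxa by occurrence frequency, individuals by
    metacommunity relative abundance). The metacommunity defaults to
    ``cm`` itself; pass ``reference`` to evaluate samples against a wider
    species pool (its OTU columns must match ``cm``).
    """
    counts = cm.counts.to_numpy()
    n_samp, n_taxa = counts.shape
    if reference is not None:
        if list(reference.otu_ids) != list(cm.otu_ids):
            raise ValueError("reference OTU columns must match the community matrix")
        occ, ab = metacommunity_weights(reference)
    else:
        occ, ab = metacommunity_weights(cm)
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if (richness > (occ > 0).sum()).any():
        raise ValueError("sample richness exceeds metacommunity richness")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_samp, n_samp))
    s1 = np.zeros(n_taxa)
    s2 = np.zeros(n_taxa)
    for k in range(n_samp):
        for l in range(k + 1, n_samp):
            denom_obs = totals[k] + totals[l]
            bc_obs = np.abs(counts[k] - counts[l]).sum() / denom_obs
            less = ties = 0
            for _ in range(n_null):
                a = null_assemblage(occ, ab, richness[k], totals[k], rng, s1)
                b = null_assemblage(occ, ab, richness[l], totals[l], rng, s2)
                bc = np.abs(a - b).sum() / denom_obs
                if bc < bc_obs - 1e-12:
                    less += 1
                elif bc <= bc_obs + 1e-12:
                    ties += 1
            rc = 2.0 * ((less + 0.5 * ties) / n_null) - 1.0
            out[k, l] = out[l, k] = rc
    return pd.DataFrame(out, index=cm.sample_ids, columns=cm.sample_ids)


# --------------------------------------------------------------------------
# Five-way process classification
# --------------------------------------------------------------------------

@dataclass
class AssemblyResult:
    """Per-pair indices and process labels plus the percentage partition."""

    pairs: pd.DataFrame          # sample1, sample2, bnti, rcbray, process
    fractions: pd.Series         # % of non-NA pairs per process
    n_pairs: int
    n_na: int


def classify_pair(bnti: float, rc: float) -> str:
    """Process label for one sample pair; thresholds are strict, and
    selection (|βNTI| > 2) is checked before dispersal."""
    if np.isnan(bnti) or np.isnan(rc):
        return "na"
    if bnti < -2:
        return "homogeneous_selection"
    if bnti > 2:
        return "heterogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogeneous_dispersal"
    return "undominated"


def classify_processes(bnti: pd.DataFrame, rc: pd.DataFrame) -> AssemblyResult:
    """Combine βNTI and RCbray into the five-process partition.

    Fractions are percentages of the non-NA upper-triangle pairs and sum
    to 100.
    """
    if list(bnti.index) != list(rc.index):
        raise ValueError("betaNTI and RCbray matrices are not aligned")
    ids = list(bnti.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = float(bnti.iloc[i, j])
            r = float(rc.iloc[i, j])
            rows.append(
                {"sample1": ids[i], "sample2": ids[j], "bnti": b,
                 "rcbray": r, "process": classify_pair(b, r)}
            )
    pairs = pd.DataFrame(rows)
    ok = pairs["process"] != "na"
    n_na = int((~ok).sum())
    if n_na:
        logger.warning("%d pair(s) excluded from fractions (NaN indices)", n_na)
    counts = pairs.loc[ok, "process"].value_counts()
    fractions = pd.Series(
        {p: 100.0 * counts.get(p, 0) / max(ok.sum(), 1) for p in PROCESSES},
        name="percent",
    )
    return AssemblyResult(pairs=pairs, fractions=fractions,
                          n_pairs=int(ok.sum()), n_na=n_na)


# --------------------------------------------------------------------------
# betaNTI vs environmental differences
# --------------------------------------------------------------------------

def bnti_env_correlation(
    bnti: pd.DataFrame,
    env: pd.DataFrame,
    variables=None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of pairwise βNTI against Δ(environment).

    For each variable, Δ is the absolute pairwise difference matrix; ρ
    is Spearman between the upper triangles and p comes from a
    Mantel-style joint permutation of sample labels. Constant variables
    yield NaN.
    """
    env = env.loc[bnti.index]
    variables = list(variables) if variables is not None else list(env.columns)
    n = len(bnti)
    iu = np.triu_indices(n, k=1)
    b = bnti.to_numpy()
    bvec = b[iu]
    ok_pairs = ~np.isnan(bvec)
    rng = np.random.default_rng(seed)
    rows = []
    for var in variables:
        v = env[var].to_numpy(float)
        delta = np.abs(v[:, None] - v[None, :])
        dvec = delta[iu]
        if np.ptp(v) == 0 or ok_pairs.sum() < 3:
            rows.append({"variable": var, "rho": np.nan, "p": np.nan})
            continue
        rho, _ = stats.spearmanr(bvec[ok_pairs], dvec[ok_pairs])
        hits = 1
        for _ in range(n_perm):
            perm = rng.permutation(n)
            dp = delta[np.ix_(perm, perm)][iu]
            rp, _ = stats.spearmanr(bvec[ok_pairs], dp[ok_pairs])
            if abs(rp) >= abs(rho):
                hits += 1
        rows.append({"variable": var, "rho": float(rho), "p": hits / (n_perm + 1)})
    return pd.DataFrame(rows)
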