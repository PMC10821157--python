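"""Environmental-driver attribution for community tables.

The workflow mirrors standard constrained-ordination practice: screen
explanatory variables by variance inflation (VIF < 10), run redundancy
analysis (RDA) on Hellinger-transformed counts with permutation tests
per factor, derive spatial eigenfunctions from geographic coordinates
(PCNM), and partition community variation between spatial and water
physicochemical variable sets with adjusted-R² inclusion–exclusion
(VPA).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .io import CommunityMatrix

__all__ = ["hellinger", "vif_filter", "rda", "pcnm", "vpa"]

EARTH_RADIUS_KM = 6371.0


def hellinger(cm: CommunityMatrix) -> pd.DataFrame:
    """Hellinger transform: square root of relative abundances."""
    return np.sqrt(cm.relative_abundance())


def _standardize(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(float)
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(X.columns[sd == 0])
        raise ValueError(f"constant explanatory column(s): {bad}")
    return (arr - arr.mean(axis=0)) / sd


def vif_filter(env: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    VIF_j = 1 / (1 - R²_j) where R²_j regresses variable j on the others
    (with intercept). Ties are broken alphabetically; the retained
    variable names are returned in the original column order.
    """
    cols = list(env.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    if len(env) <= 2:
        raise ValueError("need more than 2 samples")

    def vif_of(sub: pd.DataFrame) -> pd.Series:
        X = _standardize(sub)
        out = {}
        for j, col in enumerate(sub.columns):
            others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            ss_tot = (X[:, j] ** 2).sum()
            r2 = 1 - resid @ resid / ss_tot
            out[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    while len(cols) > 1:
        v = vif_of(env[cols])
        if (v < threshold).all():
            break
        worst = v.max()
        candidates = sorted(v.index[v == worst])
        cols.remove(candidates[0])
    return [c for c in env.columns if c in cols]


def _fitted_ss(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of squares of the OLS fit of centered Y on centered X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    yhat = X @ beta
    return float((yhat**2).sum())


def rda(
    cm: CommunityMatrix,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    transform: str = "hellinger",
):
    """Redundancy analysis of the community on environmental variables.

    The community is Hellinger-transformed (flaggable) and centered; the
    explanatory matrix is z-standardized. Constrained axes are the PCA of
    the fitted values of the multivariate regression. Per-factor
    significance is envfit-style: the marginal R² of each variable alone
    against ``n_perm`` row permutations of that variable.

    Returns a dict with site scores, eigenvalues, the total constrained
    proportion, and a per-factor table (R², permutation p).
    """
    env = env.loc[cm.sample_ids]
    n = cm.n_samples
    if env.shape[1] > n - 1:
        raise ValueError("more constraints than samples - 1")
    if transform == "hellinger":
        Yd = hellinger(cm)
    elif transform == "relative":
        Yd = cm.relative_abundance()
    elif transform == "none":
        Yd = cm.counts
    else:
        raise ValueError("transform must be 'hellinger', 'relative' or 'none'")
    Y = Yd.to_numpy(float)
    Y = Y - Y.mean(axis=0)
    X = _standardize(env)
    ss_tot = float((Y**2).sum())

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    yhat = X @ beta
    u, s, vt = np.linalg.svd(yhat, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > 1e-12 * max(eig[0], 1.0) if len(eig) else np.zeros(0, bool)
    eig = eig[keep]
    scores = u[:, keep] * s[keep]
    constrained = float((yhat**2).sum()) / ss_tot

    rng = np.random.default_rng(seed)
    rows = []
    for j, col in enumerate(env.columns):
        xj = X[:, [j]]
        r2 = _fitted_ss(Y, xj) / ss_tot
        hits = 1
        for _ in range(n_perm):
            r2p = _fitted_ss(Y, xj[rng.permutation(n)]) / ss_tot
            hits += r2p >= r2
        rows.append({"factor": col, "r2": r2, "p": hits / (n_perm + 1)})

    axes = [f"RDA{i + 1}" for i in range(scores.shape[1])]
    return {
        "scores": pd.DataFrame(scores, index=cm.sample_ids, columns=axes),
        "eigenvalues": pd.Series(eig, index=axes),
        "constrained_proportion": constrained,
        "factors": pd.DataFrame(rows),
    }


def _haversine(lonlat: np.ndarray) -> np.ndarray:
    lon = np.radians(lonlat[:, 0])[:, None]
    lat = np.radians(lonlat[:, 1])[:, None]
    dlon = lon - lon.T
    dlat = lat - lat.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pcnm(coords: pd.DataFrame, metric: str = "haversine") -> pd.DataFrame:
    """Principal coordinates of neighbour matrices (spatial eigenfunctions).

    ``coords`` holds longitude/latitude (degrees; ``metric="haversine"``,
    great-circle km) or planar x/y (``metric="planar"``). The distance
    matrix is truncated at the largest minimum-spanning-tree edge;
    beyond-threshold distances are replaced by 4× the threshold. The
    unit-norm eigenvectors of the Gower-centered truncated matrix with
    positive eigenvalues are returned as spatial variables PCNM1, ...
    """
    xy = coords.to_numpy(float)
    if len(xy) < 3:
        raise ValueError("need at least 3 samples")
    if metric == "haversine":
        d = _haversine(xy)
    elif metric == "planar":
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
    else:
        raise ValueError("metric must be 'haversine' or 'planar'")
    if d.max() == 0:
        raise ValueError("all samples at the same location")
    mst = minimum_spanning_tree(d).toarray()
    threshold = mst.max()
    trunc = np.where(d <= threshold, d, 4 * threshold)
    np.fill_diagonal(trunc, 0.0)
    a = -0.5 * trunc**2
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-8 * max(evals.max(), 1.0)
    vecs = evecs[:, pos]
    # sign convention: first nonzero loading positive, so output is stable
    for k in range(vecs.shape[1]):
        nz = np.flatnonzero(np.abs(vecs[:, k]) > 1e-12)
        if len(nz) and vecs[nz[0], k] < 0:
            vecs[:, k] = -vecs[:, k]
    return pd.DataFrame(
        vecs, index=coords.index, columns=[f"PCNM{i + 1}" for i in range(vecs.shape[1])]
    )


def _adj_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


def _effective_rank(X: pd.DataFrame) -> int:
    """Rank of the standardized design; warn naming collinear columns.

    Degrees of freedom in the adjusted R² use the rank, not the column
    count, so fully redundant sets (e.g. S duplicated as W) partition
    into a pure fraction of ~0 and a shared fraction equal to the
    single-set adjusted R² rather than erroring out.
    """
    arr = _standardize(X)
    rank = int(np.linalg.matrix_rank(arr, tol=1e-8))
    if rank < arr.shape[1]:
        bad = []
        for j in range(1, arr.shape[1]):
            if np.linalg.matrix_rank(arr[:, : j + 1], tol=1e-8) <= np.linalg.matrix_rank(
                arr[:, :j], tol=1e-8
            ):
                bad.append(X.columns[j])
        import logging

        logging.getLogger("lakemicro").warning(
            "rank-deficient explanatory matrix; redundant column(s): %s", bad
        )
    return rank


def vpa(cm: CommunityMatrix, spatial: pd.DataFrame, water: pd.DataFrame) -> dict:
    """Variation partitioning between spatial (S) and water (W) variable sets.

    Fractions are adjusted R² (Ezekiel):
    pure_S = adjR²(S∪W) − adjR²(W); pure_W = adjR²(S∪W) − adjR²(S);
    shared = adjR²(S) + adjR²(W) − adjR²(S∪W);
    residual = 1 − adjR²(S∪W). They sum to 1 identically and may be
    slightly negative, as adjusted R² fractions are.
    """
    if spatial.shape[1] == 0 or water.shape[1] == 0:
        raise ValueError("both variable sets must be non-empty")
    spatial = spatial.loc[cm.sample_ids]
    water = water.loc[cm.sample_ids]
    spatial = spatial.rename(columns=lambda c: f"S::{c}")
    water = water.rename(columns=lambda c: f"W::{c}")
    both = pd.concat([spatial, water], axis=1)
    Y = hellinger(cm).to_numpy(float)
    Y = Y - Y.mean(axis=0)
    ss_tot = float((Y**2).sum())
    n = len(Y)

    def adj(X: pd.DataFrame) -> float:
        r2 = _fitted_ss(Y, _standardize(X)) / ss_tot
        return _adj_r2(r2, n, _effective_rank(X))

    a_s, a_w, a_sw = adj(spatial), adj(water), adj(both)
    return {
        "pure_spatial": a_sw - a_w,
        "pure_water": a_sw - a_s,
        "shared": a_s + a_w - a_sw,
        "residual": 1 - a_sw,
    }
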