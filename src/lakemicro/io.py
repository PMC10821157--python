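"""Reading, writing and validation of the three input tables.

The package works on three objects throughout:

* :class:`CommunityMatrix` — samples × OTUs integer counts plus a lake
  (group) label per sample, wrapping a pandas DataFrame;
* an environment table — a numeric pandas DataFrame indexed by sample,
  returned by :func:`read_env`;
* a phylogeny — an :class:`skbio.TreeNode` with branch lengths, whose tip
  names are OTU identifiers.

Input tables follow the common amplicon convention of OTUs as rows and
samples as columns; ``orientation="samples"`` flips that.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("lakemicro")

__all__ = [
    "CommunityMatrix",
    "read_community",
    "write_community",
    "read_tree",
    "read_env",
    "align_samples",
    "rarefy",
]


@dataclass
class CommunityMatrix:
    """Samples × OTUs non-negative integer counts with group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are OTU ids, integer
        counts >= 0. Every sample must have a positive total.
    groups
        Lake/group label per sample (e.g. ``L1``…``L8``). When omitted,
        the prefix of the sample id before the first ``_`` or ``-`` is
        used.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU identifiers: {dup}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            frac, _ = np.modf(arr.astype(float))
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {c.index[i]!r}, OTU {c.columns[j]!r}: "
                    f"{arr[i, j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
            )
        if (arr.sum(axis=1) == 0).any():
            empty = c.index[arr.sum(axis=1) == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        if self.groups is None:
            self.groups = pd.Series(
                [str(s).replace("-", "_").split("_")[0] for s in c.index],
                index=c.index,
                name="group",
            )
        else:
            self.groups = pd.Series(self.groups, name="group").reindex(c.index)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()].tolist()
                raise ValueError(f"samples without a group label: {missing}")

    # -- convenience views ------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised relative abundances."""
        return self.counts.div(self.counts.sum(axis=1), axis=0)

    def drop_empty_otus(self) -> "CommunityMatrix":
        keep = self.counts.sum(axis=0) > 0
        if not keep.all():
            dropped = self.counts.columns[~keep].tolist()
            logger.warning("dropping %d all-zero OTU column(s): %s",
                           len(dropped), dropped[:10])
        return CommunityMatrix(self.counts.loc[:, keep], self.groups)

    def subset_samples(self, sample_ids) -> "CommunityMatrix":
        cm = CommunityMatrix(self.counts.loc[list(sample_ids)],
                             self.groups.loc[list(sample_ids)])
        return cm.drop_empty_otus()


def read_community(path, orientation: str = "otus", groups=None) -> CommunityMatrix:
    """Read a tab-separated OTU table.

    ``orientation="otus"`` (default) expects OTUs as rows, samples as
    columns; ``"samples"`` the transpose. All-zero rows/columns are
    dropped with a logged warning; non-integer cells and duplicate
    identifiers are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"duplicate identifiers in {path}")
    if orientation == "otus":
        df = df.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'otus' or 'samples'")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise ValueError(f"non-numeric count at sample {bad!r}, OTU {col!r}")
        frac = vals - np.floor(vals)
        if (frac != 0).any():
            bad = df.index[(frac != 0)][0]
            raise ValueError(
                f"non-integer count at sample {bad!r}, OTU {col!r}: {df.loc[bad, col]!r}"
            )
    df = df.astype(np.int64)
    df.index.name = None
    df.columns.name = None
    row_tot = df.sum(axis=1)
    if (row_tot == 0).any():
        empty = df.index[row_tot == 0].tolist()
        logger.warning("dropping %d all-zero sample row(s): %s", len(empty), empty)
        df = df.loc[row_tot > 0]
    return CommunityMatrix(df, groups).drop_empty_otus()


def write_community(cm: CommunityMatrix, path, orientation: str = "otus") -> None:
    """Write counts as TSV (OTUs as rows by default); exact round-trip."""
    df = cm.counts.T if orientation == "otus" else cm.counts
    df.to_csv(path, sep="\t", index_label="#OTU_ID" if orientation == "otus" else "#Sample_ID")


def read_tree(source, prune_to=None) -> TreeNode:
    """Read a rooted Newick tree with non-negative branch lengths.

    Parameters
    ----------
    source
        Path or Newick string.
    prune_to
        Optional iterable of tip names; the tree is sheared to that set.
    """
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read(_io.StringIO(source))
    else:
        tree = TreeNode.read(str(source))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length ({node.length}) at {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip names in tree")
    if prune_to is not None:
        want = set(prune_to)
        missing = want - set(tips)
        if missing:
            raise ValueError(f"tips absent from tree: {sorted(missing)[:10]}")
        tree = tree.shear(want)
        tree.prune()
    return tree


def read_env(path) -> pd.DataFrame:
    """Read per-sample environmental metadata (TSV, samples as rows).

    All columns are coerced to numeric; cells that fail coercion become
    NaN with a logged warning so missingness is explicit, never silent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample identifiers in {path}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        n_bad = int(vals.isna().sum() - df[col].isna().sum())
        if n_bad:
            logger.warning("column %r: %d non-numeric cell(s) set to NaN", col, n_bad)
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def align_samples(cm: CommunityMatrix, env: pd.DataFrame):
    """Inner-join community and metadata on sample id.

    Samples present on only one side are dropped with a logged count —
    never silently.
    """
    shared = [s for s in cm.sample_ids if s in env.index]
    n_cm = cm.n_samples - len(shared)
    n_env = len(env.index) - len(shared)
    if n_cm or n_env:
        logger.warning(
            "inner join dropped %d community-only and %d metadata-only sample(s)",
            n_cm, n_env,
        )
    if not shared:
        raise ValueError("no shared samples between community matrix and metadata")
    return cm.subset_samples(shared), env.loc[shared]


def rarefy(cm: CommunityMatrix, depth: int | None = None, seed: int = 0) -> CommunityMatrix:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum library size. Off by default in the
    pipeline; exposed because practice varies between labs.
    """
    rng = np.random.default_rng(seed)
    depth = int(depth or cm.counts.sum(axis=1).min())
    if (cm.counts.sum(axis=1) < depth).any():
        raise ValueError("rarefaction depth exceeds a library size")
    out = np.zeros_like(cm.counts.to_numpy())
    for i, (_, row) in enumerate(cm.counts.iterrows()):
        pool = np.repeat(np.arange(cm.n_otus), row.to_numpy())
        take = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(take, minlength=cm.n_otus)
    cmr = CommunityMatrix(
        pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns),
        cm.groups,
    )
    return cmr.drop_empty_otus()
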