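"""Data model and readers/writers for OTU tables, trees, metadata and environment tables.

Conventions: OTUs are rows and samples are columns in every file and matrix.
OTU tables are tab-separated with a ``#OTU_ID`` first column; trees are Newick;
metadata and environment tables are TSV keyed by sample id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "CountMatrix",
    "RelAbundanceMatrix",
    "Phylogeny",
    "GroupMap",
    "EnvTable",
    "read_counts",
    "write_counts",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_env",
    "write_env",
    "to_relative_abundance",
    "rarefy",
]

OTU_ID_HEADER = "#OTU_ID"


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer OTU x sample abundance table.

    Parameters
    ----------
    otu_ids : list of str
        Unique row labels.
    sample_ids : list of str
        Unique column labels.
    counts : ndarray of int, shape (n_otus, n_samples)
        Non-negative read counts.
    """

    otu_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(map(str, self.otu_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = np.argwhere(np.abs(counts - rounded) > 1e-9)
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"non-integer count at OTU {self.otu_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {counts[i, j]!r}"
                )
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        self.counts = counts.astype(np.int64)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def drop_empty_otus(self) -> "CountMatrix":
        """Remove OTUs with zero total count."""
        keep = self.counts.sum(axis=1) > 0
        return CountMatrix(
            [o for o, k in zip(self.otu_ids, keep) if k],
            self.sample_ids,
            self.counts[keep],
        )

    def select_samples(self, sample_ids) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(self.otu_ids, list(sample_ids), self.counts[:, idx])


@dataclass
class RelAbundanceMatrix:
    """Relative-abundance table: same layout as :class:`CountMatrix`, columns sum to 1."""

    otu_ids: list
    sample_ids: list
    rel: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = list(map(str, self.otu_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        rel = np.asarray(self.rel, dtype=float)
        if rel.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("rel shape does not match id lists")
        if (rel < -1e-12).any() or (rel > 1 + 1e-12).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        colsums = rel.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"sample {self.sample_ids[j]!r} column sums to {colsums[j]}, expected 1"
            )
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        self.rel = rel

    @property
    def shape(self) -> tuple:
        return self.rel.shape

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.rel, index=self.otu_ids, columns=self.sample_ids)


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths over OTU tip labels (wraps ``skbio.TreeNode``)."""

    tree: TreeNode

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(tips) < 2:
            raise ValueError("tree must have at least 2 tips")
        _check_unique(tips, "tip")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                warnings.warn("branch without length assigned 0", stacklevel=2)
                node.length = 0.0
            elif node.length < 0:
                raise ValueError(f"negative branch length at node {node.name!r}")
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def tip_names(self) -> list:
        return [t.name for t in self.tree.tips()]

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.tree.traverse(include_self=False))

    def tip_distance_matrix(self, order=None) -> pd.DataFrame:
        """Patristic tip-to-tip distances as a DataFrame (optionally reordered)."""
        dm = self.tree.tip_tip_distances()
        df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        if order is not None:
            df = df.loc[list(order), list(order)]
        return df

    def check_covers(self, otu_ids) -> None:
        """Error listing OTU ids that are not tips of the tree."""
        missing = sorted(set(otu_ids) - set(self.tip_names))
        if missing:
            raise ValueError(f"OTU ids missing from tree: {', '.join(missing)}")

    def prune_to(self, otu_ids) -> "Phylogeny":
        """Return the subtree spanning ``otu_ids`` (explicit pruning; count logged)."""
        keep = set(otu_ids)
        n_removed = len(set(self.tip_names) - keep)
        sub = self.tree.shear(sorted(keep))
        warnings.warn(f"pruned {n_removed} tips absent from the OTU table", stacklevel=2)
        return Phylogeny(sub)


@dataclass
class GroupMap:
    """Mapping sample id -> group label (e.g. DJ / XJ / PC)."""

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = {str(k): str(v) for k, v in self.mapping.items()}

    @property
    def sample_ids(self) -> list:
        return list(self.mapping)

    def groups(self) -> list:
        seen = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list:
        return [s for s, g in self.mapping.items() if g == group]

    def labels_for(self, sample_ids) -> list:
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(f"samples missing from metadata: {', '.join(missing)}")
        return [self.mapping[s] for s in sample_ids]

    def validate_against(self, counts: CountMatrix, min_per_group: int = 2) -> None:
        self.labels_for(counts.sample_ids)
        present = [s for s in counts.sample_ids]
        for g in {self.mapping[s] for s in present}:
            n = sum(1 for s in present if self.mapping[s] == g)
            if n < min_per_group:
                raise ValueError(f"group {g!r} has {n} sample(s); need >= {min_per_group}")


@dataclass
class EnvTable:
    """Sample x variable table of environmental measurements (TEM, DO, pH, TN, TP)."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_unique(self.data.columns, "environment variable")
        _check_unique(self.data.index, "sample")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list:
        return list(self.data.columns)

    def require_complete(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"samples missing from environment table: {', '.join(missing)}")
        sub = self.data.loc[list(sample_ids)]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise ValueError(f"missing environment values in variables: {', '.join(bad)}")
        return sub


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
    _check_unique(header[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.map(str)
    return df


def read_counts(path) -> CountMatrix:
    """Read a tab-separated OTU table (rows OTUs, columns samples, integer cells)."""
    df = _read_table(path)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate OTU id: {dup[0]!r}")
    return CountMatrix.from_dataframe(df)


def write_counts(counts: CountMatrix, path) -> None:
    counts.df.to_csv(path, sep="\t", index_label=OTU_ID_HEADER)


def read_tree(path) -> Phylogeny:
    """Read a single rooted Newick tree; tips without branch lengths get 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # re-raise with file context; parser reports position
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree)


def write_tree(phy: Phylogeny, path) -> None:
    phy.tree.write(str(path), format="newick")


def read_metadata(path) -> GroupMap:
    df = _read_table(path)
    if "group" not in df.columns:
        raise ValueError("metadata file must have a 'group' column")
    return GroupMap(df["group"].to_dict())


def write_metadata(groups: GroupMap, path) -> None:
    pd.DataFrame({"group": pd.Series(groups.mapping)}).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_env(path) -> EnvTable:
    df = _read_table(path)
    return EnvTable(df.astype(float))


def write_env(env: EnvTable, path) -> None:
    env.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization


def to_relative_abundance(counts: CountMatrix) -> RelAbundanceMatrix:
    """Total-sum scaling: each sample column divided by its read total."""
    totals = counts.sample_sums().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero total count")
    return RelAbundanceMatrix(counts.otu_ids, counts.sample_ids, counts.counts / totals)


def rarefy(counts: CountMatrix, depth: int, seed: int) -> CountMatrix:
    """Subsample each sample to ``depth`` reads without replacement (fixed seed).

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = counts.sample_sums()
    keep_cols, data = [], []
    for j, sid in enumerate(counts.sample_ids):
        if totals[j] < depth:
            warnings.warn(f"sample {sid!r} dropped: {totals[j]} < depth {depth}", stacklevel=2)
            continue
        data.append(rng.multivariate_hypergeometric(counts.counts[:, j], depth))
        keep_cols.append(sid)
    if not keep_cols:
        raise ValueError("no sample reaches the rarefaction depth")
    return CountMatrix(counts.otu_ids, keep_cols, np.column_stack(data))
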