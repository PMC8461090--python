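"""Count-table, tree and metadata I/O, validation, rarefaction.

The central object is :class:`CommunityTable`, a samples × taxa matrix of
nonnegative integer read counts (OTU/ASV table). Trees are handled as
``skbio.TreeNode`` and metadata as a validated ``pandas.DataFrame``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Factor levels permitted in sample metadata.
METADATA_LEVELS = {
    "membrane_type": {"POX", "PTA", "SPTA", "SPSU", "COM", "MLSS"},
    "surface_character": {"hydrophobic", "hydrophilic", "n/a"},
    "flux": {"flux", "no-flux", "n/a"},
    "day": {1, 10, 20, 30},
    "compartment": {"biofilm", "MLSS"},
    "nucleic": {"DNA", "cDNA"},
}

METADATA_COLUMNS = [
    "sample_id",
    "membrane_type",
    "surface_character",
    "flux",
    "day",
    "compartment",
    "nucleic",
]


class ValidationError(ValueError):
    """Raised when an input table, tree or metadata violates an invariant."""


@dataclass
class CommunityTable:
    """Samples × taxa table of nonnegative integer counts.

    Parameters
    ----------
    sample_ids : list of str
        Ordered unique sample identifiers (rows).
    taxon_ids : list of str
        Ordered unique taxon identifiers (columns).
    counts : ndarray of shape (n_samples, n_taxa)
        Nonnegative integer read counts.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"taxon {self.taxon_ids[bad[1]]!r}"
                )
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxon_ids[bad[1]]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        self.counts = counts

    # -- basic views -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CommunityTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, keep: list[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CommunityTable(keep, self.taxon_ids, self.counts[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


# -- count-table I/O -------------------------------------------------------


def read_count_table(path, samples_as_rows: bool = False) -> CommunityTable:
    """Read a tab-separated count table.

    On disk the conventional orientation is taxa as rows and samples as
    columns; pass ``samples_as_rows=True`` if the file is already oriented
    samples × taxa. The returned table is always samples × taxa.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty count table")
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return CommunityTable.from_dataframe(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_table(table: CommunityTable, path, samples_as_rows: bool = False) -> None:
    """Write a count table as TSV (taxa as rows by default)."""
    df = table.to_dataframe()
    if not samples_as_rows:
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


# -- tree I/O --------------------------------------------------------------


def read_tree(path, expected_taxa=None) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    ``expected_taxa`` (optional) is checked against the tip set: every
    expected taxon must be a tip label (exact string match).
    """
    source = path if hasattr(path, "read") else str(path)
    tree = TreeNode.read(source, format="newick")
    return validate_tree(tree, expected_taxa)


def validate_tree(tree: TreeNode, expected_taxa=None) -> TreeNode:
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValidationError("tree has fewer than 2 tips")
    tip_names = {t.name for t in tips}
    if None in tip_names:
        raise ValidationError("tree has unnamed tips")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError("tree has edges without branch lengths")
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    if expected_taxa is not None:
        missing = sorted(set(map(str, expected_taxa)) - tip_names)
        if missing:
            raise ValidationError(
                f"{len(missing)} taxa missing from tree: {missing[:10]}"
                + ("…" if len(missing) > 10 else "")
            )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# -- metadata I/O ----------------------------------------------------------


def read_metadata(path) -> pd.DataFrame:
    """Read and validate a tab-separated sample-metadata table."""
    # keep_default_na: the literal level "n/a" must survive the round-trip
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    df = df.copy()
    df["day"] = df["day"].astype(int)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    for col, levels in METADATA_LEVELS.items():
        bad = set(df[col]) - levels
        if bad:
            raise ValidationError(f"metadata column {col!r} has invalid levels {sorted(map(str, bad))}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def join_metadata(table: CommunityTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Return metadata aligned to the table's samples (inner order of table)."""
    meta = metadata.set_index("sample_id")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:10]}")
    return meta.loc[table.sample_ids].reset_index()


# -- transforms ------------------------------------------------------------


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Subsampling is multivariate-hypergeometric (each sample's reads are a
    finite pool drawn without replacement), matching physical subsampling of
    sequenced reads. Samples with fewer than ``depth`` total reads are
    dropped with a warning. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be ≥ 1, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise ValidationError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    rows = []
    ids = []
    for i, sid in enumerate(table.sample_ids):
        if not keep[i]:
            continue
        if sums[i] == depth:
            rows.append(table.counts[i].copy())
        else:
            rows.append(rng.multivariate_hypergeometric(table.counts[i], depth))
        ids.append(sid)
    return CommunityTable(ids, table.taxon_ids, np.asarray(rows))


def samples_below_depth(table: CommunityTable, depth: int) -> list[str]:
    """Sample ids that would be dropped by :func:`rarefy` at ``depth``."""
    sums = table.sample_sums()
    return [s for s, n in zip(table.sample_ids, sums) if n < depth]


def relative_abundance(table: CommunityTable) -> np.ndarray:
    """Row-normalised proportions; every row sums to 1."""
    sums = table.sample_sums().astype(float)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(f"zero-sum sample {table.sample_ids[zero[0]]!r}")
    return table.counts / sums[:, None]
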