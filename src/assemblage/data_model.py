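"""Core data containers and I/O.

Everything downstream consumes three objects: an :class:`OtuTable` of
non-negative integer counts (taxa x samples), a rooted phylogeny with branch
lengths covering the table's taxa (a :class:`skbio.TreeNode`), and a sample
metadata table (station, month, coordinates, environmental variables).
Square distance matrices are carried as :class:`skbio.DistanceMatrix`, which
enforces symmetry and a zero diagonal on construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

logger = logging.getLogger("assemblage")

#: Environmental variables measured per sample (units in the metadata docs).
ENV_VARIABLES = [
    "Temp", "Salinity", "Conductivity", "DO", "pH", "SRP", "COD",
    "Nitrite", "Nitrate", "AN", "DIN", "un_ionN", "Depth", "Trans", "Chl_a",
]

#: Metadata columns that are not environmental measurements.
ID_COLUMNS = ["station", "month", "replicate", "longitude", "latitude"]


class FormatError(ValueError):
    """A file's contents violate the expected format."""


class ValidationError(ValueError):
    """An object violates a structural invariant."""


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Non-negative integer OTU/ASV count matrix, taxa as rows.

    Parameters
    ----------
    taxon_ids : list of str
        Unique row labels.
    sample_ids : list of str
        Unique column labels.
    counts : ndarray of int, shape (n_taxa, n_samples)
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dup = _first_duplicate(self.taxon_ids)
            raise ValidationError(f"duplicate taxon id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")

    # -- basic views --------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            zero = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {zero!r} has zero total count")
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(list(self.taxon_ids), list(sample_ids),
                        self.counts[:, idx])

    def select_taxa(self, taxon_ids: list[str]) -> "OtuTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return OtuTable(list(taxon_ids), list(self.sample_ids),
                        self.counts[idx, :])


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate")  # pragma: no cover


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_otu_table(path, taxa_as_rows: bool = True) -> OtuTable:
    """Read a TSV count table (header = sample ids, first column = taxon ids).

    Set ``taxa_as_rows=False`` for the transposed layout (samples as rows).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not taxa_as_rows:
        df = df.T
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise FormatError(
                f"non-numeric count in sample {col!r}, taxon {bad.index[0]!r}"
            )
    return OtuTable.from_dataframe(df)


def write_otu_table(table: OtuTable, path, taxa_as_rows: bool = True) -> None:
    df = table.to_dataframe()
    if not taxa_as_rows:
        df = df.T
    df.index.name = "taxon_id" if taxa_as_rows else "sample_id"
    df.to_csv(path, sep="\t")


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree; tips lacking branch lengths get length 0."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("%d branches had no length; set to 0", n_missing)
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(map(str, df.index)))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def check_tree_coverage(table: OtuTable, tree: TreeNode) -> None:
    """Raise if any table taxon is missing from the tree's tip set."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(table.taxon_ids) - tips)
    if missing:
        raise ValidationError(
            f"{len(missing)} taxa missing from tree: {missing[:10]}"
        )


def validate_metadata(table: OtuTable, metadata: pd.DataFrame,
                      months: list[str] | None = None) -> None:
    """Check every sample has a metadata row with legal month/coordinates."""
    missing = sorted(set(table.sample_ids) - set(metadata.index))
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:10]}")
    if months is not None:
        bad = set(metadata.loc[table.sample_ids, "month"]) - set(months)
        if bad:
            raise ValidationError(f"unknown month labels: {sorted(bad)}")
    for col in ("longitude", "latitude"):
        if col in metadata.columns:
            vals = metadata.loc[table.sample_ids, col].to_numpy(float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"non-finite {col}")


# ---------------------------------------------------------------------------
# Rarefaction and abundance filtering
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped (and logged). The
    subsample per sample is a multivariate-hypergeometric draw, so each
    retained cell is bounded by the original count and column sums equal
    ``depth`` exactly. Reproducible for a fixed ``seed``.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    new_cols = []
    kept_ids = []
    for j, sid in enumerate(table.sample_ids):
        if not keep[j]:
            continue
        col = table.counts[:, j]
        if totals[j] == depth:
            new_cols.append(col.copy())
        else:
            new_cols.append(rng.multivariate_hypergeometric(col, depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(list(table.taxon_ids), kept_ids,
                    np.column_stack(new_cols))


def filter_by_mean_relative_abundance(table: OtuTable,
                                      threshold: float) -> OtuTable:
    """Keep taxa whose pooled relative abundance strictly exceeds ``threshold``.

    Pooled relative abundance = taxon total / grand total. The comparison is
    strict (a taxon sitting exactly at the threshold is removed), and taxon
    order is preserved.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    grand = table.counts.sum()
    frac = table.taxon_totals() / grand
    keep = frac > threshold
    if not keep.any():
        logger.warning("abundance filter at %g removed every taxon", threshold)
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return OtuTable(kept, list(table.sample_ids), table.counts[keep, :])


# ---------------------------------------------------------------------------
# Environmental / geographic distances
# ---------------------------------------------------------------------------

def euclidean_distance(metadata: pd.DataFrame, columns: list[str],
                       standardize: bool = True,
                       impute_mean: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distance over selected (optionally z-scored) columns.

    Missing values raise by default; pass ``impute_mean=True`` to replace them
    with the column mean (logged).
    """
    sub = metadata[columns].astype(float).copy()
    if sub.isna().any().any():
        if not impute_mean:
            col = sub.columns[sub.isna().any().argmax()]
            sample = sub.index[sub[col].isna().argmax()]
            raise ValidationError(
                f"missing value for variable {col!r} in sample {sample!r}"
            )
        logger.info("imputing missing values by column means in %s",
                    list(sub.columns[sub.isna().any()]))
        sub = sub.fillna(sub.mean())
    X = sub.to_numpy()
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = sub.columns[int(np.argmax(sd == 0))]
            raise ValidationError(f"constant variable {const!r} cannot be z-scored")
        X = (X - X.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(d, ids=list(map(str, sub.index)))


def geographic_distance(metadata: pd.DataFrame,
                        great_circle: bool = False) -> DistanceMatrix:
    """Pairwise geographic distance from longitude/latitude.

    Default is plain Euclidean distance on decimal degrees; pass
    ``great_circle=True`` for haversine distances in kilometres.
    """
    lon = metadata["longitude"].to_numpy(float)
    lat = metadata["latitude"].to_numpy(float)
    if not great_circle:
        return euclidean_distance(metadata, ["longitude", "latitude"],
                                  standardize=False)
    r_earth = 6371.0
    lam, phi = np.radians(lon), np.radians(lat)
    dlam = lam[:, None] - lam[None, :]
    dphi = phi[:, None] - phi[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    d = 2 * r_earth * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(d, ids=list(map(str, metadata.index)))
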