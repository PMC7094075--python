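"""Domain types and file IO for the four analysis artifacts.

The analysis operates on an id-aligned bundle of four objects: an ASV
count table (features x samples), a rooted phylogeny whose tips are the
ASV ids, a taxonomy table (phylum..genus per ASV), and per-sample
metadata describing the paired sampling design (plant species, organ,
community type, site, replicate, specimen). All tabular artifacts are
plain TSV; trees are newick; networks export as edge-TSV or GraphML.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("paramicro")

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

#: community-type code -> (species, organ). "I" prefixed codes are from
#: infected patches; "U" from uninfected patches; "P" is the parasite.
COMMUNITY_TYPES = {
    "PL": ("parasite", "leaf"),
    "PR": ("parasite", "root"),
    "IL": ("host", "leaf"),
    "IIR": ("host", "root"),
    "IUR": ("host", "root"),
    "UL": ("host", "leaf"),
    "UR": ("host", "root"),
    "SOIL": ("soil", "soil"),
}

METADATA_COLUMNS = (
    "species",
    "organ",
    "community_type",
    "site_id",
    "replicate",
    "specimen_id",
    "total_usable_reads",
)


class ValidationError(ValueError):
    """An input artifact violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclasses.dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer count matrix, features (rows) x samples (columns)."""

    feature_ids: tuple
    sample_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.sample_ids, "sample ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.size:
            if np.any(counts < 0):
                i, j = np.argwhere(counts < 0)[0]
                raise ValidationError(
                    f"negative count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            frac = np.mod(np.asarray(counts, dtype=float), 1.0)
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
        object.__setattr__(self, "counts", counts.astype(np.int64))

    # -- basic queries -------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def feature_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            return np.array([lookup[x] for x in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"feature id not in table: {e.args[0]!r}") from None

    # -- subsetting ----------------------------------------------------
    def select_features(self, ids: Sequence[str]) -> "FeatureTable":
        idx = self.feature_index(ids)
        return FeatureTable(tuple(ids), self.sample_ids, self.counts[idx])

    def drop_features(self, ids: Iterable[str]) -> "FeatureTable":
        drop = set(ids)
        keep = [f for f in self.feature_ids if f not in drop]
        return self.select_features(keep)

    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[x] for x in ids], dtype=int)
        return FeatureTable(self.feature_ids, tuple(ids), self.counts[:, idx])

    # -- conversion ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())


@dataclasses.dataclass
class AnalysisBundle:
    """Id-aligned table + metadata + taxonomy + tree."""

    table: FeatureTable
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    tree: TreeNode

    def __post_init__(self):
        validate_bundle(self)

    def community_table(self, community_type: str) -> FeatureTable:
        """Subset the count table to the samples of one community type."""
        ids = self.metadata.index[self.metadata["community_type"] == community_type]
        if len(ids) == 0:
            raise KeyError(f"no samples of community type {community_type!r}")
        return self.table.select_samples(list(ids))


# ---------------------------------------------------------------------------
# validators


def validate_metadata(md: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    _check_unique(list(md.index), "sample ids in metadata")
    for sid, row in md.iterrows():
        ct = row["community_type"]
        if ct not in COMMUNITY_TYPES:
            raise ValidationError(f"sample {sid!r}: unknown community type {ct!r}")
        species, organ = COMMUNITY_TYPES[ct]
        if (row["species"], row["organ"]) != (species, organ):
            raise ValidationError(
                f"sample {sid!r}: community type {ct} implies "
                f"species={species!r}, organ={organ!r}, got "
                f"({row['species']!r}, {row['organ']!r})"
            )


def validate_taxonomy(tax: pd.DataFrame) -> None:
    missing = [c for c in TAXONOMY_RANKS if c not in tax.columns]
    if missing:
        raise ValidationError(f"taxonomy missing ranks: {missing}")
    _check_unique(list(tax.index), "feature ids in taxonomy")
    for rank in TAXONOMY_RANKS:
        col = tax[rank]
        if col.isna().any() or (col.astype(str).str.len() == 0).any():
            bad = tax.index[col.isna() | (col.astype(str).str.len() == 0)][0]
            raise ValidationError(f"empty {rank} for feature {bad!r} (use {UNASSIGNED!r})")


def validate_tree(tree: TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tree tip labels")
    for node in tree.traverse(include_self=False):
        if node.length is None or not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"branch above {node.name or '<internal>'} has invalid length {node.length!r}"
            )


def validate_bundle(bundle: AnalysisBundle) -> None:
    validate_metadata(bundle.metadata)
    validate_taxonomy(bundle.taxonomy)
    validate_tree(bundle.tree)
    tips = {t.name for t in bundle.tree.tips()}
    feats = set(bundle.table.feature_ids)
    if not feats <= tips:
        raise ValidationError(
            f"{len(feats - tips)} table features missing from tree "
            f"(e.g. {sorted(feats - tips)[:3]})"
        )
    if not feats <= set(bundle.taxonomy.index):
        missing = feats - set(bundle.taxonomy.index)
        raise ValidationError(
            f"{len(missing)} table features missing from taxonomy (e.g. {sorted(missing)[:3]})"
        )
    if list(bundle.table.sample_ids) != list(bundle.metadata.index):
        raise ValidationError("table sample ids do not match metadata rows (order included)")


# ---------------------------------------------------------------------------
# readers


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ValidationError(f"non-numeric column {bad!r} in feature table {path}")
    return FeatureTable.from_dataframe(df)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col=0, dtype={"site_id": str})
    md.index = md.index.map(str)
    validate_metadata(md)
    return md


def read_taxonomy(path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna(UNASSIGNED)
    tax.index = tax.index.map(str)
    validate_taxonomy(tax)
    return tax


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    # unlabelled-length branches (e.g. the root edge) default to zero
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    validate_tree(tree)
    return tree


def read_bundle(table_path, tree_path, taxonomy_path, metadata_path) -> AnalysisBundle:
    """Load and cross-validate the four artifacts.

    Features absent from the tree or the taxonomy are logged and dropped;
    retained features keep the table's input order, so re-reading the same
    files is fully deterministic.
    """
    table = read_feature_table(table_path)
    tree = read_tree(tree_path)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)

    tips = {t.name for t in tree.tips()}
    tax_ids = set(taxonomy.index)
    dropped = [f for f in table.feature_ids if f not in tips or f not in tax_ids]
    if dropped:
        logger.warning(
            "dropping %d features absent from tree or taxonomy (first: %s)",
            len(dropped),
            dropped[:5],
        )
        table = table.drop_features(dropped)
    table = table.select_samples(list(metadata.index))
    taxonomy = taxonomy.loc[list(table.feature_ids)]
    return AnalysisBundle(table, metadata, taxonomy, tree)


# ---------------------------------------------------------------------------
# writers


def write_feature_table(table: FeatureTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="feature_id")


def write_bundle(bundle: AnalysisBundle, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "feature_table.tsv",
        "tree": out / "tree.nwk",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    write_feature_table(bundle.table, paths["table"])
    bundle.tree.write(str(paths["tree"]))
    bundle.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="feature_id")
    bundle.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return paths


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square labelled TSV; lossless to well below 1e-12 relative error."""
    if len(dm.ids) == 0:
        raise ValidationError("cannot write an empty distance matrix")
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(map(str, df.index)))


def write_network(net, path, format: str = "edge-tsv") -> None:
    """Write a co-association network as edge-TSV or GraphML."""
    if format == "edge-tsv":
        rows = [
            {"source": u, "target": v, "weight": w, "sign": "+" if w >= 0 else "-"}
            for (u, v, w) in net.edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    elif format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r} (edge-tsv or graphml)")


def read_network_edges(path) -> "nx.Graph":
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]), weight=float(row["weight"]))
    return g
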