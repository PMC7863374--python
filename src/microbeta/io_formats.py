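"""Readers, writers and validated domain types for every external format.

Supported formats: plain TSV feature tables, the mothur "shared" dialect,
two-column semicolon-lineage taxonomy files, Newick trees with branch
lengths, square-TSV and PHYLIP square distance matrices, TSV sample
metadata, and FASTA reads for the curation stage.

Identifiers are opaque, case-sensitive strings and are never normalized or
reordered: the order found in a file is the canonical order downstream.
"""

from __future__ import annotations

import math
import re
import warnings
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "PhyloTree",
    "DistanceMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "parse_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_metadata",
    "write_metadata",
    "read_fasta",
    "write_fasta",
]

_SYMMETRY_TOL = 1e-9
_N_RANKS = 6  # domain, phylum, class, order, family, genus
UNCLASSIFIED = "unclassified"
UNCLASSIFIED_PHYLUM = "unclassified bacteria"


def _check_unique(labels, kind: str) -> None:
    seen: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab in seen:
            raise ValueError(f"duplicate {kind} id {lab!r} at positions {seen[lab]} and {i}")
        seen[lab] = i


@dataclass(frozen=True)
class OtuTable:
    """Samples x OTUs count matrix; rows are samples, columns are OTUs."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                bad = np.argwhere(np.mod(counts, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized abundances, derived on the fly (never stored)."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"cannot normalize empty samples: {empty}")
        return self.counts / totals[:, None]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def select_samples(self, sample_subset) -> "OtuTable":
        idx = [self.sample_index(s) for s in sample_subset]
        return OtuTable(tuple(sample_subset), self.otu_ids, self.counts[idx, :])

    def select_otus(self, keep_mask: np.ndarray) -> "OtuTable":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        kept = tuple(o for o, k in zip(self.otu_ids, keep_mask) if k)
        return OtuTable(self.sample_ids, kept, self.counts[:, keep_mask])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.otu_ids))


class TaxonomyMap(Mapping):
    """OTU id -> ranked lineage (domain, phylum, class, order, family, genus).

    Unresolved ranks carry the explicit ``"unclassified"`` token; an OTU whose
    phylum is unresolved reports the phylum-level category
    ``"unclassified bacteria"``.
    """

    def __init__(self, lineages: Mapping[str, tuple[str, ...]]):
        clean: dict[str, tuple[str, ...]] = {}
        for otu, lineage in lineages.items():
            ranks = [r.strip() for r in lineage]
            ranks = [r if r else UNCLASSIFIED for r in ranks]
            if len(ranks) > _N_RANKS:
                ranks = ranks[:_N_RANKS]
            ranks += [UNCLASSIFIED] * (_N_RANKS - len(ranks))
            clean[otu] = tuple(ranks)
        self._lineages = clean

    def __getitem__(self, otu: str) -> tuple[str, ...]:
        return self._lineages[otu]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lineages)

    def __len__(self) -> int:
        return len(self._lineages)

    def phylum(self, otu: str) -> str:
        lineage = self._lineages.get(otu)
        if lineage is None or lineage[1] == UNCLASSIFIED:
            return UNCLASSIFIED_PHYLUM
        return lineage[1]

    def check_covers(self, otu_ids) -> None:
        missing = sorted(set(otu_ids) - set(self._lineages))
        if missing:
            raise ValueError(f"taxonomy is missing {len(missing)} OTUs: {missing[:10]}")


_REQUIRED_META_COLS = ("sample_id",)
_KNOWN_META_COLS = (
    "sample_id",
    "species_code",
    "order_group",
    "days_in_captivity",
    "outcome",
)


@dataclass
class SampleMetadata:
    """One record per sample; boolean ``treated_*`` columns are therapy flags."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in _REQUIRED_META_COLS:
            if col not in df.columns:
                raise ValueError(f"metadata is missing required column {col!r}")
        _check_unique(list(df["sample_id"]), "sample")
        if "days_in_captivity" in df.columns:
            days = pd.to_numeric(df["days_in_captivity"])
            if (days < 0).any():
                raise ValueError("days_in_captivity must be >= 0")
            df = df.assign(days_in_captivity=days.astype(int))
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"])

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Rows reordered to ``sample_ids``; errors on unknown ids."""
        indexed = self.df.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise KeyError(f"metadata has no record for samples {missing}")
        return indexed.loc[list(sample_ids)].reset_index()

    def column(self, name: str, sample_ids=None) -> np.ndarray:
        if name not in self.df.columns:
            raise KeyError(f"unknown metadata field {name!r}")
        if sample_ids is None:
            return self.df[name].to_numpy()
        return self.aligned(sample_ids)[name].to_numpy()


class PhyloTree:
    """Rooted tree with branch lengths, leaves labeled by OTU id.

    Nodes are stored as flat arrays in postorder; the root edge carries
    length 0 and is excluded from branch sums.
    """

    def __init__(self, parent: np.ndarray, length: np.ndarray, labels: list):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.length) == len(self.labels) == n):
            raise ValueError("parent/length/labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if np.isnan(self.length).any():
            raise ValueError("missing branch length")
        if (self.length < 0).any():
            raise ValueError("negative branch length")
        has_child = np.zeros(n, dtype=bool)
        for i, p in enumerate(self.parent):
            if p >= 0:
                has_child[p] = True
        self.is_leaf = ~has_child
        leaf_labels = [self.labels[i] for i in np.flatnonzero(self.is_leaf)]
        if any(lab is None for lab in leaf_labels):
            raise ValueError("every leaf must be labeled")
        _check_unique(leaf_labels, "leaf")
        self.leaf_index = {self.labels[i]: i for i in np.flatnonzero(self.is_leaf)}
        self.postorder = self._postorder()

    def _postorder(self) -> np.ndarray:
        children: list[list[int]] = [[] for _ in self.parent]
        for i, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(i)
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(children[node]):
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_index)

    def leaf_names(self) -> list[str]:
        return list(self.leaf_index)

    def total_branch_length(self) -> float:
        return float(self.length.sum())  # root edge length is 0 by construction

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf label."""
        depth = np.zeros(len(self.parent))
        for node in self.postorder[::-1]:  # preorder
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + self.length[node]
        return {lab: float(depth[i]) for lab, i in self.leaf_index.items()}

    def check_leaves(self, otu_ids) -> None:
        otus = set(otu_ids)
        leaves = set(self.leaf_index)
        missing = sorted(otus - leaves)
        if missing:
            diff = sorted(otus.symmetric_difference(leaves))
            raise ValueError(
                f"{len(missing)} OTUs are not tree leaves; symmetric difference: {diff[:20]}"
            )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered sample labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        _check_unique(self.ids, "sample")
        if not np.isfinite(vals).all():
            raise ValueError("distance matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("distance matrix contains negative values")
        asym = np.abs(vals - vals.T).max() if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetry {asym:g} exceeds tolerance {_SYMMETRY_TOL:g}")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in row-major order (n*(n-1)/2 entries)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, sample_subset) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in sample_subset if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids {missing}")
        idx = [pos[s] for s in sample_subset]
        return DistanceMatrix(tuple(sample_subset), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(path, dialect: str = "plain-tsv") -> OtuTable:
    """Read a samples x OTUs count table.

    ``plain-tsv``: header row of OTU ids, first column sample ids.
    ``mothur-shared``: header ``label  Group  numOtus  Otu...``; the label and
    numOtus columns are validated for internal consistency then dropped.
    """
    if dialect not in ("plain-tsv", "mothur-shared"):
        raise ValueError(f"unknown OTU table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if dialect == "mothur-shared":
        expected = ["label", "Group", "numOtus"]
        if list(df.columns[:3]) != expected:
            raise ValueError(
                f"malformed mothur-shared header: expected leading columns {expected}, "
                f"got {list(df.columns[:3])}"
            )
        otu_ids = list(df.columns[3:])
        for row_i, declared in enumerate(df["numOtus"]):
            if int(declared) != len(otu_ids):
                raise ValueError(
                    f"numOtus={declared} for sample {df['Group'][row_i]!r} (row {row_i}) "
                    f"but file has {len(otu_ids)} OTU columns"
                )
        sample_ids = list(df["Group"])
        body = df[otu_ids]
    else:
        sample_ids = list(df.iloc[:, 0])
        otu_ids = list(df.columns[1:])
        body = df.iloc[:, 1:]
    counts = np.empty((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            try:
                counts[i, j] = int(cell)
            except ValueError:
                raise ValueError(
                    f"non-integer cell {cell!r} at sample {sample_ids[i]!r} "
                    f"(row {i}), OTU {otu_ids[j]!r} (column {j})"
                ) from None
    return OtuTable(tuple(sample_ids), tuple(otu_ids), counts)


def write_otu_table(table: OtuTable, path, dialect: str = "plain-tsv") -> None:
    if dialect == "plain-tsv":
        df = table.to_dataframe()
        df.index.name = "sample"
        df.to_csv(path, sep="\t")
    elif dialect == "mothur-shared":
        df = table.to_dataframe().reset_index(names="Group")
        df.insert(0, "label", "0.03")
        df.insert(2, "numOtus", table.n_otus)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown OTU table dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Taxonomy

_CONFIDENCE_RE = re.compile(r"\(\d+(?:\.\d+)?\)")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column (otu_id, semicolon-delimited lineage) taxonomy table.

    Per-rank bootstrap annotations like ``Bacteria(100)`` are stripped.  An
    empty lineage maps the OTU to phylum "unclassified bacteria" with a
    warning.
    """
    lineages: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if line_no == 1 and parts[0].lower() in ("otu", "otu_id", "#otu id"):
                continue  # optional header
            if len(parts) < 2:
                otu, lineage_str = parts[0].strip(), ""
            else:
                otu, lineage_str = parts[0].strip(), parts[1]
            lineage_str = _CONFIDENCE_RE.sub("", lineage_str).strip().strip(";")
            ranks = [r.strip() for r in lineage_str.split(";")] if lineage_str else []
            ranks = [r for r in ranks if r]
            if not ranks:
                warnings.warn(
                    f"OTU {otu!r} has an empty lineage; mapped to {UNCLASSIFIED_PHYLUM!r}",
                    stacklevel=2,
                )
            lineages[otu] = tuple(ranks)
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu in taxonomy:
            fh.write(f"{otu}\t{';'.join(taxonomy[otu])};\n")


# ---------------------------------------------------------------------------
# Trees


def _tree_from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    seed = dtree.seed_node
    n_children = len(seed.child_nodes())
    if n_children > 2:
        raise ValueError(
            f"root has {n_children} children (unrooted trifurcation); "
            "midpoint-root the tree upstream before loading"
        )
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    length = np.zeros(len(nodes))
    labels: list = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError(
                    "Newick tree has an edge without a branch length; "
                    "lengths are required and are not defaulted"
                )
            length[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.is_leaf():
            raise ValueError("tree has an unlabeled leaf")
    return PhyloTree(parent, length, labels)


def parse_newick(newick: str) -> PhyloTree:
    dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _tree_from_dendropy(dtree)


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree; every edge must carry a branch length."""
    dtree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return _tree_from_dendropy(dtree)


def write_tree(tree: PhyloTree, path) -> None:
    children: dict[int, list[int]] = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(i)

    def render(node: int) -> str:
        if node in children:
            base = "(" + ",".join(render(c) for c in children[node]) + ")"
        else:
            base = tree.labels[node]
        if tree.parent[node] >= 0:
            return f"{base}:{tree.length[node]:.10g}"
        return base

    with open(path, "w") as fh:
        fh.write(render(tree.root) + ";\n")


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_matrix(dm: DistanceMatrix, path, dialect: str = "square-tsv") -> None:
    """Write a distance matrix losslessly at 10 significant digits."""
    if dialect == "square-tsv":
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(dm.ids) + "\n")
            for i, lab in enumerate(dm.ids):
                row = "\t".join(f"{v:.10g}" for v in dm.values[i])
                fh.write(f"{lab}\t{row}\n")
    elif dialect == "phylip-square":
        with open(path, "w") as fh:
            fh.write(f"{dm.n}\n")
            for i, lab in enumerate(dm.ids):
                row = "\t".join(f"{v:.10g}" for v in dm.values[i])
                fh.write(f"{lab}\t{row}\n")
    else:
        raise ValueError(f"unknown distance matrix dialect {dialect!r}")


def read_distance_matrix(path, dialect: str = "square-tsv") -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "square-tsv":
        header = lines[0].split("\t")
        ids = header[1:]
        body = lines[1:]
    elif dialect == "phylip-square":
        n = int(lines[0].strip())
        body = lines[1:]
        if len(body) != n:
            raise ValueError(f"phylip-square header declares {n} rows, found {len(body)}")
        ids = [ln.split("\t")[0] for ln in body]
    else:
        raise ValueError(f"unknown distance matrix dialect {dialect!r}")
    values = np.empty((len(ids), len(ids)))
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if parts[0] != ids[i] and dialect == "square-tsv":
            raise ValueError(f"row label {parts[0]!r} does not match column label {ids[i]!r}")
        row = parts[1:]
        if len(row) != len(ids):
            raise ValueError(f"row {parts[0]!r} has {len(row)} values, expected {len(ids)}")
        values[i] = [float(v) for v in row]
    return DistanceMatrix(tuple(ids), values)


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in df.columns:
        if col.startswith("treated_"):
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )
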