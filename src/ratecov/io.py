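"""Readers and writers for the external formats the pipeline consumes.

Trees are Newick (parsed with dendropy), branch-length tables and pairwise
score tables are TSV, gene sets and complexes are GMT. Branch identifiers
are derived from tree *topology* (the sorted leaf set below each edge), so
they survive re-serialization of the tree; terminal edges are simply named
by their leaf label.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CladeTree",
    "BranchLengthTable",
    "GeneSet",
    "GeneSetCollection",
    "CladeContribution",
    "PairScoreRecord",
    "read_clade_tree",
    "parse_clade_tree",
    "read_branch_table",
    "write_branch_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_pair_table",
    "write_pair_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _branch_id(node: dendropy.Node) -> str:
    """Stable edge identifier: leaf label for terminal edges, a short hash
    of the sorted subtended leaf set for internal edges."""
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    if len(leaves) == 1:
        return leaves[0]
    digest = hashlib.sha1(",".join(leaves).encode()).hexdigest()[:10]
    return f"b_{digest}"


@dataclass
class CladeTree:
    """A rooted species tree for one clade with stable per-edge identifiers.

    ``branch_ids`` lists one identifier per edge (every non-root node's
    subtending edge), in deterministic post-order. A rooted binary tree with
    S leaves therefore has 2S-2 branches.
    """

    clade_id: str
    tree: dendropy.Tree
    branch_ids: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    @property
    def n_branches(self) -> int:
        return len(self.branch_ids)

    def branch_lengths(self) -> pd.Series:
        """Per-branch lengths from the tree itself (NaN where unset)."""
        out = {}
        for node in self.tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            bid = _branch_id(node)
            out[bid] = np.nan if node.edge.length is None else float(node.edge.length)
        return pd.Series(out).reindex(self.branch_ids)

    def write(self, path) -> None:
        self.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _index_tree(tree: dendropy.Tree, clade_id: str) -> CladeTree:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(
            f"duplicate leaf labels in tree '{clade_id}': {sorted(dupes)}"
        )
    branch_ids = []
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        branch_ids.append(_branch_id(node))
    if len(set(branch_ids)) != len(branch_ids):
        raise FormatError(f"non-unique branch identifiers in tree '{clade_id}'")
    return CladeTree(clade_id=clade_id, tree=tree, branch_ids=branch_ids, species=sorted(labels))


def parse_clade_tree(newick: str, clade_id: str) -> CladeTree:
    """Parse a Newick string into a :class:`CladeTree`."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise FormatError(
                f"duplicate leaf labels in tree '{clade_id}': {exc}"
            ) from exc
        raise FormatError(f"malformed Newick for clade '{clade_id}': {exc}") from exc
    return _index_tree(tree, clade_id)


def read_clade_tree(path, clade_id: str) -> CladeTree:
    """Read a Newick file and assign deterministic branch identifiers."""
    with open(path) as fh:
        return parse_clade_tree(fh.read(), clade_id)


@dataclass
class BranchLengthTable:
    """Per-clade genes x branches matrix of branch lengths (substitutions/site).

    ``lengths`` is a DataFrame indexed by gene, with branch_id columns; NaN
    marks a missing (gene, branch) entry. A gene absent from the clade simply
    has no row.
    """

    clade_id: str
    lengths: pd.DataFrame

    def __post_init__(self):
        vals = self.lengths.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError(f"negative branch length in clade '{self.clade_id}'")
        if self.lengths.index.has_duplicates:
            raise FormatError(f"duplicate gene ids in clade '{self.clade_id}'")

    @property
    def genes(self) -> list[str]:
        return list(self.lengths.index)

    @property
    def branches(self) -> list[str]:
        return list(self.lengths.columns)


def read_branch_table(path, tree: CladeTree) -> BranchLengthTable:
    """Read a TSV of branch lengths (first column gene id, header = branch ids).

    Empty cells are missing data — distinct from 0, which is a legal length.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    unknown = [c for c in df.columns if c not in set(tree.branch_ids)]
    if unknown:
        raise FormatError(
            f"branch ids not present in tree '{tree.clade_id}': {unknown[:5]}"
        )
    df = df.apply(pd.to_numeric, errors="raise")
    if (df.to_numpy(dtype=float) < 0).any():
        raise FormatError(f"negative branch length in '{path}'")
    df.index = df.index.astype(str)
    return BranchLengthTable(clade_id=tree.clade_id, lengths=df.astype(float))


def write_branch_table(table: BranchLengthTable, path) -> None:
    table.lengths.to_csv(path, sep="\t", index_label="gene", na_rep="")


@dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways, complexes) with deduplicated members."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene-set name '{gs.name}'")
        self.sets[gs.name] = gs

    def filter_min_size(self, min_size: int) -> "GeneSetCollection":
        out = GeneSetCollection()
        for gs in self:
            if gs.size >= min_size:
                out.add(gs)
        return out

    def universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for gs in self:
            for g in gs.members:
                seen.setdefault(g, None)
        return list(seen)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and at least one member")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if not members:
                raise FormatError(f"{path}:{lineno}: empty gene set '{name}'")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"gene set '{name}': duplicate members removed")
            coll.add(GeneSet(name=name, members=deduped, description=desc))
    return coll


def write_gene_sets(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


@dataclass(frozen=True)
class CladeContribution:
    """One clade's contribution to a pair score: Pearson r over n branches."""

    clade_id: str
    r: float
    n: int


@dataclass
class PairScoreRecord:
    """A single integrated pair score, canonicalized so gene_a < gene_b."""

    gene_a: str
    gene_b: str
    fterc: float
    clades: tuple[CladeContribution, ...] = ()

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair not allowed: {self.gene_a}")
        if self.gene_b < self.gene_a:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def write_pair_table(records: list[PairScoreRecord], path) -> None:
    """Write pair scores as long-format TSV with per-clade stats as JSON."""
    rows = []
    for rec in records:
        rows.append(
            {
                "gene_a": rec.gene_a,
                "gene_b": rec.gene_b,
                "fterc": rec.fterc,
                "clades": json.dumps(
                    [[c.clade_id, c.r, c.n] for c in rec.clades]
                ),
            }
        )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "fterc", "clades"]).to_csv(
        path, sep="\t", index=False
    )


def read_pair_table(path) -> list[PairScoreRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    records = []
    for row in df.itertuples(index=False):
        clades = tuple(
            CladeContribution(clade_id=c[0], r=float(c[1]), n=int(c[2]))
            for c in json.loads(row.clades)
        )
        records.append(
            PairScoreRecord(
                gene_a=row.gene_a, gene_b=row.gene_b,
                fterc=float(row.fterc), clades=clades,
            )
        )
    return records
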