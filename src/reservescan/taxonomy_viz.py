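"""Taxonomy trees and annotation-layer export.

Builds a rank tree (a prefix tree over lineage paths, polytomies allowed)
from the cohort's taxonomy table, emits it as Newick with internal node
labels and no branch lengths, and projects matrix columns onto the leaves as
plain-text annotation datasets in the iTOL simple-bar / binary dialect, so
the distribution figures can be assembled in any tree viewer that reads
those files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

from .errors import IntegrityError, InvalidParameterError
from .pathway_caller import PathwayCallMatrix


@dataclass(frozen=True)
class Lineage:
    """Ordered rank labels (root to parent) plus the leaf proteome id."""

    proteome_id: str
    ranks: tuple[str, ...]
    taxid: int = 0

    def __post_init__(self) -> None:
        if not self.ranks:
            raise InvalidParameterError(f"{self.proteome_id}: empty lineage")


def lineages_from_taxonomy(taxonomy: pd.DataFrame) -> list[Lineage]:
    """Build lineages from a taxonomy table (proteome_id, taxid, rank columns)."""
    rank_cols = [c for c in taxonomy.columns if c not in ("proteome_id", "taxid")]
    return [
        Lineage(
            proteome_id=row["proteome_id"],
            ranks=tuple(str(row[c]) for c in rank_cols),
            taxid=int(row.get("taxid", 0)),
        )
        for _, row in taxonomy.iterrows()
    ]


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------


def build_tree(lineages: list[Lineage]) -> str:
    """Prefix tree over lineage paths as a Newick string.

    Shared rank prefixes become internal (labelled) nodes; leaves are
    proteome ids; sibling order is lexicographic, so equal inputs give
    byte-identical output.  A proteome id appearing under two different
    paths is a conflict.
    """
    if not lineages:
        raise InvalidParameterError("build_tree requires at least one lineage")
    seen: dict[str, tuple[str, ...]] = {}
    root_label = lineages[0].ranks[0]
    tree: dict = {}
    for lin in lineages:
        if lin.ranks[0] != root_label:
            raise IntegrityError(
                f"inconsistent root rank: {lin.ranks[0]!r} vs {root_label!r}"
            )
        if lin.proteome_id in seen:
            if seen[lin.proteome_id] != lin.ranks:
                raise IntegrityError(f"conflicting lineages for leaf {lin.proteome_id!r}")
            continue
        seen[lin.proteome_id] = lin.ranks
        node = tree
        for rank in lin.ranks:
            node = node.setdefault(rank, {})
        node[lin.proteome_id] = None  # leaf marker
    return _emit(root_label, tree[root_label]) + ";"


def _emit(label: str, children) -> str:
    if children is None:
        return label
    inner = ",".join(_emit(k, children[k]) for k in sorted(children))
    return f"({inner}){label}"


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a Newick string, preserving label underscores."""
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def canonical_newick(newick: str) -> str:
    """Parse and re-emit a Newick string in the package's canonical form
    (lexicographic sibling order, internal labels, no branch lengths)."""

    def label_of(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon else (node.label or "")
        return node.label or ""

    def emit(node: dendropy.Node) -> str:
        if node.is_leaf():
            return label_of(node)
        children = sorted(node.child_nodes(), key=label_of)
        return f"({','.join(emit(c) for c in children)}){node.label or ''}"

    tree = parse_newick(newick)
    return emit(tree.seed_node) + ";"


def tree_leaves(newick: str) -> list[str]:
    tree = parse_newick(newick)
    return [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]


# ---------------------------------------------------------------------------
# annotation layers
# ---------------------------------------------------------------------------


class LayerKind(enum.Enum):
    BAR = "bar"  # non-negative numeric value per leaf (simple-bar dataset)
    BINARY = "binary"  # 0/1 per leaf


@dataclass(frozen=True)
class LayerSpec:
    """One annotation layer: a matrix column projected onto the tree leaves."""

    layer_id: str
    kind: LayerKind
    column: str
    color: str = "#1f77b4"
    label: str = ""


def render_layer(matrix: PathwayCallMatrix, spec: LayerSpec) -> str:
    """Render one annotation dataset as iTOL-dialect text."""
    df = matrix.data
    if spec.column not in df.columns:
        raise InvalidParameterError(f"matrix has no column {spec.column!r}")
    header = "DATASET_SIMPLEBAR" if spec.kind is LayerKind.BAR else "DATASET_BINARY"
    lines = [
        header,
        "SEPARATOR COMMA",
        f"DATASET_LABEL,{spec.label or spec.layer_id}",
        f"COLOR,{spec.color}",
    ]
    if spec.kind is LayerKind.BINARY:
        lines.append("FIELD_SHAPES,1")
        lines.append(f"FIELD_LABELS,{spec.label or spec.layer_id}")
    lines.append("DATA")
    for _, row in df.iterrows():
        value = row[spec.column]
        if spec.kind is LayerKind.BINARY:
            rendered = "1" if bool(value) else "0"
        else:
            v = float(value)
            if v < 0:
                raise InvalidParameterError(
                    f"BAR layer {spec.layer_id!r}: negative value for {row['proteome_id']}"
                )
            rendered = f"{int(v)}" if float(v).is_integer() else f"{v}"
        lines.append(f"{row['proteome_id']},{rendered}")
    return "\n".join(lines) + "\n"


def export_layers(
    matrix: PathwayCallMatrix,
    tree_newick: str,
    specs: list[LayerSpec],
    outdir,
) -> dict[str, Path]:
    """Write one annotation file per layer spec; returns layer_id -> path.

    Every proteome in the matrix must be a leaf of the tree.
    """
    leaves = set(tree_leaves(tree_newick))
    missing = sorted(set(matrix.data["proteome_id"]) - leaves)
    if missing:
        raise IntegrityError(f"matrix proteomes missing from tree: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for spec in specs:
        path = outdir / f"{spec.layer_id}.txt"
        path.write_text(render_layer(matrix, spec))
        written[spec.layer_id] = path
    return written


def default_layer_specs(matrix: PathwayCallMatrix) -> list[LayerSpec]:
    """Standard figure layers: proteome size plus every enzyme copy count
    (bars) and every pathway call (binary)."""
    specs = [LayerSpec("proteome_size", LayerKind.BAR, "proteome_size", "#d62728", "Proteome size")]
    palette = ["#1f77b4", "#2ca02c", "#ff7f0e", "#9467bd", "#8c564b", "#17becf"]
    for i, e in enumerate(matrix.enzyme_ids):
        specs.append(LayerSpec(f"enzyme_{e}", LayerKind.BAR, e, palette[i % len(palette)], e))
    for i, p in enumerate(matrix.pathway_ids):
        specs.append(LayerSpec(f"pathway_{p}", LayerKind.BINARY, p, palette[i % len(palette)], p))
    return specs
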