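"""Rooted regulatory cascades.

A cascade is a tree grown breadth-first from a transcription factor:
targets of the root (per a reference regulator->target network) become
layer-1 children when their expression correlation with the root is
higher than the cascade gate (|r| > 0.8 by default); the cascade then
grows by adding targets of layer-1 genes, and so on, up to three layers.
lncRNA->gene edges inferred from physical enhancer overlap are exempt
from the correlation gate.  Cascades are grown per (cell type,
condition) with that group's own sample correlations, so losing an edge
in the disease samples shrinks or removes the disease cascade, which is
the comparison the analysis is after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig

log = logging.getLogger("regcascade")

# edge types exempt from the correlation gate (physical enhancer overlap)
GATE_EXEMPT_EDGE_TYPES = frozenset({"lncrna_gene"})


class CascadeError(ValueError):
    pass


@dataclass
class Cascade:
    root: str
    cell_type: str
    condition: str
    nodes: list[tuple[str, int]] = field(default_factory=list)   # (gene, layer)
    edges: list[tuple[str, str, str, float | None]] = field(default_factory=list)
    # edges: (parent, child, edge_type, r); r is None for ungated edges
    node_types: dict[str, str] = field(default_factory=dict)     # gene -> class

    def __post_init__(self) -> None:
        if not self.nodes:
            self.nodes = [(self.root, 0)]

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def depth(self) -> int:
        return max(layer for _, layer in self.nodes)

    def node_set(self) -> set[str]:
        return {g for g, _ in self.nodes}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(p, c) for p, c, _, _ in self.edges}

    def validate(self, config: PipelineConfig) -> None:
        """Assert the structural invariants: rooted tree, depth cap, gate."""
        layers = dict(self.nodes)
        if len(layers) != len(self.nodes):
            raise CascadeError(f"cascade {self.root}: node repeated")
        if layers.get(self.root) != 0:
            raise CascadeError(f"cascade {self.root}: root must sit at layer 0")
        if self.depth > config.max_layers:
            raise CascadeError(
                f"cascade {self.root}: depth {self.depth} exceeds max_layers "
                f"{config.max_layers}")
        parents: dict[str, str] = {}
        for parent, child, edge_type, r in self.edges:
            if parent not in layers or child not in layers:
                raise CascadeError(f"cascade {self.root}: edge {parent}->{child} "
                                   "references unknown node")
            if child in parents:
                raise CascadeError(f"cascade {self.root}: node {child} has two parents")
            parents[child] = parent
            if layers[child] != layers[parent] + 1:
                raise CascadeError(f"cascade {self.root}: edge {parent}->{child} "
                                   "does not descend one layer")
            if edge_type not in GATE_EXEMPT_EDGE_TYPES:
                if r is None or abs(r) <= config.cascade_corr_cutoff:
                    raise CascadeError(
                        f"cascade {self.root}: gated edge {parent}->{child} "
                        f"has r={r!r}, needs |r| > {config.cascade_corr_cutoff}")
        non_root = [g for g, l in self.nodes if g != self.root]
        if sorted(non_root) != sorted(parents):
            raise CascadeError(f"cascade {self.root}: non-root nodes and edge "
                               "children disagree")


def cascade_size(cascade: Cascade) -> int:
    """Number of genes in the cascade, root included."""
    return cascade.size


def _activation_lookup(activations: pd.DataFrame, cell_type: str,
                       condition: str) -> dict[tuple[str, str], tuple[str, float | None, bool]]:
    sel = activations[(activations["cell_type"] == cell_type)
                      & (activations["condition"] == condition)]
    out: dict[tuple[str, str], tuple[str, float | None, bool]] = {}
    for row in sel.itertuples(index=False):
        r = None if pd.isna(row.r) else float(row.r)
        out[(row.regulator, row.target)] = (row.edge_type, r, bool(row.active))
    return out


def grow_cascade(root: str, network: pd.DataFrame, activations: pd.DataFrame,
                 config: PipelineConfig, cell_type: str, condition: str,
                 node_types: dict[str, str] | None = None) -> Cascade:
    """Breadth-first cascade growth from ``root`` in one sample group.

    Layer l+1 candidates are network targets of layer-l nodes whose edge
    passes the gate: |r| strictly greater than ``cascade_corr_cutoff``,
    or an enhancer-overlap (lncrna_gene) edge, which is exempt.  A gene
    already in the cascade is never re-added; candidate parents are
    processed in lexicographic order so the first encounter is
    deterministic.  Growth stops after ``max_layers`` layers.
    """
    targets_of: dict[str, list[str]] = {}
    for row in network.itertuples(index=False):
        targets_of.setdefault(row.regulator, []).append(row.target)
    lookup = _activation_lookup(activations, cell_type, condition)

    nodes: list[tuple[str, int]] = [(root, 0)]
    seen = {root}
    edges: list[tuple[str, str, str, float | None]] = []
    frontier = [root]
    for layer in range(1, config.max_layers + 1):
        next_frontier: list[str] = []
        for parent in sorted(frontier):
            for child in sorted(set(targets_of.get(parent, ()))):
                if child in seen:
                    continue
                rec = lookup.get((parent, child))
                if rec is None:
                    continue
                edge_type, r, _pair_active = rec
                if edge_type in GATE_EXEMPT_EDGE_TYPES:
                    passes = _pair_active
                else:
                    passes = r is not None and abs(r) > config.cascade_corr_cutoff
                if not passes:
                    continue
                seen.add(child)
                nodes.append((child, layer))
                edges.append((parent, child, edge_type, r))
                next_frontier.append(child)
        frontier = next_frontier
        if not frontier:
            break
    types = {}
    if node_types:
        types = {g: node_types[g] for g, _ in nodes if g in node_types}
    cascade = Cascade(root=root, cell_type=cell_type, condition=condition,
                      nodes=nodes, edges=edges, node_types=types)
    cascade.validate(config)
    return cascade


def build_all_cascades(tf_list: list[str], network: pd.DataFrame,
                       activations: pd.DataFrame, config: PipelineConfig,
                       groups: list[tuple[str, str]],
                       node_types: dict[str, str] | None = None,
                       ) -> dict[tuple[str, str], list[Cascade]]:
    """One cascade per root TF per group; root-only cascades are dropped.

    A "cascade" requires at least one regulation, otherwise counts like
    "243 versus 74" would be constant at the number of TFs.
    """
    regulators = set(network["regulator"])
    out: dict[tuple[str, str], list[Cascade]] = {}
    for group in groups:
        cell_type, condition = group
        kept: list[Cascade] = []
        for root in sorted(set(tf_list)):
            if root not in regulators:
                log.info("cascade: root %s is not a regulator in the network", root)
                continue
            c = grow_cascade(root, network, activations, config, cell_type,
                             condition, node_types)
            if c.size > 1:
                kept.append(c)
        out[group] = kept
        log.info("cascade: %s/%s -> %d cascades, total size %d",
                 cell_type, condition, len(kept), sum(c.size for c in kept))
    return out


def compare_cascades(normal: list[Cascade], asd: list[Cascade],
                     size_threshold: int = 20) -> pd.DataFrame:
    """Per-root normal-vs-disease comparison within one cell type.

    status: lost (cascade in normal only), gained (disease only), shrunk,
    grown, or stable by node count.  ``lost_over_threshold`` marks lost
    cascades whose normal size exceeds ``size_threshold``.
    """
    cts = {c.cell_type for c in normal} | {c.cell_type for c in asd}
    if len(cts) > 1:
        raise CascadeError(f"compare_cascades: mixed cell types {sorted(cts)}")
    by_root_n = {c.root: c for c in normal}
    by_root_a = {c.root: c for c in asd}
    rows = []
    for root in sorted(set(by_root_n) | set(by_root_a)):
        cn, ca = by_root_n.get(root), by_root_a.get(root)
        size_n = cn.size if cn else 0
        size_a = ca.size if ca else 0
        if cn and not ca:
            status = "lost"
        elif ca and not cn:
            status = "gained"
        elif size_a < size_n:
            status = "shrunk"
        elif size_a > size_n:
            status = "grown"
        else:
            status = "stable"
        lost_edges = sorted(cn.edge_set() - (ca.edge_set() if ca else set())) if cn else []
        rows.append({
            "root": root,
            "cell_type": next(iter(cts)) if cts else "",
            "size_normal": size_n,
            "size_asd": size_a,
            "status": status,
            "lost_over_threshold": status == "lost" and size_n > size_threshold,
            "n_lost_edges": len(lost_edges),
            "lost_edges": ";".join(f"{p}->{c}" for p, c in lost_edges),
        })
    return pd.DataFrame(rows, columns=["root", "cell_type", "size_normal",
                                       "size_asd", "status",
                                       "lost_over_threshold", "n_lost_edges",
                                       "lost_edges"])
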