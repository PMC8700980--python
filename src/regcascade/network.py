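"""Assembly of the unified regulator->target network.

Three evidence streams are merged: reference TF->gene edges (a
Regulatory-Circuits-style edge list) filtered to expressed genes,
TF->lncRNA edges from promoter motif matches, and lncRNA->gene edges
inferred from physical overlap of a lncRNA locus with an enhancer
assigned to the gene.  Enhancer-derived edges are flagged as exempt
from downstream correlation gating, because the evidence is physical
rather than co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger("regcascade")

EDGE_COLUMNS = ["regulator", "target", "edge_type", "evidence"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap: same chromosome and a.start < b.end and
    b.start < a.end.  Touching intervals do not overlap; strand ignored."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def load_reference_network(path) -> pd.DataFrame:
    """Load a regulator/target TSV into deduplicated directed edges.

    A ``weight`` column, if present, only filters rows with weight <= 0.
    Self-loops are dropped (counted in the log).
    """
    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    for col in ("regulator", "target"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "weight" in df.columns:
        df = df[df["weight"].astype(float) > 0]
    loops = df["regulator"] == df["target"]
    if loops.any():
        log.info("load_reference_network: dropped %d self-loop rows", loops.sum())
    df = df[~loops]
    edges = (df[["regulator", "target"]].drop_duplicates()
             .sort_values(["regulator", "target"]).reset_index(drop=True))
    if edges.empty:
        log.warning("load_reference_network: %s yields an empty network", path)
    edges["edge_type"] = "tf_gene"
    edges["evidence"] = "reference_network"
    return edges[EDGE_COLUMNS]


def filter_by_expression(edges: pd.DataFrame, expressed_genes) -> pd.DataFrame:
    """Keep an edge iff both endpoints survived the expression filter."""
    expressed = set(expressed_genes)
    keep = edges["regulator"].isin(expressed) & edges["target"].isin(expressed)
    out = edges[keep].reset_index(drop=True)
    log.info("filter_by_expression: %d/%d edges kept", len(out), len(edges))
    return out


def motif_edges(tf_lncrna_pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """TF->lncRNA edges from significant promoter motif matches."""
    rows = sorted(set(tf_lncrna_pairs))
    return pd.DataFrame([{"regulator": tf, "target": lnc, "edge_type": "tf_lncrna",
                          "evidence": "motif"} for tf, lnc in rows],
                        columns=EDGE_COLUMNS)


def lncrna_enhancer_targets(lncrna_loci: pd.DataFrame,
                            enhancers: pd.DataFrame) -> pd.DataFrame:
    """lncRNA->gene edges from genomic overlap with the gene's enhancer.

    ``lncrna_loci`` is BED-like (chrom, start, end, name); ``enhancers``
    carries the assigned target gene id in its ``name`` column.
    Enhancers without a target name are skipped with a log entry.
    Deduplicated: one edge per (lncRNA, gene), however many enhancers of
    that gene the lncRNA touches.  These edges are exempt from
    correlation gating downstream.
    """
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    enh_by_chrom: dict[str, list] = {}
    for row in enhancers.itertuples(index=False):
        target = str(row.name) if pd.notna(row.name) else ""
        if not target or target == ".":
            skipped += 1
            continue
        enh_by_chrom.setdefault(row.chrom, []).append(
            (int(row.start), int(row.end), target))
    if skipped:
        log.info("lncrna_enhancer_targets: skipped %d enhancers without a "
                 "target gene name", skipped)
    for row in lncrna_loci.itertuples(index=False):
        for start, end, target in enh_by_chrom.get(row.chrom, ()):
            if row.start < end and start < row.end and target != row.name:
                pairs.add((str(row.name), target))
    return pd.DataFrame([{"regulator": lnc, "target": gene,
                          "edge_type": "lncrna_gene",
                          "evidence": "enhancer_overlap"}
                         for lnc, gene in sorted(pairs)], columns=EDGE_COLUMNS)


def assemble_network(*edge_tables: pd.DataFrame) -> pd.DataFrame:
    """Concatenate edge tables with global dedup on (regulator, target,
    edge_type), sorted (regulator, target) for stable deterministic order.

    The same pair under two distinct edge types is kept twice: distinct
    types are distinct evidence.
    """
    frames = [t for t in edge_tables if t is not None and len(t)]
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    merged = pd.concat(frames, ignore_index=True)
    loops = merged["regulator"] == merged["target"]
    if loops.any():
        log.info("assemble_network: dropped %d self-loops", loops.sum())
        merged = merged[~loops]
    merged = (merged.drop_duplicates(subset=["regulator", "target", "edge_type"])
              .sort_values(["regulator", "target", "edge_type"])
              .reset_index(drop=True))
    log.info("assemble_network: %d unified edges", len(merged))
    return merged[EDGE_COLUMNS]
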