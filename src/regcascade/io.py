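"""Readers and writers for the standard formats the pipeline touches.

Counts are TSV (``gene<TAB>sample1...``), annotations are BED6 plus a
7th gene-class column, gene sets are GMT, cascades are JSON trees.  All
genomic files use 0-based half-open coordinates (BED convention); that
is declared once here and relied on everywhere.  Every reader/writer
pair is a lossless round-trip on valid inputs.
"""

from __future__ import annotations

import json
import logging
import textwrap

import pandas as pd

from .cascade import Cascade
from .config import PipelineConfig, SampleSheet
from .expression import CountMatrix

log = logging.getLogger("regcascade")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- counts

def read_counts(path, sheet: SampleSheet,
                gene_class: dict[str, str] | None = None) -> CountMatrix:
    """Read a gene x sample TSV of integer counts.

    Columns may appear in any order but must match the sample sheet
    exactly; they are normalized to sheet order.  Non-integer cells and
    duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate gene ids {dup}")
    have, want = set(df.columns), set(sheet.sample_ids)
    if have != want:
        raise FormatError(
            f"{path}: sample mismatch; missing from file: {sorted(want - have)}, "
            f"unexpected in file: {sorted(have - want)}")
    values = {}
    for col in df.columns:
        try:
            values[col] = df[col].astype("int64")
        except (ValueError, TypeError):
            for gene, cell in df[col].items():
                try:
                    int(cell)
                except (ValueError, TypeError):
                    raise FormatError(
                        f"{path}: non-integer count {cell!r} at gene {gene!r}, "
                        f"sample {col!r}") from None
            raise
    ordered = pd.DataFrame(values, index=df.index)[sheet.sample_ids]
    return CountMatrix(ordered, dict(gene_class or {}))


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------- BED

def read_bed(path) -> pd.DataFrame:
    """BED6(+class) into a DataFrame; 7th column ``gene_class`` if present."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 6:
        raise FormatError(f"{path}: expected >= 6 BED columns, got {df.shape[1]}")
    cols = BED_COLUMNS + (["gene_class"] if df.shape[1] >= 7 else [])
    df = df.iloc[:, :len(cols)]
    df.columns = cols
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise FormatError(f"{path}: invalid interval at rows {list(bad.index)}")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = BED_COLUMNS + (["gene_class"] if "gene_class" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(sequences[name], width)))
            fh.write("\n")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, "
                                  "description and >= 1 member")
            name, members = parts[0], parts[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"{path}:{lineno}: duplicate members in {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sets:
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + list(sets[name])) + "\n")


# ---------------------------------------------------------------- cascades

def _cascade_to_dict(c: Cascade) -> dict:
    return {
        "root": c.root,
        "cell_type": c.cell_type,
        "condition": c.condition,
        "nodes": [{"id": g, "layer": layer, "type": c.node_types.get(g, "PCG")}
                  for g, layer in c.nodes],
        "edges": [{"from": p, "to": ch, "edge_type": t, "r": r}
                  for p, ch, t, r in c.edges],
    }


def write_cascade_json(cascades: list[Cascade], path,
                       config: PipelineConfig | None = None) -> None:
    config = config or PipelineConfig()
    for c in cascades:
        c.validate(config)
    payload = [_cascade_to_dict(c) for c in cascades]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cascade_json(path, config: PipelineConfig | None = None) -> list[Cascade]:
    config = config or PipelineConfig()
    with open(path) as fh:
        payload = json.load(fh)
    cascades = []
    for entry in payload:
        c = Cascade(
            root=entry["root"],
            cell_type=entry["cell_type"],
            condition=entry["condition"],
            nodes=[(n["id"], int(n["layer"])) for n in entry["nodes"]],
            edges=[(e["from"], e["to"], e["edge_type"],
                    None if e["r"] is None else float(e["r"]))
                   for e in entry["edges"]],
            node_types={n["id"]: n.get("type", "PCG") for n in entry["nodes"]},
        )
        c.validate(config)
        cascades.append(c)
    return cascades
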