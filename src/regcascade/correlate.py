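"""Per-group Pearson correlation of regulator-target pairs and
coordinate-expression gating.

Every edge of the unified network is annotated, per (cell type,
condition), with the Pearson correlation of its endpoints' log2-CPM
expression across that group's samples.  An edge is "active" in a
group when |r| meets the coordinate-expression cutoff (0.75 by
default); enhancer-overlap lncRNA->gene edges are active whenever both
endpoints are expressed, since that evidence is physical and not
subject to the correlation confirmation.  Negative correlations count:
repression is regulation too.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import PipelineConfig, SampleSheet
log = logging.getLogger("regcascade")

ACTIVATION_COLUMNS = ["regulator", "target", "edge_type", "cell_type",
                      "condition", "r", "active"]


def pearson(x, y) -> float | None:
    """Product-moment correlation; None when undefined (n < 3 or a
    constant vector) rather than NaN propagation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson: vectors must be 1-D and equal length")
    if len(x) < 3:
        return None
    xd = x - x.mean()
    yd = y - y.mean()
    sx = math.sqrt(float(xd @ xd))
    sy = math.sqrt(float(yd @ yd))
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(xd @ yd) / (sx * sy)
    return max(-1.0, min(1.0, r))


def annotate_correlations(network: pd.DataFrame, expr_log: pd.DataFrame,
                          sheet: SampleSheet,
                          config: PipelineConfig | None = None,
                          positive_only: bool = False) -> pd.DataFrame:
    """One activation record per edge per (cell_type, condition).

    Gating uses |r| >= pair_corr_cutoff (or r >= cutoff with
    ``positive_only``).  lncrna_gene edges get r computed for reporting
    but are active unconditionally when both genes are expressed.
    Edges touching genes absent from the matrix are inactive in every
    group (logged once per gene).
    """
    config = config or PipelineConfig()
    cutoff = config.pair_corr_cutoff
    values = expr_log.to_numpy()
    gene_row = {g: i for i, g in enumerate(expr_log.index)}
    col_of = {s: j for j, s in enumerate(expr_log.columns)}
    missing_logged: set[str] = set()
    rows = []
    for cell_type, condition in sheet.groups():
        samples = sheet.samples(cell_type, condition)
        cols = [col_of[s] for s in samples if s in col_of]
        for edge in network.itertuples(index=False):
            r: float | None = None
            reg_i = gene_row.get(edge.regulator)
            tgt_i = gene_row.get(edge.target)
            present = reg_i is not None and tgt_i is not None
            for g, i in ((edge.regulator, reg_i), (edge.target, tgt_i)):
                if i is None and g not in missing_logged:
                    log.info("annotate_correlations: gene %s absent from the "
                             "expression matrix; its edges are inactive", g)
                    missing_logged.add(g)
            if present:
                r = pearson(values[reg_i, cols], values[tgt_i, cols])
            if edge.edge_type == "lncrna_gene":
                active = present
            elif r is None:
                active = False
            elif positive_only:
                active = r >= cutoff
            else:
                active = abs(r) >= cutoff
            rows.append({"regulator": edge.regulator, "target": edge.target,
                         "edge_type": edge.edge_type, "cell_type": cell_type,
                         "condition": condition,
                         "r": np.nan if r is None else r, "active": active})
    table = pd.DataFrame(rows, columns=ACTIVATION_COLUMNS)
    for (ct, cond), sub in table.groupby(["cell_type", "condition"], sort=False):
        log.info("annotate_correlations: %s/%s -> %d/%d active edges",
                 ct, cond, int(sub["active"].sum()), len(sub))
    return table


def active_targets(activations: pd.DataFrame, cell_type: str,
                   condition: str) -> set[str]:
    sel = activations[(activations["cell_type"] == cell_type)
                      & (activations["condition"] == condition)
                      & activations["active"]]
    return set(sel["target"])


def condition_unique_targets(activations: pd.DataFrame, cell_type: str,
                             condition_a: str, condition_b: str) -> set[str]:
    """Targets of >= 1 active edge under condition A that have no active
    edge under condition B (same cell type) — e.g. regulation targets
    present in disease samples only."""
    return (active_targets(activations, cell_type, condition_a)
            - active_targets(activations, cell_type, condition_b))
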