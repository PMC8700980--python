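"""Per-sample pathway activity by a rank random-walk (GSVA-style) score.

For each sample, genes are ranked by their ECDF value across samples
(computed on log2(count+1)-scale expression), and a weighted
Kolmogorov-Smirnov-like walk over the ranked list accumulates in-set
weight against a uniform out-of-set penalty.  The score is the sum of
the largest positive and largest negative deviations of the walk, so it
lies in [-1, 1]: positive when the set's genes concentrate at the top
of the sample's ranking, negative at the bottom.

The exact recipe (fully specified so it is reproducible from this code
alone):

1. per gene i, ECDF across the n samples: F_i(x) = (1/n) sum_k 1[x_ik <= x];
2. per sample, rank genes by F descending, ties broken by gene id;
   rank r in {1..p} with 1 = highest;
3. weight w_i = |p/2 - r_i|;
4. walk over genes in rank order:
   v(l) = sum_{i<=l, in set} w_i / sum_{in set} w_i
        - sum_{i<=l, not in set} 1/(p - m);
5. score = max(0, max_l v) + min(0, min_l v).

Because only ranks enter, scores are invariant to any strictly
increasing per-gene transform of the expression values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import SampleSheet

log = logging.getLogger("regcascade")


class PathwayError(ValueError):
    pass


def validate_gene_sets(sets: dict[str, list[str]], expressed) -> dict[str, list[str]]:
    """Intersect each set with the expressed genes; empty results error."""
    expressed = set(expressed)
    out = {}
    for name in sets:
        members = [g for g in sets[name] if g in expressed]
        if not members:
            raise PathwayError(f"gene set {name!r} has no expressed members")
        out[name] = members
    return out


def _sample_ranks(expr_log: pd.DataFrame) -> np.ndarray:
    """Rank matrix (genes x samples); rank 1 = highest ECDF in the sample."""
    x = expr_log.to_numpy(dtype=float)
    p, n = x.shape
    # ECDF across samples, per gene: proportion of the gene's values <= x_ik
    order = np.argsort(x, axis=1, kind="stable")
    ecdf = np.empty_like(x)
    # handle ties: F(x) = (#values <= x)/n
    for i in range(p):
        xi = x[i]
        sorted_xi = xi[order[i]]
        counts = np.searchsorted(sorted_xi, xi, side="right")
        ecdf[i] = counts / n
    # per sample, rank genes by F descending, ties by gene id (index order
    # after lexicographic sort of ids)
    id_rank = np.argsort(np.argsort(expr_log.index.to_numpy()))
    ranks = np.empty((p, n), dtype=np.int64)
    for k in range(n):
        keys = np.lexsort((id_rank, -ecdf[:, k]))  # primary: -F, tie: gene id
        ranks[keys, k] = np.arange(1, p + 1)
    return ranks


def gsva_scores(expr_log: pd.DataFrame,
                gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Activity matrix, sets x samples, each score in [-1, 1]."""
    p = expr_log.shape[0]
    gene_pos = {g: i for i, g in enumerate(expr_log.index)}
    ranks = _sample_ranks(expr_log)
    weights = np.abs(p / 2.0 - ranks)
    out = {}
    for name in sorted(gene_sets):
        members = gene_sets[name]
        in_set = np.zeros(p, dtype=bool)
        for g in members:
            if g in gene_pos:
                in_set[gene_pos[g]] = True
        m = int(in_set.sum())
        if m == 0 or m == p:
            raise PathwayError(f"gene set {name!r}: walk undefined for "
                               f"m={m} of p={p} genes")
        scores = np.empty(expr_log.shape[1])
        for k in range(expr_log.shape[1]):
            order = np.argsort(ranks[:, k], kind="stable")
            inset_ord = in_set[order]
            w_ord = np.where(inset_ord, weights[order, k], 0.0)
            denom = w_ord.sum()
            gain = np.cumsum(w_ord) / denom if denom > 0 else np.zeros(p)
            penalty = np.cumsum(~inset_ord) / (p - m)
            v = gain - penalty
            scores[k] = max(0.0, v.max()) + min(0.0, v.min())
        out[name] = scores
    am = pd.DataFrame(out, index=expr_log.columns).T
    am.index.name = "set"
    assert ((am.to_numpy() >= -1 - 1e-12) & (am.to_numpy() <= 1 + 1e-12)).all()
    return am


def median_activity(am: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Exact sample median score per set per (cell_type, condition)."""
    cols = {}
    for cell_type, condition in sheet.groups():
        samples = [s for s in sheet.samples(cell_type, condition)
                   if s in am.columns]
        if not samples:
            raise PathwayError(f"group ({cell_type}, {condition}) has no "
                               "samples in the activity matrix")
        cols[f"{cell_type}/{condition}"] = am[samples].median(axis=1)
    return pd.DataFrame(cols)


def compare_stage_activity(scores_a, scores_b,
                           paired: bool = False) -> tuple[float, float]:
    """Two-sided Student's t-test between two per-pathway score vectors.

    Classical pooled-variance unpaired t by default (``paired=True``
    switches to the paired test).  Degenerate zero-variance input falls
    to the limit: p = 1 for equal means, p -> 0 otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise PathwayError("compare_stage_activity: each group needs >= 2 values")
    if paired:
        if len(a) != len(b):
            raise PathwayError("paired comparison needs equal-length vectors")
        d = a - b
        if d.std(ddof=1) == 0:
            return (0.0, 1.0) if d.mean() == 0 else (float("inf"), 0.0)
        t, pval = stats.ttest_rel(a, b)
        return float(t), float(pval)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            log.info("compare_stage_activity: zero pooled variance, equal means")
            return 0.0, 1.0
        log.info("compare_stage_activity: zero pooled variance, p -> 0 limit")
        return float("inf"), 0.0
    t, pval = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(pval)
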