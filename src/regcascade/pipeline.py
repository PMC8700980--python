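"""File-based stage orchestration.

Each stage reads its predecessors' files from the working directory,
writes its own outputs there, and logs a one-line summary, so the
pipeline is resumable and each stage independently testable.  Stage
outputs are pure functions of (inputs, config, seed): running the same
configuration twice produces byte-identical trees.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .cascade import build_all_cascades, compare_cascades
from .config import CELL_TYPES, PipelineConfig, SampleSheet
from .correlate import annotate_correlations, condition_unique_targets
from .enrich import hypergeom_enrich
from .expression import (CountMatrix, call_degs, filter_unexpressed,
                         nb_differential_test, normalize_cpm_log)
from .motif import (extract_promoters, hits_to_edges, parse_jaspar,
                    scan_promoters, set_thresholds)
from .network import (assemble_network, filter_by_expression,
                      load_reference_network, lncrna_enhancer_targets,
                      motif_edges)
from .pathway import (compare_stage_activity, gsva_scores, median_activity,
                      validate_gene_sets)
from .simulate import SimDesign, generate_study, write_truth

log = logging.getLogger("regcascade")

STAGE_ORDER = ["simulate", "filter", "de", "gsva", "scan-motifs",
               "build-network", "correlate", "cascades", "compare", "enrich"]


class PipelineError(RuntimeError):
    pass


def _require(outdir: Path, filename: str, producer: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineError(f"missing {filename}; run the '{producer}' stage first")
    return path


def _float_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def stage_simulate(config: PipelineConfig, outdir: Path,
                   design: SimDesign | None = None):
    outdir.mkdir(parents=True, exist_ok=True)
    study = generate_study(design, seed=config.seed)
    rio.write_fasta(study.genome, outdir / "genome.fa")
    rio.write_bed(study.genes, outdir / "genes.bed")
    rio.write_bed(study.enhancers, outdir / "enhancers.bed")
    from .motif import write_jaspar
    write_jaspar([study.pwms[tf] for tf in sorted(study.pwms)],
                 outdir / "motifs.jaspar")
    _float_csv(study.network, outdir / "network.tsv", index=False)
    study.sheet.write_tsv(outdir / "samples.tsv")
    for ct in CELL_TYPES:
        samples = study.sheet.samples(cell_type=ct)
        if samples:
            sub = study.counts.counts[samples].copy()
            sub.index.name = "gene"
            sub.to_csv(outdir / f"counts_{ct}.tsv", sep="\t")
    rio.write_gmt(study.gene_sets, outdir / "pathways.gmt")
    classes = pd.Series(study.counts.gene_class, name="gene_class")
    classes.rename_axis("gene").to_csv(outdir / "gene_classes.tsv", sep="\t")
    write_truth(study.truth, outdir / "truth.json")
    log.info("simulate: study written to %s", outdir)
    return study


def _load_counts(outdir: Path, producer: str = "simulate"
                 ) -> tuple[CountMatrix, SampleSheet]:
    sheet = SampleSheet.read_tsv(_require(outdir, "samples.tsv", producer))
    classes = pd.read_csv(_require(outdir, "gene_classes.tsv", producer),
                          sep="\t", index_col=0)["gene_class"].to_dict()
    frames = []
    for ct in CELL_TYPES:
        path = outdir / f"counts_{ct}.tsv"
        if path.exists():
            frames.append(pd.read_csv(path, sep="\t", index_col=0))
    if not frames:
        raise PipelineError(f"no counts_<celltype>.tsv files; run '{producer}' first")
    combined = pd.concat(frames, axis=1)
    cm = CountMatrix(combined[sheet.sample_ids], classes)
    return cm, sheet


def _load_filtered(outdir: Path) -> tuple[CountMatrix, SampleSheet]:
    path = _require(outdir, "counts.filtered.tsv", "filter")
    sheet = SampleSheet.read_tsv(_require(outdir, "samples.tsv", "simulate"))
    classes = pd.read_csv(_require(outdir, "gene_classes.tsv", "simulate"),
                          sep="\t", index_col=0)["gene_class"].to_dict()
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df[sheet.sample_ids], classes), sheet


def stage_filter(config: PipelineConfig, outdir: Path) -> CountMatrix:
    cm, _sheet = _load_counts(outdir)
    filtered = filter_unexpressed(cm, config.min_median_count)
    out = filtered.counts.copy()
    out.index.name = "gene"
    out.to_csv(outdir / "counts.filtered.tsv", sep="\t")
    log.info("filter: %d -> %d genes", len(cm.genes), len(filtered.genes))
    return filtered


def stage_de(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    cm, sheet = _load_filtered(outdir)
    summaries = []
    for ct in CELL_TYPES:
        asd = sheet.samples(ct, "ASD")
        normal = sheet.samples(ct, "normal")
        if len(asd) < 2 or len(normal) < 2:
            continue
        res = nb_differential_test(cm, asd, normal, config)  # log2FC: ASD over normal
        _float_csv(res, outdir / f"de_{ct}.tsv", index=False)
        degs = call_degs(res, config)
        summaries.append({"cell_type": ct, "n_degs": len(degs["PCG"]) + len(degs["ncRNA"]),
                          "n_pcg_degs": len(degs["PCG"]),
                          "n_ncrna_degs": len(degs["ncRNA"])})
    summary = pd.DataFrame(summaries)
    _float_csv(summary, outdir / "de_summary.tsv", index=False)
    return summary


def stage_gsva(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    cm, sheet = _load_filtered(outdir)
    sets = rio.read_gmt(_require(outdir, "pathways.gmt", "simulate"))
    sets = validate_gene_sets(sets, cm.genes)
    # activity is scored on log2(count + 1), per the study's recipe
    expr = np.log2(cm.counts.astype(float) + 1.0)
    am = gsva_scores(expr, sets)
    _float_csv(am, outdir / "gsva_scores.tsv")
    med = median_activity(am, sheet)
    _float_csv(med, outdir / "gsva_medians.tsv")
    rows = []
    for cond in ("normal", "ASD"):
        base = med.get(f"iPSC/{cond}")
        for later in ("NPC", "neuron"):
            other = med.get(f"{later}/{cond}")
            if base is None or other is None:
                continue
            t, p = compare_stage_activity(base.to_numpy(), other.to_numpy())
            rows.append({"condition": cond, "stage_a": "iPSC", "stage_b": later,
                         "t": t, "pvalue": p})
    tests = pd.DataFrame(rows)
    _float_csv(tests, outdir / "gsva_stage_tests.tsv", index=False)
    return tests


def stage_scan_motifs(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    genome = rio.read_fasta(_require(outdir, "genome.fa", "simulate"))
    genes = rio.read_bed(_require(outdir, "genes.bed", "simulate"))
    pwms = parse_jaspar(_require(outdir, "motifs.jaspar", "simulate"),
                        background=config.background,
                        pseudocount=config.pwm_pseudocount)
    set_thresholds(pwms, config.motif_pvalue)
    promoters = extract_promoters(genes, genome, config.promoter_upstream,
                                  config.promoter_downstream,
                                  gene_classes={"lncRNA", "antisense"})
    hits = scan_promoters(pwms, promoters)
    table = pd.DataFrame([{"tf": h.tf_name, "lncrna": h.sequence_id,
                           "offset": h.offset, "strand": h.strand,
                           "score": h.score} for h in hits],
                         columns=["tf", "lncrna", "offset", "strand", "score"])
    _float_csv(table, outdir / "motif_hits.tsv", index=False)
    edges = motif_edges(hits_to_edges(hits))
    _float_csv(edges, outdir / "motif_edges.tsv", index=False)
    return table


def stage_build_network(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    reference = load_reference_network(_require(outdir, "network.tsv", "simulate"))
    filtered, _sheet = _load_filtered(outdir)
    expressed = set(filtered.genes)
    tf_gene = filter_by_expression(reference, expressed)
    tf_lnc = pd.read_csv(_require(outdir, "motif_edges.tsv", "scan-motifs"), sep="\t")
    tf_lnc = filter_by_expression(tf_lnc, expressed)
    genes = rio.read_bed(_require(outdir, "genes.bed", "simulate"))
    enhancers = rio.read_bed(_require(outdir, "enhancers.bed", "simulate"))
    lnc_loci = genes[genes.get("gene_class", "PCG").isin(["lncRNA", "antisense"])]
    lnc_gene = lncrna_enhancer_targets(lnc_loci, enhancers)
    lnc_gene = filter_by_expression(lnc_gene, expressed)
    unified = assemble_network(tf_gene, tf_lnc, lnc_gene)
    _float_csv(unified, outdir / "network_unified.tsv", index=False)
    return unified


def stage_correlate(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    unified = pd.read_csv(_require(outdir, "network_unified.tsv", "build-network"),
                          sep="\t")
    cm, sheet = _load_filtered(outdir)
    expr = normalize_cpm_log(cm)
    activations = annotate_correlations(unified, expr, sheet, config)
    _float_csv(activations, outdir / "activations.tsv", index=False)
    rows = []
    for ct in CELL_TYPES:
        if not sheet.samples(ct):
            continue
        unique = condition_unique_targets(activations, ct, "ASD", "normal")
        rows.append({"cell_type": ct, "n_asd_only_targets": len(unique),
                     "targets": ";".join(sorted(unique))})
    _float_csv(pd.DataFrame(rows), outdir / "unique_targets.tsv", index=False)
    return activations


def stage_cascades(config: PipelineConfig, outdir: Path):
    unified = pd.read_csv(_require(outdir, "network_unified.tsv", "build-network"),
                          sep="\t")
    activations = pd.read_csv(_require(outdir, "activations.tsv", "correlate"),
                              sep="\t")
    sheet = SampleSheet.read_tsv(_require(outdir, "samples.tsv", "simulate"))
    classes = pd.read_csv(outdir / "gene_classes.tsv", sep="\t",
                          index_col=0)["gene_class"].to_dict()
    # default root list: every TF-class regulator of the reference network
    tf_roots = sorted(set(unified.loc[unified["edge_type"] == "tf_gene",
                                      "regulator"]))
    cascades = build_all_cascades(tf_roots, unified, activations, config,
                                  sheet.groups(), node_types=classes)
    for (ct, cond), group in cascades.items():
        rio.write_cascade_json(group, outdir / f"cascades_{ct}_{cond}.json",
                               config)
    return cascades


def stage_compare(config: PipelineConfig, outdir: Path,
                  size_threshold: int = 20) -> pd.DataFrame:
    frames = []
    for ct in CELL_TYPES:
        normal_path = outdir / f"cascades_{ct}_normal.json"
        asd_path = outdir / f"cascades_{ct}_ASD.json"
        if not normal_path.exists() or not asd_path.exists():
            continue
        normal = rio.read_cascade_json(normal_path, config)
        asd = rio.read_cascade_json(asd_path, config)
        report = compare_cascades(normal, asd, size_threshold)
        if report.empty:
            report["cell_type"] = []
        else:
            report["cell_type"] = ct
        frames.append(report)
    if not frames:
        raise PipelineError("no cascades_<ct>_<cond>.json files; run 'cascades' first")
    report = pd.concat(frames, ignore_index=True)
    _float_csv(report, outdir / "cascade_report.tsv", index=False)
    return report


def stage_enrich(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    cm, _sheet = _load_filtered(outdir)
    sets = rio.read_gmt(_require(outdir, "pathways.gmt", "simulate"))
    unique = pd.read_csv(_require(outdir, "unique_targets.tsv", "correlate"),
                         sep="\t")
    universe = set(cm.genes)
    frames = []
    queries: list[tuple[str, set[str]]] = []
    for row in unique.itertuples(index=False):
        targets = [] if pd.isna(row.targets) or not row.targets \
            else str(row.targets).split(";")
        queries.append((f"{row.cell_type}_asd_only_targets",
                        set(targets) & universe))
    for ct in CELL_TYPES:
        de_path = outdir / f"de_{ct}.tsv"
        if de_path.exists():
            res = pd.read_csv(de_path, sep="\t")
            degs = set(res.loc[res["significant"], "gene"]) & universe
            queries.append((f"{ct}_degs", degs))
    for label, query in queries:
        if not query:
            log.info("enrich: empty query %s, skipped", label)
            continue
        res = hypergeom_enrich(query, universe, sets)
        res.insert(0, "query", label)
        frames.append(res)
    result = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["query", "term", "k", "K", "n",
                                         "N", "pvalue", "fdr"]))
    _float_csv(result, outdir / "enrichment.tsv", index=False)
    return result


_STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "de": stage_de,
    "gsva": stage_gsva,
    "scan-motifs": stage_scan_motifs,
    "build-network": stage_build_network,
    "correlate": stage_correlate,
    "cascades": stage_cascades,
    "compare": stage_compare,
    "enrich": stage_enrich,
}


def run_stage(name: str, config: PipelineConfig, outdir: Path):
    if name not in _STAGES:
        raise PipelineError(f"unknown stage {name!r}; choose from {STAGE_ORDER}")
    return _STAGES[name](config, Path(outdir))


def run_all(config: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    for name in STAGE_ORDER:
        log.info("run-all: stage %s", name)
        run_stage(name, config, outdir)
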