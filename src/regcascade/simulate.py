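"""Synthetic study generator with planted ground truth.

Emits a complete desk-scale study — genome, gene/enhancer annotations,
TF motifs, a reference regulator->target network, and NB expression
counts for three cell types x two conditions — together with a
machine-readable truth file, so every downstream stage of the pipeline
can be tested end-to-end without downloading anything.

The expression model is latent-activity linear-Gaussian with a
negative-binomial emission: each root TF draws a latent activity
a ~ N(0, 1) per sample; each target's latent value is
``beta * parent + eps`` with eps ~ N(0, 0.25), propagated in
topological order; the latent value is standardized to unit variance
(analytically, per node and condition) and exponentiated into a mean
count ``mu = baseline * 2**(z + lfc * I[DE gene, ASD, NPC/neuron])``;
counts are NB(mu, phi).  In ASD samples a planted fraction of edges is
"broken" (beta set to 0), which is what the cascade comparison is meant
to detect.  Planted differential expression appears only at the NPC and
neuron stages, reproducing the study's signature of few iPSC DEGs and
many later ones.

Default coupling (beta = 5) and dispersion (phi = 0.005) are chosen so
the planted-edge correlation on the log scale,
``rho = corr_latent / (1 + nu)`` with NB log-noise
``nu = (phi + 1/mu) / ln(2)**2``, is ~0.98 — comfortably above the 0.8
cascade gate at the study's smallest group size (n = 8-9) — while
uncoupled distractor edges stay near 0.  The derivation is in the
methods note; weaker coupling makes the 0.8 gate miss planted edges in
expectation and the recovery tests ill-posed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import CELL_TYPES, CONDITIONS, SampleSheet
from .expression import CountMatrix
from .motif import BASES, PWMRecord, revcomp

log = logging.getLogger("regcascade")


class SimulationError(ValueError):
    pass


def _default_samples() -> dict[str, int]:
    # the study's sample counts: iPSC 11/17, NPC 9/21, neuron 8/17
    return {"iPSC|normal": 11, "iPSC|ASD": 17,
            "NPC|normal": 9, "NPC|ASD": 21,
            "neuron|normal": 8, "neuron|ASD": 17}


@dataclass
class SimDesign:
    n_tfs: int = 3
    n_pcgs: int = 100
    n_lncrnas: int = 6
    branching: int = 2                 # children per cascade node
    depth: int = 3                     # planted cascade layers below the root
    samples: dict[str, int] = field(default_factory=_default_samples)
    nb_dispersion: float = 0.005       # phi; Var = mu + phi mu^2
    coupling_strength: float = 5.0     # beta, latent-activity units
    latent_noise_var: float = 0.25     # sigma^2 of eps
    frac_edges_broken_in_asd: float = 0.3
    n_de_genes: int = 30               # planted DEGs per affected stage
    planted_lfc: float = 2.0           # log2 units
    n_distractors: int = 400           # beta = 0 reference-network edges
    baseline_log2_range: tuple[float, float] = (11.0, 13.0)  # counts 2048..8192
    motif_length: int = 10
    sites_per_lncrna: int = 1
    enhancer_overlap_fraction: float = 1.0
    lncrnas_per_tf: int = 2
    gene_length: int = 500
    chrom_name: str = "chrS"
    n_unexpressed: int = 2             # near-zero genes exercising the filter

    def validate(self) -> None:
        for key in ("n_tfs", "n_pcgs", "n_lncrnas", "branching", "depth",
                    "gene_length"):
            if getattr(self, key) < 1:
                raise SimulationError(f"{key} must be >= 1")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        for key in ("frac_edges_broken_in_asd", "enhancer_overlap_fraction"):
            if not (0.0 <= getattr(self, key) <= 1.0):
                raise SimulationError(f"{key} must lie in [0, 1]")
        if any(n < 1 for n in self.samples.values()):
            raise SimulationError("every sample group must have >= 1 sample")
        n_cascade = self.n_tfs * sum(self.branching ** l
                                     for l in range(1, self.depth + 1))
        if self.n_pcgs < n_cascade + self.n_lncrnas + self.n_unexpressed:
            raise SimulationError(
                f"n_pcgs={self.n_pcgs} too small for {n_cascade} cascade genes "
                f"+ {self.n_lncrnas} enhancer targets + {self.n_unexpressed} "
                "unexpressed genes")

    def groups(self) -> list[tuple[str, str]]:
        present = {tuple(k.split("|")) for k in self.samples}
        return [(ct, cond) for ct in CELL_TYPES for cond in CONDITIONS
                if (ct, cond) in present]


@dataclass
class SimTruth:
    de_genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    motif_sites: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (lncRNA, TF, offset within promoter sequence, strand)
    active_edges: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    # "cell_type|condition" -> [(regulator, target, beta)]
    broken_edges: list[tuple[str, str]] = field(default_factory=list)
    enhancer_links: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "de_genes": {ct: [[g, f] for g, f in v]
                         for ct, v in self.de_genes.items()},
            "motif_sites": [[l, t, o, s] for l, t, o, s in self.motif_sites],
            "active_edges": {k: [[a, b, w] for a, b, w in v]
                             for k, v in self.active_edges.items()},
            "broken_edges": [[a, b] for a, b in self.broken_edges],
            "enhancer_links": [[a, b] for a, b in self.enhancer_links],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            de_genes={ct: [(g, float(f)) for g, f in v]
                      for ct, v in d["de_genes"].items()},
            motif_sites=[(l, t, int(o), s) for l, t, o, s in d["motif_sites"]],
            active_edges={k: [(a, b, float(w)) for a, b, w in v]
                          for k, v in d["active_edges"].items()},
            broken_edges=[(a, b) for a, b in d["broken_edges"]],
            enhancer_links=[(a, b) for a, b in d["enhancer_links"]],
        )


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


# ------------------------------------------------------------- topology

@dataclass
class Topology:
    """Deterministic planted structure implied by a design (no RNG)."""

    tfs: list[str]
    cascade_edges: list[tuple[str, str, int]]       # (parent, child, child layer)
    lncrna_of_tf: dict[str, list[str]]              # TF -> lncRNAs it regulates
    enhancer_links: list[tuple[str, str]]           # (lncRNA, target gene)
    free_pcgs: list[str]
    unexpressed: list[str]
    de_pool: list[str]
    gene_class: dict[str, str]
    all_genes: list[str]

    def cascade_nodes(self, root: str) -> set[str]:
        """Planted PCG-tree nodes reachable from ``root``."""
        children: dict[str, list[str]] = {}
        for p, c, _ in self.cascade_edges:
            children.setdefault(p, []).append(c)
        out, stack = {root}, [root]
        while stack:
            for c in children.get(stack.pop(), ()):
                out.add(c)
                stack.append(c)
        return out

    def planted_cascade_nodes(self, root: str,
                              broken: set[tuple[str, str]] = frozenset(),
                              ) -> set[str]:
        """Full planted node set of the cascade rooted at ``root``:
        the PCG tree plus the root's lncRNAs and their enhancer targets,
        minus every subtree cut off by a broken edge."""
        children: dict[str, list[str]] = {}
        for p, c, _ in self.cascade_edges:
            children.setdefault(p, []).append(c)
        for tf, lncs in self.lncrna_of_tf.items():
            children.setdefault(tf, []).extend(lncs)
        for lnc, tgt in self.enhancer_links:
            children.setdefault(lnc, []).append(tgt)
        out, stack = {root}, [root]
        while stack:
            p = stack.pop()
            for c in children.get(p, ()):
                if (p, c) in broken or c in out:
                    continue
                out.add(c)
                stack.append(c)
        return out


def planted_topology(design: SimDesign) -> Topology:
    design.validate()
    tfs = [f"TF{i+1:02d}" for i in range(design.n_tfs)]
    pcgs = [f"G{i+1:03d}" for i in range(design.n_pcgs)]
    lncrnas = [f"LNC{i+1:02d}" for i in range(design.n_lncrnas)]

    per_tf = sum(design.branching ** l for l in range(1, design.depth + 1))
    cascade_edges: list[tuple[str, str, int]] = []
    cursor = 0
    for tf in tfs:
        layer_nodes = {0: [tf]}
        for layer in range(1, design.depth + 1):
            layer_nodes[layer] = []
            for parent in layer_nodes[layer - 1]:
                for _ in range(design.branching):
                    child = pcgs[cursor]
                    cursor += 1
                    cascade_edges.append((parent, child, layer))
                    layer_nodes[layer].append(child)
    free = pcgs[cursor:]

    lncrna_of_tf: dict[str, list[str]] = {tf: [] for tf in tfs}
    for j, lnc in enumerate(lncrnas):
        lncrna_of_tf[tfs[j % design.n_tfs]].append(lnc)

    enh_targets = free[:design.n_lncrnas]
    enhancer_links = [(lnc, enh_targets[j]) for j, lnc in enumerate(lncrnas)]
    unexpressed = free[design.n_lncrnas:design.n_lncrnas + design.n_unexpressed]
    de_pool = free[design.n_lncrnas + design.n_unexpressed:]

    gene_class = {g: "PCG" for g in tfs + pcgs}
    gene_class.update({l: "lncRNA" for l in lncrnas})
    return Topology(tfs=tfs, cascade_edges=cascade_edges,
                    lncrna_of_tf=lncrna_of_tf, enhancer_links=enhancer_links,
                    free_pcgs=free, unexpressed=unexpressed, de_pool=de_pool,
                    gene_class=gene_class, all_genes=tfs + pcgs + lncrnas)


# ------------------------------------------------- genome and annotation

PROMOTER_UP = 1000
PROMOTER_DOWN = 200
_SLOT_GAP = 600
SLOT_WIDTH = PROMOTER_UP + PROMOTER_DOWN + 2 * _SLOT_GAP  # 2400 bp per gene


def generate_genome_and_annotation(design: SimDesign, seed: int,
                                   background=(0.25, 0.25, 0.25, 0.25),
                                   ) -> tuple[dict[str, str], pd.DataFrame,
                                              pd.DataFrame, Topology]:
    """Synthetic chromosome, gene BED and enhancer BED.

    Every gene gets a 2400 bp slot so that its strand-aware promoter
    window [-1000, +200) fits inside the chromosome and no two promoter
    windows overlap (keeps planted-motif truth unambiguous).  lncRNA
    loci are placed so that the configured fraction overlap an enhancer
    assigned to their planted target gene.
    """
    topo = planted_topology(design)
    rng = np.random.default_rng(seed)
    n_genes = len(topo.all_genes)
    genome_len = (n_genes + 1) * SLOT_WIDTH
    if design.gene_length > 2 * _SLOT_GAP + PROMOTER_DOWN:
        raise SimulationError(
            f"gene_length {design.gene_length} needs a wider slot; "
            f"minimum chromosome stride would exceed {SLOT_WIDTH} bp")
    seq = rng.choice(list(BASES), size=genome_len,
                     p=np.asarray(background, dtype=float))
    genome = {design.chrom_name: "".join(seq)}

    rows = []
    for i, gene in enumerate(topo.all_genes):
        promoter_start = i * SLOT_WIDTH + _SLOT_GAP
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = promoter_start + PROMOTER_UP
            start, end = tss, tss + design.gene_length
        else:
            end = promoter_start + PROMOTER_DOWN       # promoter = [end-200, end+1000)
            start = end - design.gene_length
        rows.append({"chrom": design.chrom_name, "start": start, "end": end,
                     "name": gene, "score": 0, "strand": strand,
                     "gene_class": topo.gene_class[gene]})
    genes = pd.DataFrame(rows)

    enh_rows = []
    n_overlap = int(round(design.enhancer_overlap_fraction
                          * len(topo.enhancer_links)))
    loci = genes.set_index("name")
    for j, (lnc, target) in enumerate(topo.enhancer_links):
        locus = loci.loc[lnc]
        if j < n_overlap:
            start = int(locus.start) + 100
            end = min(start + 200, int(locus.end))
        else:  # placed clear of every gene slot: no overlap
            start = genome_len - SLOT_WIDTH + 200 * (j + 1)
            end = start + 150
        enh_rows.append({"chrom": design.chrom_name, "start": start,
                         "end": end, "name": target, "score": 0,
                         "strand": "."})
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "name",
                                      "score", "strand"])
    log.info("generate_genome_and_annotation: %d genes, %d enhancers, "
             "chromosome %s of %d bp", n_genes, len(enhancers),
             design.chrom_name, genome_len)
    return genome, genes, enhancers, topo


def generate_motifs(design: SimDesign, seed: int) -> dict[str, PWMRecord]:
    """One information-rich PWM per TF with a random consensus.

    Column counts are heterogeneous (dominant base 50-90, minor bases
    1-12 out of ~100 observations), like real binding profiles; this
    keeps the score distribution fine-grained so the exact-p-value
    threshold lands close to the requested budget rather than far below
    it, while the consensus stays unambiguous and maximally scoring.
    """
    rng = np.random.default_rng(seed)
    topo = planted_topology(design)
    pwms = {}
    for tf in topo.tfs:
        consensus = rng.integers(0, 4, size=design.motif_length)
        counts = rng.integers(1, 13, size=(4, design.motif_length)).astype(float)
        counts[consensus, np.arange(design.motif_length)] = rng.integers(
            50, 91, size=design.motif_length)
        pwms[tf] = PWMRecord(tf, counts)
    return pwms


def plant_motif_sites(genome: dict[str, str], genes: pd.DataFrame,
                      pwm: PWMRecord, sites_per_lncrna: int, rng,
                      lncrnas: list[str],
                      occupied: dict[str, list[tuple[int, int]]] | None = None,
                      ) -> tuple[dict[str, str], list[tuple[str, str, int, str]]]:
    """Write the motif consensus into lncRNA promoter windows.

    Offsets and strands are recorded in promoter-sequence coordinates
    (what the scanner reports): a '-' strand site means the reverse
    complement of the consensus appears in the promoter sequence.
    Previously planted intervals (``occupied``, updated in place) are
    never overwritten.  Zero requested sites leave the genome unchanged.
    """
    if pwm.length > PROMOTER_UP + PROMOTER_DOWN:
        raise SimulationError(f"motif {pwm.tf_name} longer than the promoter window")
    sites: list[tuple[str, str, int, str]] = []
    if sites_per_lncrna == 0:
        return genome, sites
    occupied = occupied if occupied is not None else {}
    by_name = genes.set_index("name")
    consensus = pwm.consensus()
    window_len = PROMOTER_UP + PROMOTER_DOWN
    for lnc in lncrnas:
        locus = by_name.loc[lnc]
        chrom = str(locus.chrom)
        if locus.strand == "+":
            win_start = int(locus.start) - PROMOTER_UP
        else:
            win_start = int(locus.end) - PROMOTER_DOWN
        used = occupied.setdefault(lnc, [])
        for _ in range(sites_per_lncrna):
            placed = False
            for _attempt in range(200):
                offset = int(rng.integers(0, window_len - pwm.length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                if any(offset < e and s < offset + pwm.length for s, e in used):
                    continue
                site_seq = consensus if strand == "+" else revcomp(consensus)
                if locus.strand == "+":
                    gpos = win_start + offset
                    plus_seq = site_seq
                else:
                    # promoter sequence is the revcomp of the genomic window
                    gpos = win_start + window_len - offset - pwm.length
                    plus_seq = revcomp(site_seq)
                chrom_seq = genome[chrom]
                genome[chrom] = (chrom_seq[:gpos] + plus_seq
                                 + chrom_seq[gpos + pwm.length:])
                used.append((offset, offset + pwm.length))
                sites.append((lnc, pwm.tf_name, offset, strand))
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"promoter of {lnc} too crowded for {sites_per_lncrna} "
                    f"sites of motif {pwm.tf_name}")
    return genome, sites


# ------------------------------------------------------ reference network

def generate_reference_network(design: SimDesign, seed: int,
                               ) -> tuple[pd.DataFrame, Topology]:
    """Planted cascade forest plus beta = 0 distractor edges (TSV form).

    Distractors run between free genes (index-ordered, so the graph
    stays acyclic) or from free genes into cascade genes; they never
    leave a cascade node, so a chance activation cannot corrupt the
    planted cascades' node sets while edge-level specificity stays
    measurable.
    """
    topo = planted_topology(design)
    rng = np.random.default_rng(seed)
    rows = [{"regulator": p, "target": c, "weight": 1.0}
            for p, c, _ in topo.cascade_edges]
    # sources exclude enhancer-target genes: those sit inside planted
    # cascades (as lncRNA children), and distractors must never leave a
    # cascade node
    pool = topo.unexpressed + topo.de_pool
    seen = {(r["regulator"], r["target"]) for r in rows}
    cascade_targets = [c for _, c, _ in topo.cascade_edges]
    n_placed = 0
    guard = 0
    while n_placed < design.n_distractors and guard < design.n_distractors * 50:
        guard += 1
        src = pool[int(rng.integers(0, len(pool)))]
        if rng.random() < 0.3:
            dst = cascade_targets[int(rng.integers(0, len(cascade_targets)))]
        else:
            dst = pool[int(rng.integers(0, len(pool)))]
            if pool.index(dst) <= pool.index(src):   # enforce acyclicity
                continue
        if src == dst or (src, dst) in seen:
            continue
        seen.add((src, dst))
        rows.append({"regulator": src, "target": dst, "weight": 1.0})
        n_placed += 1
    if n_placed < design.n_distractors:
        raise SimulationError("could not place the requested distractor edges")
    network = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    g = nx.DiGraph(network[["regulator", "target"]].itertuples(index=False))
    if not nx.is_directed_acyclic_graph(g):
        raise SimulationError("generated reference network contains a cycle")
    return network, topo


# --------------------------------------------------------- expression

def _build_truth(design: SimDesign, topo: Topology, seed: int) -> SimTruth:
    rng = np.random.default_rng(seed)
    beta = design.coupling_strength
    gated = ([(p, c, beta) for p, c, _ in topo.cascade_edges]
             + [(tf, lnc, beta) for tf in topo.tfs
                for lnc in topo.lncrna_of_tf[tf]])
    exempt = [(lnc, tgt, beta) for lnc, tgt in topo.enhancer_links]
    n_break = int(round(design.frac_edges_broken_in_asd * len(gated)))
    idx = rng.choice(len(gated), size=n_break, replace=False)
    broken = sorted((gated[i][0], gated[i][1]) for i in idx)
    broken_set = set(broken)

    de_genes: dict[str, list[tuple[str, float]]] = {"iPSC": []}
    for ct in ("NPC", "neuron"):
        k = min(design.n_de_genes, len(topo.de_pool))
        chosen = rng.choice(len(topo.de_pool), size=k, replace=False)
        de_genes[ct] = sorted((topo.de_pool[i], design.planted_lfc)
                              for i in chosen)

    active: dict[str, list[tuple[str, str, float]]] = {}
    for ct, cond in design.groups():
        edges = []
        for reg, tgt, b in gated + exempt:
            if cond == "ASD" and (reg, tgt) in broken_set:
                continue
            edges.append((reg, tgt, b))
        active[f"{ct}|{cond}"] = sorted(edges)
    return SimTruth(de_genes=de_genes, active_edges=active,
                    broken_edges=broken, enhancer_links=list(topo.enhancer_links))


def simulate_expression(design: SimDesign, topo: Topology, truth: SimTruth,
                        seed: int) -> tuple[CountMatrix, SampleSheet]:
    """NB counts for every sample group, driven by the latent-activity model."""
    rng = np.random.default_rng(seed)
    genes = topo.all_genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    baselines = 2.0 ** rng.uniform(*design.baseline_log2_range, size=len(genes))
    for g in topo.unexpressed:
        baselines[gene_idx[g]] = 2.0

    order = list(nx.topological_sort(nx.DiGraph(
        [(r, t) for edges in truth.active_edges.values()
         for r, t, _ in edges])))
    order += [g for g in genes if g not in set(order)]

    sigma2 = design.latent_noise_var
    phi = design.nb_dispersion
    columns: dict[str, np.ndarray] = {}
    records = []
    for ct, cond in design.groups():
        n = design.samples[f"{ct}|{cond}"]
        betas = {(r, t): b for r, t, b in truth.active_edges[f"{ct}|{cond}"]}
        parents: dict[str, list[tuple[str, float]]] = {}
        for (r, t), b in betas.items():
            parents.setdefault(t, []).append((r, b))
        # analytic latent variance per node under this condition
        var: dict[str, float] = {}
        latent: dict[str, np.ndarray] = {}
        for g in order:
            ps = parents.get(g, [])
            if not ps:
                var[g] = 1.0
                latent[g] = rng.standard_normal(n)
            else:
                v = sigma2 + sum(b * b * var[r] for r, b in ps)
                var[g] = v
                latent[g] = (sum(b * latent[r] for r, b in ps)
                             + math.sqrt(sigma2) * rng.standard_normal(n))
        de_offset = {g: f for g, f in truth.de_genes.get(ct, [])} \
            if cond == "ASD" else {}
        counts = np.empty((len(genes), n), dtype=np.int64)
        for g in genes:
            z = latent[g] / math.sqrt(var[g])
            shift = de_offset.get(g, 0.0)
            mu = baselines[gene_idx[g]] * np.power(2.0, z + shift)
            if not np.all(np.isfinite(mu)):
                raise SimulationError(f"non-finite mean count for gene {g}")
            if phi < 1e-12:
                counts[gene_idx[g]] = rng.poisson(mu)
            else:
                r_param = 1.0 / phi
                p_param = r_param / (r_param + mu)
                counts[gene_idx[g]] = rng.negative_binomial(r_param, p_param)
        for k in range(n):
            sid = f"{ct}_{cond}_{k+1:02d}"
            columns[sid] = counts[:, k]
            records.append((sid, ct, cond))
    frame = pd.DataFrame(columns, index=genes)
    sheet = SampleSheet.from_records(records)
    cm = CountMatrix(frame[sheet.sample_ids], dict(topo.gene_class))
    log.info("simulate_expression: %d genes x %d samples", *cm.counts.shape)
    return cm, sheet


def generate_gene_sets(design: SimDesign, topo: Topology, truth: SimTruth,
                       seed: int, n_random_sets: int = 4,
                       random_set_size: int = 15) -> dict[str, list[str]]:
    """Pathway-style gene sets: the planted stage DE programs plus
    random member sets, for activity scoring and enrichment."""
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for ct in ("NPC", "neuron"):
        members = [g for g, _ in truth.de_genes.get(ct, [])]
        if members:
            sets[f"planted_de_{ct}"] = members
    candidates = [g for g in topo.all_genes if g not in set(topo.unexpressed)]
    for j in range(n_random_sets):
        chosen = rng.choice(len(candidates), size=random_set_size, replace=False)
        sets[f"random_set_{j+1}"] = sorted(candidates[i] for i in chosen)
    return sets


# --------------------------------------------------------- orchestration

@dataclass
class SimStudy:
    design: SimDesign
    topology: Topology
    genome: dict[str, str]
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    pwms: dict[str, PWMRecord]
    network: pd.DataFrame
    counts: CountMatrix
    sheet: SampleSheet
    gene_sets: dict[str, list[str]]
    truth: SimTruth


def generate_study(design: SimDesign | None = None, seed: int = 0) -> SimStudy:
    """Generate the full synthetic study; deterministic in (design, seed)."""
    design = design or SimDesign()
    design.validate()
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2 ** 31 - 1, size=6)
    genome, genes, enhancers, topo = generate_genome_and_annotation(
        design, int(seeds[0]))
    pwms = generate_motifs(design, int(seeds[1]))
    truth = _build_truth(design, topo, int(seeds[2]))
    plant_rng = np.random.default_rng(int(seeds[3]))
    occupied: dict[str, list[tuple[int, int]]] = {}
    for tf in topo.tfs:
        genome, sites = plant_motif_sites(
            genome, genes, pwms[tf], design.sites_per_lncrna, plant_rng,
            lncrnas=topo.lncrna_of_tf[tf], occupied=occupied)
        truth.motif_sites.extend(sites)
    truth.motif_sites.sort()
    network, _ = generate_reference_network(design, int(seeds[4]))
    counts, sheet = simulate_expression(design, topo, truth, int(seeds[5]))
    gene_sets = generate_gene_sets(design, topo, truth, int(seeds[5]) + 1)
    return SimStudy(design=design, topology=topo, genome=genome, genes=genes,
                    enhancers=enhancers, pwms=pwms, network=network,
                    counts=counts, sheet=sheet, gene_sets=gene_sets,
                    truth=truth)
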