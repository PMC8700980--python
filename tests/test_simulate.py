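import numpy as np
import pytest

from regcascade.expression import normalize_cpm_log
from regcascade.motif import extract_promoters, revcomp
from regcascade.simulate import (SimDesign, SimTruth, SimulationError,
                                 _build_truth, generate_genome_and_annotation,
                                 generate_motifs, generate_reference_network,
                                 generate_study, planted_topology,
                                 plant_motif_sites, read_truth,
                                 simulate_expression, write_truth)


def small_design(**kw):
    base = dict(n_tfs=2, n_pcgs=40, n_lncrnas=2, n_distractors=10,
                lncrnas_per_tf=1, n_de_genes=5)
    base.update(kw)
    return SimDesign(**base)


class TestGenomeAndAnnotation:
    def test_gene_count_and_promoters_in_bounds(self):
        design = small_design()
        genome, genes, _enh, topo = generate_genome_and_annotation(design, 1)
        assert len(genes) == 2 + 40 + 2
        chrom_len = len(genome[design.chrom_name])
        for row in genes.itertuples(index=False):
            if row.strand == "+":
                a, b = row.start - 1000, row.start + 200
            else:
                a, b = row.end - 200, row.end + 1000
            assert 0 <= a < b <= chrom_len

    def test_promoter_windows_disjoint(self):
        design = small_design()
        _genome, genes, _enh, _topo = generate_genome_and_annotation(design, 1)
        windows = []
        for row in genes.itertuples(index=False):
            if row.strand == "+":
                windows.append((row.start - 1000, row.start + 200))
            else:
                windows.append((row.end - 200, row.end + 1000))
        windows.sort()
        for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
            assert b1 <= a2

    def test_full_overlap_fraction_every_lncrna_hits_enhancer(self):
        """Brute-force O(n*m) interval check against the emitted BEDs."""
        design = small_design(enhancer_overlap_fraction=1.0)
        _genome, genes, enh, topo = generate_genome_and_annotation(design, 2)
        lnc = genes[genes["gene_class"] == "lncRNA"]
        for row in lnc.itertuples(index=False):
            overlaps = [e for e in enh.itertuples(index=False)
                        if e.chrom == row.chrom and row.start < e.end
                        and e.start < row.end]
            assert overlaps, f"{row.name} overlaps no enhancer"

    def test_zero_overlap_fraction(self):
        design = small_design(enhancer_overlap_fraction=0.0)
        _genome, genes, enh, _topo = generate_genome_and_annotation(design, 2)
        lnc = genes[genes["gene_class"] == "lncRNA"]
        for row in lnc.itertuples(index=False):
            assert not any(e.chrom == row.chrom and row.start < e.end
                           and e.start < row.end
                           for e in enh.itertuples(index=False))

    def test_determinism_byte_identical(self):
        a = generate_genome_and_annotation(small_design(), 7)
        b = generate_genome_and_annotation(small_design(), 7)
        assert a[0] == b[0]
        assert a[1].equals(b[1]) and a[2].equals(b[2])


class TestPlantMotifSites:
    def setup_pieces(self, seed=3):
        design = small_design()
        genome, genes, _enh, topo = generate_genome_and_annotation(design, seed)
        pwms = generate_motifs(design, seed)
        return design, genome, genes, topo, pwms

    def test_planted_windows_contain_consensus(self):
        design, genome, genes, topo, pwms = self.setup_pieces()
        rng = np.random.default_rng(0)
        tf = topo.tfs[0]
        genome, sites = plant_motif_sites(genome, genes, pwms[tf], 1, rng,
                                          lncrnas=[l for t in topo.tfs
                                                   for l in topo.lncrna_of_tf[t]])
        assert len(sites) == design.n_lncrnas
        promoters = extract_promoters(genes, genome, 1000, 200)
        consensus = pwms[tf].consensus()
        for lnc, tf_name, offset, strand in sites:
            window = promoters[lnc][offset:offset + pwms[tf].length]
            expected = consensus if strand == "+" else revcomp(consensus)
            assert window == expected

    def test_zero_sites_leave_genome_unchanged(self):
        _design, genome, genes, topo, pwms = self.setup_pieces()
        before = dict(genome)
        rng = np.random.default_rng(0)
        out, sites = plant_motif_sites(genome, genes, pwms[topo.tfs[0]], 0,
                                       rng, lncrnas=["LNC01"])
        assert sites == [] and out == before

    def test_crowded_window_raises(self):
        _design, genome, genes, topo, pwms = self.setup_pieces()
        rng = np.random.default_rng(0)
        with pytest.raises(SimulationError, match="crowded"):
            plant_motif_sites(genome, genes, pwms[topo.tfs[0]], 150, rng,
                              lncrnas=["LNC01"])


class TestReferenceNetwork:
    def test_planted_tree_edge_count(self):
        # 1 TF, branching 2, depth 3 -> 2 + 4 + 8 = 14 true edges
        design = small_design(n_tfs=1, branching=2, depth=3, n_distractors=0,
                              n_lncrnas=1)
        net, topo = generate_reference_network(design, 1)
        assert len(net) == 14
        truth = _build_truth(design, topo, 1)
        active = {(a, b) for a, b, _ in truth.active_edges["NPC|normal"]}
        assert set(zip(net["regulator"], net["target"])) <= active

    def test_acyclic_by_topological_sort_oracle(self):
        import networkx as nx
        net, _topo = generate_reference_network(small_design(), 5)
        g = nx.DiGraph(zip(net["regulator"], net["target"]))
        assert list(nx.topological_sort(g))  # raises on cycles


class TestSimulateExpression:
    def run_sim(self, design, seed=0):
        topo = planted_topology(design)
        truth = _build_truth(design, topo, seed)
        return topo, truth, *simulate_expression(design, topo, truth, seed)

    def test_uncoupled_pairs_have_near_zero_correlation(self):
        design = small_design(coupling_strength=0.0, n_de_genes=0,
                              samples={"NPC|normal": 200})
        topo, truth, cm, sheet = self.run_sim(design, seed=1)
        expr = normalize_cpm_log(cm)
        p, c, _ = truth.active_edges["NPC|normal"][0]
        r = np.corrcoef(expr.loc[p], expr.loc[c])[0, 1]
        assert abs(r) < 3 / np.sqrt(200)

    def test_noiseless_limit_correlation_one(self):
        design = small_design(coupling_strength=1.0, latent_noise_var=1e-12,
                              nb_dispersion=1e-13, n_de_genes=0,
                              samples={"NPC|normal": 50})
        topo, truth, cm, _sheet = self.run_sim(design, seed=2)
        expr = normalize_cpm_log(cm)
        parent, child, _ = truth.active_edges["NPC|normal"][0]
        r = np.corrcoef(expr.loc[parent], expr.loc[child])[0, 1]
        assert r > 0.99

    def test_planted_lfc_recovered(self):
        design = small_design(nb_dispersion=0.05, planted_lfc=2.0,
                              samples={"NPC|normal": 20, "NPC|ASD": 20})
        topo, truth, cm, sheet = self.run_sim(design, seed=3)
        asd = sheet.samples("NPC", "ASD")
        normal = sheet.samples("NPC", "normal")
        ratios = []
        for gene, _ in truth.de_genes["NPC"]:
            ma = cm.counts.loc[gene, asd].mean()
            mb = cm.counts.loc[gene, normal].mean()
            ratios.append(np.log2(ma / mb))
        assert abs(np.mean(ratios) - 2.0) < 0.3

    def test_de_offset_absent_in_ipsc(self):
        design = small_design(samples={"iPSC|normal": 30, "iPSC|ASD": 30,
                                       "NPC|normal": 30, "NPC|ASD": 30})
        topo, truth, cm, sheet = self.run_sim(design, seed=4)
        gene = truth.de_genes["NPC"][0][0]
        ipsc_ratio = np.log2(cm.counts.loc[gene, sheet.samples("iPSC", "ASD")].mean()
                             / cm.counts.loc[gene, sheet.samples("iPSC", "normal")].mean())
        npc_ratio = np.log2(cm.counts.loc[gene, sheet.samples("NPC", "ASD")].mean()
                            / cm.counts.loc[gene, sheet.samples("NPC", "normal")].mean())
        assert abs(ipsc_ratio) < 1.0
        assert npc_ratio > 1.0


class TestTruthIO:
    def test_round_trip(self, tmp_path, study):
        write_truth(study.truth, tmp_path / "t.json")
        back = read_truth(tmp_path / "t.json")
        assert back == study.truth

    def test_empty_truth_serializes(self, tmp_path):
        write_truth(SimTruth(), tmp_path / "t.json")
        assert read_truth(tmp_path / "t.json") == SimTruth()

    def test_single_broken_edge(self, tmp_path):
        t = SimTruth(broken_edges=[("TF01", "G001")])
        write_truth(t, tmp_path / "t.json")
        assert read_truth(tmp_path / "t.json").broken_edges == [("TF01", "G001")]


class TestStudyLevelProperties:
    def test_full_study_deterministic(self, study):
        again = generate_study(seed=0)
        assert again.genome == study.genome
        assert again.counts.counts.equals(study.counts.counts)
        assert again.truth == study.truth
        assert again.network.equals(study.network)

    def test_correlation_separation_in_normal_npc(self, study):
        """Active-edge |r| median >= 0.8 and distractor median <= 0.3 —
        the premise that makes the 0.8 cascade gate recover planted
        structure."""
        from regcascade.expression import filter_unexpressed
        cm = filter_unexpressed(study.counts, 20)
        expr = normalize_cpm_log(cm)
        cols = study.sheet.samples("NPC", "normal")
        vals = expr[cols]

        def r(a, b):
            return np.corrcoef(vals.loc[a], vals.loc[b])[0, 1]

        active = [(a, b) for a, b, _ in study.truth.active_edges["NPC|normal"]]
        r_active = [abs(r(a, b)) for a, b in active
                    if a in vals.index and b in vals.index]
        planted = set(active)
        distract = [(a, b) for a, b in
                    zip(study.network["regulator"], study.network["target"])
                    if (a, b) not in planted]
        r_distract = [abs(r(a, b)) for a, b in distract
                      if a in vals.index and b in vals.index]
        assert np.median(r_active) >= 0.8
        assert np.median(r_distract) <= 0.3
        # edge-level specificity: few distractors clear the pair cutoff
        assert np.mean(np.array(r_distract) >= 0.75) <= 0.05

    def test_planted_de_genes_exist_in_annotation(self, study):
        names = set(study.genes["name"])
        for ct, genes in study.truth.de_genes.items():
            for g, _ in genes:
                assert g in names

    def test_broken_edges_subset_of_normal_active(self, study):
        normal = {(a, b) for a, b, _ in study.truth.active_edges["NPC|normal"]}
        assert set(map(tuple, study.truth.broken_edges)) <= normal

    def test_motif_sites_inside_promoter_windows(self, study):
        window = 1000 + 200
        for _lnc, tf, offset, _strand in study.truth.motif_sites:
            assert 0 <= offset <= window - study.pwms[tf].length
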