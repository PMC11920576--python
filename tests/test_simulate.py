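import numpy as np
import pytest

from secircuit.diffse import diff_se_genes, filter_degs, intersect_candidates
from secircuit.io import read_fasta
from secircuit.simulate import (STITCH, TSS_EXCL, SimulationConfig,
                                SimulationError, plant_roles,
                                simulate_bundle, simulate_deg_table,
                                simulate_expression, simulate_genome,
                                simulate_ontology, write_bundle)

from conftest import small_sim_config


class TestConfigValidation:
    def test_candidate_overlap_infeasible(self):
        with pytest.raises(SimulationError, match="candidate_overlap"):
            SimulationConfig(n_se_model=5, shared_se_gene_overlap=2,
                             candidate_overlap=18)

    def test_multiplier_floor(self):
        with pytest.raises(SimulationError, match="multiplier"):
            SimulationConfig(se_signal_multiplier=2)

    def test_shared_overlap_bounded(self):
        with pytest.raises(SimulationError, match="overlap exceeds"):
            SimulationConfig(n_se_ea=4, shared_se_gene_overlap=5)


class TestGenome:
    def test_deterministic_fasta(self, tmp_path):
        cfg = small_sim_config(1)
        for d in ("a", "b"):
            write_bundle(simulate_bundle(cfg), tmp_path / d)
        assert (tmp_path / "a" / "genome.fa").read_bytes() == \
            (tmp_path / "b" / "genome.fa").read_bytes()

    def test_tf_count_uses_floor(self):
        cfg = SimulationConfig(
            n_genes=10, tf_fraction=0.3, clique_tfs=("T1", "T2", "T3"),
            n_se_model=5, n_se_ea=2, shared_se_gene_overlap=1,
            candidate_overlap=1, n_up_model=2, n_up_ea=1,
            n_chroms=1, chrom_length=600_000, n_typical_peaks=0)
        roles = plant_roles(cfg)
        assert len(roles.tf_genes) == 3

    def test_genes_must_fit(self):
        cfg = small_sim_config()
        bad = SimulationConfig(**{**cfg.__dict__, "chrom_length": 100_000,
                                  "n_chroms": 1})
        with pytest.raises(SimulationError, match="do not fit"):
            simulate_genome(bad)

    def test_gene_grid_spacing(self, small_bundle):
        by_chrom = {}
        for g in small_bundle.genes:
            by_chrom.setdefault(g.chrom, []).append(g.tss)
        for tss in by_chrom.values():
            tss = sorted(tss)
            assert all(b - a >= 30_000 - 2_000 for a, b in zip(tss, tss[1:]))


class TestPeaks:
    def test_planted_se_geometry(self, small_bundle):
        """Constituent gaps stay under the stitching distance and clear of
        every TSS-exclusion window."""
        tss = {}
        for g in small_bundle.genes:
            tss.setdefault(g.chrom, []).append(g.tss)
        for cond in ("model", "ea"):
            for gene, regions in small_bundle.manifest.se_regions[cond].items():
                for (c1, s1, e1), (_c2, s2, _e2) in zip(regions, regions[1:]):
                    assert 0 < s2 - e1 <= STITCH
                for c, s, e in regions:
                    assert all(e - 1 < t - TSS_EXCL or s > t + TSS_EXCL
                               for t in tss[c])

    def test_conditions_share_typical_peaks(self, small_bundle):
        typ = {c: sorted(p for p in small_bundle.peaks[c]
                         if p.name.startswith("typ_"))
               for c in ("model", "ea")}
        assert typ["model"] == typ["ea"]

    def test_planted_clusters_occupy_top_ranks(self, small_bundle):
        """Planted SEs outrank every typical region in input-subtracted
        signal (verified through the caller)."""
        from secircuit.se_caller import call_super_enhancers
        t, cut, _, _ = call_super_enhancers(
            small_bundle.peaks["model"], small_bundle.genes)
        n_planted = len(small_bundle.manifest.se_regions["model"])
        top = t.head(n_planted)
        assert (top["n_constituents"] ==
                small_bundle.config.se_constituents).all()

    def test_clique_motifs_planted_as_exact_substrings(self, small_bundle):
        pwm = {p.tf_name: p for p in small_bundle.pwms}
        seqs = small_bundle.se_sequences("model")
        for owner in small_bundle.manifest.roles.clique:
            joined = "|".join(seqs[owner])
            for tf in small_bundle.manifest.roles.clique:
                assert joined.count(pwm[tf].consensus) >= \
                    small_bundle.config.own_motif_copies


class TestPlantedSets:
    def test_study_scale_venn_counts(self):
        roles = plant_roles(SimulationConfig.study_scale(0))
        d = diff_se_genes(roles.model_se_genes, roles.ea_se_genes)
        assert len(d.lost_after_ea) == 367
        assert len(d.gained_after_ea) == 41
        assert len(d.shared) == 36
        assert len(roles.candidates) == 18

    def test_candidates_are_lost_and_upregulated(self):
        cfg = SimulationConfig.study_scale(3)
        roles = plant_roles(cfg)
        deg = simulate_deg_table(cfg, roles)
        sets = filter_degs(deg)
        d = diff_se_genes(roles.model_se_genes, roles.ea_se_genes)
        got = intersect_candidates(d, sets, "lost_up_model")
        assert got.genes == frozenset(roles.candidates)
        assert intersect_candidates(d, sets, "gained_up_ea").genes == \
            frozenset()

    def test_deg_null_genes_not_significant(self):
        cfg = small_sim_config(2)
        roles = plant_roles(cfg)
        deg = simulate_deg_table(cfg, roles)
        planted = roles.up_model | roles.up_ea
        for r in deg:
            if r.gene_id not in planted:
                assert r.qvalue > 0.05


class TestExpression:
    def test_deterministic(self):
        cfg = small_sim_config(4)
        roles = plant_roles(cfg)
        a, _ = simulate_expression(cfg, roles)
        b, _ = simulate_expression(cfg, roles)
        assert (a.values == b.values).all()

    def test_null_effect_makes_key_gene_exchangeable(self):
        cfg = SimulationConfig(**{**small_sim_config(5).__dict__,
                                  "expression_effect_sd": 0.0,
                                  "decoy_effect_sd": 0.0})
        roles = plant_roles(cfg)
        expr, groups = simulate_expression(cfg, roles)
        key = expr.loc[roles.key_gene]
        m = key[[s for s in expr.columns if groups[s] == "model"]].mean()
        e = key[[s for s in expr.columns if groups[s] == "ea"]].mean()
        sd = key.std()
        assert abs(m - e) < 2 * sd


class TestOntology:
    def test_dag_size_and_annotation_consistency(self):
        cfg = small_sim_config(6)
        roles = plant_roles(cfg)
        dag, ann, sets = simulate_ontology(cfg, roles)
        assert len(dag) >= 30
        for ts in ann.values():
            assert ts and all(t in dag for t in ts)
        assert roles.key_gene in ann
        key_terms = set(ann[roles.key_gene])
        for g, ts in ann.items():
            if g != roles.key_gene:
                assert set(t for t in ts if t.startswith("leaf_")) <= \
                    key_terms | set(ts)

    def test_gene_sets_nonempty(self):
        cfg = small_sim_config(7)
        dag, ann, sets = simulate_ontology(cfg, plant_roles(cfg))
        assert len(sets) >= 1
        assert all(sets[n] for n in sets.sets)


def test_bundle_audit_is_self_consistent(small_bundle):
    # simulate_bundle already ran audit_bundle; re-assert key counts here
    r = small_bundle.manifest.roles
    cfg = small_bundle.config
    assert len(r.model_se_genes) == cfg.n_se_model
    assert len(r.ea_se_genes) == cfg.n_se_ea
    assert len(r.shared) == cfg.shared_se_gene_overlap
    assert set(r.candidates) == r.lost & r.up_model


def test_written_bundle_files_parse_back(tmp_path, small_bundle):
    paths = write_bundle(small_bundle, tmp_path)
    genome = read_fasta(paths["genome"])
    assert set(genome) == set(small_bundle.genome)
    assert len(genome["chr1"]) == small_bundle.config.chrom_length
    from secircuit.io import read_gene_annotation, read_peaks
    genes = read_gene_annotation(paths["genes"])
    assert {g.gene_id for g in genes} == set(small_bundle.manifest.roles.gene_ids)
    peaks = read_peaks(paths["model_peaks"], dialect="bed6+signal")
    assert len(peaks) == len(small_bundle.peaks["model"])
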