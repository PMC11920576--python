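import numpy as np
import pytest

from secircuit.crc import (CircuitGraph, Circuit, SelfRegulatingTF,
                           UNIFORM_BACKGROUND, _int_logodds_matrix,
                           build_tf_graph, detect_self_regulating,
                           enumerate_circuits, identify_se_tfs, MotifHit,
                           pwm_threshold_score, scan_motifs, score_circuits,
                           score_distribution)
from secircuit.io import GeneModel, PWM

from _oracles import brute_circuits, brute_pwm_tail


def _random_pwm(rng, k, name="M", conc=2.0):
    return PWM.from_counts(name, rng.dirichlet([conc] * 4, size=k))


def _informative_pwm(name, consensus):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((len(consensus), 4))
    counts[np.arange(len(consensus)), [idx[b] for b in consensus]] = 97.0
    return PWM.from_counts(name, counts)


RC = str.maketrans("ACGT", "TGCA")


class TestPWMThreshold:
    def test_single_base_enumeration(self):
        pwm = PWM("M", ((0.97, 0.01, 0.01, 0.01),))
        thr, tails = pwm_threshold_score(pwm, p_threshold=0.25)
        # only 'A' reaches the threshold, with exact tail 0.25
        m = _int_logodds_matrix(pwm, UNIFORM_BACKGROUND)
        assert thr == m[0, 0]
        assert tails[thr] == pytest.approx(0.25)
        assert all(s < thr for s in m[0, 1:4])

    def test_threshold_one_admits_minimum_score(self):
        rng = np.random.default_rng(0)
        pwm = _random_pwm(rng, 4)
        thr, _ = pwm_threshold_score(pwm, p_threshold=1.0)
        scores, _ = score_distribution(pwm)
        assert thr == scores.min()

    def test_invalid_threshold_rejected(self):
        pwm = PWM("M", ((0.25, 0.25, 0.25, 0.25),))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pwm_threshold_score(pwm, p_threshold=bad)

    def test_dp_equals_exhaustive_enumeration(self):
        """Exact tail probabilities match brute-force 4^k enumeration for
        50 random PWMs of length <= 6, under two backgrounds."""
        rng = np.random.default_rng(1)
        for i in range(50):
            k = int(rng.integers(1, 7))
            bg = (0.25,) * 4 if i % 2 else (0.2, 0.3, 0.3, 0.2)
            pwm = _random_pwm(rng, k, conc=float(rng.uniform(0.5, 5)))
            m = _int_logodds_matrix(pwm, bg)[:, :4]
            expected = brute_pwm_tail(m, bg)
            scores, probs = score_distribution(pwm, bg)
            tail = np.cumsum(probs[::-1])[::-1]
            got = dict(zip(scores.tolist(), tail.tolist()))
            assert set(got) == set(expected)
            for s in expected:
                assert got[s] == pytest.approx(expected[s], abs=1e-12)

    def test_tail_monotone_in_score(self):
        rng = np.random.default_rng(2)
        pwm = _random_pwm(rng, 5)
        scores, probs = score_distribution(pwm)
        tail = np.cumsum(probs[::-1])[::-1]
        assert (np.diff(tail) <= 1e-15).all()


class TestScanning:
    def test_planted_consensus_found_on_plus_strand(self):
        pwm = _informative_pwm("T1", "ACGTACGTAA")
        seq = "C" * 10 + "ACGTACGTAA" + "C" * 10
        hits = scan_motifs({"se1": [seq]}, [pwm])
        plus = [h for h in hits if h.strand == "+"]
        assert [h.offset for h in plus] == [10]

    def test_reverse_complement_found_on_minus_strand(self):
        pwm = _informative_pwm("T1", "ACGTACGTAA")
        rc = "ACGTACGTAA".translate(RC)[::-1]
        seq = "C" * 7 + rc + "C" * 13
        hits = scan_motifs({"se1": [seq]}, [pwm])
        minus = [h for h in hits if h.strand == "-"]
        assert [h.offset for h in minus] == [7]

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        pwm = _informative_pwm("T1", "ACGTACGTAA")
        assert scan_motifs({"se1": ["ACG"]}, [pwm]) == []

    def test_n_bases_score_as_background(self):
        pwm = _informative_pwm("T1", "AAAAAAAAAA")
        # consensus with two Ns still passes: 8 matched positions dominate
        hits = scan_motifs({"se1": ["AANAAAAANA"]}, [pwm])
        assert any(h.strand == "+" and h.offset == 0 for h in hits)

    def test_hit_rate_matches_threshold_calibration(self):
        """Per-position hit rate on random sequence at p = 1e-4 is within
        3 Monte-Carlo SE of 2e-4 (two strands)."""
        rng = np.random.default_rng(3)
        pwm = _random_pwm(rng, 8, name="M8")
        n = 400_008
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        hits = scan_motifs({"s": [seq]}, [pwm], p_threshold=1e-4)
        positions = n - 7
        rate = len(hits) / positions
        se = np.sqrt(2e-4 * (1 - 2e-4) / positions)
        assert abs(rate - 2e-4) <= 3 * se


class TestGraphConstruction:
    def test_identify_se_tfs(self, caplog):
        genes = [GeneModel("T1", "chr1", "+", 0, True),
                 GeneModel("T2", "chr1", "+", 50_000, True),
                 GeneModel("G1", "chr1", "+", 100_000, False)]
        pwms = [_informative_pwm("T1", "ACGTACGTAA")]
        assignment = {"se1": "T1", "se2": "G1", "se3": "T2", "se4": "T1"}
        with caplog.at_level("WARNING"):
            out = identify_se_tfs(assignment, genes, pwms)
        assert out == {"T1": ["se1", "se4"]}    # multi-SE TF keeps both
        assert "T2" in caplog.text              # TF without a PWM logged

    def _hits(self, spec):
        """spec: {(tf, se): count} -> synthetic MotifHit list."""
        hits = []
        for (tf, se), c in spec.items():
            for i in range(c):
                hits.append(MotifHit(tf, se, 0, i, "+", 5.0, 1e-5))
        return hits

    def test_self_regulation_boundary_three_vs_two(self):
        tf_ses = {"A": ["seA"], "B": ["seB"]}
        hits = self._hits({("A", "seA"): 3, ("B", "seB"): 2})
        out = detect_self_regulating(tf_ses, hits, min_instances=3)
        assert [t.tf_name for t in out] == ["A"]
        assert out[0].own_motif_count == 3

    def test_min_instances_one_keeps_single_hit(self):
        tf_ses = {"A": ["seA"]}
        out = detect_self_regulating(tf_ses, self._hits({("A", "seA"): 1}),
                                     min_instances=1)
        assert [t.tf_name for t in out] == ["A"]

    def test_edges_and_asymmetry(self):
        tf_ses = {"A": ["seA"], "B": ["seB"]}
        hits = self._hits({("A", "seA"): 3, ("B", "seB"): 3,
                           ("A", "seB"): 3, ("B", "seA"): 1})
        selfreg = detect_self_regulating(tf_ses, hits)
        g = build_tf_graph(selfreg, hits)
        assert ("A", "B") in g.edges and ("B", "A") not in g.edges
        assert ("A", "A") in g.edges and ("B", "B") in g.edges

    def test_degree_table_hand_counted(self):
        nodes = ["A", "B", "C", "D"]
        edges = {("A", "A"), ("B", "B"), ("C", "C"), ("D", "D"),
                 ("A", "B"), ("B", "A"), ("A", "C"), ("D", "A")}
        g = CircuitGraph(nodes, edges)
        t = g.degree_table().set_index("tf")
        # self-loops excluded from the reported degrees
        assert t.loc["A", "out_degree"] == 2 and t.loc["A", "in_degree"] == 2
        assert t.loc["B", "out_degree"] == 1 and t.loc["B", "in_degree"] == 1
        assert t.loc["C", "in_degree"] == 1 and t.loc["C", "out_degree"] == 0
        assert t.loc["D", "out_degree"] == 1 and t.loc["D", "in_degree"] == 0


class TestCircuits:
    def _graph(self, nodes, pairs):
        edges = {(n, n) for n in nodes} | set(pairs)
        return CircuitGraph(list(nodes), edges)

    def test_bidirectional_triangle(self):
        g = self._graph("ABC", [(a, b) for a in "ABC" for b in "ABC" if a != b])
        assert [c.members for c in enumerate_circuits(g)] == [("A", "B", "C")]

    def test_path_yields_two_pairs(self):
        g = self._graph("ABC", [("A", "B"), ("B", "A"),
                                ("B", "C"), ("C", "B")])
        assert [c.members for c in enumerate_circuits(g)] == \
            [("A", "B"), ("B", "C")]

    def test_one_directional_edge_is_not_a_circuit(self):
        g = self._graph("AB", [("A", "B")])
        assert enumerate_circuits(g) == []

    def test_matches_exhaustive_subset_oracle(self):
        """200 random digraphs with <= 12 nodes: recursive enumeration
        equals brute-force subset checking (and networkx cross-check)."""
        import networkx as nx
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            nodes = [f"T{i}" for i in range(n)]
            edges = {(n_, n_) for n_ in nodes}
            for a in nodes:
                for b in nodes:
                    if a != b and rng.random() < 0.35:
                        edges.add((a, b))
            g = CircuitGraph(nodes, edges)
            got = [c.members for c in enumerate_circuits(g)]
            assert got == brute_circuits(nodes, edges)
            ug = nx.Graph((a, b) for a, b in edges
                          if a != b and (b, a) in edges)
            nx_cliques = sorted(tuple(sorted(c))
                                for c in nx.find_cliques(ug) if len(c) >= 2)
            assert got == nx_cliques

    def test_min_instances_monotonicity(self):
        """Raising min_instances never adds nodes, edges or circuits."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            tfs = [f"T{i}" for i in range(6)]
            tf_ses = {t: [f"se{t}"] for t in tfs}
            hits = []
            for a in tfs:
                for b in tfs:
                    for i in range(int(rng.integers(0, 6))):
                        hits.append(MotifHit(a, f"se{b}", 0, i, "+", 1.0, 1e-5))
            prev_nodes = prev_edges = prev_circ = None
            for mi in (1, 2, 3, 4):
                sr = detect_self_regulating(tf_ses, hits, mi)
                g = build_tf_graph(sr, hits, mi)
                circ = {c.members for c in enumerate_circuits(g)}
                if prev_nodes is not None:
                    assert set(g.nodes) <= prev_nodes
                    assert g.edges <= prev_edges
                    assert all(any(set(c) <= set(p) for p in prev_circ)
                               for c in circ)
                prev_nodes, prev_edges, prev_circ = set(g.nodes), g.edges, circ


class TestScoring:
    def test_single_circuit_scores_one(self):
        scored, rep = score_circuits([Circuit(("A", "B"))])
        assert scored[0].score == pytest.approx(1.0)
        assert rep.members == ("A", "B")

    def test_membership_frequency_tie_resolved_lexicographically(self):
        scored, rep = score_circuits([Circuit(("A", "B")), Circuit(("A", "C"))])
        assert [c.score for c in scored] == [pytest.approx(0.75)] * 2
        assert rep.members == ("A", "B")

    def test_empty_list_warns(self, caplog):
        with caplog.at_level("WARNING"):
            scored, rep = score_circuits([])
        assert scored == [] and rep is None


def test_bundle_circuit_members_are_self_regulating(small_bundle):
    """On generated data every reported circuit member is self-regulating
    and every ordered member pair has an edge."""
    from secircuit.se_caller import call_super_enhancers
    b = small_bundle
    t, _, ranked, _ = call_super_enhancers(b.peaks["model"], b.genes)
    se = t[t.is_super]
    assignment = {f"{r.chrom}:{r.start}-{r.end}": r.gene_id
                  for r in se.itertuples(index=False) if r.gene_id}
    tf_ses = identify_se_tfs(assignment, b.genes, b.pwms)
    id2entry = {ranked.region_id(i): e for i, e in enumerate(ranked.entries)}
    seqs = {sid: [b.sequence(c.chrom, c.start, c.end)
                  for c in id2entry[sid].constituents]
            for ses in tf_ses.values() for sid in ses}
    hits = scan_motifs(seqs, [p for p in b.pwms if p.tf_name in tf_ses])
    selfreg = detect_self_regulating(tf_ses, hits)
    graph = build_tf_graph(selfreg, hits)
    selfreg_names = {t.tf_name for t in selfreg}
    for c in enumerate_circuits(graph):
        assert set(c.members) <= selfreg_names
        for a in c.members:
            for bb in c.members:
                if a != bb:
                    assert (a, bb) in graph.edges
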