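"""Statistical-parsimony networks, haplogroups and introgression counts."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from taxpop import alignments as aio
from taxpop import network as net
from taxpop.alignments import Alignment


def table_from_seqs(seqs, pops=None):
    recs = [(f"s{i}", s) for i, s in enumerate(seqs)]
    aln = Alignment(recs)
    smap = pd.DataFrame({"sample_id": [r[0] for r in recs],
                         "population": pops or ["p"] * len(recs),
                         "taxon": ["t"] * len(recs),
                         "ploidy": [1] * len(recs)})
    return aio.collapse_haplotypes(aln, smap), smap


class TestConnectionLimit:
    def test_explicit_limit_overrides_formula(self):
        assert net.connection_limit(600, max_steps=14) == 14

    def test_nondecreasing_in_alignment_length(self):
        limits = [net.connection_limit(L) for L in (100, 300, 600, 1200, 2400)]
        assert limits == sorted(limits)
        assert limits[-1] > 0

    def test_threshold_one_forbids_any_connection(self):
        # the parsimony probability is strictly below 1 for any j >= 1
        assert net.connection_limit(1000, p_threshold=1.0) == 0

    def test_probability_decreases_in_steps(self):
        probs = [net.parsimony_probability(j, 600) for j in range(1, 15)]
        assert probs == sorted(probs, reverse=True)


class TestBuildNetwork:
    def test_one_step_chain_has_no_intermediates(self):
        table, _ = table_from_seqs(["AAAA", "AAAT", "AATT"])
        network = net.build_parsimony_network(table, limit=5)
        g = network.graph
        assert network.n_inferred() == 0
        assert set(map(frozenset, g.edges())) == {
            frozenset({"H1", "H2"}), frozenset({"H2", "H3"})}

    def test_distant_haplotype_isolated_into_second_component(self):
        table, _ = table_from_seqs(["A" * 20, "A" * 19 + "T", "C" * 10 + "A" * 10])
        network = net.build_parsimony_network(table, limit=5)
        comps = network.components()
        assert len(comps) == 2
        assert {"H1", "H2"} in comps and {"H3"} in comps

    def test_multistep_connection_goes_through_intermediates(self):
        table, _ = table_from_seqs(["AAAA", "TTAA"])
        network = net.build_parsimony_network(table, limit=5)
        assert network.n_inferred() == 1
        assert nx.shortest_path_length(network.graph, "H1", "H2") == 2

    def test_no_edge_spans_more_than_one_step_and_paths_bound_distance(self):
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        seqs = list({"".join(bases[rng.integers(0, 4, 8)]) for _ in range(6)})
        table, _ = table_from_seqs(seqs)
        network = net.build_parsimony_network(table, limit=8)
        dist = network.distances
        # sampled-to-sampled graph distance is at least the Hamming distance
        for a, b in itertools.combinations(table.haplotype_ids(), 2):
            try:
                steps = nx.shortest_path_length(network.graph, a, b)
            except nx.NetworkXNoPath:
                continue
            assert steps >= dist.loc[a, b]

    def test_matches_bruteforce_minimum_spanning_construction(self):
        rng = np.random.default_rng(22)
        bases = np.array(list("ACGT"))
        for trial in range(5):
            seqs = list({"".join(bases[rng.integers(0, 4, 10)])
                         for _ in range(6)})
            table, _ = table_from_seqs(seqs)
            limit = 6
            network = net.build_parsimony_network(table, limit)
            ids = table.haplotype_ids()
            d = network.distances
            # brute force: grow components level by level, recording which
            # pairs connect at their own distance
            comp = {h: {h} for h in ids}
            expected_pairs = set()
            for level in sorted({int(d.loc[a, b]) for a, b in
                                 itertools.combinations(ids, 2)}):
                if level == 0 or level > limit:
                    continue
                frozen = {h: frozenset(c) for h, c in comp.items()}
                joined = []
                for a, b in itertools.combinations(ids, 2):
                    if int(d.loc[a, b]) == level and frozen[a] != frozen[b]:
                        expected_pairs.add((a, b, level))
                        joined.append((a, b))
                for a, b in joined:
                    union = comp[a] | comp[b]
                    for h in union:
                        comp[h] = union
            # compare realised connections and intermediate count
            n_intermediates = sum(lv - 1 for _, _, lv in expected_pairs)
            assert network.n_inferred() == n_intermediates
            for a, b, lv in expected_pairs:
                assert nx.shortest_path_length(network.graph, a, b) == lv

    def test_components_separated_beyond_limit(self):
        table, _ = table_from_seqs(["A" * 12, "C" * 6 + "A" * 6, "C" * 12])
        network = net.build_parsimony_network(table, limit=4)
        comps = network.components()
        d = network.distances
        for c1, c2 in itertools.combinations(comps, 2):
            assert min(d.loc[a, b] for a in c1 for b in c2) > 4

    def test_order_invariance_of_component_partition(self):
        rng = np.random.default_rng(23)
        seqs = ["AAAA", "AAAT", "TTTT", "TTTA", "AAAA", "TTTT"]
        t1, _ = table_from_seqs(seqs)
        shuffled = [seqs[i] for i in rng.permutation(len(seqs))]
        t2, _ = table_from_seqs(shuffled)
        n1 = net.build_parsimony_network(t1, limit=2)
        n2 = net.build_parsimony_network(t2, limit=2)
        parts1 = {frozenset(t1.sequences[h] for h in c) for c in n1.components()}
        parts2 = {frozenset(t2.sequences[h] for h in c) for c in n2.components()}
        assert parts1 == parts2


class TestClassify:
    def _fixture(self):
        seqs = (["A" * 20] * 5 + ["A" * 19 + "T"] * 2      # group 1
                + ["C" * 10 + "A" * 10] * 4)               # group 2, far away
        taxa = ["mairei"] * 5 + ["taiwanese"] * 2 + ["taiwanese"] * 4
        recs = [(f"s{i}", s) for i, s in enumerate(seqs)]
        aln = Alignment(recs)
        smap = pd.DataFrame({"sample_id": [r[0] for r in recs],
                             "population": ["p"] * len(recs),
                             "taxon": taxa, "ploidy": [1] * len(recs)})
        table = aio.collapse_haplotypes(aln, smap)
        network = net.build_parsimony_network(table, limit=3)
        return network, table, smap

    def test_majority_taxon_labels_component(self):
        network, table, smap = self._fixture()
        asg = net.classify_haplogroups(network, table, smap)
        assert set(asg.haplotype_labels.values()) == {"mairei", "taiwanese"}
        # the two Taiwanese sequences inside the mairei-majority component
        counts = asg.counts("taiwanese")
        assert counts["mairei"] == 2
        assert counts["taiwanese"] == 4

    def test_single_component_single_haplogroup(self):
        table, smap = table_from_seqs(["AAAA", "AAAT"])
        network = net.build_parsimony_network(table, limit=3)
        asg = net.classify_haplogroups(network, table, smap)
        assert len(set(asg.haplotype_labels.values())) == 1

    def test_majority_tie_breaks_by_label_order_with_warning(self):
        seqs = ["G" * 8] * 3 + ["G" * 7 + "T"] * 3
        taxa = ["zeta"] * 3 + ["alpha"] * 3
        recs = [(f"s{i}", s) for i, s in enumerate(seqs)]
        smap = pd.DataFrame({"sample_id": [r[0] for r in recs],
                             "population": ["p"] * 6, "taxon": taxa,
                             "ploidy": [1] * 6})
        table = aio.collapse_haplotypes(Alignment(recs), smap)
        network = net.build_parsimony_network(table, limit=3)
        asg = net.classify_haplogroups(network, table, smap)
        assert set(asg.haplotype_labels.values()) == {"alpha"}
        assert asg.warnings

    def test_reference_haplotypes_cut_one_network(self):
        # one connected chain, but labels seeded at the two ends
        table, smap = table_from_seqs(
            ["AAAAAA", "AAAAAT", "AAAATT", "AAATTT"])
        network = net.build_parsimony_network(table, limit=6)
        asg = net.classify_haplogroups(
            network, table, smap,
            reference_haplotypes={"left": "H1", "right": "H4"})
        assert asg.haplotype_labels["H1"] == "left"
        assert asg.haplotype_labels["H2"] == "left"
        assert asg.haplotype_labels["H4"] == "right"

    def test_count_introgressed(self):
        network, table, smap = self._fixture()
        asg = net.classify_haplogroups(network, table, smap)
        count, total, percent = net.count_introgressed(asg, "taiwanese", "mairei")
        assert (count, total) == (2, 6)
        assert percent == pytest.approx(33.3)
        count, total, percent = net.count_introgressed(asg, "mairei", "taiwanese")
        assert (count, percent) == (0, 0.0)
        with pytest.raises(ValueError, match="taxon"):
            net.count_introgressed(asg, "nope", "mairei")
        with pytest.raises(ValueError, match="haplogroup"):
            net.count_introgressed(asg, "mairei", "nope")
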