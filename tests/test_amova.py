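"""Distance matrices, Phi-statistics, AMOVA and NJ clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from taxpop import amova as am
from taxpop.alignments import Alignment


def make_map(ids, pops, taxa):
    return pd.DataFrame({"sample_id": ids, "population": pops,
                         "taxon": taxa, "ploidy": [1] * len(ids)})


class TestSequenceDistance:
    def test_identical_and_single_difference(self):
        aln = Alignment([("a", "ACGT"), ("b", "ACGT"), ("c", "ACTT")])
        d = am.sequence_distance_matrix(aln).to_frame()
        assert d.loc["a", "b"] == 0
        assert d.loc["a", "c"] == 1

    def test_matches_bruteforce_column_scan(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGTN"))
        recs = [(f"s{i}", "".join(bases[rng.integers(0, 5, 50)]))
                for i in range(10)]
        aln = Alignment(recs)
        d = am.sequence_distance_matrix(aln, include_indel_chars=False).to_frame()
        for (ia, sa), (ib, sb) in itertools.combinations(recs, 2):
            expect = sum(1 for x, y in zip(sa, sb)
                         if x != "N" and y != "N" and x != y)
            assert d.loc[ia, ib] == expect

    def test_indel_characters_add_single_steps(self):
        aln = Alignment([("a", "AC--T"), ("b", "ACGGT")])
        with_ind = am.sequence_distance_matrix(aln, include_indel_chars=True)
        assert with_ind.to_frame().loc["a", "b"] == 1


# ---------------------------------------------------------------------------
# independent small-instance oracle: textbook nested ANOVA on distances,
# written with explicit loops


def _oracle_3level(d2, groups, pops):
    N = len(pops)
    def ssd(idx):
        return sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ssd_t = ssd(range(N))
    ssd_wg = sum(ssd([i for i in range(N) if groups[i] == g])
                 for g in sorted(set(groups)))
    ssd_wp = sum(ssd([i for i in range(N) if pops[i] == p])
                 for p in sorted(set(pops)))
    G, P = len(set(groups)), len(set(pops))
    m = {p: pops.count(p) for p in set(pops)}
    M = {g: groups.count(g) for g in set(groups)}
    grp_of = {p: groups[pops.index(p)] for p in set(pops)}
    A = sum(sum(m[p] ** 2 for p in m if grp_of[p] == g) / M[g] for g in M)
    B = sum(v ** 2 for v in m.values()) / N
    C = sum(v ** 2 for v in M.values()) / N
    sig_c = ssd_wp / (N - P)
    sig_b = ((ssd_wg - ssd_wp) / (P - G) - sig_c) / ((N - A) / (P - G))
    ms_ag = (ssd_t - ssd_wg) / (G - 1)
    sig_a = (ms_ag - sig_c - (A - B) / (G - 1) * sig_b) / ((N - C) / (G - 1))
    return sig_a, sig_b, sig_c


class TestAmova:
    def test_forced_partition_gives_phict_one(self):
        base, alt = "A" * 40, "C" * 10 + "A" * 30
        recs = ([(f"a{i}", base) for i in range(6)]
                + [(f"b{i}", alt) for i in range(6)])
        smap = make_map([r[0] for r in recs],
                        ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3,
                        ["A"] * 6 + ["B"] * 6)
        res = am.amova(Alignment(recs), smap, n_permutations=0)
        assert res.phi["Phi_CT"] == pytest.approx(1.0)
        assert res.table["percent"].iloc[0] == pytest.approx(100.0)

    def test_all_identical_sequences(self):
        recs = [(f"s{i}", "ACGT" * 5) for i in range(8)]
        smap = make_map([r[0] for r in recs],
                        ["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2 + ["p4"] * 2,
                        ["A"] * 4 + ["B"] * 4)
        res = am.amova(Alignment(recs), smap, n_permutations=0)
        assert (res.table["variance"] == 0).all()

    def test_components_match_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        recs = [(f"s{i}", "".join(bases[rng.integers(0, 4, 40)]))
                for i in range(12)]
        pops = ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 4 + ["p4"] * 2
        groups = ["A"] * 6 + ["B"] * 6
        smap = make_map([r[0] for r in recs], pops, groups)
        aln = Alignment(recs)
        res = am.amova(aln, smap, n_permutations=0)
        d2 = am.sequence_distance_matrix(aln).values
        sa, sb, sc = _oracle_3level(d2, groups, pops)
        assert res.table["variance"].to_numpy() == pytest.approx([sa, sb, sc])

    def test_percent_variation_sums_to_100(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        for trial in range(5):
            recs = [(f"s{i}", "".join(bases[rng.integers(0, 4, 30)]))
                    for i in range(10)]
            smap = make_map([r[0] for r in recs],
                            ["p1"] * 3 + ["p2"] * 2 + ["p3"] * 3 + ["p4"] * 2,
                            ["A"] * 5 + ["B"] * 5)
            res = am.amova(Alignment(recs), smap, n_permutations=0)
            assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_diploid_design_reports_phi_is(self):
        rng = np.random.default_rng(10)
        bases = np.array(list("ACGT"))
        recs = []
        for i in range(8):
            for h in (1, 2):
                recs.append((f"i{i}_h{h}", "".join(bases[rng.integers(0, 4, 30)])))
        smap = make_map([f"i{i}" for i in range(8)],
                        ["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2 + ["p4"] * 2,
                        ["A"] * 4 + ["B"] * 4)
        smap["ploidy"] = 2
        res = am.amova(Alignment(recs, ploidy_mode="diploid_phased"), smap,
                       n_permutations=0)
        assert set(res.phi) == {"Phi_CT", "Phi_SC", "Phi_ST", "Phi_IS"}
        assert len(res.table) == 4
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)


class TestPairwisePhist:
    def test_fixed_populations_give_one(self):
        phi, _ = am.pairwise_phist(["A" * 20] * 4, ["C" * 5 + "A" * 15] * 4)
        assert phi == pytest.approx(1.0)

    def test_panmictic_samples_give_near_zero(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        pool = ["".join(bases[rng.integers(0, 4, 60)]) for _ in range(4)]
        values = []
        for _ in range(10):
            seqs = [pool[i] for i in rng.integers(0, 4, 16)]
            phi, _ = am.pairwise_phist(seqs[:8], seqs[8:])
            values.append(phi)
        assert abs(np.mean(values)) < 0.1

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            am.pairwise_phist(["ACGT"], ["ACGT", "ACGT"])

    def test_equals_two_population_amova(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        seqs_a = ["".join(bases[rng.integers(0, 4, 30)]) for _ in range(4)]
        seqs_b = ["".join(bases[rng.integers(0, 4, 30)]) for _ in range(4)]
        phi, _ = am.pairwise_phist(seqs_a, seqs_b)
        recs = ([(f"a{i}", s) for i, s in enumerate(seqs_a)]
                + [(f"b{i}", s) for i, s in enumerate(seqs_b)])
        smap = make_map([r[0] for r in recs], ["pa"] * 4 + ["pb"] * 4, ["x"] * 8)
        res = am.amova(Alignment(recs), smap, n_permutations=0)
        assert phi == pytest.approx(res.phi["Phi_ST"])

    def test_null_permutation_pvalues_are_uniform(self):
        # single panmictic pool split arbitrarily in two: the rejection
        # rate at alpha must sit within binomial tolerance of alpha
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        n_rep, n_perm, alpha = 200, 60, 0.05
        rejections = 0
        for rep in range(n_rep):
            pool = ["".join(bases[rng.integers(0, 4, 20)]) for _ in range(3)]
            seqs = [pool[i] for i in rng.integers(0, 3, 12)]
            _, p = am.pairwise_phist(seqs[:6], seqs[6:],
                                     n_permutations=n_perm, seed=int(rng.integers(2**31)))
            if p is not None and p <= alpha:
                rejections += 1
        rate = rejections / n_rep
        tol = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rate <= alpha + tol


class TestNjTree:
    def test_recovers_additive_four_taxon_tree(self):
        # tree ((a:2,b:3):6,(c:1,d:2)) with internal edge summed into the
        # unrooted trifurcation; the matrix is exactly additive
        dm = am.DistanceMatrix(
            list("abcd"),
            np.array([[0, 5, 9, 10], [5, 0, 10, 11],
                      [9, 10, 0, 3], [10, 11, 3, 0]], dtype=float))
        newick = am.nj_tree(dm)
        import dendropy
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (x, y), expect in {("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 10,
                               ("b", "c"): 10, ("b", "d"): 11, ("c", "d"): 3}.items():
            assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(expect)

    def test_three_taxon_tie_is_deterministic(self):
        dm = am.DistanceMatrix(list("abc"), np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float))
        assert am.nj_tree(dm) == am.nj_tree(dm)

    def test_label_permutation_permutes_leaves_only(self):
        rng = np.random.default_rng(14)
        vals = rng.random((5, 5))
        d = np.triu(vals, 1)
        d = d + d.T
        labels = list("vwxyz")
        dm1 = am.nj_tree(am.DistanceMatrix(labels, d))
        perm = [3, 1, 4, 0, 2]
        dm2 = am.nj_tree(am.DistanceMatrix(
            [labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert dm1 == dm2   # input label order is canonicalised

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            am.nj_tree(am.DistanceMatrix(["a", "b"], np.zeros((2, 2))))
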