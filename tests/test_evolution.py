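import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mapkascade import evolution as evo
from mapkascade import simulate as sim

NT_PARAMS = evo.AlignParams(matrix=None, match=1.0, mismatch=-1.0,
                            gap_open=-2.0, gap_extend=-2.0)


def _brute_force_best_score(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Enumerate every global alignment of two tiny sequences (linear
    gap penalty) and return the best score."""
    best = [-math.inf]

    def go(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            go(i + 1, j, score + gap)
        if j < len(b):
            go(i, j + 1, score + gap)

    go(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = evo.global_align("MKWVTFI", "MKWVTFI")
        assert aln.aligned_a == aln.aligned_b == "MKWVTFI"
        identity, coverage = evo.pair_identity_coverage(aln, 7, 7)
        assert (identity, coverage) == (100.0, 1.0)

    def test_tiny_alignment_matches_exhaustive_enumeration(self):
        aln = evo.global_align("ACGT", "ACT", NT_PARAMS)
        assert aln.score == _brute_force_best_score("ACGT", "ACT")
        assert sum(1 for c in aln.aligned_a + aln.aligned_b if c == "-") == 1

    def test_random_tiny_pairs_match_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            aln = evo.global_align(a, b, NT_PARAMS)
            assert aln.score == pytest.approx(_brute_force_best_score(a, b))

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=25))
            assert evo.global_align(a, b).score == evo.global_align(b, a).score

    def test_degapping_recovers_inputs(self):
        aln = evo.global_align("MKWTFI", "MKWVTFIE")
        assert aln.aligned_a.replace("-", "") == "MKWTFI"
        assert aln.aligned_b.replace("-", "") == "MKWVTFIE"

    def test_invalid_alphabet_raises(self):
        with pytest.raises(ValueError):
            evo.global_align("AC1T", "ACT", NT_PARAMS)


class TestIdentityCoverage:
    def test_seven_matches_over_ten_columns(self):
        from mapkascade.models import PairwiseAlignment
        aln = PairwiseAlignment("ACGTACGTAC", "ACGTACGGGG", 0.0)
        identity, coverage = evo.pair_identity_coverage(aln, 10, 10)
        assert (identity, coverage) == (70.0, 1.0)

    def test_counting_oracle_on_random_alignments(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 40)))
            aln = evo.global_align(a, b, NT_PARAMS)
            cols = list(zip(aln.aligned_a, aln.aligned_b))
            matches = sum(1 for x, y in cols if x == y != "-")
            paired = sum(1 for x, y in cols if "-" not in (x, y))
            identity, coverage = evo.pair_identity_coverage(aln, len(a), len(b))
            assert identity == pytest.approx(100 * matches / len(cols))
            assert coverage == pytest.approx(paired / max(len(a), len(b)))


class TestClassifyTandem:
    COORDS = pd.DataFrame(
        {"chrom": ["c2", "c2", "c2", "c2", "c1"], "order": [1, 2, 3, 4, 1]},
        index=["gA", "gB", "gC", "gD", "gE"])

    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b",
                                           "identity_pct", "coverage_frac"])

    def test_adjacent_high_identity_pair_is_tandem(self):
        pairs = self._pairs([("gA", "gB", 73.56, 0.9)])
        out, events = evo.classify_tandem(pairs, self.COORDS)
        assert len(out) == 1 and out["dup_type"].iloc[0] == "TD"
        assert events == 1

    def test_low_identity_rejected(self):
        pairs = self._pairs([("gA", "gB", 65.0, 0.9)])
        out, events = evo.classify_tandem(pairs, self.COORDS)
        assert len(out) == 0 and events == 0

    def test_different_chromosome_rejected(self):
        pairs = self._pairs([("gA", "gE", 95.0, 0.95)])
        out, _ = evo.classify_tandem(pairs, self.COORDS)
        assert len(out) == 0

    def test_too_distant_rejected_unless_slack_raised(self):
        pairs = self._pairs([("gA", "gD", 95.0, 0.95)])
        out, _ = evo.classify_tandem(pairs, self.COORDS, max_intervening=1)
        assert len(out) == 0
        out, _ = evo.classify_tandem(pairs, self.COORDS, max_intervening=2)
        assert len(out) == 1

    def test_cluster_counts_one_event_for_linked_pairs(self):
        pairs = self._pairs([("gA", "gB", 80.0, 0.9),
                             ("gA", "gC", 78.0, 0.9)])
        out, events = evo.classify_tandem(pairs, self.COORDS,
                                          max_intervening=1)
        assert len(out) == 2
        assert events == 1
        assert out["cluster"].nunique() == 1

    def test_unknown_gene_raises(self):
        pairs = self._pairs([("gA", "gZ", 80.0, 0.9)])
        with pytest.raises(KeyError, match="gZ"):
            evo.classify_tandem(pairs, self.COORDS)


class TestCodonAlign:
    def test_gapless_alignment_concatenates_codons(self):
        from mapkascade.models import PairwiseAlignment
        cds_a, cds_b = "ATGAAA", "ATGAAG"
        aln = PairwiseAlignment("MK", "MK", 0.0)
        assert evo.codon_align(aln, cds_a, cds_b) == (cds_a, cds_b)

    def test_protein_gap_becomes_codon_gap(self):
        from mapkascade.models import PairwiseAlignment
        aln = PairwiseAlignment("M-K", "MEK", 0.0)
        ca, cb = evo.codon_align(aln, "ATGAAA", "ATGGAGAAG")
        assert ca == "ATG---AAA"
        assert cb == "ATGGAGAAG"

    def test_translation_mismatch_names_position(self):
        from mapkascade.models import PairwiseAlignment
        aln = PairwiseAlignment("MK", "MK", 0.0)
        with pytest.raises(ValueError, match="residue 1"):
            evo.codon_align(aln, "ATGGGG", "ATGAAA")

    def test_back_translation_consistency_on_simulated_pairs(self):
        for seed in range(5):
            anc = sim.random_cds(60, seed=seed)
            a, b = sim.simulate_duplicate_pair(anc, 0.1, seed=seed,
                                               target_ka=0.05)
            aln = evo.global_align(evo.translate_cds(a), evo.translate_cds(b))
            ca, cb = evo.codon_align(aln, a, b)
            assert evo.translate_cds(ca.replace("-", "")) == \
                aln.aligned_a.replace("-", "")
            assert evo.translate_cds(cb.replace("-", "")) == \
                aln.aligned_b.replace("-", "")


class TestNG86:
    def test_identical_sequences(self):
        ka, ks, ratio = evo.ng86_kaks("ATGAAA", "ATGAAA")
        assert (ka, ks) == (0.0, 0.0)
        assert ratio is None

    def test_hand_counted_synonymous_example(self):
        # ten TTT codons vs nine TTT plus one TTC: S = 10/3, Sd = 1,
        # pS = 0.3, Ks = -0.75 ln(0.6)
        ka, ks, ratio = evo.ng86_kaks("TTT" * 10, "TTT" * 9 + "TTC")
        assert ka == 0.0
        assert ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-10)
        assert ratio == 0.0

    def test_internal_stop_raises(self):
        with pytest.raises(ValueError, match="stop"):
            evo.ng86_kaks("ATGTAAATG", "ATGTAAATG")

    def test_length_not_multiple_of_three_raises(self):
        with pytest.raises(ValueError):
            evo.ng86_kaks("ATGA", "ATGA")

    def test_agrees_with_biopython_reference(self):
        """Independent oracle: Bio.Align.analysis NG86 on the same
        codon alignments."""
        from Bio.Align import PairwiseAligner
        from Bio.Align.analysis import calculate_dn_ds
        aligner = PairwiseAligner()
        for seed in range(8):
            anc = sim.random_cds(120, seed=100 + seed)
            a, b = sim.simulate_duplicate_pair(anc, 0.15, seed=seed,
                                               target_ka=0.05)
            ka, ks, _ = evo.ng86_kaks(a, b)
            aln = next(iter(aligner.align(a, b)))
            dn, ds = calculate_dn_ds(aln, method="NG86")
            # small slack: the reference averages mutational pathways
            # through stop codons, this implementation excludes them
            # when a stop-free pathway exists
            assert ka == pytest.approx(dn, abs=0.01)
            assert ks == pytest.approx(ds, abs=0.01)

    def test_synonymous_only_simulation_gives_zero_ka(self):
        anc = sim.random_cds(100, seed=9)
        a, b = sim.simulate_duplicate_pair(anc, 0.3, seed=9)
        ka, ks, _ = evo.ng86_kaks(a, b)
        assert ka == 0.0
        assert ks > 0


class TestClockArithmetic:
    def test_ratio_matches_published_rows(self):
        assert evo.kaks_ratio(0.0091, 0.1896) == pytest.approx(0.047996, abs=5e-7)
        assert evo.kaks_ratio(0.1927, 1.2025) == pytest.approx(0.160249, abs=5e-7)

    def test_ratio_zero_and_undefined(self):
        assert evo.kaks_ratio(0.0, 0.5) == 0.0
        assert evo.kaks_ratio(0.1, 0.0) is None

    def test_ratio_scale_invariance(self):
        assert evo.kaks_ratio(0.2, 0.8) == pytest.approx(
            evo.kaks_ratio(0.2 * 7.3, 0.8 * 7.3))

    def test_divergence_time_published_rows(self):
        assert evo.divergence_time(0.1896, 6.1e-9) == pytest.approx(15.54, abs=5e-3)
        assert evo.divergence_time(1.2025, 6.1e-9) == pytest.approx(98.57, abs=5e-3)

    def test_divergence_time_zero_and_linear(self):
        assert evo.divergence_time(0.0, 6.1e-9) == 0.0
        assert evo.divergence_time(0.4, 6.1e-9) == pytest.approx(
            2 * evo.divergence_time(0.2, 6.1e-9))


def _random_additive_tree(n_leaves, rng):
    """Random binary tree; returns (leaf labels, distance matrix)."""
    labels = [f"t{i}" for i in range(n_leaves)]
    # start from a 2-leaf tree, attach remaining leaves to random edges
    # tree as dict node -> list of (child, branch length); node 0 = root
    parent = {}
    edges = []  # (u, v, length)
    node_count = n_leaves  # internal nodes numbered from n_leaves
    adj = {i: [] for i in range(n_leaves)}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    add_edge(0, 1, float(rng.uniform(0.1, 2.0)))
    for leaf in range(2, n_leaves):
        # pick a random existing edge, split it with a new internal node
        u = int(rng.choice([k for k in adj if adj[k]]))
        v, w = adj[u][int(rng.integers(len(adj[u])))]
        adj[u] = [(x, y) for x, y in adj[u] if x != v or y != w]
        adj[v] = [(x, y) for x, y in adj[v] if x != u or y != w]
        mid = node_count
        node_count += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, leaf, float(rng.uniform(0.1, 2.0)))
    # all-pairs leaf distances by BFS
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j in range(n_leaves):
            d[i, j] = dist[j]
    return labels, d


def _patristic_from_newick(newick, labels):
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestNeighborJoining:
    def test_two_taxa(self):
        assert evo.nj_tree([[0, 1.0], [1.0, 0]], ["A", "B"]) == \
            "(A:0.5,B:0.5);"

    def test_four_taxon_split_and_lengths_vs_least_squares_oracle(self):
        # additive matrix from ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        d[2, 3] = d[3, 2] = 7.0
        newick = evo.nj_tree(d, labels)
        # oracle: least-squares branch fit over the 3 unrooted topologies
        best = None
        for split in (("A", "B"), ("A", "C"), ("A", "D")):
            others = [x for x in labels if x not in split]
            pairs = list(itertools.combinations(range(4), 2))
            idx = {name: i for i, name in enumerate(labels)}
            # branch order: eA,eB,eC,eD,internal
            design = []
            for i, j in pairs:
                row = [0.0] * 5
                row[i] = row[j] = 1.0
                group_i = labels[i] in split
                group_j = labels[j] in split
                row[4] = 0.0 if group_i == group_j else 1.0
                design.append(row)
            y = np.array([d[i, j] for i, j in pairs])
            coef, res, *_ = np.linalg.lstsq(np.array(design), y, rcond=None)
            rss = float(((np.array(design) @ coef - y) ** 2).sum())
            if best is None or rss < best[0]:
                best = (rss, split)
        assert best[1] == ("A", "B")
        patristic = _patristic_from_newick(newick, labels)
        np.testing.assert_allclose(patristic, d, atol=1e-9)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(12)
        for n in (4, 5, 6, 7, 8):
            for _ in range(4):
                labels, d = _random_additive_tree(n, rng)
                newick = evo.nj_tree(d, labels)
                patristic = _patristic_from_newick(newick, labels)
                np.testing.assert_allclose(patristic, d, atol=1e-8)

    def test_asymmetric_matrix_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            evo.nj_tree([[0, 1], [2, 0]], ["A", "B"])


class TestNeutralSimulatorConsistency:
    def test_ka_approx_ks_under_neutral_rates(self):
        """Under equal planted synonymous and nonsynonymous rates the
        NG86 estimates should not differ systematically."""
        from scipy import stats
        kas, kss = [], []
        for seed in range(60):
            anc = sim.random_cds(200, seed=2000 + seed)
            a, b = sim.simulate_duplicate_pair(anc, 0.1, seed=seed,
                                               target_ka=0.1)
            ka, ks, _ = evo.ng86_kaks(a, b)
            kas.append(ka)
            kss.append(ks)
        t = stats.ttest_rel(kas, kss)
        assert t.pvalue > 0.01
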