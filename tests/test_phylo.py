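"""Distances, clustering, neighbor joining, bootstrap and tree diagnostics."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bafscreen import (
    Alignment,
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    f84_distance,
    kmeans_1d,
    nj_tree,
    placement_report,
    robinson_foulds,
    select_panel,
    tn93_distance,
)
from bafscreen.phylo import _bipartitions


def tn93_by_hand(n, ts1, ts2, tv, freqs):
    """Direct numeric evaluation of the TN93 closed form from counts."""
    pA, pC, pG, pT = freqs
    pR, pY = pA + pG, pC + pT
    P1, P2, Q = ts1 / n, ts2 / n, tv / n
    k1 = 2 * pA * pG / pR
    k2 = 2 * pC * pT / pY
    k3 = 2 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
    return (
        -k1 * math.log(1 - P1 / k1 - Q / (2 * pR))
        - k2 * math.log(1 - P2 / k2 - Q / (2 * pY))
        - k3 * math.log(1 - Q / (2 * pR * pY))
    )


class TestTN93:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 100
        assert tn93_distance(s, s) == 0.0

    def test_pure_transversions_match_hand_formula(self):
        # 8 frequency-preserving transversions (A<->T, C<->G) in 160 sites
        a = "AAAACCCCGGGGTTTT" * 10
        b = list(a)
        b[0], b[1] = "T", "T"
        b[4], b[5] = "G", "G"
        b[8], b[9] = "C", "C"
        b[12], b[13] = "A", "A"
        b = "".join(b)
        expected = tn93_by_hand(160, 0, 0, 8, (0.25, 0.25, 0.25, 0.25))
        assert tn93_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_mixed_substitutions_match_hand_counts(self):
        rng = np.random.default_rng(1)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), size=5000))
        b = list(a)
        idx = rng.choice(5000, size=150, replace=False)
        for i in idx:
            b[i] = bases[(bases.index(b[i]) + rng.integers(1, 4)) % 4]
        b = "".join(b)
        # independent counting
        purines = set("AG")
        ts1 = sum(
            1 for x, y in zip(a, b) if x != y and x in purines and y in purines
        )
        ts2 = sum(
            1 for x, y in zip(a, b) if x != y and x not in purines and y not in purines
        )
        tv = sum(1 for x, y in zip(a, b) if x != y and (x in purines) != (y in purines))
        counts = {c: (a + b).count(c) for c in bases}
        tot = sum(counts.values())
        freqs = tuple(counts[c] / tot for c in bases)
        expected = tn93_by_hand(5000, ts1, ts2, tv, freqs)
        assert tn93_distance(a, b) == pytest.approx(expected, rel=1e-9)

    def test_masking_differing_site_cannot_increase_distance(self):
        a = "ACGT" * 50
        b = "TCGT" + "ACGT" * 49  # one transversion at site 1
        d_full = tn93_distance(a, b)
        b_masked = "NCGT" + "ACGT" * 49
        assert tn93_distance(a, b_masked) <= d_full

    def test_het_codes_equivalent_to_missing(self):
        a = "ACGT" * 50
        b = "RCGT" + "ACGT" * 49
        c = "NCGT" + "ACGT" * 49
        assert tn93_distance(a, b) == tn93_distance(a, c)

    def test_zero_usable_sites_is_error(self):
        with pytest.raises(ValueError):
            tn93_distance("NNNN", "ACGT")


class TestF84:
    def test_identical_zero(self):
        assert f84_distance("ACGT" * 50, "ACGT" * 50) == 0.0

    def test_jc_limit_at_equal_frequencies(self):
        # ratio 0.5 with equal base frequencies has no transition bias:
        # the ML distance collapses to Jukes-Cantor
        rng = np.random.default_rng(3)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), size=40000))
        b = list(a)
        idx = rng.choice(40000, size=2000, replace=False)
        for i in idx:
            b[i] = bases[(bases.index(b[i]) + rng.integers(1, 4)) % 4]
        b = "".join(b)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert f84_distance(a, b, 0.5) == pytest.approx(jc, abs=2e-4)

    def test_matches_matrix_exponential_grid_oracle(self):
        # independent likelihood via expm of the F84 rate matrix on a grid
        from scipy.linalg import expm
        from bafscreen.phylo import _f84_rates, _pair_counts
        from bafscreen._seq import encode

        rng = np.random.default_rng(5)
        bases = "ACGT"
        a = "".join(rng.choice(list(bases), p=[0.3, 0.2, 0.3, 0.2], size=8000))
        b = list(a)
        idx = rng.choice(8000, size=240, replace=False)
        for i in idx:
            b[i] = bases[(bases.index(b[i]) + rng.integers(1, 4)) % 4]
        b = "".join(b)
        tstv = 0.7
        n, ts1, ts2, tv, freqs, xtab = _pair_counts(encode(a), encode(b))
        aR, aY = _f84_rates(freqs, tstv)
        pA, pC, pG, pT = freqs
        # F84 rate matrix (A C G T), beta = 1
        rates = np.zeros((4, 4))
        for i, j in itertools.permutations(range(4), 2):
            rates[i, j] = freqs[j]
        rates[0, 2] *= aR
        rates[2, 0] *= aR
        rates[1, 3] *= aY
        rates[3, 1] *= aY
        np.fill_diagonal(rates, -rates.sum(axis=1))
        mu = -np.dot(freqs, np.diag(rates))

        def ll(d):
            P = expm(rates * d / mu)
            return (xtab * np.log(np.maximum(P, 1e-300))).sum()

        grid = np.linspace(1e-4, 0.2, 4001)
        d_oracle = grid[int(np.argmax([ll(d) for d in grid]))]
        assert f84_distance(a, b, tstv) == pytest.approx(d_oracle, abs=1e-4)


class TestKmeans1D:
    def test_separated_pairs(self):
        labels = kmeans_1d([0.0, 0.1, 10.0, 10.1], 2)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_singletons_zero_loss(self):
        vals = [3.0, 1.0, 2.0]
        labels = kmeans_1d(vals, 3)
        assert sorted(labels) == [0, 1, 2]

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            kmeans_1d([1.0, 1.0, 2.0], 3)

    @staticmethod
    def brute_force_loss(values, K):
        xs = sorted(values)
        n = len(xs)
        best = math.inf
        for cuts in itertools.combinations(range(1, n), K - 1):
            bounds = [0, *cuts, n]
            loss = 0.0
            for lo, hi in zip(bounds, bounds[1:]):
                seg = xs[lo:hi]
                m = sum(seg) / len(seg)
                loss += sum((x - m) ** 2 for x in seg)
            best = min(best, loss)
        return best

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=4,
            max_size=12,
            unique=True,
        ),
        st.integers(min_value=1, max_value=4),
    )
    def test_globally_optimal_vs_enumeration(self, values, K):
        labels = kmeans_1d(values, K)
        loss = 0.0
        for k in set(labels):
            seg = [v for v, lab in zip(values, labels) if lab == k]
            m = sum(seg) / len(seg)
            loss += sum((x - m) ** 2 for x in seg)
        assert loss == pytest.approx(self.brute_force_loss(values, K), abs=1e-8)


class TestSelectPanel:
    def test_k_equal_to_count_selects_all(self):
        dists = {f"s{i}": float(i) for i in range(5)}
        assert sorted(select_panel(dists, 5, seed=0)) == sorted(dists)

    def test_52_of_168(self):
        rng = np.random.default_rng(8)
        dists = {f"s{i}": float(v) for i, v in enumerate(rng.random(168))}
        chosen = select_panel(dists, 52, seed=1)
        assert len(chosen) == len(set(chosen)) == 52

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        dists = {f"s{i}": float(v) for i, v in enumerate(rng.random(30))}
        assert select_panel(dists, 7, seed=4) == select_panel(dists, 7, seed=4)


def matrix_from_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], D, np.full((n, n), 1000))


class TestNeighborJoining:
    def test_exact_on_additive_four_taxon_matrix(self):
        D = matrix_from_tree("((A:1,B:2):1,(C:3,D:4):1);")
        tree = nj_tree(D)
        assert _bipartitions(tree) == {frozenset({"A", "B"})} or _bipartitions(
            tree
        ) == {frozenset({"C", "D"})}
        # branch lengths recovered exactly (leaf edges)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4}, abs=1e-9)

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]]),
            np.full((3, 3), 100),
        )
        tree = nj_tree(D)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0}, abs=1e-12)

    def test_equal_distances_deterministic(self):
        D = DistanceMatrix(
            list("ABCDE"), np.ones((5, 5)) - np.eye(5), np.full((5, 5), 100)
        )
        t1 = nj_tree(D).as_string("newick")
        t2 = nj_tree(D).as_string("newick")
        assert t1 == t2

    def test_undefined_distances_rejected(self):
        M = np.ones((4, 4)) - np.eye(4)
        M[0, 1] = M[1, 0] = np.nan
        D = DistanceMatrix(list("ABCD"), M, np.full((4, 4), 100))
        with pytest.raises(ValueError, match="A"):
            nj_tree(D)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_recovers_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa = [f"t{i}" for i in range(n)]
        # random binary topology with strictly positive branch lengths
        import random as pyrandom

        from dendropy.simulate import treesim

        tns = dendropy.TaxonNamespace(taxa)
        true = treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            taxon_namespace=tns,
            num_extant_tips=n,
            rng=pyrandom.Random(seed),
        )
        for e in true.preorder_edge_iter():
            if e.length is not None:
                e.length = float(rng.uniform(0.1, 2.0))
        pdm = true.phylogenetic_distance_matrix()
        ts = sorted(tns, key=lambda t: t.label)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(ts[i], ts[j])
        est = nj_tree(DistanceMatrix([t.label for t in ts], D, np.full((n, n), 100)))
        assert robinson_foulds(est, true) == 0

    def test_agrees_with_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        n = 7
        pts = rng.random((n, 3))
        M = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"x{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(labels, M, np.full((n, n), 100)))
        theirs = skbio_nj(SkbioDM(M, ids=labels))
        theirs_dp = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert robinson_foulds(mine, theirs_dp) == 0


class TestBootstrap:
    def _two_clade_alignment(self, L=10_000, seed=0):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        root = rng.integers(0, 4, L)

        def mutate(seq, p):
            out = seq.copy()
            hits = rng.random(L) < p
            out[hits] = (out[hits] + rng.integers(1, 4, hits.sum())) % 4
            return out

        left = mutate(root, 0.05)
        right = mutate(root, 0.05)
        seqs = {}
        for i in range(2):
            seqs[f"L{i}"] = "".join(bases[mutate(left, 0.001)])
            seqs[f"R{i}"] = "".join(bases[mutate(right, 0.001)])
        return Alignment.from_dict(seqs)

    def test_clear_split_gets_full_support(self):
        aln = self._two_clade_alignment()
        res = bootstrap_support(aln, n_reps=50, seed=3)
        assert res.supports
        assert all(s == 100.0 for s in res.supports.values())

    def test_single_replicate_supports_are_binary(self):
        aln = self._two_clade_alignment(L=2000, seed=5)
        res = bootstrap_support(aln, n_reps=1, seed=1)
        assert set(res.supports.values()) <= {0.0, 100.0}

    def test_hundred_replicates_integer_percent(self):
        aln = self._two_clade_alignment(L=1000, seed=7)
        res = bootstrap_support(aln, n_reps=100, seed=2)
        assert res.n_replicates == 100
        for s in res.supports.values():
            assert s == pytest.approx(round(s), abs=1e-9)


class TestPhylipOutput:
    def test_square_matrix_format(self, tmp_path):
        from bafscreen.phylo import write_phylip_distances

        D = DistanceMatrix(
            ["alpha", "averyverylongname", "c"],
            np.array([[0, 0.1, 0.2], [0.1, 0, np.nan], [0.2, np.nan, 0]]),
            np.full((3, 3), 100),
        )
        path = tmp_path / "d.phy"
        write_phylip_distances(D, path)
        lines = path.read_text().splitlines()
        assert lines[0].strip() == "3"
        assert lines[1].startswith("alpha     0.000000")
        assert lines[2][:10] == "averyveryl"  # 10-character name field
        assert "-1.000000" in lines[2]  # undefined sentinel


class TestPlacement:
    def test_baseline_against_itself(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,(F:0.5,D:1):0.5):1,E:2);", schema="newick")
        rep = placement_report(t, "F", {"C"}, {"D"}, baseline_tree=t, outgroup="E")
        assert rep["rf"] == 0
        assert rep["within_recipient"]
        assert not rep["sister_to_contaminant"]

    def test_rf_of_single_nni_is_two(self):
        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t1, t1) == 0

    def test_missing_focal_rejected(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(ValueError):
            placement_report(t, "Z", {"A"}, {"B"})
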