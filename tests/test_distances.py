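import numpy as np
import pytest

from mitobias.distances import (
    DistanceMatrix,
    bf_distance,
    bf_distance_matrix,
    jc_distance_matrix,
    logdet_distance_matrix,
    neighbor_joining,
    sample_quartets,
    tally_quartet_topologies,
)
from mitobias.seq_data import Alignment
from mitobias.treeutils import has_split, robinson_foulds, to_newick


class TestBFDistance:
    def test_identity(self):
        assert bf_distance([0.3, 0.2, 0.1, 0.4], [0.3, 0.2, 0.1, 0.4]) == 0.0

    def test_disjoint_maximal(self):
        assert bf_distance([1, 0, 0, 0], [0, 1, 0, 0]) == 1.0

    def test_direct_evaluation(self):
        got = bf_distance([0.4, 0.3, 0.2, 0.1], [0.25, 0.25, 0.25, 0.25])
        assert got == pytest.approx(0.20)

    def test_half_l1_oracle_random(self, rng):
        for _ in range(200):
            p, q = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
            assert bf_distance(p, q) == pytest.approx(0.5 * np.abs(p - q).sum())

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(1000):
            p, q, r = (rng.dirichlet(np.ones(4)) for _ in range(3))
            dpq, dqr, dpr = bf_distance(p, q), bf_distance(q, r), bf_distance(p, r)
            assert dpq >= 0
            assert dpq == pytest.approx(bf_distance(q, p))
            assert dpr <= dpq + dqr + 1e-12

    def test_mismatched_alphabets(self):
        with pytest.raises(ValueError):
            bf_distance([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_generalizes_to_aa_vectors(self, rng):
        p, q = rng.dirichlet(np.ones(20)), rng.dirichlet(np.ones(20))
        assert bf_distance(p, q) == pytest.approx(0.5 * np.abs(p - q).sum())


class TestBFMatrix:
    def test_identical_profiles_zero(self):
        p = [0.25, 0.25, 0.25, 0.25]
        dm = bf_distance_matrix({"a": p, "b": p, "c": p})
        assert np.allclose(dm.values, 0.0)

    def test_matches_pairwise_loop(self, rng):
        profiles = {f"t{i}": rng.dirichlet(np.ones(4)) for i in range(5)}
        dm = bf_distance_matrix(profiles)
        for i, a in enumerate(profiles):
            for j, b in enumerate(profiles):
                assert dm.values[i, j] == pytest.approx(
                    bf_distance(profiles[a], profiles[b])
                )

    def test_permutation_consistency(self, rng):
        profiles = {f"t{i}": rng.dirichlet(np.ones(4)) for i in range(4)}
        dm = bf_distance_matrix(profiles)
        rev = bf_distance_matrix(dict(reversed(list(profiles.items()))))
        assert rev.get("t0", "t2") == pytest.approx(dm.get("t0", "t2"))


class TestLogDet:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACGTACGT"] * 3, "nt4")
        dm = logdet_distance_matrix(aln)
        assert dm.get("a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_grows_with_divergence(self, rng):
        """Distance increases with substitutions under a non-stationary process."""
        from mitobias.likelihood import gtr_model, simulate_under_model
        from mitobias.treeutils import from_newick

        dists = []
        for t in (0.05, 0.3, 0.8):
            tree = from_newick(f"(a:{t / 2},b:{t / 2});")
            model = gtr_model("nt4", freqs=np.array([0.4, 0.1, 0.2, 0.3]))
            aln = simulate_under_model(tree, model, 4000, np.random.default_rng(5))
            dists.append(logdet_distance_matrix(aln).get("a", "b"))
        assert dists[0] < dists[1] < dists[2]

    def test_unrelated_sequences_large(self, rng):
        data = rng.choice(list("ACGT"), size=(2, 2000))
        aln = Alignment(["a", "b"], ["".join(r) for r in data] + [], "nt4")
        aln = Alignment(["a", "b", "c"], ["".join(r) for r in data] + ["".join(rng.choice(list("ACGT"), size=2000))], "nt4")
        dm = logdet_distance_matrix(aln)
        assert dm.get("a", "b") > 1.0 or not np.isfinite(dm.get("a", "b"))

    def test_too_few_shared_columns_flagged(self):
        aln = Alignment(["a", "b", "c"], ["AC??", "??GT", "ACGT"], "nt4")
        dm = logdet_distance_matrix(aln)
        assert np.isnan(dm.get("a", "b"))
        assert dm.flags[("a", "b")] == "undefined"


class TestNeighborJoining:
    def test_additive_matrix_recovers_tree(self):
        # quartet ((a,b),(c,d)) with branch lengths a=2,b=3,c=4,d=5, inner=1
        taxa = ["a", "b", "c", "d"]
        vals = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(taxa, vals))
        assert has_split(tree, {"a", "b"})
        # exact branch lengths on the additive matrix
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(2.0)
        assert lengths["d"] == pytest.approx(5.0)

    def test_three_taxa_closed_form(self):
        vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], vals))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_ultrametric_consistent_with_upgma_topology(self):
        # clean ultrametric: ((a,b),(c,d)) with heights 1 < 2 < 3
        taxa = ["a", "b", "c", "d"]
        vals = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(taxa, vals))
        assert has_split(tree, {"a", "b"}) and has_split(tree, {"c", "d"})

    def test_no_negative_lengths(self, rng):
        vals = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        vals[iu] = rng.uniform(0.01, 1.0, size=len(iu[0]))
        vals = vals + vals.T
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(5)], vals))
        for e in tree.preorder_edge_iter():
            assert e.length is None or e.length >= 0

    def test_nonfinite_rejected(self):
        vals = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], vals))


class TestMLDistances:
    def test_recovers_pairwise_divergence(self):
        from mitobias.distances import ml_distance_matrix
        from mitobias.likelihood import gtr_model, simulate_under_model
        from mitobias.treeutils import from_newick

        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        tree = from_newick("(a:0.12,b:0.18);")
        aln = simulate_under_model(tree, model, 20_000, np.random.default_rng(3))
        dm = ml_distance_matrix(aln, model)
        assert dm.get("a", "b") == pytest.approx(0.30, rel=0.08)

    def test_saturated_pair_stays_bounded(self, rng):
        from mitobias.distances import ml_distance_matrix
        from mitobias.likelihood import gtr_model

        rows = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(2)]
        aln = Alignment(["a", "b"], rows, "nt4")
        dm = ml_distance_matrix(aln, gtr_model("nt4"))
        assert np.isfinite(dm.get("a", "b"))


class TestOLSBranchLengths:
    def test_additive_matrix_reproduced(self):
        from mitobias.treeutils import from_newick, ols_branch_lengths

        nwk = "((a:2.0,b:3.0):1.0,c:4.0,d:5.0);"
        taxa = ["a", "b", "c", "d"]
        vals = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        tree = ols_branch_lengths(from_newick(nwk), vals, taxa)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(2.0, abs=1e-6)
        assert lengths["d"] == pytest.approx(5.0, abs=1e-6)


class TestQuartets:
    def test_empty_sample(self):
        gm = {"x1": "g1", "x2": "g2", "x3": "g3", "x4": "g4"}
        assert sample_quartets(gm, ["g1", "g2", "g3", "g4"], 0, 1) == []

    def test_seed_reproducibility(self):
        gm = {f"t{i}": f"g{i % 4}" for i in range(12)}
        pat = ["g0", "g1", "g2", "g3"]
        assert sample_quartets(gm, pat, 50, 9) == sample_quartets(gm, pat, 50, 9)

    def test_within_group_sampling_uniform(self):
        gm = {f"t{i}": "g0" if i < 3 else f"g{1 + (i - 3) % 3}" for i in range(12)}
        pat = ["g0", "g1", "g2", "g3"]
        qs = sample_quartets(gm, pat, 3000, 3)
        first = [q[0] for q in qs]
        for t in {t for t, g in gm.items() if g == "g0"}:
            freq = first.count(t) / len(first)
            assert abs(freq - 1 / 3) < 0.03  # ~3.5 sigma binomial

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            sample_quartets({"a": "g1"}, ["g1", "g2", "g3", "g4"], 5, 1)

    def test_tally_conservation_and_degenerate(self):
        aln = Alignment(["a", "b", "c", "d"], ["AAAA"] * 4, "nt4")
        tally = tally_quartet_topologies(
            aln, [("a", "b", "c", "d")] * 5, method="logdet_nj"
        )
        assert sum(tally.counts.values()) == tally.n_quartets == 5
        assert tally.counts["unresolved"] == 5

    def test_stationary_gtr_quartet_recovered(self):
        """Long stationary-GTR quartets resolve to the generating topology."""
        from mitobias.likelihood import gtr_model, simulate_under_model
        from mitobias.treeutils import from_newick

        tree = from_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        aln = simulate_under_model(tree, model, 5000, np.random.default_rng(11))
        for method in ("logdet_nj", "ml_gtr"):
            tally = tally_quartet_topologies(
                aln, [("a", "b", "c", "d")], method=method, pattern=list("wxyz")
            )
            assert tally.counts["w,x|y,z"] == 1, method


def test_logdet_beats_jc_under_composition_shift():
    """On single-class data with clade-specific composition (third codon
    positions, where the shift is strongest), LogDet quartets recover the
    generating topology while Jukes-Cantor quartets are pulled to the
    compositional grouping.  LogDet's guarantee is per homogeneous site
    class, so the check isolates one class and isolates composition from
    the long-branch factor."""
    from mitobias.simulate import robust_like_config, simulate_alignment

    hits = {"logdet_nj": 0, "jc_nj": 0}
    n = 12
    for rep in range(n):
        cfg = robust_like_config(
            n_per_group=1,
            n_codons=3000,
            seed=1000 + rep,
            rate_multiplier=1.0,
            depths={"robust_stem": 0.2, "outgroup_stem": 0.2, "backbone": 0.04},
        )
        aln, _ = simulate_alignment(cfg)
        pos3 = Alignment(aln.taxon_ids, aln.data[:, 2::3], "nt4")
        quartet = [("robust_1", "complex_1", "corallimorph_1", "outgroup_1")]
        for method in hits:
            tally = tally_quartet_topologies(
                pos3, quartet, method=method, pattern=list("rcmo")
            )
            hits[method] += tally.counts["r,c|m,o"]
    assert hits["logdet_nj"] > hits["jc_nj"]
    assert hits["logdet_nj"] > n // 2
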