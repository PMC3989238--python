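import itertools

import numpy as np
import pytest

from mitobias.alphabets import resolve
from mitobias.likelihood import (
    PruningEngine,
    discrete_gamma_rates,
    empirical_frequencies,
    exclude_fast_sites,
    fit_model,
    gtr_model,
    jtt_model,
    nni_search,
    optimize_branch_lengths,
    posterior_site_rates,
    simulate_under_model,
    site_log_likelihoods,
)
from mitobias.seq_data import Alignment
from mitobias.treeutils import from_newick, robinson_foulds, to_arrays, to_newick


def enumeration_site_loglik(aln, tree, model):
    """Independent oracle: sum over all internal-state assignments."""
    arr = to_arrays(tree)
    rates, weights, p_inv = model.mixture()
    k = model.k
    idx = {s: i for i, s in enumerate(resolve(aln.alphabet))}
    pi = model.equilibrium_freqs
    internal = [i for i in range(arr.n_nodes) if i not in arr.leaf_taxon]
    out = []
    for site in range(aln.n_columns):
        obs = {
            nid: idx.get(aln.data[aln.taxon_ids.index(taxon), site], -1)
            for nid, taxon in arr.leaf_taxon.items()
        }
        lik_mix = 0.0
        for r, wgt in zip(rates, weights):
            mats = {
                i: model.transition_matrices(arr.edge_length[i], np.array([r]))[0]
                for i in range(arr.n_nodes)
                if arr.parent[i] >= 0
            }
            lik = 0.0
            for assign in itertools.product(range(k), repeat=len(internal)):
                amap = dict(zip(internal, assign))
                pr = pi[amap[arr.root]]
                for i in range(arr.n_nodes):
                    if arr.parent[i] < 0:
                        continue
                    ps = amap[int(arr.parent[i])]
                    if i in arr.leaf_taxon:
                        pr *= 1.0 if obs[i] < 0 else mats[i][ps, obs[i]]
                    else:
                        pr *= mats[i][ps, amap[i]]
                lik += pr
            lik_mix += wgt * lik
        if p_inv > 0:
            seen = {o for o in obs.values() if o >= 0}
            if len(seen) <= 1:
                lik_mix += p_inv * (pi[seen.pop()] if seen else 1.0)
        out.append(np.log(lik_mix))
    return np.array(out)


def _random_model(alphabet, rng, gamma=True, p_inv=0.0):
    if alphabet == "aa20":
        return jtt_model(gamma_shape=0.7 if gamma else None, n_categories=3,
                         p_invariant=p_inv)
    k = len(resolve(alphabet))
    S = np.abs(rng.normal(1, 0.3, (k, k)))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0)
    f = rng.dirichlet(np.ones(k) * 5)
    return gtr_model(alphabet, S, f, gamma_shape=0.7 if gamma else None,
                     n_categories=3, p_invariant=p_inv)


FIVE_TAXON_TREE = "((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.08,E:0.4);"


class TestPruningOracle:
    @pytest.mark.parametrize("alphabet", ["nt4", "ry2", "aa4", "aa6", "aa20"])
    def test_matches_enumeration_all_alphabets(self, alphabet, rng):
        tree = from_newick(FIVE_TAXON_TREE)
        syms = resolve(alphabet)
        data = ["".join(rng.choice(list(syms + "-?"), size=5)) for _ in range(5)]
        aln = Alignment(list("ABCDE"), data, alphabet)
        model = _random_model(alphabet, rng, p_inv=0.15)
        got = site_log_likelihoods(aln, tree, model).values
        want = enumeration_site_loglik(aln, tree, model)
        assert np.abs(got - want).max() < 1e-8

    def test_zero_branch_identical_pair(self):
        model = gtr_model("nt4", freqs=np.array([0.1, 0.2, 0.3, 0.4]))
        tree = from_newick("(A:0.0,B:0.0);")
        aln = Alignment(["A", "B"], ["C", "C"], "nt4")
        got = site_log_likelihoods(aln, tree, model).values[0]
        assert got == pytest.approx(np.log(0.2), abs=1e-9)

    def test_long_branch_independence_limit(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4])
        model = gtr_model("nt4", freqs=pi)
        tree = from_newick("(A:18.0,B:18.0);")
        aln = Alignment(["A", "B"], ["A", "T"], "nt4")
        got = site_log_likelihoods(aln, tree, model).values[0]
        assert got == pytest.approx(np.log(pi[0]) + np.log(pi[3]), abs=1e-4)

    def test_invariant_to_taxon_order_and_rerooting(self, rng):
        aln_rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        model = _random_model("nt4", rng)
        a1 = Alignment(list("ABCDE"), aln_rows, "nt4")
        order = [3, 1, 4, 0, 2]
        a2 = Alignment([list("ABCDE")[i] for i in order],
                       [aln_rows[i] for i in order], "nt4")
        t1 = from_newick(FIVE_TAXON_TREE)
        t2 = from_newick(FIVE_TAXON_TREE)
        node = next(
            n for n in t2.postorder_internal_node_iter() if n.parent_node is not None
        )
        t2.reroot_at_node(node, update_bipartitions=False)
        l1 = site_log_likelihoods(a1, t1, model).total
        l2 = site_log_likelihoods(a2, t2, model).total
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_gamma_infinite_shape_is_rate_homogeneous(self, rng):
        aln = Alignment(list("ABCDE"),
                        ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)],
                        "nt4")
        tree = from_newick(FIVE_TAXON_TREE)
        homo = gtr_model("nt4", freqs=np.full(4, 0.25))
        gam = gtr_model("nt4", freqs=np.full(4, 0.25), gamma_shape=5e4, n_categories=5)
        l1 = site_log_likelihoods(aln, tree, homo).total
        l2 = site_log_likelihoods(aln, tree, gam).total
        assert l1 == pytest.approx(l2, abs=1e-3)


class TestEdgeDecomposition:
    def test_edge_factorisation_equals_full_likelihood(self, rng):
        """For every edge, lnL computed from the inside partial, the outside
        partial and that edge's transition matrix equals the full pruning
        lnL — at the current length and at perturbed lengths."""
        tree = from_newick(FIVE_TAXON_TREE)
        model = _random_model("nt4", rng)
        aln = Alignment(
            list("ABCDE"),
            ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(5)],
            "nt4",
        )
        eng = PruningEngine(aln, tree, model)
        rates, weights, _ = model.mixture()
        logw = np.log(weights)
        L, lsL, W, lsW = eng._edge_caches(rates)
        for e in range(eng.arrays.n_nodes):
            if eng.arrays.parent[e] < 0:
                continue
            keep = eng.arrays.edge_length[e]
            for t in (keep, 0.01, 0.7):
                eng.arrays.edge_length[e] = t
                full = eng.log_likelihood()
                via_edge = eng._edge_loglik(
                    L[e], lsL[e], W[e], lsW[e], t, rates, logw
                )
                assert via_edge == pytest.approx(full, abs=1e-8)
            eng.arrays.edge_length[e] = keep

    def test_fast_sweeps_approach_exact_optimum(self, rng):
        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                          gamma_shape=0.7, n_categories=3)
        true = from_newick("((A:0.1,B:0.3):0.15,(C:0.2,D:0.05):0.08,E:0.4);")
        aln = simulate_under_model(true, model, 400, np.random.default_rng(77))
        start = "((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5,E:0.5);"
        e1 = PruningEngine(aln, from_newick(start), model)
        fast = e1.fast_length_sweeps(4)
        e2 = PruningEngine(aln, from_newick(start), model)
        exact = e2.optimize_branch_lengths()
        assert fast >= exact - 1.0


class TestDiscreteGamma:
    def test_mean_is_one(self):
        for alpha in (0.2, 0.5, 1.0, 3.0):
            rates = discrete_gamma_rates(alpha, 5)
            assert rates.mean() == pytest.approx(1.0)
            assert (np.diff(rates) > 0).all()

    def test_small_alpha_is_more_dispersed(self):
        r_small = discrete_gamma_rates(0.3, 5)
        r_big = discrete_gamma_rates(3.0, 5)
        assert r_small.std() > r_big.std()


class TestBranchOptimization:
    def test_lnl_never_decreases_and_recovers_length(self, rng):
        true = from_newick("(A:0.08,B:0.22);")
        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        aln = simulate_under_model(true, model, 20_000, np.random.default_rng(3))
        start = from_newick("(A:0.5,B:0.5);")
        eng = PruningEngine(aln, start, model)
        l0 = eng.log_likelihood()
        l1 = eng.optimize_branch_lengths()
        assert l1 >= l0
        total = eng.arrays.edge_length.sum()
        assert total == pytest.approx(0.30, rel=0.1)

    def test_zero_variation_collapses_lengths(self):
        aln = Alignment(list("ABCD"), ["AAAA"] * 4, "nt4")
        tree = from_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);")
        tree, _ = optimize_branch_lengths(aln, tree, gtr_model("nt4"))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length < 1e-4


class TestFitModel:
    def test_gamma_shape_recovery(self):
        true_alpha = 0.5
        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                          gamma_shape=true_alpha, n_categories=5)
        tree = from_newick("((A:0.3,B:0.3):0.12,(C:0.3,D:0.3):0.12);")
        aln = simulate_under_model(tree, model, 10_000, np.random.default_rng(9))
        fitted, _, _ = fit_model(aln, tree, "GTR+G+F", outer_rounds=2)
        assert fitted.gamma_shape == pytest.approx(true_alpha, rel=0.25)

    def test_gtr_exchangeability_recovery(self):
        S = np.array(
            [[0, 1, 4, 1], [1, 0, 1, 4], [4, 1, 0, 1], [1, 4, 1, 0]], dtype=float
        )
        model = gtr_model("nt4", S, np.array([0.3, 0.2, 0.2, 0.3]))
        tree = from_newick("((A:0.25,B:0.25):0.1,(C:0.25,D:0.25):0.1);")
        aln = simulate_under_model(tree, model, 10_000, np.random.default_rng(17))
        fitted, _, _ = fit_model(aln, tree, "GTR+F", outer_rounds=2)
        est = fitted.exchangeabilities
        # normalize both to the G-T rate
        ratio_true = S[0, 2] / S[2, 3]
        ratio_est = est[0, 2] / est[2, 3]
        assert ratio_est == pytest.approx(ratio_true, rel=0.10)

    def test_ry_data_uses_two_states(self):
        from mitobias.recoding import ry_recode

        rng = np.random.default_rng(2)
        aln = Alignment(list("ABCD"),
                        ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(4)],
                        "nt4")
        ry = ry_recode(aln)
        tree = from_newick("((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);")
        fitted, _, _ = fit_model(ry, tree, "GTR+F", outer_rounds=1)
        assert fitted.k == 2

    def test_bic_prefers_true_simpler_model(self):
        """BIC of the generating (rate-homogeneous) family is no worse than
        the over-parameterised +G+I alternative on large simulated data."""
        from mitobias.likelihood import compare_models

        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        tree = from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = simulate_under_model(tree, model, 8_000, np.random.default_rng(23))
        table = compare_models(aln, tree, ["GTR+F", "GTR+G+I+F"], outer_rounds=1)
        assert table.loc["GTR+F", "BIC"] <= table.loc["GTR+G+I+F", "BIC"] + 1e-6


class TestSiteRates:
    def test_invariable_site_below_one(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), size=29)) + "A" for _ in range(4)]
        aln = Alignment(list("ABCD"), rows, "nt4")
        tree = from_newick("((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);")
        model = gtr_model("nt4", gamma_shape=0.5, n_categories=5)
        sr = posterior_site_rates(aln, tree, model)
        assert sr.values[-1] < 1.0
        assert sr.values.mean() == pytest.approx(1.0)

    def test_identical_sites_all_equal_one(self):
        aln = Alignment(list("ABCD"), ["ACA", "ACC", "ACG", "ACT"], "nt4")
        # every column distinct but all sites of a column-type equal
        aln = Alignment(list("ABCD"), ["AAAA", "CCCC", "GGGG", "TTTT"], "nt4")
        tree = from_newick("((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);")
        model = gtr_model("nt4", gamma_shape=0.8, n_categories=4)
        sr = posterior_site_rates(aln, tree, model)
        assert np.allclose(sr.values, 1.0)

    def test_matches_bayes_rule_toy(self):
        """3-site toy: ER from the engine equals a direct Bayes computation."""
        aln = Alignment(["A", "B"], ["AAG", "AAT"], "nt4")
        tree = from_newick("(A:0.2,B:0.2);")
        model = gtr_model("nt4", gamma_shape=1.0, n_categories=3)
        sr = posterior_site_rates(aln, tree, model)

        rates, weights, _ = model.mixture()
        ers = []
        for site in range(3):
            liks = []
            for r in rates:
                P = model.transition_matrices(0.4, np.array([r]))[0]
                i = "ACGT".index(aln.data[0, site])
                j = "ACGT".index(aln.data[1, site])
                liks.append(model.equilibrium_freqs[i] * P[i, j])
            liks = np.array(liks) * weights
            ers.append((rates * liks / liks.sum()).sum())
        ers = np.array(ers)
        ers = ers / ers.mean()
        assert np.allclose(sr.values, ers, atol=1e-8)


class TestFastSiteExclusion:
    def test_identity_and_empty_limits(self, random_nt_alignment):
        tree_n = random_nt_alignment.n_taxa
        rates = posterior_site_rates(
            random_nt_alignment,
            from_newick(
                "(" + ",".join(f"s{i}:0.2" for i in range(tree_n)) + ");"
            ),
            gtr_model("nt4", gamma_shape=0.5),
        )
        full, f0 = exclude_fast_sites(random_nt_alignment, rates, np.inf)
        assert f0 == 0.0 and full.n_columns == random_nt_alignment.n_columns
        empty, f1 = exclude_fast_sites(random_nt_alignment, rates, 0.0)
        assert empty.n_columns == 0 and f1 == 1.0

    def test_fraction_monotone_in_threshold(self, random_nt_alignment):
        tree = from_newick(
            "(" + ",".join(f"s{i}:0.2" for i in range(random_nt_alignment.n_taxa)) + ");"
        )
        rates = posterior_site_rates(
            random_nt_alignment, tree, gtr_model("nt4", gamma_shape=0.5)
        )
        fracs = [
            exclude_fast_sites(random_nt_alignment, rates, thr)[1]
            for thr in (2.99, 1.99, 1.49, 0.75)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestNNISearch:
    def test_four_taxa_equals_exhaustive(self):
        true_tree = from_newick("((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08);")
        model = gtr_model("nt4", freqs=np.array([0.3, 0.2, 0.2, 0.3]))
        aln = simulate_under_model(true_tree, model, 3000, np.random.default_rng(31))
        # exhaustive over the 3 quartet topologies
        tops = [
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);",
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1);",
            "((A:0.1,D:0.1):0.1,(B:0.1,C:0.1):0.1);",
        ]
        scores = []
        for nwk in tops:
            _, lnl = optimize_branch_lengths(aln, from_newick(nwk), model)
            scores.append(lnl)
        best_exhaustive = max(scores)
        start = from_newick(tops[1])
        found, lnl = nni_search(aln, model, start)
        assert lnl == pytest.approx(best_exhaustive, abs=0.05)
        assert robinson_foulds(to_newick(found), tops[0]) == 0

    def test_final_lnl_not_below_start(self, rng):
        aln = Alignment(
            list("ABCDE"),
            ["".join(rng.choice(list("ACGT"), size=100)) for _ in range(5)],
            "nt4",
        )
        model = gtr_model("nt4")
        start = from_newick(FIVE_TAXON_TREE)
        _, l_start = optimize_branch_lengths(aln, start, model)
        _, l_final = nni_search(aln, model, from_newick(FIVE_TAXON_TREE))
        assert l_final >= l_start - 1e-6


class TestSimulateUnderModel:
    def test_composition_converges_to_equilibrium(self):
        pi = np.array([0.55, 0.05, 0.1, 0.3])
        model = gtr_model("nt4", freqs=pi)
        tree = from_newick("(A:6.0,B:6.0);")
        aln = simulate_under_model(tree, model, 30_000, np.random.default_rng(41))
        freqs = empirical_frequencies(aln)
        assert np.abs(freqs - pi).max() < 0.015

    def test_deterministic_under_seed(self):
        model = gtr_model("nt4", gamma_shape=0.5)
        tree = from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        a = simulate_under_model(tree, model, 500, np.random.default_rng(5))
        b = simulate_under_model(tree, model, 500, np.random.default_rng(5))
        assert a == b
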