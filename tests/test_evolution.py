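"""Model distances, NJ reconstruction, bootstrap supports, model choice."""

import logging
import math

import numpy as np
import pytest

from invadiv.dataio import ValidationError
from invadiv.evolution import (SaturationError, SubstitutionModel,
                               bootstrap_condense, distance_matrix,
                               evolve_pair, fit_model,
                               mean_between_population_distance, nj_tree,
                               pairwise_model_distance, select_model,
                               simulate_alignment)
from invadiv.simulate import make_worked_example


def random_additive_matrix(n_taxa: int, rng) -> np.ndarray:
    """Path-length matrix of a random binary tree with random edge lengths."""
    groups = [{i: 0.0} for i in range(n_taxa)]   # leaf -> distance to subtree root
    D = np.zeros((n_taxa, n_taxa))
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), size=2, replace=False))
        ra, rb = rng.uniform(0.1, 2.0, size=2)
        a, b = groups[i], groups[j]
        for la, da in a.items():
            for lb, db in b.items():
                D[la, lb] = D[lb, la] = da + ra + db + rb
        merged = {la: da + ra for la, da in a.items()}
        merged.update({lb: db + rb for lb, db in b.items()})
        del groups[j], groups[i]
        groups.append(merged)
    return D


def _model(name, **params):
    defaults = {"K2P": {"kappa": 2.0}, "HKY85": {"kappa": 2.0},
                "TN93": {"kappa1": 2.0, "kappa2": 2.0}}
    return SubstitutionModel(name, params=params or defaults.get(name, {}))


class TestDistances:
    @pytest.mark.parametrize("name", ["JC69", "K2P", "HKY85", "TN93"])
    def test_identical_pair_is_zero_under_every_model(self, name):
        seq = "ACGT" * 30
        assert pairwise_model_distance(seq, seq, _model(name)) == \
               pytest.approx(0.0, abs=1e-12)

    def test_jc_closed_form_at_p_ten_percent(self):
        # 10 mismatches over 100 sites: d = -3/4 ln(1 - 4*0.1/3)
        s1 = "A" * 100
        s2 = "C" * 10 + "A" * 90
        d = pairwise_model_distance(s1, s2, _model("JC69"))
        assert d == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-12)
        assert d == pytest.approx(0.10733, abs=5e-6)

    def test_k2p_matches_formula_oracle(self):
        # P = 0.08 transitions (A<->G), Q = 0.02 transversions (A<->C)
        s1 = "A" * 100
        s2 = "G" * 8 + "C" * 2 + "A" * 90
        d = pairwise_model_distance(s1, s2, _model("K2P"))
        P, Q = 0.08, 0.02
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_gamma_correction_exceeds_plain_distance(self):
        s1 = "A" * 100
        s2 = "C" * 15 + "A" * 85
        plain = pairwise_model_distance(s1, s2, _model("JC69"))
        g = SubstitutionModel("JC69", gamma=True, gamma_shape=0.3)
        assert pairwise_model_distance(s1, s2, g) > plain

    def test_distances_increase_with_nested_mutation_sets(self):
        base = "ACGT" * 50
        prev = {name: 0.0 for name in ("JC69", "K2P", "TN93")}
        for k in (2, 6, 12, 20):
            mutated = "".join(
                ("C" if c == "A" else "A") if i < k else c
                for i, c in enumerate(base))
            for name in prev:
                d = pairwise_model_distance(base, mutated, _model(name))
                assert d >= prev[name]
                prev[name] = d

    def test_saturation_is_an_explicit_error(self):
        s1 = "A" * 40
        s2 = "C" * 30 + "A" * 10   # p = 0.75 saturates the JC log
        with pytest.raises(SaturationError):
            pairwise_model_distance(s1, s2, _model("JC69"))

    def test_ambiguous_sites_excluded_pairwise(self):
        s1 = "ANGTA" * 20
        s2 = "ACGTN" * 20
        d = pairwise_model_distance(s1, s2, _model("JC69"))
        assert d == pytest.approx(0.0, abs=1e-12)


class TestMeanBetweenPopulations:
    def test_identical_populations_give_zero(self):
        pop = ["ACGT" * 20] * 4
        assert mean_between_population_distance(pop, pop, _model("JC69")) == 0

    def test_two_by_two_toy_equals_hand_average(self):
        ps = make_worked_example({"a": [(1, 0), (1, 2)],
                                  "b": [(1, 4), (1, 5)]}, length=100)
        a, b = ps.sequences("a"), ps.sequences("b")
        jc = _model("JC69")
        pairs = [pairwise_model_distance(x, y, jc) for x in a for y in b]
        assert mean_between_population_distance(a, b, jc) == \
               pytest.approx(np.mean(pairs), abs=1e-12)

    def test_two_clades_recover_realized_divergence(self):
        # two populations fixed for haplotypes 30 sites apart over 1000 bp
        ps = make_worked_example({"a": [(5, 0)], "b": [(5, 30)]}, length=1000)
        d = mean_between_population_distance(ps.sequences("a"),
                                             ps.sequences("b"),
                                             _model("JC69"))
        realized_p = 0.03
        assert abs(d - realized_p) / realized_p < 0.10  # JC ~ p at small p

    def test_net_distance_subtracts_within_group_means(self):
        ps = make_worked_example({"a": [(2, 0), (2, 2)], "b": [(4, 10)]},
                                 length=200)
        a, b = ps.sequences("a"), ps.sequences("b")
        jc = _model("JC69")
        plain = mean_between_population_distance(a, b, jc)
        net = mean_between_population_distance(a, b, jc, net=True)
        within_a = pairwise_model_distance(a[0], a[2], jc) * 4 / 6  # 4 mixed pairs of 6
        assert net == pytest.approx(plain - 0.5 * within_a, abs=1e-12)


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        D = np.array([[0, 5, 9, 9], [5, 0, 10, 10],
                      [9, 10, 0, 8], [9, 10, 8, 0]], float)
        tree = nj_tree(D, list("abcd"))
        pdm = tree.tree.phylogenetic_distance_matrix()
        tns = tree.tree.taxon_namespace
        for i in range(4):
            for j in range(i + 1, 4):
                assert pdm.distance(tns[i], tns[j]) == pytest.approx(
                    D[i, j], abs=1e-12)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(D, list("abc"))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_random_additive_matrices_reproduced_as_path_lengths(self, rng):
        for n_taxa in (5, 6, 8):
            for _ in range(3):
                D = random_additive_matrix(n_taxa, rng)
                taxa = [f"t{i}" for i in range(n_taxa)]
                out = nj_tree(D, taxa)
                opdm = out.tree.phylogenetic_distance_matrix()
                otns = out.tree.taxon_namespace
                for i in range(n_taxa):
                    for j in range(i + 1, n_taxa):
                        assert opdm.distance(
                            otns.get_taxon(taxa[i]), otns.get_taxon(taxa[j])
                        ) == pytest.approx(D[i, j], rel=1e-9)

    def test_ultrametric_matrix_matches_upgma_clusters(self):
        # clusters ((a,b),(c,d)),e at heights 1 < 2 < 3
        D = np.array([
            [0, 2, 4, 4, 6],
            [2, 0, 4, 4, 6],
            [4, 4, 0, 2, 6],
            [4, 4, 2, 0, 6],
            [6, 6, 6, 6, 0]], float)
        tree = nj_tree(D, list("abcde"))
        parts = set()
        all_labels = frozenset("abcde")
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            parts.add(min(below, all_labels - below,
                          key=lambda s: (len(s), tuple(sorted(s)))))
        assert parts == {frozenset("ab"), frozenset("cd")}

    def test_agreement_with_reference_nj_implementation(self, rng):
        import skbio

        def canon_parts(pairs_iter, all_labels):
            out = set()
            for below in pairs_iter:
                below = frozenset(below)
                if 2 <= len(below) <= len(all_labels) - 2:
                    out.add(min(below, all_labels - below,
                                key=lambda s: (len(s), tuple(sorted(s)))))
            return out

        n = 7
        taxa = [f"t{i}" for i in range(n)]
        D = random_additive_matrix(n, rng)
        all_labels = frozenset(taxa)
        ours = nj_tree(D, taxa)
        ours_parts = canon_parts(
            ([lf.taxon.label for lf in node.leaf_iter()]
             for node in ours.tree.preorder_node_iter()
             if not node.is_leaf() and node.parent_node is not None),
            all_labels)
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=taxa))
        ref_parts = canon_parts(
            ([t.name for t in node.tips()] for node in ref.non_tips()),
            all_labels)
        assert ours_parts == ref_parts

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            nj_tree(np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], float),
                    list("abc"))


class TestBootstrap:
    def test_strong_split_retained_with_high_support(self):
        ps = make_worked_example({"a": [(4, 0)], "b": [(4, 30)]}, length=500)
        seqs = [r.sequence for r in ps.records]
        labels = [r.id for r in ps.records]
        tree = bootstrap_condense(seqs, labels, _model("JC69"),
                                  n_boot=100, threshold=75, seed=0)
        supports = [int(n.label) for n in tree.tree.preorder_node_iter()
                    if n.label and not n.is_leaf()]
        assert supports and max(supports) > 99

    def test_uninformative_alignment_collapses_to_star(self):
        tree = bootstrap_condense(["ACGT" * 50] * 5,
                                  [f"t{i}" for i in range(5)],
                                  _model("JC69"), n_boot=20, seed=0)
        internal = [n for n in tree.tree.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert internal == []

    def test_threshold_above_100_collapses_everything(self):
        seqs, labels = simulate_alignment(7, 400, _model("JC69"),
                                          tree_scale=0.05, seed=3)
        tree = bootstrap_condense(seqs, labels, _model("JC69"), n_boot=30,
                                  threshold=101, seed=0)
        internal = [n for n in tree.tree.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert internal == []

    def test_supports_invariant_to_input_order_after_sorting(self):
        ps = make_worked_example({"a": [(3, 0)], "b": [(3, 25)]}, length=300)
        recs = list(ps.records)
        def run(records):
            ordered = sorted(records, key=lambda r: r.id)
            return bootstrap_condense([r.sequence for r in ordered],
                                      [r.id for r in ordered],
                                      _model("JC69"), n_boot=50,
                                      seed=11).newick
        assert run(recs) == run(list(reversed(recs)))

    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_condense(["ACGT"] * 3, list("abc"), _model("JC69"),
                               n_boot=0)


class TestModelSelection:
    def test_two_haplotype_input_falls_back_to_jc(self, caplog):
        with caplog.at_level(logging.WARNING, logger="invadiv"):
            model = select_model(["AAAA"] * 3 + ["AAAC"] * 2)
        assert model.name == "JC69"
        assert "falling back" in caplog.text

    def test_jc_data_selects_jc(self):
        wins = 0
        for seed in range(20):
            seqs, labels = simulate_alignment(8, 509, _model("JC69"),
                                              tree_scale=0.02, seed=100 + seed)
            wins += select_model(seqs, labels).label == "JC69"
        assert wins >= 16  # >= 80% of replicates

    def test_transition_bias_selects_kappa_model(self):
        wins = 0
        biased = SubstitutionModel("K2P", params={"kappa": 8.0})
        for seed in range(20):
            seqs, labels = simulate_alignment(8, 509, biased,
                                              tree_scale=0.05, seed=200 + seed)
            wins += select_model(seqs, labels).name in ("K2P", "HKY85", "TN93")
        assert wins >= 18  # >= 90% of replicates

    def test_bic_penalises_parameters_on_equal_likelihood(self):
        seqs, labels = simulate_alignment(6, 400, _model("JC69"),
                                          tree_scale=0.03, seed=7)
        jc_fit = fit_model(seqs, labels, "JC69", gamma=False)
        k2p_fit = fit_model(seqs, labels, "K2P", gamma=False)
        assert k2p_fit.lnL >= jc_fit.lnL - 1e-6   # nested model
        assert k2p_fit.bic - jc_fit.bic >= \
               -2 * (k2p_fit.lnL - jc_fit.lnL) + math.log(400) - 1e-6


def test_jc_distance_inverts_simulation_within_15_percent():
    jc = SubstitutionModel("JC69")
    estimates = []
    for seed in range(20):
        a, b = evolve_pair(0.1, 10000, jc, seed=seed)
        estimates.append(pairwise_model_distance(a, b, jc))
    assert abs(np.mean(estimates) - 0.1) / 0.1 < 0.15


def test_distance_matrix_caps_saturated_pairs_when_asked(rng):
    seqs = ["A" * 40, "C" * 30 + "A" * 10, "A" * 39 + "C"]
    with pytest.raises(SaturationError):
        distance_matrix(seqs, SubstitutionModel("JC69"))
    capped = distance_matrix(seqs, SubstitutionModel("JC69"),
                             saturation_value=10.0)
    assert capped[0, 1] == 10.0 and capped[0, 2] < 1.0
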