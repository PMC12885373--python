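"""Diversity metrics: closed forms, metric axioms, scikit-bio cross-checks."""

import io

import numpy as np
import pytest

from ampbias.compositions import clr, make_contrast_matrix, perturb, phi, phi_inverse
from ampbias.diversity import (
    DistanceMatrix,
    MetricSpec,
    TreeIndex,
    alpha_diversity,
    beta_diversity,
    distance_matrix,
    read_newick,
    write_newick,
)
from ampbias.synthetic import simulate_tree


class TestAlphaClosedForms:
    def test_uniform_three_taxa(self):
        u = np.full(3, 1 / 3)
        assert alpha_diversity(u, "shannon") == pytest.approx(np.log(3), abs=1e-12)
        assert alpha_diversity(u, "simpson") == pytest.approx(2 / 3, abs=1e-12)
        assert alpha_diversity(u, "gini") == pytest.approx(0.0, abs=1e-12)
        assert alpha_diversity(u, "aitchison_norm") == pytest.approx(0.0, abs=1e-12)

    def test_shannon_hand_value(self):
        assert alpha_diversity([0.5, 0.25, 0.25], "shannon") == pytest.approx(
            1.5 * np.log(2), abs=1e-12
        )

    def test_aitchison_norm_hand_value(self):
        assert alpha_diversity([0.8, 0.2], "aitchison_norm") == pytest.approx(
            np.log(4) / np.sqrt(2), abs=1e-12
        )

    def test_gini_degenerate_limit(self):
        eps = 1e-6
        val = alpha_diversity([1 - 2 * eps, eps, eps], "gini")
        assert val == pytest.approx(2 / 3, abs=1e-5)

    def test_shannon_bounded_by_log_D(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            d = rng.integers(2, 10)
            c = rng.dirichlet(np.ones(d))
            assert alpha_diversity(c, "shannon") <= np.log(d) + 1e-12
        assert alpha_diversity(np.full(5, 0.2), "shannon") == pytest.approx(np.log(5), abs=1e-12)

    def test_beta_metric_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            alpha_diversity([0.5, 0.5], "bray_curtis")


class TestBetaClosedForms:
    def test_identical_compositions_zero(self, alr3):
        c = np.array([0.5, 0.3, 0.2])
        tree = TreeIndex(simulate_tree(["a", "b", "c"], 0), ["a", "b", "c"])
        for metric in ("bray_curtis", "aitchison_distance", "weighted_unifrac"):
            assert beta_diversity(c, c, metric, tree=tree) == pytest.approx(0.0, abs=1e-12)

    def test_bray_curtis_limit(self):
        eps = 1e-9
        d = beta_diversity([0.5 - eps, 0.5, eps], [eps, 0.5, 0.5 - eps], "bray_curtis")
        assert d == pytest.approx(0.5, abs=1e-6)

    def test_unifrac_cherry(self):
        tree = read_newick("(A:1,B:1);")
        idx = TreeIndex(tree, ["A", "B"])
        eps = 1e-12
        p, q = np.array([1 - eps, eps]), np.array([eps, 1 - eps])
        assert idx.weighted_unifrac(p, q, normalized=True) == pytest.approx(1.0, abs=1e-9)
        assert idx.weighted_unifrac(p, q, normalized=False) == pytest.approx(2.0, abs=1e-9)

    def test_aitchison_hand_value(self):
        d = beta_diversity([0.8, 0.2], [0.2, 0.8], "aitchison_distance")
        assert d == pytest.approx(np.sqrt(2) * np.log(4), abs=1e-12)

    def test_unifrac_requires_tree(self):
        with pytest.raises(ValueError, match="tree"):
            beta_diversity([0.5, 0.5], [0.4, 0.6], "weighted_unifrac")

    def test_unifrac_taxon_mismatch_rejected(self):
        tree = simulate_tree(["a", "b", "c"], 0)
        with pytest.raises(ValueError):
            beta_diversity(
                [0.3, 0.3, 0.4], [0.2, 0.4, 0.4], "weighted_unifrac", tree=tree,
                taxon_ids=["a", "b", "WRONG"],
            )


class TestMetricProperties:
    def test_bray_curtis_bounds_and_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            d = rng.integers(2, 8)
            p, q = rng.dirichlet(np.ones(d)), rng.dirichlet(np.ones(d))
            v = beta_diversity(p, q, "bray_curtis")
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(beta_diversity(q, p, "bray_curtis"), abs=1e-15)

    def test_normalized_unifrac_bounds(self):
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(6)]
        idx = TreeIndex(simulate_tree(labels, 11), labels)
        for _ in range(200):
            p, q = rng.dirichlet(np.ones(6)), rng.dirichlet(np.ones(6))
            v = idx.weighted_unifrac(p, q, normalized=True)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(idx.weighted_unifrac(q, p), abs=1e-15)

    def test_aitchison_metric_axioms(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            d = rng.integers(2, 7)
            a, b, c = (rng.dirichlet(np.ones(d)) for _ in range(3))
            dab = beta_diversity(a, b, "aitchison_distance")
            dba = beta_diversity(b, a, "aitchison_distance")
            dac = beta_diversity(a, c, "aitchison_distance")
            dcb = beta_diversity(c, b, "aitchison_distance")
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-10  # triangle inequality
        assert beta_diversity(a, a, "aitchison_distance") == pytest.approx(0.0, abs=1e-12)

    def test_aitchison_invariant_but_bray_unifrac_sensitive(self):
        # joint perturbation: the geometry behind immunity to shared PCR bias
        rng = np.random.default_rng(6)
        labels = [f"t{i}" for i in range(5)]
        idx = TreeIndex(simulate_tree(labels, 2), labels)
        psi = make_contrast_matrix("alr", 5)
        worst_ait, worst_bray, worst_uni = 0.0, 0.0, 0.0
        for _ in range(1000):
            e1, e2 = rng.standard_normal((2, 4))
            g = rng.standard_normal(4)
            c1, c2 = phi_inverse(e1, psi), phi_inverse(e2, psi)
            c1p = phi_inverse(perturb(e1, g), psi)
            c2p = phi_inverse(perturb(e2, g), psi)
            worst_ait = max(
                worst_ait,
                abs(
                    beta_diversity(c1p, c2p, "aitchison_distance")
                    - beta_diversity(c1, c2, "aitchison_distance")
                ),
            )
            worst_bray = max(
                worst_bray,
                abs(beta_diversity(c1p, c2p, "bray_curtis") - beta_diversity(c1, c2, "bray_curtis")),
            )
            worst_uni = max(
                worst_uni,
                abs(
                    idx.weighted_unifrac(c1p, c2p) - idx.weighted_unifrac(c1, c2)
                ),
            )
        assert worst_ait < 1e-10
        assert worst_bray > 1e-3
        assert worst_uni > 1e-3


class TestSkbioCrossChecks:
    """Independent oracle: scikit-bio implementations of the same metrics."""

    def _sk_tree(self, tree):
        import skbio

        return skbio.TreeNode.read(
            io.StringIO(tree.as_string(schema="newick", suppress_rooting=True))
        )

    def test_weighted_unifrac_matches_skbio(self):
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(8)]
        tree = simulate_tree(labels, 9)
        idx = TreeIndex(tree, labels)
        sk_tree = self._sk_tree(tree)
        for _ in range(10):
            cp = rng.integers(1, 10_000, size=8)
            cq = rng.integers(1, 10_000, size=8)
            p, q = cp / cp.sum(), cq / cq.sum()
            assert idx.weighted_unifrac(p, q, normalized=False) == pytest.approx(
                sk_wu(cp, cq, taxa=labels, tree=sk_tree), abs=1e-10
            )
            assert idx.weighted_unifrac(p, q, normalized=True) == pytest.approx(
                sk_wu(cp, cq, taxa=labels, tree=sk_tree, normalized=True), abs=1e-10
            )

    def test_bray_curtis_matches_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(13)
        for _ in range(20):
            p, q = rng.dirichlet(np.ones(6)), rng.dirichlet(np.ones(6))
            assert beta_diversity(p, q, "bray_curtis") == pytest.approx(
                braycurtis(p, q), abs=1e-12
            )


class TestDistanceMatrix:
    def test_identical_points_zero_matrix(self):
        c = np.array([0.4, 0.6])
        dm = distance_matrix([c, c], "aitchison_distance")
        assert np.allclose(dm.entries, 0.0, atol=1e-15)

    def test_symmetry_and_elementwise_match(self):
        rng = np.random.default_rng(8)
        comps = [rng.dirichlet(np.ones(4)) for _ in range(10)]
        dm = distance_matrix(comps, "bray_curtis")
        assert np.max(np.abs(dm.entries - dm.entries.T)) < 1e-12
        for i in range(10):
            for j in range(10):
                expect = 0.0 if i == j else beta_diversity(comps[i], comps[j], "bray_curtis")
                assert dm.entries[i, j] == pytest.approx(expect, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])


class TestNewick:
    def test_simple_cherry(self):
        t = read_newick("(A:1,B:1);")
        tips = list(t.leaf_node_iter())
        assert {n.taxon.label for n in tips} == {"A", "B"}
        assert [n.edge.length for n in tips] == [1.0, 1.0]

    def test_three_taxa_with_internal_edge(self):
        t = read_newick("((A:1,B:2):0.5,C:3);")
        assert len(list(t.leaf_node_iter())) == 3
        internal = [
            n.edge.length
            for n in t.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        assert internal == [0.5]

    def test_round_trip(self, tmp_path):
        t1 = simulate_tree([f"t{i}" for i in range(7)], 3)
        path = tmp_path / "tree.nwk"
        write_newick(t1, path)
        t2 = read_newick(path)
        idx1 = TreeIndex(t1)
        idx2 = TreeIndex(t2)
        assert idx1.taxon_order == idx2.taxon_order
        assert np.allclose(sorted(idx1.edge_lengths), sorted(idx2.edge_lengths), atol=1e-9)
        rng = np.random.default_rng(0)
        p, q = rng.dirichlet(np.ones(7)), rng.dirichlet(np.ones(7))
        assert idx1.weighted_unifrac(p, q) == pytest.approx(idx2.weighted_unifrac(p, q), abs=1e-9)

    def test_missing_lengths_warn(self):
        with pytest.warns(UserWarning, match="branch length"):
            read_newick("(A:1,(B,C:2):1);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A:1,A:1);")


def test_metric_spec_validation():
    with pytest.raises(ValueError):
        MetricSpec("jaccard")
    with pytest.raises(ValueError):
        MetricSpec("shannon", {"bogus": 1})
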