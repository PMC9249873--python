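"""Likelihood kernel (pruning vs brute-force enumeration), category
assignment and fast-site stripping."""

import itertools

import numpy as np
import pytest

from phylocurate import (
    Alignment,
    PartitionTable,
    SupermatrixBundle,
    assign_site_categories,
    parse_newick,
    poisson_model,
    simulate_alignment,
    site_loglik_per_category,
    strip_fast_categories,
)
from phylocurate.models import lg_model
from phylocurate.site_rates import LOG_ZERO, SiteRateAssignment, mixture_loglik


def enumeration_loglik(aln, tree, model, rate=1.0):
    """Brute force: sum over all internal-state assignments of the
    product of transition probabilities along every edge."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    codes = {
        n.name: aln.state_matrix()[aln.taxon_labels.index(n.name)]
        for n in nodes
        if n.is_leaf
    }
    P = {id(n): model.transition_matrix(n.length * rate) for n in nodes}
    out = np.zeros(aln.n_sites)
    for s in range(aln.n_sites):
        total = 0.0
        for assign in itertools.product(range(20), repeat=len(internal)):
            states = dict(zip((id(n) for n in internal), assign))
            for n in nodes:
                if n.is_leaf:
                    states[id(n)] = codes[n.name][s]
            prob = model.frequencies[states[id(tree.root)]]
            for n in nodes:
                if n.parent is None:
                    continue
                x, y = states[id(n.parent)], states[id(n)]
                if y < 0:  # missing leaf: marginalize by summing P row = 1
                    continue
                if x < 0:
                    raise AssertionError("internal states are always assigned")
                prob *= P[id(n)][x, y]
            total += prob
        out[s] = np.log(total) if total > 0 else LOG_ZERO
    return out


class TestPruningOracle:
    def test_two_identical_taxa_zero_length(self, poisson1):
        aln = Alignment(["X", "Y"], np.array([list("AA"), list("AA")]).T.reshape(2, 2))
        aln = Alignment(["X", "Y"], np.array([list("AR"), list("AR")]))
        tree = parse_newick("(X:0,Y:0);")
        ll = site_loglik_per_category(aln, tree, poisson1)
        np.testing.assert_allclose(ll[:, 0], -np.log(20), atol=1e-12)

    def test_two_differing_taxa_zero_length_sentinel(self, poisson1):
        aln = Alignment(["X", "Y"], np.array([list("AR"), list("RR")]))
        tree = parse_newick("(X:0,Y:0);")
        ll = site_loglik_per_category(aln, tree, poisson1)
        assert ll[0, 0] <= LOG_ZERO / 2  # impossible site
        np.testing.assert_allclose(ll[1, 0], -np.log(20), atol=1e-12)

    @pytest.mark.parametrize("model_fn", [poisson_model, lg_model])
    def test_four_taxon_enumeration(self, model_fn):
        """Pruning equals the 20^2 internal-state enumeration."""
        model = model_fn()
        tree = parse_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.0);")
        aln, _ = simulate_alignment(tree, model, 10, seed=1)
        got = site_loglik_per_category(aln, tree, model)[:, 0]
        want = enumeration_loglik(aln, tree, model)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_five_taxon_enumeration_with_gamma(self, tree5):
        model = poisson_model(alpha=0.8, K=2)
        aln, _ = simulate_alignment(tree5, model, 6, seed=2)
        # punch in some missing data
        aln.matrix[0, 0] = "-"
        aln.matrix[2, 3] = "X"
        got = site_loglik_per_category(aln, tree5, model)
        for k, rate in enumerate(model.category_rates):
            want = enumeration_loglik(aln, tree5, model, rate=rate)
            np.testing.assert_allclose(got[:, k], want, atol=1e-10)

    def test_rerooting_invariance(self, tree5, poisson_g4):
        """A reversible model gives the same likelihood from any rooting
        of the same unrooted tree."""
        aln, _ = simulate_alignment(tree5, poisson_g4, 40, seed=3)
        ll1 = site_loglik_per_category(aln, tree5, poisson_g4)
        rerooted = parse_newick(
            "(C:0.15,D:0.25,((A:0.1,B:0.2):0.05,E:0.3):0.1);"
        )
        ll2 = site_loglik_per_category(aln, rerooted, poisson_g4)
        np.testing.assert_allclose(ll1, ll2, atol=1e-10)

    def test_missing_taxon_in_tree_errors(self, tree5, poisson1):
        aln = Alignment(["A", "B"], np.array([list("AR"), list("AR")]))
        with pytest.raises(ValueError, match="absent"):
            site_loglik_per_category(aln, tree5, poisson1)

    def test_all_gap_column_uninformative(self, tree5, poisson1):
        aln, _ = simulate_alignment(tree5, poisson1, 3, seed=4)
        aln.matrix[:, 1] = "-"
        ll = site_loglik_per_category(aln, tree5, poisson1)
        # fully ambiguous column has likelihood 1
        assert ll[1, 0] == pytest.approx(0.0, abs=1e-10)


class TestAssignment:
    def test_k1_trivial(self):
        a = assign_site_categories(np.full((5, 1), -3.0), np.ones(1))
        assert (a.category == 1).all()
        np.testing.assert_allclose(a.posterior_mean_rate, 1.0)

    def test_softmax_example(self):
        """Posterior of loglik (-10, -1) at K=2 concentrates on the
        second category."""
        rates = np.array([0.5, 1.5])
        a = assign_site_categories(np.array([[-10.0, -1.0]]), rates)
        expected = np.exp([-10.0, -1.0])
        expected /= expected.sum()
        np.testing.assert_allclose(a.posterior[0], expected, rtol=1e-9)
        assert a.posterior[0, 1] == pytest.approx(0.99988, abs=1e-5)
        assert a.category[0] == 2
        np.testing.assert_allclose(
            a.posterior_mean_rate[0], expected @ rates, rtol=1e-9
        )

    def test_posterior_rows_normalized(self, small_gene, poisson_g4):
        tree, aln, _ = small_gene
        ll = site_loglik_per_category(aln, tree, poisson_g4)
        a = assign_site_categories(ll, poisson_g4.category_rates)
        np.testing.assert_allclose(a.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert (a.category == a.posterior.argmax(axis=1) + 1).all()

    def test_tie_goes_to_lower_index(self):
        a = assign_site_categories(np.array([[-1.0, -1.0]]), np.array([0.5, 1.5]))
        assert a.category[0] == 1

    def test_all_sentinel_row_prior_fallback(self):
        with pytest.warns(UserWarning, match="zero likelihood"):
            a = assign_site_categories(
                np.full((1, 3), LOG_ZERO), np.array([0.2, 0.9, 1.9])
            )
        assert a.category[0] == 1
        np.testing.assert_allclose(a.posterior[0], 1 / 3)


def _toy_bundle(n_sites=10):
    rng = np.random.default_rng(0)
    mat = rng.choice(list("ARND"), size=(4, n_sites))
    aln = Alignment(["a", "b", "c", "d"], mat)
    parts = PartitionTable([("g1", 1, n_sites // 2), ("g2", n_sites // 2 + 1, n_sites)])
    return SupermatrixBundle(aln=aln, partitions=parts)


class TestStripFast:
    def _assignment(self, cats, rates):
        cats = np.asarray(cats)
        K = len(rates)
        post = np.eye(K)[cats - 1]
        return SiteRateAssignment(
            cats, np.asarray(rates)[cats - 1], post, np.asarray(rates)
        )

    def test_zero_removal_identity(self):
        b = _toy_bundle()
        a = self._assignment([1] * 10, [0.5, 1.5])
        assert strip_fast_categories(b, a, 0) is b

    def test_known_assignment_removes_top_category(self):
        b = _toy_bundle()
        cats = [1, 2, 3, 3, 2, 1, 3, 2, 1, 1]
        a = self._assignment(cats, [0.2, 1.0, 1.8])
        out = strip_fast_categories(b, a, 1)
        kept = [i + 1 for i, c in enumerate(cats) if c != 3]
        assert list(out.aln.site_ids) == kept
        assert {s for s, r in out.removed_sites} == {3, 4, 7}
        assert all(r == "fast_category" for _, r in out.removed_sites)
        # partitions remapped: g1 loses sites 3,4 -> width 3; g2 loses 7
        assert out.partitions.entries == [("g1", 1, 3), ("g2", 4, 7)]

    def test_n_remove_bounds(self):
        b = _toy_bundle()
        a = self._assignment([1] * 10, [0.5, 1.5])
        with pytest.raises(ValueError):
            strip_fast_categories(b, a, 2)

    def test_mean_retained_rate_decreases(self, small_gene, poisson_g4):
        tree, aln, _ = small_gene
        parts = PartitionTable([("g", 1, aln.n_sites)])
        bundle = SupermatrixBundle(aln=aln, partitions=parts)
        ll = site_loglik_per_category(aln, tree, poisson_g4)
        a = assign_site_categories(ll, poisson_g4.category_rates)
        means = []
        for n_remove in range(poisson_g4.K):
            out = strip_fast_categories(bundle, a, n_remove)
            kept0 = out.aln.site_ids - 1
            means.append(a.posterior_mean_rate[kept0].mean())
        assert all(m1 > m2 for m1, m2 in zip(means, means[1:]))


def test_mixture_loglik_guards_sentinel():
    ll = np.array([[LOG_ZERO, LOG_ZERO], [-1.0, LOG_ZERO]])
    out = mixture_loglik(ll)
    assert out[0] <= LOG_ZERO / 2
    assert out[1] == pytest.approx(-1.0 + np.log(0.5))


def test_equal_count_rate_bins_alternative_mode():
    from phylocurate.site_rates import equal_count_rate_bins

    pmr = np.array([0.3, 2.0, 1.0, 0.1, 1.5, 0.7, 0.9, 1.2])
    cats = equal_count_rate_bins(pmr, 4)
    # two sites per bin, ordered by rate
    assert list(cats) == [1, 4, 3, 1, 4, 2, 2, 3]
    # bin means increase
    means = [pmr[cats == k].mean() for k in (1, 2, 3, 4)]
    assert all(a < b for a, b in zip(means, means[1:]))
    with pytest.raises(ValueError):
        equal_count_rate_bins(pmr, 0)
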