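"""Gene screening: distances/NJ, long-branch fence, anomaly rules,
paralogy flags and the keep/drop decision table."""

import numpy as np
import pytest

from phylocurate import (
    Alignment,
    TaxonomyMap,
    bootstrap_supports,
    build_gene_tree,
    decide_gene,
    detect_anomalous_grouping,
    detect_long_branches,
    flag_paralogy,
    parse_newick,
    poisson_model,
    simulate_alignment,
    simulate_tree,
)
from phylocurate.gene_screen import (
    ScreenReport,
    _nj_tree,
    ml_distance_matrix,
    ml_pairwise_distance,
)
from phylocurate.models import lg_model, poisson_distance


# ---------------------------------------------------------------------------
# Distances + NJ
# ---------------------------------------------------------------------------

class TestDistances:
    def test_brent_matches_poisson_closed_form(self, poisson1):
        """The generic 1-D ML optimizer agrees with the analytic Poisson
        distance computed from the proportion of differing sites."""
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.integers(20, size=n)
        y = x.copy()
        flip = rng.random(n) < 0.25
        y[flip] = rng.integers(20, size=flip.sum())
        C = np.zeros((20, 20))
        np.add.at(C, (x, y), 1.0)
        p_hat = np.mean(x != y)
        assert ml_pairwise_distance(C, poisson1) == pytest.approx(
            poisson_distance(p_hat), abs=1e-4
        )

    def test_fast_path_matches_brent_with_gamma(self, poisson_g4):
        tree = simulate_tree(4, seed=5, height=0.6)
        aln, _ = simulate_alignment(tree, poisson_g4, 1500, seed=6)
        D_fast = ml_distance_matrix(aln, poisson_g4)
        codes = aln.state_matrix()
        for i, j in [(0, 1), (1, 3)]:
            C = np.zeros((20, 20))
            np.add.at(C, (codes[i], codes[j]), 1.0)
            assert D_fast[i, j] == pytest.approx(
                ml_pairwise_distance(C, poisson_g4), abs=1e-3
            )

    def test_no_overlap_errors(self, poisson1):
        aln = Alignment(["a", "b"], np.array([list("AR--"), list("--AR")]))
        with pytest.raises(ValueError, match="no non-missing"):
            ml_distance_matrix(aln, poisson1)

    def test_saturated_pair_capped(self, poisson1):
        C = np.full((20, 20), 1.0)  # p_hat = 0.95 = saturation limit
        with pytest.warns(UserWarning, match="capped"):
            assert ml_pairwise_distance(C, poisson1) == 10.0


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        """NJ on an additive matrix recovers topology and exact branch
        lengths (four-point condition)."""
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        D = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            dtype=float,
        )
        t = _nj_tree(D, ["a", "b", "c", "d"])
        assert t.bipartitions() == {frozenset({"c", "d"})}
        term = t.terminal_branch_lengths()
        assert term == pytest.approx({"a": 1, "b": 2, "c": 4, "d": 5})
        Dt, labels = t.distance_matrix(["a", "b", "c", "d"])
        np.testing.assert_allclose(Dt, D, atol=1e-9)

    def test_three_taxa_star(self, poisson1):
        aln = Alignment(
            ["a", "b", "c"],
            np.array([list("ARNDAR"), list("ARNECN"), list("ANNDCR")]),
        )
        t = build_gene_tree(aln, poisson1)
        assert sorted(t.leaf_names()) == ["a", "b", "c"]
        assert t.bipartitions() == set()

    def test_too_few_taxa(self, poisson1):
        aln = Alignment(["a", "b"], np.array([list("AR"), list("AR")]))
        with pytest.raises(ValueError, match=">= 3 taxa"):
            build_gene_tree(aln, poisson1)

    def test_recovers_true_topology_on_clean_genes(self, poisson_g4):
        hits = 0
        for seed in range(10):
            tree = simulate_tree(10, seed=100 + seed, height=0.7)
            aln, _ = simulate_alignment(tree, poisson_g4, 2000, seed=200 + seed)
            est = build_gene_tree(aln, poisson_g4)
            hits += est.robinson_foulds(tree) == 0
        assert hits >= 8

    def test_lg_model_path(self):
        model = lg_model()
        tree = simulate_tree(5, seed=9, height=0.5)
        aln, _ = simulate_alignment(tree, model, 800, seed=10)
        est = build_gene_tree(aln, model)
        assert est.robinson_foulds(tree) == 0


class TestBootstrap:
    def test_supports_bounded_and_deterministic(self, poisson1):
        tree = simulate_tree(8, seed=21, height=0.7)
        aln, _ = simulate_alignment(tree, poisson1, 400, seed=22)
        t1 = bootstrap_supports(aln, poisson1, n_reps=30, seed=5)
        t2 = bootstrap_supports(aln, poisson1, n_reps=30, seed=5)
        assert t1.to_newick() == t2.to_newick()
        sups = [
            n.support
            for n in t1.preorder()
            if not n.is_leaf and n.parent is not None and n.support is not None
        ]
        assert sups and all(0 <= s <= 100 for s in sups)

    def test_strong_signal_gives_full_support(self, poisson1):
        tree = simulate_tree(6, seed=31, height=0.5)
        aln, _ = simulate_alignment(tree, poisson1, 5000, seed=32)
        t = bootstrap_supports(aln, poisson1, n_reps=25, seed=1)
        sups = t.bipartitions(with_support=True)
        assert all(s == 100.0 for s in sups.values())

    def test_support_grows_with_sites(self, poisson1):
        """Mean true-edge support increases with gene length."""
        tree = simulate_tree(8, seed=41, height=0.4)
        true_bip = tree.bipartitions()
        means = []
        for n_sites in (60, 400, 2500):
            aln, _ = simulate_alignment(tree, poisson1, n_sites, seed=42)
            t = bootstrap_supports(aln, poisson1, n_reps=40, seed=2)
            sups = t.bipartitions(with_support=True)
            vals = [s for b, s in sups.items() if b in true_bip and s is not None]
            means.append(np.mean(vals) if vals else 0.0)
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]


# ---------------------------------------------------------------------------
# Long branches
# ---------------------------------------------------------------------------

def _taxonomy(ingroup, outgroup, clades=None, whitelist=()):
    clade = {}
    flags = {}
    for t in ingroup:
        clade[t] = clades.get(t, "In") if clades else "In"
        flags[t] = True
    for t in outgroup:
        clade[t] = "Out"
        flags[t] = False
    return TaxonomyMap(clade, flags, frozenset(whitelist))


class TestLongBranches:
    def test_hand_computed_fence(self):
        """Ingroup terminals {0.09,0.10,0.11,0.12,1.50}: Q3 + 1.5 IQR =
        0.12 + 1.5 x 0.02 = 0.15; only the 1.50 taxon is flagged."""
        t = parse_newick(
            "(I1:0.09,I2:0.10,((I3:0.11,I4:0.12):0.1,"
            "(I5:1.5,(O1:0.1,O2:0.1):0.3):0.1):0.1);"
        )
        tax = _taxonomy(["I1", "I2", "I3", "I4", "I5"], ["O1", "O2"])
        assert detect_long_branches(t, tax) == {"I5"}

    def test_all_equal_no_outliers(self):
        t = parse_newick("(I1:0.1,I2:0.1,(I3:0.1,(I4:0.1,O1:0.2):0.1):0.1);")
        tax = _taxonomy(["I1", "I2", "I3", "I4"], ["O1"])
        assert detect_long_branches(t, tax) == set()

    def test_outgroup_excluded_from_cohort(self):
        """A long outgroup branch neither flags itself nor distorts the
        ingroup fence."""
        t = parse_newick("(I1:0.1,I2:0.11,(I3:0.09,(I4:0.1,O1:5.0):0.1):0.1);")
        tax = _taxonomy(["I1", "I2", "I3", "I4"], ["O1"])
        assert detect_long_branches(t, tax) == set()

    def test_fewer_than_four_ingroup_warns_empty(self):
        t = parse_newick("(I1:0.1,I2:0.1,(O1:0.1,O2:5.0):0.1);")
        tax = _taxonomy(["I1", "I2"], ["O1", "O2"])
        with pytest.warns(UserWarning, match="fewer than 4"):
            assert detect_long_branches(t, tax) == set()


# ---------------------------------------------------------------------------
# Anomalous grouping
# ---------------------------------------------------------------------------

class TestAnomalies:
    # X nests inside the outgroup; {s} is the support of the nesting
    # clade, the other edges stay below the threshold
    fixture = (
        "((X:1,O1:1){s}:1,(O2:1,O3:1)88:1,"
        "(I1:1,(I2:1,I3:1)80:1)85:1);"
    )

    def _tax(self):
        return _taxonomy(["X", "I1", "I2", "I3"], ["O1", "O2", "O3"])

    def test_outgroup_nesting_flagged_above_threshold(self):
        t = parse_newick(self.fixture.format(s=95))
        assert detect_anomalous_grouping(t, self._tax()) == [("X", 95.0)]

    def test_below_threshold_not_flagged(self):
        t = parse_newick(self.fixture.format(s=85))
        assert detect_anomalous_grouping(t, self._tax()) == []

    def test_interrupted_outgroup_flagged_via_outer_edge(self):
        """When a taxon breaks outgroup monophyly, the high-support edge
        separating it + the outgroup from the rest of the ingroup is
        itself evidence of anomalous grouping."""
        t = parse_newick(
            "((X:1,O1:1)60:1,(O2:1,O3:1)88:1,"
            "(I1:1,(I2:1,I3:1)80:1)95:1);"
        )
        assert detect_anomalous_grouping(t, self._tax()) == [("X", 95.0)]

    def test_basal_ingroup_taxon_not_flagged(self):
        """A lineage that is its clade's sole representative and sits
        sister to the monophyletic outgroup is a legitimate basal
        placement, not an anomaly."""
        t = parse_newick(
            "(((O1:1,O2:1)99:1,X:1)98:1,I1:1,(I2:1,I3:1)99:1);"
        )
        tax = _taxonomy(
            ["X", "I1", "I2", "I3"], ["O1", "O2"],
            clades={"X": "Basal", "I1": "In", "I2": "In", "I3": "In"},
        )
        assert detect_anomalous_grouping(t, tax) == []

    def test_displaced_clade_member_flagged(self):
        """The same topology IS anomalous when the taxonomy expects X
        inside the ingroup with its clade-mates."""
        t = parse_newick(
            "(((O1:1,O2:1)99:1,X:1)98:1,I1:1,(I2:1,I3:1)99:1);"
        )
        tax = _taxonomy(["X", "I1", "I2", "I3"], ["O1", "O2"])
        assert detect_anomalous_grouping(t, tax) == [("X", 98.0)]

    def test_foreign_clade_nesting(self):
        t = parse_newick(
            "(((A1:1,(A2:1,F:1)95:1)92:1,A3:1)97:1,"
            "(B1:1,B2:1)99:1,(O1:1,O2:1)99:1);"
        )
        tax = _taxonomy(
            ["A1", "A2", "A3", "F", "B1", "B2"],
            ["O1", "O2"],
            clades={"A1": "CladeA", "A2": "CladeA", "A3": "CladeA",
                    "F": "CladeB", "B1": "CladeB", "B2": "CladeB"},
        )
        assert detect_anomalous_grouping(t, tax) == [("F", 92.0)]

    def test_no_outgroup_warns(self):
        t = parse_newick("((I1:1,I2:1)95:1,I3:1,(I4:1,I5:1)95:1);")
        tax = _taxonomy(["I1", "I2", "I3", "I4", "I5"], [])
        with pytest.warns(UserWarning, match="no outgroup"):
            assert detect_anomalous_grouping(t, tax) == []

    def test_uncovered_taxon_errors(self):
        t = parse_newick("((I1:1,I2:1)95:1,I3:1,(ZZ:1,O1:1)95:1);")
        tax = _taxonomy(["I1", "I2", "I3"], ["O1"])
        with pytest.raises(ValueError, match="cover"):
            detect_anomalous_grouping(t, tax)


# ---------------------------------------------------------------------------
# Paralogy
# ---------------------------------------------------------------------------

class TestParalogy:
    def _aln(self, labels):
        rng = np.random.default_rng(1)
        return Alignment(labels, rng.choice(list("ARND"), size=(len(labels), 8)))

    def test_single_copy_empty(self):
        aln = self._aln(["a", "b", "c", "d"])
        tree = parse_newick("((a:1,b:1):1,c:1,d:1);")
        assert flag_paralogy(aln, tree) == []

    def test_cherry_copies_flagged_not_dropped(self):
        labels = ["a", "a__copy2", "b", "c", "d"]
        aln = self._aln(labels)
        tree = parse_newick("((a:1,a__copy2:1):1,(b:1,c:1):1,d:1);")
        flags = flag_paralogy(aln, tree)
        assert len(flags) == 1
        assert flags[0].taxon == "a" and flags[0].copy_count == 2
        assert flags[0].is_cherry
        report = decide_gene(
            ScreenReport("g", paralog_flags=flags),
            _taxonomy(["a", "b", "c", "d"], []),
        )
        assert report.decision == "keep"

    def test_scattered_copies_non_cherry(self):
        labels = ["a", "a__copy2", "b", "c", "d"]
        aln = self._aln(labels)
        tree = parse_newick("((a:1,b:1):1,(a__copy2:1,c:1):1,d:1);")
        flags = flag_paralogy(aln, tree)
        assert len(flags) == 1 and not flags[0].is_cherry
        report = decide_gene(
            ScreenReport("g", paralog_flags=flags),
            _taxonomy(["a", "b", "c", "d"], []),
        )
        assert report.decision == "drop" and report.reasons == ["paralogy"]

    def test_strict_mode_drops_cherries(self):
        labels = ["a", "a__copy2", "b", "c", "d"]
        aln = self._aln(labels)
        tree = parse_newick("((a:1,a__copy2:1):1,(b:1,c:1):1,d:1);")
        report = decide_gene(
            ScreenReport("g", paralog_flags=flag_paralogy(aln, tree)),
            _taxonomy(["a", "b", "c", "d"], []),
            strict_paralogy=True,
        )
        assert report.decision == "drop"


# ---------------------------------------------------------------------------
# Decision table
# ---------------------------------------------------------------------------

class TestDecideGene:
    tax = None

    def setup_method(self):
        self.tax = _taxonomy(
            ["w1", "w2", "x", "y", "z"],
            ["o"],
            clades={"w1": "White", "w2": "White", "x": "In", "y": "In", "z": "In"},
            whitelist=["White"],
        )

    def _report(self, lb=(), anomalies=(), flags=()):
        return ScreenReport(
            "g", long_branch_taxa=set(lb), anomalies=list(anomalies),
            paralog_flags=list(flags),
        )

    def test_three_long_branches_drop(self):
        r = decide_gene(self._report(lb={"x", "y", "z"}), self.tax)
        assert r.decision == "drop" and r.reasons == ["long_branches"]

    def test_two_long_branches_keep(self):
        r = decide_gene(self._report(lb={"x", "y"}), self.tax)
        assert r.decision == "keep" and r.reasons == []

    def test_whitelist_exempts(self):
        """3 long-branch taxa, 1 whitelisted -> effective count 2 -> keep."""
        r = decide_gene(self._report(lb={"x", "y", "w1"}), self.tax)
        assert r.decision == "keep"
        r2 = decide_gene(self._report(lb={"x", "y", "z", "w1", "w2"}), self.tax)
        assert r2.decision == "drop"

    def test_anomaly_drops(self):
        r = decide_gene(self._report(anomalies=[("x", 95.0)]), self.tax)
        assert r.decision == "drop" and "anomalous_grouping" in r.reasons

    def test_monotone_in_long_branches(self):
        """Adding a long-branch taxon never converts drop -> keep."""
        from itertools import combinations

        taxa = ["x", "y", "z", "w1"]
        decisions = {}
        for k in range(len(taxa) + 1):
            for combo in combinations(taxa, k):
                r = decide_gene(self._report(lb=set(combo)), self.tax)
                decisions[frozenset(combo)] = r.decision
        for small, dec_small in decisions.items():
            for big, dec_big in decisions.items():
                if small < big and dec_small == "drop":
                    assert dec_big == "drop"


class TestShortSequenceScreen:
    def test_optional_min_ungapped_filter(self, poisson1):
        from phylocurate.gene_screen import screen_gene
        from phylocurate import TaxonomyMap, simulate_tree, simulate_alignment
        import numpy as np

        tree = simulate_tree(6, seed=61, height=0.5)
        aln, _ = simulate_alignment(tree, poisson1, 200, seed=62)
        # gut one taxon's sequence to 20% coverage
        aln.matrix[2, 40:] = "-"
        tax = TaxonomyMap(
            {t: ("Out" if t in ("T005", "T006") else "In")
             for t in aln.taxon_labels},
            {t: t not in ("T005", "T006") for t in aln.taxon_labels},
        )
        off = screen_gene("g", aln, tax, poisson1, n_boot=5, seed=1)
        assert "short_sequences" not in off.reasons  # default: filter off
        on = screen_gene("g", aln, tax, poisson1, n_boot=5, seed=1,
                         min_ungapped_fraction=0.5)
        assert on.short_taxa == {aln.taxon_labels[2]}
        assert on.decision == "drop" and "short_sequences" in on.reasons
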