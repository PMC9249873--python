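"""End-to-end validation experiments on synthetic data.

Each function generates its own data with a known ground truth, runs
the relevant pipeline stage, and returns the measured quantities
(sensitivities, recovery statistics, calibration rates).  The
experiments double as the package's acceptance benchmarks: the test
suite asserts on their outputs and ``scripts/acceptance.py`` reports
them.

Problem sizes are chosen so the full battery runs in minutes on one
core: gene sets of 60-100 genes at 500-1000 sites, 4-taxon topology
tests at 5,000-10,000 sites, and 200 calibration replicates.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy.stats import norm, spearmanr

from .gene_screen import (
    bootstrap_supports,
    build_gene_tree,
    detect_anomalous_grouping,
    detect_long_branches,
    flag_paralogy,
    screen_gene,
)
from .internode_certainty import ic_all_edges, internal_edges, quartet_counts
from .io import PartitionTable, SiteLnLTable, parse_newick
from .models import discrete_gamma_rates, poisson_model
from .simulate import SimParams, simulate_alignment, simulate_study, simulate_tree
from .site_rates import (
    assign_site_categories,
    site_loglik_per_category,
    strip_fast_categories,
)
from .supermatrix import SupermatrixBundle, concatenate, filter_gappy_taxa, filter_sites
from .topology_tests import au_pvalue, rell_bootstrap, sitelh_from_trees, test_hypotheses


def _sub(seed: int, tag: int) -> int:
    """Derive a substream seed below 2^31."""
    return int(np.random.default_rng([seed, tag]).integers(2**31 - 1))


# ---------------------------------------------------------------------------
# Likelihood kernel vs enumeration oracle
# ---------------------------------------------------------------------------

def _enumeration_loglik(aln, tree, model, rate=1.0):
    """Brute-force likelihood: sum over all internal-state assignments."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    codes = aln.state_matrix()
    row = {t: i for i, t in enumerate(aln.taxon_labels)}
    P = {id(n): model.transition_matrix(n.length * rate) for n in nodes}
    out = np.zeros(aln.n_sites)
    for s in range(aln.n_sites):
        total = 0.0
        for assign in itertools.product(range(20), repeat=len(internal)):
            states = {id(n): a for n, a in zip(internal, assign)}
            for n in nodes:
                if n.is_leaf:
                    states[id(n)] = codes[row[n.name], s]
            prob = model.frequencies[states[id(tree.root)]]
            for n in nodes:
                if n.parent is None or states[id(n)] < 0:
                    continue
                prob *= P[id(n)][states[id(n.parent)], states[id(n)]]
            total += prob
        out[s] = np.log(total)
    return out


def likelihood_oracle(seed: int) -> dict:
    """Pruning vs enumeration on a 4-taxon tree, plus re-rooting
    invariance on a 5-taxon tree; returns max absolute deviations."""
    model = poisson_model(alpha=0.9, K=2)
    tree = parse_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.4):0.05);")
    aln, _ = simulate_alignment(tree, model, 8, seed=_sub(seed, 1))
    got = site_loglik_per_category(aln, tree, model)
    dev = 0.0
    for k, rate in enumerate(model.category_rates):
        want = _enumeration_loglik(aln, tree, model, rate=rate)
        dev = max(dev, float(np.max(np.abs(got[:, k] - want))))

    t5a = parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.25):0.1,E:0.3);")
    t5b = parse_newick("(C:0.15,D:0.25,((A:0.1,B:0.2):0.05,E:0.3):0.1);")
    aln5, _ = simulate_alignment(t5a, model, 40, seed=_sub(seed, 2))
    ll_a = site_loglik_per_category(aln5, t5a, model)
    ll_b = site_loglik_per_category(aln5, t5b, model)
    reroot_dev = float(np.max(np.abs(ll_a - ll_b)))
    return {"pruning_vs_enumeration_max_abs": dev,
            "rerooting_max_abs": reroot_dev,
            "n": aln.n_sites}


# ---------------------------------------------------------------------------
# Discrete gamma
# ---------------------------------------------------------------------------

def gamma_category_rates() -> dict:
    """alpha=1, K=4 category rates (closed-form truncated-exponential
    bin means, renormalized to mean 1)."""
    r = discrete_gamma_rates(1.0, 4)
    return {f"rate_{k + 1}": float(v) for k, v in enumerate(r)}


# ---------------------------------------------------------------------------
# Site-rate recovery and stripping
# ---------------------------------------------------------------------------

def site_rate_recovery(seed: int, n_sites: int = 5000, n_taxa: int = 16) -> dict:
    """Categorize simulated sites (K=4, alpha=1) with the true guide
    tree and score the assignment against the known categories."""
    model = poisson_model(alpha=1.0, K=4)
    tree = simulate_tree(n_taxa, seed=_sub(seed, 3), height=0.75)
    aln, cats = simulate_alignment(tree, model, n_sites, seed=_sub(seed, 4))
    ll = site_loglik_per_category(aln, tree, model)
    assign = assign_site_categories(ll, model.category_rates)
    accuracy = float(np.mean(assign.category == cats))
    rho = float(
        spearmanr(assign.posterior_mean_rate, model.category_rates[cats - 1]).statistic
    )
    bundle = SupermatrixBundle(
        aln=aln, partitions=PartitionTable([("g", 1, aln.n_sites)])
    )
    means = []
    for n_remove in range(model.K):
        out = strip_fast_categories(bundle, assign, n_remove)
        means.append(float(assign.posterior_mean_rate[out.aln.site_ids - 1].mean()))
    monotone = all(a > b for a, b in zip(means, means[1:]))
    return {
        "category_accuracy": accuracy,
        "chance_accuracy": 1.0 / model.K,
        "spearman_rate_recovery": rho,
        "stripping_monotone": float(monotone),
        "n": n_sites,
    }


# ---------------------------------------------------------------------------
# Internode certainty
# ---------------------------------------------------------------------------

def ic_benchmark(seed: int) -> dict:
    """IC on identical-tree evaluation sets (must be 1.0 everywhere) and
    exhaustive-vs-sampled agreement in binomial standard errors."""
    ref = simulate_tree(8, seed=_sub(seed, 5), height=1.0)
    res = ic_all_edges(ref, [ref.copy() for _ in range(100)])
    ic_identical = float(min(e.ic for e in res.edges))

    evals = [
        simulate_tree(8, seed=_sub(seed, 6) + i, height=1.0) for i in range(20)
    ]
    m = 10_000
    worst = 0.0
    for child in internal_edges(ref):
        ex = quartet_counts(ref, child, evals, mode="exhaustive")
        sa = quartet_counts(ref, child, evals, mode="sampled", m=m,
                            seed=_sub(seed, 7))
        for q_ex, q_sa in ((ex.q_ref, sa.q_ref), (ex.q_alt1, sa.q_alt1),
                           (ex.q_alt2, sa.q_alt2)):
            p = q_ex / ex.n_evaluated
            se = np.sqrt(max(p * (1 - p), 1e-12) / m)
            worst = max(worst, abs(q_sa / sa.n_evaluated - p) / se)
    return {
        "ic_identical_trees": ic_identical,
        "sampled_vs_exhaustive_max_se": float(worst),
        "n": len(res.edges),
    }


# ---------------------------------------------------------------------------
# AU test
# ---------------------------------------------------------------------------

_QUARTET = {
    "A": "((T1:0.2,T2:0.2):{b},(T3:0.2,T4:0.2):{b});",
    "B": "((T1:0.2,T3:0.2):{b},(T2:0.2,T4:0.2):{b});",
    "C": "((T1:0.2,T4:0.2):{b},(T2:0.2,T3:0.2):{b});",
}


def au_type1_calibration(
    seed: int, n_sims: int = 200, n_sites: int = 5000, B: int = 1000
) -> dict:
    """Type-I error of the AU test at the least-favorable null.

    Data are simulated from the boundary of the three quartet
    resolutions (internal branch zero); candidates carry fixed, equal
    branch lengths so the experiment calibrates the multiscale
    bootstrap machinery itself.  (Re-optimizing branch lengths per
    dataset truncates competing resolutions onto the star tree and
    makes the test over-conservative — the known polytomy
    conservatism; see the methods note.)  The rejection rate of the
    first candidate at threshold 0.05 should approximate the nominal
    level.
    """
    model = poisson_model()
    true = parse_newick(_QUARTET["A"].format(b=0.0))
    pvals = []
    for s in range(n_sims):
        aln, _ = simulate_alignment(true, model, n_sites, seed=_sub(seed, 100 + s))
        cands = [
            (k, parse_newick(_QUARTET[k].format(b=0.01)))
            for k in ("A", "B", "C")
        ]
        table = sitelh_from_trees(aln, cands, model, optimize_bl=False)
        res = test_hypotheses(table, B=B, seed=_sub(seed, 5000 + s))
        pvals.append(res.by_id("A").fit.p_au)
    pvals = np.asarray(pvals)
    return {
        "rejection_rate_at_0.05": float(np.mean(pvals < 0.05)),
        "n": n_sims,
    }


def au_power_check(
    seed: int, n_sims: int = 100, n_sites: int = 10_000, B: int = 1000
) -> dict:
    """Data simulated under a resolved topology A: A should survive the
    AU test (p >= 0.05) in nearly every run, with candidates A, B, C."""
    model = poisson_model()
    true = parse_newick(_QUARTET["A"].format(b=0.02))
    ok = 0
    for s in range(n_sims):
        aln, _ = simulate_alignment(true, model, n_sites, seed=_sub(seed, 300 + s))
        cands = [
            (k, parse_newick(_QUARTET[k].format(b=0.02)))
            for k in ("A", "B", "C")
        ]
        table = sitelh_from_trees(aln, cands, model, optimize_bl=False)
        res = test_hypotheses(table, B=B, seed=_sub(seed, 7000 + s))
        ok += res.by_id("A").verdict == "not_rejected"
    return {"true_tree_not_rejected_rate": ok / n_sims, "n": n_sims}


def au_fit_recovery(seed: int, B: int = 10_000) -> dict:
    """Recover known (d, c) = (1.2, 0.3) from noisy multiscale BP
    curves; also compare the RELL sampler against expectations on a
    dominant-topology fixture."""
    rng = np.random.default_rng(_sub(seed, 8))
    scales = np.round(np.arange(0.5, 1.45, 0.1), 10)
    d_true, c_true = 1.2, 0.3
    bp_true = 1.0 - norm.cdf(d_true * np.sqrt(scales) + c_true / np.sqrt(scales))
    bp_obs = rng.binomial(B, bp_true) / B
    fit = au_pvalue(bp_obs, scales, B=B)
    # RELL sanity: a strictly dominant topology wins every replicate
    lnl = np.vstack([np.full(50, -1.0), np.full(50, -1.3)])
    bp = rell_bootstrap(SiteLnLTable(["A", "B"], lnl), B=500,
                        seed=_sub(seed, 9))
    return {
        "d_error": abs(fit.d - d_true),
        "c_error": abs(fit.c - c_true),
        "p_au_error": abs(fit.p_au - (1.0 - norm.cdf(d_true - c_true))),
        "dominant_bp": float(bp[0].min()),
        "n": B,
    }


# ---------------------------------------------------------------------------
# Gene screening
# ---------------------------------------------------------------------------

def screening_benchmark(
    seed: int,
    n_genes_fast: int = 100,
    n_genes_boot: int = 60,
    n_boot: int = 100,
) -> dict:
    """Sensitivity of the three artifact detectors plus the clean-gene
    keep rate, each measured on its own synthetic gene set under the
    generator's default conditions."""
    model = poisson_model(alpha=1.0, K=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        # long branches: NJ gene trees, Tukey fence
        _, genes, truth, tax = simulate_study(
            SimParams(n_genes=n_genes_fast, p_long_branch=1.0, seed=_sub(seed, 10))
        )
        hits = tot = 0
        for gid, aln in genes:
            found = detect_long_branches(build_gene_tree(aln, model), tax)
            inj = {t for g, t in truth.of_kind("long_branch") if g == gid}
            tot += len(inj)
            hits += len(inj & found)
        lb_sens = hits / max(tot, 1)

        # paralogs: non-cherry multi-copy taxa
        _, genes, truth, tax = simulate_study(
            SimParams(n_genes=n_genes_fast, p_paralog=1.0, seed=_sub(seed, 11))
        )
        hits = tot = 0
        for gid, aln in genes:
            flags = flag_paralogy(aln, build_gene_tree(aln, model))
            found = {f.taxon for f in flags if not f.is_cherry}
            inj = {t for g, t in truth.of_kind("paralog") if g == gid}
            tot += len(inj)
            hits += len(inj & found)
        par_sens = hits / max(tot, 1)

        # contaminants: anomalous grouping on bootstrap-annotated trees
        _, genes, truth, tax = simulate_study(
            SimParams(
                n_genes=n_genes_boot, sites_per_gene=1000, p_contaminant=1.0,
                seed=_sub(seed, 12),
            )
        )
        hits = tot = 0
        for i, (gid, aln) in enumerate(genes):
            gt = bootstrap_supports(aln, model, n_reps=n_boot,
                                    seed=_sub(seed, 13) + i)
            found = {t for t, s in detect_anomalous_grouping(gt, tax)}
            inj = {t for g, t in truth.of_kind("contaminant") if g == gid}
            tot += len(inj)
            hits += len(inj & found)
        con_sens = hits / max(tot, 1)

        # false-positive control: artifact-free genes through the full screen
        _, genes, truth, tax = simulate_study(
            SimParams(n_genes=n_genes_boot, seed=_sub(seed, 14))
        )
        kept = sum(
            screen_gene(gid, aln, tax, model, n_boot=n_boot,
                        seed=_sub(seed, 15) + i).decision == "keep"
            for i, (gid, aln) in enumerate(genes)
        )
    return {
        "long_branch_sensitivity": lb_sens,
        "paralog_sensitivity": par_sens,
        "contaminant_sensitivity": con_sens,
        "clean_gene_keep_rate": kept / n_genes_boot,
        "n": n_genes_fast,
    }


# ---------------------------------------------------------------------------
# Supermatrix bookkeeping
# ---------------------------------------------------------------------------

def supermatrix_bookkeeping(seed: int) -> dict:
    """Concatenate a synthetic gene set with heterogeneous occupancy,
    apply the occupancy filters in order, and verify the bookkeeping
    identities (width/taxon conservation, strict gappy boundary)."""
    _, genes, _, _ = simulate_study(
        SimParams(n_genes=40, sites_per_gene=300,
                  missing_taxon_fraction=0.25, seed=_sub(seed, 16))
    )
    bundle = concatenate(genes)
    initial_w, initial_t = bundle.width, bundle.n_taxa
    after_taxa = filter_gappy_taxa(bundle, 0.80)
    final = filter_sites(after_taxa)
    width_ok = final.width + len(final.removed_sites) == initial_w
    taxa_ok = final.n_taxa + len(final.removed_taxa) == initial_t
    boundary_ok = all(frac > 0.80 for _, frac in final.removed_taxa)
    parts_ok = final.partitions.total_width == final.width
    return {
        "initial_sites": initial_w,
        "final_sites": final.width,
        "initial_taxa": initial_t,
        "final_taxa": final.n_taxa,
        "bookkeeping_identities_hold": float(
            width_ok and taxa_ok and boundary_ok and parts_ok
        ),
        "n": initial_w,
    }
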