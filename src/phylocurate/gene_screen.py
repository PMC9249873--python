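"""Per-gene quality screening: long branches, anomalous groupings,
paralogy, and the keep/drop decision.

Screening operates on a per-gene tree (supplied externally, or built
here by neighbor joining on maximum-likelihood pairwise distances) and
a taxonomy table naming each taxon's expected clade and in/outgroup
status.  The rules:

* a gene is dropped when it contains >= 3 long-branch ingroup taxa
  (Tukey-fence outliers of terminal branch length), not counting taxa
  from whitelisted clades that are long-branched everywhere;
* a gene is dropped when any taxon groups with the outgroup, or
  resolves inside a foreign expected clade, with bootstrap support
  above 90;
* a gene is dropped when any taxon has multiple sequence copies that do
  not form a single cherry (putative paralogs rather than
  alleles/isoforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alignment import Alignment
from .io import TaxonomyMap, parse_newick
from .models import RateModel, N_STATES
from .simulate import copy_owner
from .trees import PhyloTree

MAX_DISTANCE = 10.0


# ---------------------------------------------------------------------------
# ML pairwise distances
# ---------------------------------------------------------------------------

def _is_poisson(model: RateModel) -> bool:
    S = model.exchangeabilities
    off = S[~np.eye(N_STATES, dtype=bool)]
    return np.allclose(off, off[0]) and np.allclose(
        model.frequencies, 1.0 / N_STATES
    )


def _poisson_mixture_distance(
    p_hat: np.ndarray, model: RateModel, cap: float = MAX_DISTANCE
) -> np.ndarray:
    """Solve E[p_diff](d) = p_hat for the Poisson family.

    Under equal exchangeabilities/frequencies the pair likelihood
    depends on the data only through the proportion of differing sites,
    so the ML distance solves sum_k w_k (19/20)(1 - exp(-20/19 d r_k))
    = p_hat; vectorized bisection (monotone in d).
    """
    limit = (N_STATES - 1) / N_STATES
    rates = model.category_rates
    p_hat = np.asarray(p_hat, dtype=float)

    def expected_p(d):
        return limit * (
            1.0 - np.exp(-np.outer(d, rates) / limit).mean(axis=1)
        )

    lo = np.zeros(p_hat.shape)
    hi = np.full(p_hat.shape, cap)
    saturated = p_hat >= expected_p(np.atleast_1d(hi.ravel())).reshape(hi.shape)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = expected_p(mid.ravel()).reshape(mid.shape) < p_hat
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    d = 0.5 * (lo + hi)
    d[saturated] = cap
    return d


def ml_pairwise_distance(
    counts: np.ndarray, model: RateModel, cap: float = MAX_DISTANCE
) -> float:
    """1-D ML distance from a 20x20 aligned-pair count matrix.

    Maximizes sum_xy C_xy log(pi_x sum_k w_k P_k(d)[x, y]) by bounded
    Brent search; saturated pairs are capped with a warning.
    """
    C = np.asarray(counts, dtype=float)
    if C.sum() == 0:
        raise ValueError("pair has no overlapping non-missing sites")
    nz = C > 0
    pi = model.frequencies

    def neg_lnl(d):
        P = np.zeros((N_STATES, N_STATES))
        for rate in model.category_rates:
            P += model.transition_matrix(d * rate)
        P /= model.K
        with np.errstate(divide="ignore"):
            lp = np.log(np.clip(P, 1e-310, None)) + np.log(pi)[:, None]
        return -float((C[nz] * lp[nz]).sum())

    res = minimize_scalar(
        neg_lnl, bounds=(1e-9, cap), method="bounded",
        options={"xatol": 1e-6},
    )
    d = float(res.x)
    if d > 0.98 * cap:
        warnings.warn(f"near-saturated pair; distance capped at {cap}")
        return cap
    return d


def ml_distance_matrix(aln: Alignment, model: RateModel) -> np.ndarray:
    """All-pairs ML distances; fast sufficient-statistic path for the
    Poisson family, per-pair numeric optimization otherwise."""
    codes = aln.state_matrix()
    n = aln.n_taxa
    valid = codes >= 0
    D = np.zeros((n, n))
    if _is_poisson(model):
        p_hat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                if not both.any():
                    raise ValueError(
                        f"taxa {aln.taxon_labels[i]!r} and {aln.taxon_labels[j]!r} "
                        "share no non-missing sites"
                    )
                p_hat[i, j] = p_hat[j, i] = np.mean(codes[i, both] != codes[j, both])
        D = _poisson_mixture_distance(p_hat, model)
        np.fill_diagonal(D, 0.0)
    else:
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                if not both.any():
                    raise ValueError(
                        f"taxa {aln.taxon_labels[i]!r} and {aln.taxon_labels[j]!r} "
                        "share no non-missing sites"
                    )
                C = np.zeros((N_STATES, N_STATES))
                np.add.at(C, (codes[i, both], codes[j, both]), 1.0)
                D[i, j] = D[j, i] = ml_pairwise_distance(C, model)
    return D


def _nj_tree(D: np.ndarray, labels: list[str]) -> PhyloTree:
    dm = DistanceMatrix(D, ids=labels)
    tnode = _skbio_nj(dm)
    tree = parse_newick(str(tnode))
    for node in tree.preorder():  # clamp tiny negatives from NJ arithmetic
        if node.length < 0:
            node.length = 0.0
    return tree


def build_gene_tree(aln: Alignment, model: RateModel) -> PhyloTree:
    """Neighbor joining on model-corrected (ML) pairwise distances.

    Negative NJ branch estimates are clamped to zero; saturated pairs
    are capped at distance 10.
    """
    if aln.n_taxa < 3:
        raise ValueError("need >= 3 taxa to build a tree")
    D = ml_distance_matrix(aln, model)
    return _nj_tree(D, list(aln.taxon_labels))


def bootstrap_supports(
    aln: Alignment, model: RateModel, n_reps: int = 100, seed: int = 0
) -> PhyloTree:
    """Point NJ tree with internal edges labeled by the bipartition
    frequency (x100) over site-resampled NJ replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = build_gene_tree(aln, model)
    rng = np.random.default_rng(seed)
    tallies: dict[frozenset, int] = {b: 0 for b in tree.bipartitions()}
    n = aln.n_sites
    for _ in range(n_reps):
        idx = rng.integers(n, size=n)
        # resampled columns get fresh ids (duplicates break provenance ids)
        rep_aln = Alignment(list(aln.taxon_labels), aln.matrix[:, idx])
        try:
            rep_tree = build_gene_tree(rep_aln, model)
        except ValueError:  # replicate lost all overlap for some pair
            continue
        for b in rep_tree.bipartitions():
            if b in tallies:
                tallies[b] += 1
    all_leaves = frozenset(aln.taxon_labels)
    ref = min(all_leaves)
    sets = tree.leafsets()
    for node in tree.preorder():
        if node.is_leaf or node is tree.root:
            continue
        below = sets[node]
        side = below if ref not in below else all_leaves - below
        if side in tallies:
            node.support = 100.0 * tallies[side] / n_reps
    return tree


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

def detect_long_branches(
    tree: PhyloTree, taxonomy: TaxonomyMap, fence_k: float = 1.5
) -> set:
    """Ingroup taxa whose terminal branch exceeds the Tukey fence
    Q3 + fence_k * IQR of ingroup terminal branch lengths (quantiles by
    linear interpolation)."""
    term = tree.terminal_branch_lengths()
    ingroup_terms = {
        label: L
        for label, L in term.items()
        if taxonomy.ingroup.get(copy_owner(label), False)
    }
    if len(ingroup_terms) < 4:
        warnings.warn("fewer than 4 ingroup taxa; long-branch rule skipped")
        return set()
    values = np.array(list(ingroup_terms.values()))
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + fence_k * (q3 - q1)
    return {copy_owner(label) for label, L in ingroup_terms.items() if L > fence}


def detect_anomalous_grouping(
    tree: PhyloTree, taxonomy: TaxonomyMap, support_threshold: float = 90.0
) -> list[tuple[str, float]]:
    """Taxa in phylogenetically impossible positions at high support.

    Rule 1 (outgroup nesting): X is anomalous iff some edge with
    support > threshold has X on a side containing >= 1 outgroup member
    and no other ingroup member.  Rule 2 (foreign clade): X is
    anomalous iff some such side contains, besides X, only members of a
    single expected clade different from X's.  Returns (taxon, support)
    pairs, keeping the highest offending support per taxon.
    """
    leaf_labels = tree.leaf_names()
    owners = {lab: copy_owner(lab) for lab in leaf_labels}
    uncovered = [o for o in owners.values() if o not in taxonomy.clade]
    if uncovered:
        raise ValueError(f"taxonomy does not cover: {sorted(set(uncovered))}")
    out_present = any(not taxonomy.ingroup[owners[l]] for l in leaf_labels)
    if not out_present:
        warnings.warn("no outgroup taxa in tree; only foreign-clade rule applies")

    biparts = tree.bipartitions(with_support=True)
    all_leaves = frozenset(leaf_labels)
    out_set = frozenset(
        l for l in leaf_labels if not taxonomy.ingroup[owners[l]]
    )
    n_out_total = len(out_set)
    # is the outgroup monophyletic in this tree? (a pendant outgroup of
    # size <= 1 trivially is)
    out_monophyletic = n_out_total <= 1 or any(
        side == out_set
        for bip in biparts
        for side in (bip, all_leaves - bip)
    )
    clade_count: dict[str, int] = {}
    for l in leaf_labels:
        clade_count[taxonomy.clade[owners[l]]] = (
            clade_count.get(taxonomy.clade[owners[l]], 0) + 1
        )
    found: dict[str, float] = {}
    for bip, support in biparts.items():
        if support is None or support <= support_threshold:
            continue
        for side in (bip, all_leaves - bip):
            members = sorted(side)
            ing = [l for l in members if taxonomy.ingroup[owners[l]]]
            outs = [l for l in members if not taxonomy.ingroup[owners[l]]]
            # rule 1: lone ingroup taxon grouped with outgroup members.
            # A side holding X plus the ENTIRE outgroup is also what a
            # genuinely basal ingroup lineage produces (the root lies
            # inside that side when the tree is rooted on the outgroup's
            # common edge), so that configuration only counts when no
            # basal reading exists: X interrupts outgroup monophyly, or
            # X's expected clade-mates sit elsewhere in the tree (the
            # taxonomy says X belongs with them, not at the root).
            if out_present and len(ing) == 1 and outs:
                x = owners[ing[0]]
                clade_mates_present = any(
                    owners[l] != x and taxonomy.clade[owners[l]] == taxonomy.clade[x]
                    for l in leaf_labels
                )
                nested = (
                    len(outs) < n_out_total
                    or not out_monophyletic
                    or clade_mates_present
                )
                if nested:
                    found[x] = max(found.get(x, 0.0), support)
            # rule 2: taxon strictly inside a foreign expected clade: the
            # side holds X plus only clade-c members, and clade c has
            # further members outside the side (X interrupts the clade,
            # rather than being its sister).
            if not outs and len(members) >= 3:
                for l in members:
                    others = [m for m in members if owners[m] != owners[l]]
                    if not others or len(others) < 2:
                        continue
                    other_clades = {taxonomy.clade[owners[m]] for m in others}
                    my_clade = taxonomy.clade[owners[l]]
                    if len(other_clades) == 1 and my_clade not in other_clades:
                        foreign = next(iter(other_clades))
                        if clade_count.get(foreign, 0) > len(others):
                            x = owners[l]
                            found[x] = max(found.get(x, 0.0), support)
    return sorted(found.items())


def _is_unrooted_clade(tree: PhyloTree, members: frozenset) -> bool:
    sets = tree.leafsets()
    all_leaves = frozenset(tree.leaf_names())
    for node, below in sets.items():
        if below == members or all_leaves - below == members:
            return True
    return False


@dataclass
class ParalogFlag:
    taxon: str
    copy_count: int
    is_cherry: bool


def flag_paralogy(gene_aln: Alignment, gene_tree: PhyloTree) -> list[ParalogFlag]:
    """Flag taxa with multiple sequence copies.

    Copies that form a single cherry/clade in the gene tree are likely
    alleles or isoforms (``is_cherry=True``); copies scattered across
    the tree are paralogy signs.
    """
    by_owner: dict[str, list[str]] = {}
    for label in gene_aln.taxon_labels:
        by_owner.setdefault(copy_owner(label), []).append(label)
    flags = []
    for taxon, labels in sorted(by_owner.items()):
        if len(labels) < 2:
            continue
        is_cherry = _is_unrooted_clade(gene_tree, frozenset(labels))
        flags.append(ParalogFlag(taxon, len(labels), is_cherry))
    return flags


@dataclass
class ScreenReport:
    """Everything the keep/drop decision needs, per gene."""

    gene_id: str
    long_branch_taxa: set = field(default_factory=set)
    anomalies: list = field(default_factory=list)
    paralog_flags: list = field(default_factory=list)
    short_taxa: set = field(default_factory=set)
    decision: str = "keep"
    reasons: list = field(default_factory=list)

    def has_paralogy_sign(self, strict: bool = False) -> bool:
        if strict:
            return bool(self.paralog_flags)
        return any(not f.is_cherry for f in self.paralog_flags)


def decide_gene(
    report: ScreenReport,
    taxonomy: TaxonomyMap,
    max_long_branches: int = 3,
    strict_paralogy: bool = False,
) -> ScreenReport:
    """Apply the drop rules, filling decision and reasons.

    Drop iff the number of long-branch taxa outside whitelisted clades
    reaches *max_long_branches*, OR any anomalous grouping was found,
    OR the gene shows a paralogy sign (a non-cherry multi-copy taxon;
    cherries count only in strict mode), OR the optional short-sequence
    screen flagged any taxon.
    """
    reasons = []
    if report.short_taxa:
        reasons.append("short_sequences")
    effective_lb = {
        t for t in report.long_branch_taxa if not taxonomy.is_whitelisted(t)
    }
    if len(effective_lb) >= max_long_branches:
        reasons.append("long_branches")
    if report.anomalies:
        reasons.append("anomalous_grouping")
    if report.has_paralogy_sign(strict=strict_paralogy):
        reasons.append("paralogy")
    report.decision = "drop" if reasons else "keep"
    report.reasons = reasons
    return report


def screen_gene(
    gene_id: str,
    aln: Alignment,
    taxonomy: TaxonomyMap,
    model: RateModel,
    tree: Optional[PhyloTree] = None,
    n_boot: int = 100,
    seed: int = 0,
    fence_k: float = 1.5,
    support_threshold: float = 90.0,
    max_long_branches: int = 3,
    min_ungapped_fraction: Optional[float] = None,
) -> ScreenReport:
    """Run the full screen on one gene; builds a bootstrap-annotated NJ
    tree unless one is supplied.

    *min_ungapped_fraction* enables the optional short-sequence screen
    (off by default): taxa whose non-missing fraction of the alignment
    falls below the threshold are flagged and drop the gene.
    """
    if tree is None:
        tree = bootstrap_supports(aln, model, n_reps=n_boot, seed=seed)
    short: set = set()
    if min_ungapped_fraction is not None:
        present = 1.0 - aln.missing_mask().mean(axis=1)
        short = {
            copy_owner(t)
            for t, frac in zip(aln.taxon_labels, present)
            if frac < min_ungapped_fraction
        }
    report = ScreenReport(
        gene_id=gene_id,
        long_branch_taxa=detect_long_branches(tree, taxonomy, fence_k=fence_k),
        anomalies=detect_anomalous_grouping(
            tree, taxonomy, support_threshold=support_threshold
        ),
        paralog_flags=flag_paralogy(aln, tree),
        short_taxa=short,
    )
    return decide_gene(report, taxonomy, max_long_branches=max_long_branches)
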