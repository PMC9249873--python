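"""Synthetic phylogenomic data with known ground truth.

Generates gene alignments along a common species tree with discrete-
gamma rate heterogeneity across sites, heterogeneous per-gene taxon
occupancy, and injected artifacts mimicking the failure modes a
curation pipeline must catch:

* ``paralog`` — a taxon gains a second sequence copy derived from a
  distant subtree, evolved further (a hidden duplication);
* ``contaminant`` — a taxon's sequence is re-simulated from a lineage
  attached to the outgroup ancestor (wrong-source sequence);
* ``long_branch`` — a taxon's terminal branch is multiplied by a large
  factor before simulating its sequence (rate acceleration);
* ``masked`` — a taxon is deleted from a gene (missing data).

Every modification is recorded in a :class:`GroundTruth` object, so
downstream detectors can be scored for sensitivity/specificity.  A
single global seed is fanned out to per-gene substreams keyed by gene
index: adding genes never perturbs earlier genes' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .alignment import AMINO_ACIDS, Alignment
from .io import TaxonomyMap
from .models import RateModel, discrete_gamma_rates
from .trees import Node, PhyloTree

PARALOG_SEP = "__copy"


# ---------------------------------------------------------------------------
# Parameters & ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Knobs of the synthetic study.

    Defaults emulate a modest phylotranscriptomic gene set: tens of
    taxa, hundreds of sites per gene, gamma rate heterogeneity with
    alpha = 1, and low per-gene artifact rates.
    """

    n_taxa: int = 16
    n_genes: int = 50
    sites_per_gene: int = 500
    alpha: float = 1.0
    K_sim: int = 4
    tree_height: float = 0.75
    birth_rate: float = 1.0
    p_paralog: float = 0.0
    p_contaminant: float = 0.0
    p_long_branch: float = 0.0
    long_branch_factor: float = 10.0
    paralog_extra_divergence: float = 1.0
    missing_taxon_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_paralog,
            self.p_contaminant,
            self.p_long_branch,
            self.missing_taxon_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError("artifact probabilities must be in [0, 1]")
        if self.long_branch_factor <= 1:
            raise ValueError("long_branch_factor must be > 1")


@dataclass
class GroundTruth:
    """Labels for every modification applied to the clean gene set."""

    species_tree: PhyloTree
    artifacts: set = field(default_factory=set)  # (gene_id, taxon, kind)
    site_categories: dict = field(default_factory=dict)  # gene_id -> np.ndarray

    def of_kind(self, kind: str) -> set:
        return {(g, t) for g, t, k in self.artifacts if k == kind}

    def genes_with_artifacts(self) -> set:
        return {g for g, _, _ in self.artifacts}


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float = 1.0,
    rng: np.random.Generator | None = None,
) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to the requested root-to-tip height.

    All leaves are contemporaneous (ultrametric), labeled T001..Tnnn in
    birth order.  Same seed, same Newick string.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    birth_times = {a: 0.0, b: 0.0}
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node.length = t - birth_times[node]
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        birth_times[c1] = birth_times[c2] = t
        active.extend([c1, c2])
    # one more waiting time so the last split is interior
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth_times[node]
    # name leaves in traversal order before validation
    stack, i = [root], 0
    while stack:
        node = stack.pop()
        if not node.children:
            i += 1
            node.name = f"T{i:03d}"
        stack.extend(reversed(node.children))
    tree = PhyloTree(root, rooted=True)
    tree.scale_branches(height / t)
    return tree


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _evolve(
    parent_states: np.ndarray,
    t: float,
    site_rates: np.ndarray,
    model: RateModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample child states from P(t * r_s) row-wise."""
    child = np.empty_like(parent_states)
    for rate in np.unique(site_rates):
        idx = np.nonzero(site_rates == rate)[0]
        P = model.transition_matrix(t * rate)
        C = np.cumsum(P, axis=1)
        u = rng.random(idx.size)
        child[idx] = (C[parent_states[idx]] < u[:, None]).sum(axis=1)
    return child


def _simulate_states(
    tree: PhyloTree, model: RateModel, n_sites: int, rng: np.random.Generator
):
    """Node states for every node plus the true per-site categories."""
    cats = rng.integers(model.K, size=n_sites)  # 0-based
    site_rates = model.category_rates[cats]
    Cpi = np.cumsum(model.frequencies)
    root_states = (Cpi[None, :] < rng.random(n_sites)[:, None]).sum(axis=1)
    states = {id(tree.root): root_states}
    for node in tree.preorder():
        if node.parent is None:
            continue
        states[id(node)] = _evolve(
            states[id(node.parent)], node.length, site_rates, model, rng
        )
    return states, cats + 1, site_rates


def _states_to_rows(tree: PhyloTree, states: dict) -> Alignment:
    aa = np.array(list(AMINO_ACIDS))
    labels, rows = [], []
    for leaf in tree.leaves():
        labels.append(leaf.name)
        rows.append(aa[states[id(leaf)]])
    return Alignment(labels, np.array(rows))


def simulate_alignment(
    tree: PhyloTree, model: RateModel, n_sites: int, seed: int = 0
) -> tuple[Alignment, np.ndarray]:
    """Simulate one alignment; returns (Alignment, true 1-based categories)."""
    if tree.total_length() < 0:
        raise ValueError("tree must have non-negative total length")
    rng = np.random.default_rng(seed)
    states, cats, _ = _simulate_states(tree, model, n_sites, rng)
    return _states_to_rows(tree, states), cats


# ---------------------------------------------------------------------------
# Outgroup convention & taxonomy
# ---------------------------------------------------------------------------

def split_outgroup(species_tree: PhyloTree) -> tuple[set, set]:
    """The smaller side of the root split is the outgroup."""
    sets = species_tree.leafsets()
    sides = [sets[ch] for ch in species_tree.root.children]
    sides.sort(key=lambda s: (len(s), sorted(s)))
    out = set(sides[0])
    ing = set(species_tree.leaf_names()) - out
    return ing, out


def default_taxonomy(
    species_tree: PhyloTree, whitelist_known_long_branches: bool = True
) -> TaxonomyMap:
    """Taxonomy derived from the species tree: the smaller root clade is
    the outgroup; ingroup clade labels follow the subtrees hanging off
    the ingroup ancestor.

    Lineages whose TRUE pendant branch is a Tukey-fence outlier of the
    ingroup are whitelisted by name (their clade labels stay intact),
    emulating the practice of exempting a priori known long-branch
    lineages from the long-branch gene-drop count.
    """
    ingroup, outgroup = split_outgroup(species_tree)
    sets = species_tree.leafsets()
    ing_root = next(
        ch for ch in species_tree.root.children if set(sets[ch]) == ingroup
    )
    clade: dict[str, str] = {t: "Out" for t in outgroup}
    for i, ch in enumerate(ing_root.children, start=1):
        for t in sets[ch]:
            clade[t] = f"Clade{i}"
    whitelist: set = set()
    if whitelist_known_long_branches:
        pend = species_tree.terminal_branch_lengths()
        vals = np.array([pend[t] for t in sorted(ingroup)])
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + 1.5 * (q3 - q1)
        whitelist = {t for t in ingroup if pend[t] > fence}
    ingroup_flag = {t: t in ingroup for t in species_tree.leaf_names()}
    return TaxonomyMap(clade, ingroup_flag, frozenset(whitelist))


# ---------------------------------------------------------------------------
# Gene sets with artifacts
# ---------------------------------------------------------------------------

@dataclass
class GeneSimulation:
    """A simulated gene plus the state it needs for artifact injection."""

    gene_id: str
    tree: PhyloTree  # gene's own copy of the species tree
    states: dict
    site_rates: np.ndarray
    categories: np.ndarray
    rng: np.random.Generator
    model: RateModel


def simulate_gene_set(
    species_tree: PhyloTree, model: RateModel, params: SimParams
) -> list[GeneSimulation]:
    """Clean per-gene simulations with per-gene RNG substreams."""
    genes = []
    for g in range(params.n_genes):
        rng = np.random.default_rng([params.seed, g])
        tree = species_tree.copy()
        states, cats, site_rates = _simulate_states(
            tree, model, params.sites_per_gene, rng
        )
        genes.append(
            GeneSimulation(
                gene_id=f"g{g + 1:04d}",
                tree=tree,
                states=states,
                site_rates=site_rates,
                categories=cats,
                rng=rng,
                model=model,
            )
        )
    return genes


def inject_artifacts(
    gene_set: list[GeneSimulation],
    species_tree: PhyloTree,
    params: SimParams,
) -> tuple[list[tuple[str, Alignment]], GroundTruth]:
    """Apply paralog/contaminant/long-branch/masking artifacts.

    Each artifact kind hits a gene with its per-gene probability,
    affecting one randomly chosen ingroup taxon; masking is drawn per
    taxon per gene (heterogeneous occupancy).  Returns the (gene_id,
    Alignment) list and the complete ground-truth labels.
    """
    import warnings

    truth = GroundTruth(species_tree=species_tree.copy())
    ingroup, outgroup = split_outgroup(species_tree)
    sets = species_tree.leafsets()
    height = species_tree.height()
    depths = species_tree.node_depths()
    out: list[tuple[str, Alignment]] = []
    aa = np.array(list(AMINO_ACIDS))

    for gene in gene_set:
        rng = gene.rng
        tree = gene.tree
        states = dict(gene.states)
        truth.site_categories[gene.gene_id] = gene.categories
        leaves = {n.name: n for n in tree.leaves()}
        seqs: dict[str, np.ndarray] = {
            name: states[id(node)] for name, node in leaves.items()
        }
        ing_list = sorted(n for n in leaves if n in ingroup)
        g_sets = tree.leafsets()

        if rng.random() < params.p_long_branch:
            taxon = ing_list[rng.integers(len(ing_list))]
            node = leaves[taxon]
            # elongation is floored at factor x the cohort's upper-quartile
            # pendant: multiplying a near-zero pendant would label an
            # artifact that is not actually a long branch.  Since the
            # Tukey fence is Q3 + 1.5*IQR <= 2.5*Q3 for non-negative
            # lengths, factor*Q3 (factor > 2.5) guarantees a true outlier.
            q3 = float(
                np.percentile([leaves[t].length for t in ing_list], 75)
            )
            seqs[taxon] = _evolve(
                states[id(node.parent)],
                params.long_branch_factor * max(node.length, q3),
                gene.site_rates,
                gene.model,
                rng,
            )
            truth.artifacts.add((gene.gene_id, taxon, "long_branch"))

        if rng.random() < params.p_contaminant:
            candidates = [t for t in ing_list
                          if (gene.gene_id, t, "long_branch") not in truth.artifacts]
            if candidates:
                taxon = candidates[rng.integers(len(candidates))]
                # wrong-source sequence: a lineage attached to a random
                # outgroup terminal, diverged so the total root-to-
                # contaminant path is 2x tree height (a real organism's
                # sequence is concretely related to one outgroup lineage,
                # not to an ancestral node)
                out_sorted = sorted(outgroup)
                source = out_sorted[rng.integers(len(out_sorted))]
                src_node = next(n for n in tree.leaves() if n.name == source)
                src_depth = depths[
                    next(n for n in species_tree.leaves() if n.name == source)
                ]
                pendant = max(2.0 * height - src_depth, 0.05 * height)
                seqs[taxon] = _evolve(
                    states[id(src_node)], pendant, gene.site_rates, gene.model, rng
                )
                truth.artifacts.add((gene.gene_id, taxon, "contaminant"))

        if rng.random() < params.p_paralog:
            clean = [t for t in ing_list
                     if not any((gene.gene_id, t, k) in truth.artifacts
                                for k in ("long_branch", "contaminant"))]
            if clean:
                taxon = clean[rng.integers(len(clean))]
                # copy sourced from a leaf in the other root subtree half
                side = next(s for s in (g_sets[c] for c in tree.root.children)
                            if taxon in s)
                others = sorted(set(tree.leaf_names()) - set(side))
                source = others[rng.integers(len(others))]
                copy = _evolve(
                    seqs[source],
                    params.paralog_extra_divergence,
                    gene.site_rates,
                    gene.model,
                    rng,
                )
                seqs[f"{taxon}{PARALOG_SEP}2"] = copy
                truth.artifacts.add((gene.gene_id, taxon, "paralog"))

        if params.missing_taxon_fraction > 0:
            mask = rng.random(len(ing_list)) < params.missing_taxon_fraction
            for taxon, m in zip(ing_list, mask):
                if m and len(seqs) > 4:
                    base_present = [s for s in seqs if copy_owner(s) != taxon]
                    if len(base_present) >= 4:
                        for label in [s for s in seqs if copy_owner(s) == taxon]:
                            del seqs[label]
                        truth.artifacts.add((gene.gene_id, taxon, "masked"))

        labels = sorted(seqs)
        rows = np.array([aa[seqs[t]] for t in labels])
        out.append((gene.gene_id, Alignment(labels, rows)))

    if truth.genes_with_artifacts() == {g.gene_id for g in gene_set} and gene_set:
        warnings.warn("no artifact-free gene remains at these artifact rates")
    return out, truth


def copy_owner(label: str) -> str:
    """Taxon that owns a (possibly multi-copy) sequence label."""
    return label.split(PARALOG_SEP)[0]


def simulate_study(
    params: SimParams, model: RateModel | None = None
) -> tuple[PhyloTree, list[tuple[str, Alignment]], GroundTruth, TaxonomyMap]:
    """One-call study generator: species tree, gene set, truth, taxonomy."""
    from .models import poisson_model

    if model is None:
        model = poisson_model(alpha=params.alpha, K=params.K_sim)
    tree = simulate_tree(
        params.n_taxa, params.birth_rate, seed=params.seed, height=params.tree_height
    )
    genes = simulate_gene_set(tree, model, params)
    gene_alns, truth = inject_artifacts(genes, tree, params)
    taxonomy = default_taxonomy(tree)
    return tree, gene_alns, truth, taxonomy


def params_snapshot(params: SimParams) -> dict:
    return asdict(params)
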