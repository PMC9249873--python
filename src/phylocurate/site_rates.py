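"""Site-rate categorization and fast-site stripping.

The likelihood kernel is Felsenstein pruning under a reversible
amino-acid model with K discrete-gamma categories.  Each alignment
column gets a posterior distribution over the K rate categories
(uniform 1/K prior), an empirical-Bayes argmax category, and a
posterior-mean rate; the site-removal assay then strips all sites
assigned to the fastest categories.

Gap and unknown residues are treated as fully ambiguous (conditional
likelihood 1 for every state).  Per-site likelihoods of exactly zero
(impossible columns under zero-length branches) are guarded with the
sentinel log-likelihood -1e300 and never exponentiated unprotected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .models import RateModel
from .trees import PhyloTree

#: sentinel for log(0); large negative, finite
LOG_ZERO = -1e300


def _prune_category(
    codes: np.ndarray,
    order: list,
    lengths: dict,
    leaf_row: dict,
    model: RateModel,
    rate: float,
) -> np.ndarray:
    """Log-likelihood per site pattern for one rate category.

    codes: (n_leaves, n_patterns) int8 state codes, -1 = missing.
    order: postorder node list; child_index/lengths keyed by node id.
    """
    n_pat = codes.shape[1]
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_pat)
    eye = np.eye(20)
    for node in order:
        if node.is_leaf:
            states = codes[leaf_row[node.name]]
            p = np.ones((n_pat, 20))
            obs = states >= 0
            p[obs] = eye[states[obs]]
            partial[id(node)] = p
        else:
            p = np.ones((n_pat, 20))
            for ch in node.children:
                P = model.transition_matrix(lengths[id(ch)] * rate)
                p *= partial.pop(id(ch)) @ P.T
            # rescale to dodge underflow on deep trees
            mx = p.max(axis=1)
            safe = mx > 0
            scale = np.where(safe, mx, 1.0)
            p /= scale[:, None]
            logscale += np.where(safe, np.log(scale), 0.0)
            partial[id(node)] = p
    root_p = partial[id(order[-1])]
    lik = root_p @ model.frequencies
    out = np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)) + logscale, LOG_ZERO)
    # a pattern whose scaling hit zero is impossible
    out[~np.isfinite(out)] = LOG_ZERO
    return out


def compress_patterns(aln: Alignment, leaf_names: list) -> tuple:
    """Unique site patterns restricted to *leaf_names*.

    Returns (codes, inverse): codes is (n_leaves, n_patterns) int8 in
    leaf_names order, inverse maps each original site to its pattern.
    Precompute once when scoring many trees over the same leaf set.
    """
    missing = [t for t in leaf_names if t not in aln.taxon_labels]
    if missing:
        raise ValueError(f"tree taxa absent from alignment: {missing}")
    sub = aln.take_taxa(list(leaf_names))
    codes_full = sub.state_matrix()  # (n_leaves, n_sites)
    patterns, inverse = np.unique(codes_full.T, axis=0, return_inverse=True)
    return patterns.T, inverse


def site_loglik_per_category(
    aln: Alignment, tree: PhyloTree, model: RateModel, _compressed=None
) -> np.ndarray:
    """n_sites x K matrix of log P(site | tree, model, rate r_k).

    The tree's leaves must all be present in the alignment; alignment
    taxa absent from the tree are ignored.  Site patterns are compressed
    before pruning and expanded afterwards.
    """
    leaf_names = tree.leaf_names()
    codes, inverse = (
        _compressed
        if _compressed is not None
        else compress_patterns(aln, leaf_names)
    )

    order = list(tree.postorder())
    lengths = {id(n): n.length for n in order}
    leaf_row = {name: i for i, name in enumerate(leaf_names)}

    out = np.empty((codes.shape[1], model.K))
    for k, rate in enumerate(model.category_rates):
        out[:, k] = _prune_category(codes, order, lengths, leaf_row, model, rate)
    return out[inverse]


def total_loglik(aln: Alignment, tree: PhyloTree, model: RateModel) -> float:
    """Total log-likelihood with rates integrated out (uniform prior)."""
    return float(sitewise_mixture_loglik(aln, tree, model).sum())


def sitewise_mixture_loglik(
    aln: Alignment, tree: PhyloTree, model: RateModel, _compressed=None
) -> np.ndarray:
    """Per-site log sum_k (1/K) exp(lnl_sk), sentinel-guarded."""
    ll = site_loglik_per_category(aln, tree, model, _compressed=_compressed)
    return mixture_loglik(ll)


def mixture_loglik(loglik_matrix: np.ndarray) -> np.ndarray:
    ll = np.asarray(loglik_matrix, dtype=float)
    K = ll.shape[1]
    mx = ll.max(axis=1)
    guarded = mx > LOG_ZERO / 2
    shifted = np.where(guarded[:, None], ll - mx[:, None], 0.0)
    out = np.where(
        guarded, mx + np.log(np.exp(shifted).sum(axis=1) / K), LOG_ZERO
    )
    return out


@dataclass
class SiteRateAssignment:
    """Per-site rate-category posteriors.

    category: 1-based empirical-Bayes argmax (ties to the lower index).
    posterior_mean_rate: sum_k posterior_k * r_k.
    posterior: (n_sites, K), rows sum to 1.
    """

    category: np.ndarray
    posterior_mean_rate: np.ndarray
    posterior: np.ndarray
    category_rates: np.ndarray

    @property
    def K(self) -> int:
        return self.posterior.shape[1]

    def __len__(self) -> int:
        return len(self.category)


def assign_site_categories(
    loglik_matrix: np.ndarray, category_rates: np.ndarray
) -> SiteRateAssignment:
    """Empirical-Bayes rate-category assignment with uniform prior.

    posterior(k | s) ~ (1/K) exp(loglik[s, k]), normalized per site.
    Sites whose every category hit the log-zero sentinel fall back to
    the prior (category 1 under uniform weights), with a warning.
    """
    ll = np.asarray(loglik_matrix, dtype=float)
    n_sites, K = ll.shape
    rates = np.asarray(category_rates, dtype=float)
    if rates.shape != (K,):
        raise ValueError("category_rates length must match loglik columns")
    mx = ll.max(axis=1)
    dead = mx <= LOG_ZERO / 2
    if np.any(dead):
        import warnings

        warnings.warn(
            f"{int(dead.sum())} site(s) have zero likelihood in every category; "
            "assigned by prior weight"
        )
    shifted = np.where(dead[:, None], 0.0, ll - np.where(dead, 0.0, mx)[:, None])
    w = np.exp(np.clip(shifted, -745.0, 0.0))
    posterior = w / w.sum(axis=1, keepdims=True)
    category = posterior.argmax(axis=1) + 1  # argmax ties -> lower index
    pmr = posterior @ rates
    return SiteRateAssignment(category, pmr, posterior, rates)


def equal_count_rate_bins(posterior_mean_rates: np.ndarray, K: int) -> np.ndarray:
    """Alternative categorization mode: rank sites by posterior-mean
    rate and cut into K equal-count bins (1 = slowest).  Ties broken by
    site order; returns 1-based categories."""
    pmr = np.asarray(posterior_mean_rates, dtype=float)
    n = pmr.size
    if K < 1 or n == 0:
        raise ValueError("need K >= 1 and at least one site")
    order = np.argsort(pmr, kind="stable")
    cats = np.empty(n, dtype=np.int64)
    edges = (np.arange(1, K + 1) * n) // K
    start = 0
    for k, stop in enumerate(edges, start=1):
        cats[order[start:stop]] = k
        start = stop
    return cats


def strip_fast_categories(bundle, assignment: SiteRateAssignment, n_remove: int):
    """Remove all sites in the *n_remove* fastest categories.

    Returns a new SupermatrixBundle with partitions remapped and the
    removed fraction recorded; ``n_remove`` must be < K.
    """
    from .supermatrix import SupermatrixBundle

    K = assignment.K
    if not 0 <= n_remove < K:
        raise ValueError(f"n_remove must be in [0, {K - 1}], got {n_remove}")
    if len(assignment) != bundle.aln.n_sites:
        raise ValueError("assignment length != supermatrix width")
    if n_remove == 0:
        return bundle
    order = np.argsort(assignment.category_rates)  # ascending rate
    fast = set((order[-n_remove:] + 1).tolist())
    drop_mask = np.isin(assignment.category, sorted(fast))
    keep_idx = np.nonzero(~drop_mask)[0]
    if keep_idx.size == 0:
        raise ValueError("stripping would remove every site")
    current_coords = np.arange(1, bundle.aln.n_sites + 1)
    new_parts = bundle.partitions.remap(current_coords[keep_idx])
    removed = [
        (int(bundle.aln.site_ids[i]), "fast_category")
        for i in np.nonzero(drop_mask)[0]
    ]
    return SupermatrixBundle(
        aln=bundle.aln.take_sites(keep_idx),
        partitions=new_parts,
        removed_taxa=list(bundle.removed_taxa),
        removed_sites=list(bundle.removed_sites) + removed,
    )
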