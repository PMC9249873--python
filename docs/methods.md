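# Methods

`phylocurate` implements the curation and robustness workflow used in
supermatrix phylogenomics of deep, ancient radiations: screen single-gene
alignments for artifacts, concatenate the survivors, probe the result by
removing fast-evolving sites, and quantify support for the recovered deep
splits with quartet internode certainty and the Approximately Unbiased (AU)
topology test. Every stage is exercised end to end on synthetic data with a
known ground truth; this note records the models, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do not
show.

## Substitution model and likelihood engine

All likelihoods use a reversible amino-acid model: symmetric exchangeabilities
S, equilibrium frequencies π, rate matrix q_ij = s_ij·π_j with the diagonal
set so rows sum to zero, scaled so the expected rate Σ_i π_i(−q_ii) = 1 —
branch lengths are therefore expected substitutions per site. Transition
matrices come from the eigendecomposition of the symmetrized matrix
diag(√π)·Q·diag(1/√π), computed once per model. Two parameterizations are
built in:

* **Poisson** — equal exchangeabilities, uniform frequencies (the 20-state
  Jukes–Cantor analogue). Used as the simulation default because pairwise
  distances have a closed form, which makes oracles exact and bootstrap
  screening fast.
* **LG** — the Le & Gascuel (2008) matrix, with optional empirical (`+F`)
  frequencies counted from the data. Default for site-rate work on real
  matrices.

Rate heterogeneity across sites is discrete gamma: K equal-probability
categories, each represented by its bin mean (renormalized so the category
mean is exactly 1). At α=1, K=4 the closed form gives
(0.13695, 0.47675, 1.00000, 2.38629).

Site likelihoods are computed by Felsenstein pruning with per-node rescaling
(log-scale accumulators) and site-pattern compression. Gap (`-`) and unknown
(`X`) residues are fully ambiguous (partial likelihood 1 in every state).
Impossible sites (probability exactly 0, e.g. conflicting states across a
zero-length branch) carry the sentinel log-likelihood −1e300 and are never
exponentiated unguarded. The pruning kernel is validated against brute-force
enumeration over all internal-state assignments on small trees (agreement to
1e-10) and against re-rooting invariance, which holds for any reversible
model.

## Synthetic data generator

The generator emulates a multi-gene phylotranscriptomic study: a pure-birth
(Yule) species tree rescaled to a chosen root-to-tip height, per-gene
alignments simulated along it with iid per-site gamma rate categories, and
four kinds of injected artifacts with complete ground-truth labels:

* **long_branch** — one ingroup taxon's sequence is re-evolved from its
  parent along an elongated pendant branch. The elongated length is
  `long_branch_factor × max(own pendant, Q3 of ingroup pendants)`. The floor
  matters: Yule pendants can be arbitrarily short, and multiplying a
  near-zero pendant would record an "artifact" that changes nothing. Since
  the Tukey fence is Q3 + 1.5·IQR ≤ 2.5·Q3 for non-negative lengths, any
  factor above 2.5 (default 10) guarantees the labeled branch is a true
  outlier of its cohort.
* **contaminant** — the taxon's sequence is replaced by one evolved from a
  randomly chosen *outgroup terminal*, with pendant length set so the total
  root-to-contaminant path is twice the tree height. Attaching to a terminal
  rather than to the outgroup ancestor reflects what contamination is — the
  sequence of an actual organism, concretely related to one real lineage —
  and gives the contaminant a well-defined nearest neighbor; a sequence
  evolved independently from a deep ancestral node for twice the tree height
  is close to saturation and nearly equidistant from every taxon, which is
  not how contaminant reads behave.
* **paralog** — the taxon keeps its own copy and gains a second copy derived
  from a leaf in the opposite root subtree, evolved further by
  `paralog_extra_divergence` (default 1.0 substitutions/site). Injecting an
  extra copy (rather than replacing the original) is what makes hidden
  duplication observable to a screen that keys on multi-copy taxa.
* **masked** — the taxon is deleted from the gene (occupancy heterogeneity).

A single global seed fans out to per-gene substreams keyed by gene index, so
extending a study never perturbs existing genes. Defaults: 16 taxa, 50 genes,
500 sites/gene, α=1 with K=4 simulation categories, tree height 0.75
substitutions/site root-to-tip — a modest but realistic deep-phylogenomics
regime where fast sites are saturated but most signal survives.

The generator's taxonomy derives from the species tree: the smaller side of
the root is the outgroup; ingroup clade labels follow the subtrees of the
ingroup ancestor. Ingroup lineages whose *true* pendant branch is a
Tukey-fence outlier are whitelisted by name, emulating the standard practice
of exempting a priori known long-branch lineages from gene-level long-branch
counting (without the exemption, any study whose true tree contains three or
more naturally long pendants would discard every gene).

What the generator does **not** emulate: indels (gaps arise only from
masking), codon structure, heterotachy, profile (site-frequency) mixtures,
alignment error, and within-gene recombination. Benchmarks passing on this
data show the pipeline's rules behave as specified under their own model
assumptions; they do not certify performance on real transcriptome data.

## Gene screening

Gene trees are built by neighbor joining on maximum-likelihood pairwise
distances (negative NJ estimates clamped to zero; saturated pairs capped at
distance 10). Under the Poisson family the ML distance depends on the data
only through the proportion of differing sites and is solved directly
(closed form at K=1, monotone bisection under a gamma mixture); for general
models each pair is optimized by bounded Brent search on the 20×20 count
matrix. Bootstrap supports are bipartition frequencies over site-resampled
NJ replicates. Screening rules:

* **Long branches** — ingroup terminal branches above the Tukey fence
  (Q3 + 1.5·IQR, linear-interpolation quantiles) of the ingroup cohort.
* **Anomalous grouping** (applied at supports above 90): a taxon alone with
  part of the outgroup on one side of a high-support edge is flagged. A side
  holding the taxon plus the *entire* outgroup is also what a genuinely
  basal ingroup lineage produces — rooted on the outgroup's common edge the
  two readings coincide — so that configuration counts only when no basal
  reading exists: the taxon interrupts outgroup monophyly, or its expected
  clade-mates sit elsewhere in the tree. A taxon is also flagged when a
  high-support side places it strictly inside a foreign expected clade
  (members of one other clade around it, further members of that clade
  outside).
* **Paralogy** — any taxon with ≥2 sequence copies is flagged; copies that
  form a single cherry/clade are treated as alleles or isoforms and do not
  drop the gene by default (strict mode available); scattered copies are
  paralogy signs.
* **Decision** — drop a gene iff it has ≥3 long-branch taxa outside
  whitelisted clades/taxa, or any anomalous grouping, or a paralogy sign.

## Supermatrix assembly

Genes are concatenated with gap-padding for absent taxa and 1-based inclusive
partition coordinates. Filters run in a fixed order — gappy taxa first
(strictly more than 80% gap/unknown), then constant sites and sites with
more than 50% missing data — because removing taxa changes which columns are
constant or gappy. `X` counts as missing alongside `-` (switchable); a column
is constant if its non-missing residues are identical (strict variant
available). All removals are logged against original coordinates, so any
filtered matrix can be audited and the site-removal assay replayed.

## Site-rate categorization and fast-site stripping

Each supermatrix column gets per-category log-likelihoods under the K-category
model on a fixed guide tree (no branch or α re-optimization during
categorization: the guide tree is taken as given, matching how PMSF-style
rate assignment is run in practice). Posteriors use the uniform 1/K prior;
the category is the empirical-Bayes argmax (ties to the slower category);
the posterior-mean rate is also recorded. An alternative mode bins sites by
posterior-mean rate into K equal-count categories
(`equal_count_rate_bins`). Stripping removes all sites
assigned to the n fastest categories and remaps partitions. On synthetic
data with known categories (5,000 sites, K=4, α=1, 16 taxa) the argmax
recovers categories at ~2.7× chance and the posterior-mean rate tracks the
true rate at Spearman ρ ≈ 0.87; the mean retained rate decreases strictly
as categories are stripped.

## Internode certainty

For each internal edge of a reference tree, quartets take one leaf from each
of the four incident subtrees; every evaluation tree containing all four
leaves votes for one of the three resolved topologies (polytomies abstain;
trees missing a leaf simply do not vote — the missing-taxon correction).
Counts are pooled across evaluation trees (the equally-weighted flavor) and
scored as IC = 1 + Σ p_i·log₃ p_i, sign-flipped when the reference topology
is not the strict plurality. Enumeration is exhaustive up to 10,000 quartets
per edge; beyond that, quartets are sampled uniformly with a fixed seed.
Quartet resolution inside an evaluation tree uses the four-point condition
on topological (edge-count) leaf distances, computed once per tree.

## AU topology test

Candidates are compared through per-site log-likelihood vectors (read from a
`.sitelh`-style file or computed internally; branch lengths optionally
optimized coordinate-wise by bounded Brent sweeps until the total gain drops
below 1e-3). The multiscale RELL bootstrap resamples round(n·r) sites at
scales r = 0.5…1.4 (ten values), B replicates each; a candidate's BP(r) is
its share of replicate maxima with exact ties splitting credit equally.
Internally the resampling draws multinomial counts over unique per-site
*difference* columns — distributionally identical to naive site resampling,
exactly invariant to per-site constants shared by all candidates, and much
faster. z(r) = Φ⁻¹(1−BP) is fitted as d·√r + c/√r by one-step weighted least
squares (binomial delta-method weights; BP clamped to [1/2B, 1−1/2B];
degenerate all-clamped fits flagged and forced to the corresponding bound),
and p_AU = 1 − Φ(d−c). The plain r=1 proportion (p-RELL) is reported
alongside. A candidate is rejected when p_AU < 0.05.

Calibration. At the least-favorable null — data simulated from the unresolved
quartet (internal branch zero), candidates the three resolutions with fixed,
equal branch lengths — the rejection rate of a designated true resolution at
the 0.05 threshold is near-nominal (≈0.05–0.09 over 200 replicates at
B=1,000). Two deliberate choices here: (i) the one-step WLS fit is not
iterated (stable at the B used, and a documented simplification of the fully
iterative original); (ii) candidate branch lengths are *not* re-optimized
per dataset in the calibration experiment, because the non-negativity
truncation at the boundary collapses competing resolutions onto the star
tree and drives the rejection rate toward zero — the known conservatism of
testing at a polytomy. With re-optimization enabled the measured rate is
≤0.01, i.e. the test errs on the safe side; the fixed-length experiment is
what calibrates the multiscale machinery itself. Data simulated under a
clearly resolved topology leave the true tree un-rejected in ≥95% of runs
(with re-optimization this only gets safer).

## Numerical details and degenerate inputs

* Quantiles everywhere use numpy's linear interpolation.
* The −∞ likelihood sentinel is −1e300; mixture and posterior computations
  shift by the per-site maximum before exponentiating and clip exponents at
  −745.
* Sites whose every category hits the sentinel fall back to the prior
  (category 1) with a warning; all-gap columns have likelihood 1.
* Empty intersections (taxon pairs with no shared non-missing site) are
  errors, not silently imputed.
* Filters refuse to empty a matrix (removing every taxon or site raises).
* NJ negative branch estimates are clamped to zero after the fact; the tree
  topology is unchanged.
* Bootstrap replicate alignments get fresh site ids (provenance ids do not
  survive resampling-with-replacement, by design).

## Benchmark problem sizes

The validation battery (also run by `scripts/acceptance.py`) uses: gene sets
of 60–100 genes (500–1,000 sites) per screening experiment with 100
bootstrap replicates per gene; 5,000 sites for site-rate recovery; 8-leaf
internode-certainty fixtures with m = 10,000 sampled quartets; 4-taxon AU
experiments at 5,000–10,000 sites, B = 1,000, with 100 power and 200
calibration replicates; and B = 10,000 for the (d, c)-recovery check. The
full battery completes in a few minutes on one core.

## Known limitations

* The profile-mixture (C60/PMSF) aspect of site-rate estimation is
  deliberately out of scope; categorization uses a single-profile model.
* Gene trees come from NJ on ML distances, not full ML tree search; supplied
  Newick gene trees bypass this entirely.
* The anomaly rules formalize stated screening criteria; manual curation of
  real datasets catches failure modes (misalignment, chimeras) these rules
  do not model.
* The AU implementation uses the standard ten-scale grid and one-step WLS;
  scale grids are configurable but the fit is not iteratively reweighted.
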