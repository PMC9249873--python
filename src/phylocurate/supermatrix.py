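"""Supermatrix assembly and occupancy filtering.

Kept genes are concatenated into one partitioned matrix; taxa absent
from a gene are padded with gaps.  Filtering follows a fixed order —
gappy taxa first, then constant and high-missing sites — because the
taxon filter changes which columns are constant or gappy.  All removals
are logged against original coordinates so a filtering run can be
audited and replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import GAP, UNKNOWN, Alignment
from .io import PartitionTable


@dataclass
class SupermatrixBundle:
    """Concatenated alignment + partition table + removal provenance."""

    aln: Alignment
    partitions: PartitionTable
    removed_taxa: list[tuple[str, float]] = field(default_factory=list)
    removed_sites: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.partitions.entries and self.partitions.total_width != self.aln.n_sites:
            raise ValueError(
                f"partitions tile {self.partitions.total_width} sites but "
                f"alignment has {self.aln.n_sites}"
            )

    @property
    def width(self) -> int:
        return self.aln.n_sites

    @property
    def n_taxa(self) -> int:
        return self.aln.n_taxa


def concatenate(genes: list[tuple[str, Alignment]]) -> SupermatrixBundle:
    """Concatenate per-gene alignments into a supermatrix.

    The row set is the union of all taxa (first-seen order); a taxon
    missing from a gene contributes a block of gaps.  Partition
    coordinates are 1-based inclusive in gene input order.
    """
    ids = [g for g, _ in genes]
    if len(set(ids)) != len(ids):
        dups = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id(s): {', '.join(dups)}")
    taxa: list[str] = []
    for _, aln in genes:
        for t in aln.taxon_labels:
            if t not in taxa:
                taxa.append(t)
    blocks = []
    entries = []
    pos = 0
    for gene_id, aln in genes:
        block = np.full((len(taxa), aln.n_sites), GAP, dtype="<U1")
        for i, t in enumerate(aln.taxon_labels):
            block[taxa.index(t)] = aln.matrix[i]
        blocks.append(block)
        entries.append((gene_id, pos + 1, pos + aln.n_sites))
        pos += aln.n_sites
    matrix = (
        np.concatenate(blocks, axis=1) if blocks else np.empty((0, 0), dtype="<U1")
    )
    return SupermatrixBundle(
        aln=Alignment(taxa, matrix), partitions=PartitionTable(entries)
    )


def filter_gappy_taxa(
    bundle: SupermatrixBundle,
    max_gap_fraction: float = 0.80,
    count_unknown: bool = True,
) -> SupermatrixBundle:
    """Drop taxa whose gap/unknown fraction is strictly above the
    threshold (default: over 80% gappy sites).

    ``count_unknown`` controls whether ``X`` counts toward gappiness
    alongside ``-`` (it does by default; the two are not distinguished).
    """
    if not 0 < max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in (0, 1]")
    miss = bundle.aln.missing_mask(count_unknown=count_unknown)
    frac = miss.mean(axis=1) if bundle.aln.n_sites else np.zeros(bundle.aln.n_taxa)
    drop = frac > max_gap_fraction
    if drop.all():
        raise ValueError("gappy-taxon filter would remove every taxon")
    removed = [
        (bundle.aln.taxon_labels[i], float(frac[i])) for i in np.nonzero(drop)[0]
    ]
    keep = [t for i, t in enumerate(bundle.aln.taxon_labels) if not drop[i]]
    return SupermatrixBundle(
        aln=bundle.aln.take_taxa(keep),
        partitions=PartitionTable(list(bundle.partitions.entries)),
        removed_taxa=list(bundle.removed_taxa) + removed,
        removed_sites=list(bundle.removed_sites),
    )


def filter_sites(
    bundle: SupermatrixBundle,
    remove_constant: bool = True,
    max_missing_fraction: float = 0.50,
    strict_constant: bool = False,
    count_unknown: bool = True,
) -> SupermatrixBundle:
    """Remove constant sites and sites with too much missing data.

    A site is constant iff all its non-missing residues are identical
    (single-residue columns included); with ``strict_constant`` a column
    containing any missing cell is never called constant.  Missing
    fraction counts ``-`` and (by default) ``X``.  When both rules fire
    the site is logged as ``missing``.  Partitions are remapped and
    empty partitions dropped.
    """
    aln = bundle.aln
    miss = aln.missing_mask(count_unknown=count_unknown)
    n_taxa = aln.n_taxa
    miss_frac = miss.mean(axis=0)
    too_missing = (
        miss_frac > max_missing_fraction
        if max_missing_fraction is not None
        else np.zeros(aln.n_sites, dtype=bool)
    )

    constant = np.zeros(aln.n_sites, dtype=bool)
    if remove_constant:
        for j in range(aln.n_sites):
            residues = aln.matrix[~miss[:, j], j]
            if residues.size == 0:
                continue
            if np.all(residues == residues[0]):
                if strict_constant and miss[:, j].any():
                    continue
                constant[j] = True

    drop = too_missing | constant
    if drop.all() and aln.n_sites > 0:
        raise ValueError("site filter would remove every site")
    keep_idx = np.nonzero(~drop)[0]
    removed = []
    for j in np.nonzero(drop)[0]:
        reason = "missing" if too_missing[j] else "constant"
        removed.append((int(aln.site_ids[j]), reason))
    current_coords = np.arange(1, aln.n_sites + 1)
    new_parts = bundle.partitions.remap(current_coords[keep_idx])
    return SupermatrixBundle(
        aln=aln.take_sites(keep_idx),
        partitions=new_parts,
        removed_taxa=list(bundle.removed_taxa),
        removed_sites=list(bundle.removed_sites) + removed,
    )
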