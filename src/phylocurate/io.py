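"""Readers and writers for every external format the pipeline touches.

Formats: relaxed FASTA (wrapped or unwrapped), Newick with optional
support-as-internal-label, relaxed PHYLIP for supermatrices, RAxML-style
partition text, IQ-TREE ``.sitelh``-style per-site log-likelihood tables,
and a taxon<TAB>clade<TAB>ingroup|outgroup taxonomy TSV.

Coordinates are 1-based inclusive everywhere user-visible (RAxML
partition convention).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np
from Bio import SeqIO

from .alignment import ALPHABET, Alignment, from_sequences
from .trees import Node, PhyloTree

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Lowercase is normalized to uppercase; ``?`` maps to ``X`` and ``.``
    to ``-``.  Ragged rows, duplicate labels and characters outside the
    20-amino-acid + gap/unknown alphabet are errors.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("?", "X").replace(".", "-")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return from_sequences(records)


def write_fasta(aln: Alignment, path: PathLike, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(fasta_text(aln, wrap=wrap))


def fasta_text(aln: Alignment, wrap: int = 60) -> str:
    buf = _io.StringIO()
    for label in aln.taxon_labels:
        buf.write(f">{label}\n")
        seq = aln.sequence(label)
        if wrap:
            for i in range(0, len(seq), wrap):
                buf.write(seq[i : i + wrap] + "\n")
        else:
            buf.write(seq + "\n")
    return buf.getvalue()


def write_phylip(aln: Alignment, path: PathLike) -> None:
    """Relaxed (long-name) sequential PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f"{aln.n_taxa} {aln.n_sites}\n")
        for label in aln.taxon_labels:
            fh.write(f"{label}  {aln.sequence(label)}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[0-9]*\.?[0-9]+([eE][-+]?[0-9]+)?$")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Numeric internal-node labels are interpreted as edge supports;
    absent branch lengths default to 0.  Degree-2 internal nodes are
    suppressed.  Supports on the root edge are ignored (unrooted
    semantics).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc

    def _convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name)
        else:
            node = Node()
            label = dnode.label
            if label is not None and _NUMERIC_RE.match(str(label)):
                node.support = float(label)
            elif label:
                node.name = str(label)
            for ch in dnode.child_nodes():
                node.add_child(_convert(ch))
        node.length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return node

    root = _convert(dtree.seed_node)
    root.length = 0.0
    root.support = None
    tree = PhyloTree(root)
    tree.suppress_unifurcations()
    return tree


def read_newick(path: PathLike) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def read_newick_list(path: PathLike) -> list[PhyloTree]:
    """One tree per non-empty line (bootstrap/evaluation tree sets)."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return trees


def write_newick(tree: PhyloTree, path: PathLike, **kw) -> None:
    Path(path).write_text(tree.to_newick(**kw) + "\n")


# ---------------------------------------------------------------------------
# Partition tables
# ---------------------------------------------------------------------------

@dataclass
class PartitionTable:
    """Contiguous, ordered gene -> column ranges (1-based inclusive)."""

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        seen = set()
        for gene_id, start, end in self.entries:
            if end < start:
                raise ValueError(f"partition {gene_id}: end {end} < start {start}")
            if start != prev_end + 1:
                raise ValueError(
                    f"partition {gene_id}: starts at {start}, expected {prev_end + 1}"
                )
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id}")
            seen.add(gene_id)
            prev_end = end

    @property
    def total_width(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def gene_of_site(self, site: int) -> str:
        for gene_id, start, end in self.entries:
            if start <= site <= end:
                return gene_id
        raise KeyError(site)

    def remap(self, kept_original_sites: np.ndarray) -> "PartitionTable":
        """Rebuild the table after column filtering.

        *kept_original_sites* are the retained 1-based coordinates into
        the matrix this table currently describes.  Empty partitions are
        dropped.
        """
        kept = np.asarray(kept_original_sites)
        entries = []
        pos = 0
        for gene_id, start, end in self.entries:
            n_kept = int(np.count_nonzero((kept >= start) & (kept <= end)))
            if n_kept:
                entries.append((gene_id, pos + 1, pos + n_kept))
                pos += n_kept
        return PartitionTable(entries)


def write_partitions(table: PartitionTable, model_tag: str = "LG") -> str:
    """RAxML-style partition text: ``<model_tag>, <gene_id> = <start>-<end>``."""
    return "".join(
        f"{model_tag}, {gene_id} = {start}-{end}\n"
        for gene_id, start, end in table.entries
    )


def read_partitions(text: str) -> PartitionTable:
    entries = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        m = re.match(r"^\s*\S+\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$", line)
        if not m:
            raise ValueError(f"malformed partition line {lineno}: {line!r}")
        entries.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return PartitionTable(entries)


# ---------------------------------------------------------------------------
# Per-site log-likelihood tables (IQ-TREE .sitelh dialect)
# ---------------------------------------------------------------------------

@dataclass
class SiteLnLTable:
    """Per-topology vectors of per-site log-likelihoods (nats)."""

    topology_ids: list[str]
    lnl: np.ndarray  # shape (n_topologies, n_sites)

    def __post_init__(self) -> None:
        self.lnl = np.asarray(self.lnl, dtype=float)
        if self.lnl.ndim != 2 or self.lnl.shape[0] != len(self.topology_ids):
            raise ValueError("lnl must be (n_topologies, n_sites)")
        if not np.all(np.isfinite(self.lnl)):
            raise ValueError("site log-likelihoods must be finite")

    @property
    def n_sites(self) -> int:
        return self.lnl.shape[1]

    @property
    def n_topologies(self) -> int:
        return self.lnl.shape[0]


def read_sitelh(path: PathLike) -> SiteLnLTable:
    """Read a ``.sitelh``-style table.

    Dialect: header line ``ntrees nsites``, then one line per tree:
    ``<name> <lnL_1> ... <lnL_n>``.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty sitelh file {path}")
    header = lines[0].split()
    if len(header) != 2:
        raise ValueError(f"bad sitelh header: {lines[0]!r}")
    n_trees, n_sites = int(header[0]), int(header[1])
    body = lines[1:]
    if len(body) != n_trees:
        raise ValueError(f"expected {n_trees} tree rows, found {len(body)}")
    names, rows = [], []
    for ln in body:
        parts = ln.split()
        name, vals = parts[0], parts[1:]
        if len(vals) != n_sites:
            raise ValueError(
                f"tree {name}: expected {n_sites} site values, found {len(vals)}"
            )
        names.append(name)
        rows.append([float(v) for v in vals])
    return SiteLnLTable(names, np.array(rows))


def write_sitelh(table: SiteLnLTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"{table.n_topologies} {table.n_sites}\n")
        for name, row in zip(table.topology_ids, table.lnl):
            fh.write(name + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy table
# ---------------------------------------------------------------------------

@dataclass
class TaxonomyMap:
    """taxon -> (clade label, ingroup flag), plus long-branch whitelist.

    Whitelist entries may name a clade or an individual taxon; either
    way the matching taxa are exempt from the long-branch count that can
    drop a gene (kept regardless, as is done for a priori known wholly
    long-branch lineages).
    """

    clade: dict[str, str]
    ingroup: dict[str, bool]
    whitelist: frozenset = frozenset()

    def __post_init__(self) -> None:
        known = set(self.clade.values()) | set(self.clade)
        missing = [c for c in self.whitelist if c not in known]
        if missing:
            raise ValueError(
                f"whitelist entries not in taxonomy (clade or taxon): {missing}"
            )

    def ingroup_taxa(self) -> set:
        return {t for t, flag in self.ingroup.items() if flag}

    def outgroup_taxa(self) -> set:
        return {t for t, flag in self.ingroup.items() if not flag}

    def is_whitelisted(self, taxon: str) -> bool:
        return taxon in self.whitelist or self.clade.get(taxon) in self.whitelist


def read_taxonomy(path: PathLike, whitelist: Optional[set] = None) -> TaxonomyMap:
    """TSV with columns taxon, clade, ingroup|outgroup."""
    clade: dict[str, str] = {}
    ingroup: dict[str, bool] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"taxonomy line {lineno}: expected 3 columns")
        taxon, cl, flag = parts
        if flag not in ("ingroup", "outgroup"):
            raise ValueError(
                f"taxonomy line {lineno}: flag must be ingroup|outgroup, got {flag!r}"
            )
        if taxon in clade:
            raise ValueError(f"duplicate taxon {taxon!r} in taxonomy")
        clade[taxon] = cl
        ingroup[taxon] = flag == "ingroup"
    return TaxonomyMap(clade, ingroup, frozenset(whitelist or ()))


def write_taxonomy(tax: TaxonomyMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for taxon in tax.clade:
            flag = "ingroup" if tax.ingroup[taxon] else "outgroup"
            fh.write(f"{taxon}\t{tax.clade[taxon]}\t{flag}\n")
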