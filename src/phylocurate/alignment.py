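"""Amino-acid alignment container shared by every pipeline stage.

The matrix is a rectangular taxa x sites array over the 20 standard amino
acids plus ``-`` (gap) and ``X`` (unknown).  ``site_ids`` carries the
original 1-based column indices so that provenance survives column
filtering (occupancy filters, fast-site stripping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN

#: residue -> state index in PAML order; gap/unknown are not states
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_MISSING = frozenset((GAP, UNKNOWN))


@dataclass
class Alignment:
    """Rectangular taxa x sites amino-acid matrix.

    Parameters
    ----------
    taxon_labels : list of str
        Unique row labels, in matrix order.
    matrix : numpy.ndarray
        2-D array of dtype ``<U1`` (one character per cell).
    site_ids : numpy.ndarray
        Original 1-based column indices, strictly increasing, one per
        current column.
    """

    taxon_labels: list[str]
    matrix: np.ndarray
    site_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.taxon_labels) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.taxon_labels)} labels for {self.matrix.shape[0]} rows"
            )
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dups = sorted(
                {t for t in self.taxon_labels if self.taxon_labels.count(t) > 1}
            )
            raise ValueError(f"duplicate taxon label(s): {', '.join(dups)}")
        if self.site_ids is None:
            self.site_ids = np.arange(1, self.matrix.shape[1] + 1)
        self.site_ids = np.asarray(self.site_ids, dtype=np.int64)
        if self.site_ids.shape != (self.matrix.shape[1],):
            raise ValueError("site_ids length must equal alignment width")
        if self.site_ids.size and np.any(np.diff(self.site_ids) <= 0):
            raise ValueError("site_ids must be strictly increasing")

    # -- basic geometry -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxon_labels.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return "".join(self.row(taxon))

    # -- missingness ----------------------------------------------------
    def missing_mask(self, count_unknown: bool = True) -> np.ndarray:
        """Boolean mask of cells counted as missing.

        ``-`` always counts; ``X`` counts unless *count_unknown* is False
        (the two are not distinguished by the occupancy filters by
        default).
        """
        mask = self.matrix == GAP
        if count_unknown:
            mask |= self.matrix == UNKNOWN
        return mask

    def state_matrix(self) -> np.ndarray:
        """Integer state codes; missing cells get -1."""
        out = np.full(self.matrix.shape, -1, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            out[self.matrix == aa] = i
        return out

    # -- subsetting ------------------------------------------------------
    def take_taxa(self, labels: list[str]) -> "Alignment":
        idx = [self.taxon_labels.index(t) for t in labels]
        return Alignment(list(labels), self.matrix[idx], self.site_ids.copy())

    def drop_taxa(self, labels: set[str]) -> "Alignment":
        keep = [t for t in self.taxon_labels if t not in labels]
        return self.take_taxa(keep)

    def take_sites(self, col_idx: np.ndarray) -> "Alignment":
        col_idx = np.asarray(col_idx, dtype=np.int64)
        return Alignment(
            list(self.taxon_labels), self.matrix[:, col_idx], self.site_ids[col_idx]
        )

    def copy(self) -> "Alignment":
        return Alignment(
            list(self.taxon_labels), self.matrix.copy(), self.site_ids.copy()
        )


def from_sequences(records: list[tuple[str, str]]) -> Alignment:
    """Build an Alignment from (label, sequence) pairs, validating the
    alphabet and rectangularity."""
    if not records:
        raise ValueError("no sequences")
    labels = [r[0] for r in records]
    width = len(records[0][1])
    rows = []
    for label, seq in records:
        if len(seq) != width:
            raise ValueError(
                f"unequal length: taxon '{label}' has {len(seq)} residues, "
                f"expected {width}"
            )
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"illegal character '{ch}' in taxon '{label}' at column {pos}"
                )
        rows.append(list(seq))
    return Alignment(labels, np.array(rows, dtype="<U1"))
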