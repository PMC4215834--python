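"""Labeled multiple alignments: I/O, gap-column filtering and reference coordinates.

The analyses in this package compare two clades of sequences inside one
gapped multiple alignment.  Every sequence carries a group label, ``IN``
(the focal clade) or ``OUT`` (everything else).  This module reads such a
labeled alignment from an aligned FASTA plus a two-column label table,
removes alignment columns dominated by gaps, and maintains the map between
alignment columns and the residue numbering of a designated reference
sequence (e.g. *E. coli* for the 23S rRNA) so that per-site scores can be
reported in reference coordinates.

Conventions
-----------
* Columns and reference residues are numbered 1-based.
* Sequences are stored uppercase with T normalized to U (rRNA genes are
  usually deposited as DNA).
* Any character outside ``{A, C, G, U}`` — gaps, ambiguity codes, anything
  else — is treated as missing data ("gap") throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

NUCLEOTIDES = ("A", "C", "G", "U")
IN = "IN"
OUT = "OUT"
VALID_LABELS = frozenset({IN, OUT})


@dataclass
class LabeledAlignment:
    """A gapped alignment whose sequences are partitioned into two groups.

    Parameters
    ----------
    ids
        Sequence identifiers, in alignment order.
    seqs
        Aligned sequences, all of equal length, uppercase RNA with ``-``
        (or any non-ACGU character) marking missing data.
    group_of
        Map from identifier to ``"IN"`` or ``"OUT"``.
    """

    ids: list[str]
    seqs: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            for i, s in zip(self.ids, self.seqs):
                if len(s) != len(self.seqs[0]):
                    raise ValueError(
                        f"ragged alignment: sequence {i!r} has length {len(s)}, "
                        f"expected {len(self.seqs[0])}"
                    )
        for i in self.ids:
            if i not in self.group_of:
                raise ValueError(f"sequence {i!r} has no group label")
            if self.group_of[i] not in VALID_LABELS:
                raise ValueError(
                    f"unknown group label {self.group_of[i]!r} for {i!r}; "
                    f"expected IN or OUT"
                )

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def group_ids(self, group: str) -> list[str]:
        return [i for i in self.ids if self.group_of[i] == group]

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, n_columns)."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean row mask selecting the sequences of one group."""
        return np.array([self.group_of[i] == group for i in self.ids])

    def subset_columns(self, columns_1based: list[int]) -> "LabeledAlignment":
        idx = [c - 1 for c in columns_1based]
        seqs = ["".join(s[j] for j in idx) for s in self.seqs]
        return LabeledAlignment(list(self.ids), seqs, dict(self.group_of))


@dataclass
class ColumnFilterResult:
    """Outcome of removing gap-heavy columns.

    ``kept_columns`` are 1-based indices into the *original* alignment, so
    downstream scores can always be reported in original coordinates.
    """

    kept_columns: list[int]
    filtered: LabeledAlignment
    gap_fraction: np.ndarray  # per original column


@dataclass
class CoordinateMap:
    """Alignment-column <-> reference-residue map for one reference sequence.

    Residue numbers count only the non-gap characters of the reference, from
    1.  Columns where the reference itself is gapped map to ``None``.
    """

    reference_id: str
    col_to_ref: dict[int, int | None]
    ref_to_col: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_to_col:
            self.ref_to_col = {
                r: c for c, r in self.col_to_ref.items() if r is not None
            }

    @property
    def n_residues(self) -> int:
        return len(self.ref_to_col)


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def is_gap_char(ch: str) -> bool:
    return ch not in NUCLEOTIDES


def read_labels(labels_file: str) -> dict[str, str]:
    """Read a two-column TSV of ``id<TAB>IN|OUT``."""
    group_of: dict[str, str] = {}
    with open(labels_file) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{labels_file}:{lineno}: expected 'id<TAB>label', got {line!r}"
                )
            seq_id, label = parts[0].strip(), parts[1].strip().upper()
            if label not in VALID_LABELS:
                raise ValueError(
                    f"{labels_file}:{lineno}: unknown label {label!r} "
                    f"(expected IN or OUT)"
                )
            group_of[seq_id] = label
    return group_of


def read_labeled_alignment(alignment_file: str, labels_file: str) -> LabeledAlignment:
    """Read an aligned FASTA together with its group-label table.

    Every FASTA identifier must appear in the label table; extra labels are
    ignored.  Sequences are normalized (uppercase, T→U).
    """
    group_of = read_labels(labels_file)
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(alignment_file, "fasta"):
        ids.append(record.id)
        seqs.append(normalize_sequence(str(record.seq)))
    if not ids:
        raise ValueError(f"no sequences found in {alignment_file}")
    missing = [i for i in ids if i not in group_of]
    if missing:
        raise ValueError(f"unlabeled sequence id(s): {', '.join(missing)}")
    return LabeledAlignment(ids, seqs, {i: group_of[i] for i in ids})


def write_labeled_alignment(
    aln: LabeledAlignment, alignment_file: str, labels_file: str
) -> None:
    with open(alignment_file, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")
    with open(labels_file, "w") as fh:
        for i in aln.ids:
            fh.write(f"{i}\t{aln.group_of[i]}\n")


def column_gap_fractions(aln: LabeledAlignment) -> np.ndarray:
    """Fraction of sequences, both groups pooled, that are gapped per column."""
    mat = aln.to_matrix()
    is_nt = np.isin(mat, NUCLEOTIDES)
    return 1.0 - is_nt.mean(axis=0)


def filter_gap_columns(
    aln: LabeledAlignment, max_gap: float = 0.5
) -> ColumnFilterResult:
    """Remove alignment columns whose pooled gap fraction exceeds ``max_gap``.

    The inequality is strict: a column with gap fraction exactly ``max_gap``
    is retained.  With the default 0.5 this removes exactly the columns
    gapped in more than half of the sequences.
    """
    if not 0.0 <= max_gap <= 1.0:
        raise ValueError(f"max_gap must be in [0, 1], got {max_gap}")
    gap_frac = column_gap_fractions(aln)
    kept = [c + 1 for c in range(aln.n_columns) if gap_frac[c] <= max_gap]
    if not kept:
        raise ValueError("no columns survive filtering")
    return ColumnFilterResult(
        kept_columns=kept,
        filtered=aln.subset_columns(kept),
        gap_fraction=gap_frac,
    )


def build_coordinate_map(aln: LabeledAlignment, reference_id: str) -> CoordinateMap:
    """Map alignment columns to the residue numbering of one reference row."""
    if reference_id not in aln.group_of:
        raise ValueError(f"reference id {reference_id!r} not in alignment")
    ref_seq = aln.seqs[aln.ids.index(reference_id)]
    col_to_ref: dict[int, int | None] = {}
    residue = 0
    for col, ch in enumerate(ref_seq, start=1):
        if is_gap_char(ch):
            col_to_ref[col] = None
        else:
            residue += 1
            col_to_ref[col] = residue
    return CoordinateMap(reference_id=reference_id, col_to_ref=col_to_ref)
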