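"""Sequence-logo matrices and degenerate −10 element scanning.

Aligned upstream DNA regions are summarized as a per-position frequency /
information matrix (the content of a sequence LOGO, in bits), and
individual sequences are scanned for matches to an IUPAC-degenerate
consensus such as the σ70-style −10 hexamer, allowing a bounded number of
mismatches.  Hit positions can be expressed relative to an anchor such as
a start codon (negative = upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

DNA_BASES = ("A", "C", "G", "T")

# base -> set of concrete bases it stands for, e.g. N -> {A,C,G,T}
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}


@dataclass
class PositionMatrix:
    """Per-position base frequencies and information content in bits.

    ``freq`` is a DataFrame (positions x A,C,G,T) of frequencies over the
    non-gap characters at each position; ``info`` is ``2 − H`` bits per
    position.  By default no small-sample correction is applied; pass
    ``small_sample_correction=True`` to
    :func:`build_position_matrix` for the WebLOGO-style
    ``(4−1)/(2·ln2·n)`` subtraction.
    """

    freq: pd.DataFrame
    info: np.ndarray

    @property
    def length(self) -> int:
        return len(self.freq)


@dataclass
class ConsensusHit:
    """One match of the consensus pattern within a sequence."""

    sequence_id: str
    offset: int  # 1-based start of the match
    mismatches: int
    matched_text: str

    @property
    def end(self) -> int:
        """1-based inclusive end position of the match."""
        return self.offset + len(self.matched_text) - 1


def build_position_matrix(
    aligned_regions: list[str], small_sample_correction: bool = False
) -> PositionMatrix:
    """Frequency/information matrix from equal-length aligned DNA strings.

    Frequencies at each position are computed over the non-gap characters
    only (so they sum to one); information is ``2 − H`` where H is the
    Shannon uncertainty of that distribution.
    """
    if len(aligned_regions) < 2:
        raise ValueError("need at least 2 sequences to build a matrix")
    seqs = [s.upper().replace("U", "T") for s in aligned_regions]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"ragged input: lengths {sorted(lengths)}")
    length = lengths.pop()
    mat = np.array([list(s) for s in seqs], dtype="U1")
    counts = np.stack([(mat == b).sum(axis=0) for b in DNA_BASES], axis=1).astype(float)
    denom = counts.sum(axis=1)
    freq = np.divide(
        counts, denom[:, None], out=np.zeros_like(counts), where=denom[:, None] > 0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
    info = 2.0 - h
    if small_sample_correction:
        n = np.maximum(denom, 1.0)
        info = np.maximum(info - 3.0 / (2.0 * np.log(2.0) * n), 0.0)
    return PositionMatrix(
        freq=pd.DataFrame(freq, columns=list(DNA_BASES), index=range(1, length + 1)),
        info=info,
    )


def _pattern_sets(consensus: str) -> list[frozenset[str]]:
    sets = []
    for ch in consensus.upper().replace("U", "T"):
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern")
        sets.append(IUPAC_SETS[ch])
    return sets


def scan_consensus(
    sequence: str,
    consensus: str,
    max_mismatch: int = 0,
    sequence_id: str = "",
) -> list[ConsensusHit]:
    """All offsets where ``sequence`` matches the degenerate consensus.

    A position mismatches when the sequence base is not in the IUPAC class
    of the pattern base; hits have at most ``max_mismatch`` mismatching
    positions.  The scan is forward-strand only: promoters are
    strand-specific relative to the gene they drive.
    """
    if not consensus:
        raise ValueError("empty consensus pattern")
    seq = sequence.upper().replace("U", "T")
    sets = _pattern_sets(consensus)
    k = len(sets)
    if k > len(seq):
        raise ValueError("pattern longer than sequence")
    hits: list[ConsensusHit] = []
    for start in range(len(seq) - k + 1):
        window = seq[start : start + k]
        mm = sum(1 for ch, allowed in zip(window, sets) if ch not in allowed)
        if mm <= max_mismatch:
            hits.append(ConsensusHit(sequence_id, start + 1, mm, window))
    return hits


def annotate_relative_position(hit: ConsensusHit, anchor: int) -> int:
    """Signed position of a hit relative to an anchor coordinate.

    The anchor is a 1-based feature coordinate (e.g. the first base of a
    start codon).  For a hit entirely upstream the offset is measured from
    the pattern end to the anchor and is negative (a hit ending 12 bases
    before the anchor reports −12); for a hit at or downstream of the
    anchor it is measured from the pattern start (a hit starting at the
    anchor reports 0).
    """
    if hit.end < anchor:
        return hit.end - anchor
    return hit.offset - anchor


def hits_to_frame(hits: list[ConsensusHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.sequence_id, h.offset, h.mismatches, h.matched_text) for h in hits],
        columns=["sequence_id", "offset", "mismatches", "matched_text"],
    )
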