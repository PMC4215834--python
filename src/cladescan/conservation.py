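"""Per-site conservation statistics for a two-group alignment.

For each alignment site *s* and each group the four nucleotide frequencies
*f_N* are computed with the full group size as denominator, so gapped cells
reduce the nucleotide frequencies instead of being renormalized away.  From
these the module derives:

* the Shannon uncertainty ``H(s) = -sum_N f_N log2 f_N`` in bits
  (``H_max = 2`` bits for four equiprobable nucleotides);
* the gap-penalized total information
  ``T(s) = (1 - H(s)/H_max) * (1 - gap_fraction)`` on a 0–1 scale;
* the group average ``T_avg`` over retained sites, which absorbs the two
  groups' different overall divergence;
* the relative information ``R(s) = T(s) / T_avg``;
* the between-group difference ``D(s) = R_out(s) - R_in(s)``, positive at
  sites that evolve faster in the in-group.

"Signature" sites — columns where one nucleotide is present in at least 90%
of the in-group but at most 10% of the out-group — are called directly from
the frequency profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import IN, NUCLEOTIDES, OUT, LabeledAlignment

H_MAX = 2.0  # bits; four equiprobable nucleotides

_TOL = 1e-9


@dataclass
class SiteProfile:
    """Per-group nucleotide frequencies and gap fractions at one column.

    Frequencies use the group size as denominator; at a column with gaps
    the four nucleotide frequencies of a group sum to less than one, and
    frequencies plus gap fraction sum to exactly one.
    """

    column: int  # 1-based original column index
    freq_in: dict[str, float]
    freq_out: dict[str, float]
    gap_in: float
    gap_out: float


@dataclass
class SignatureCall:
    """A (column, nucleotide) pair fixed in the in-group and rare outside."""

    column: int
    nucleotide: str
    freq_in: float
    freq_out: float


@dataclass
class SiteScoreTable:
    """Per-site information scores for both groups.

    ``scores`` has one row per retained column with columns
    ``column, H_in, H_out, gap_in, gap_out, T_in, T_out, R_in, R_out, D``.
    """

    scores: pd.DataFrame
    t_avg_in: float
    t_avg_out: float


def shannon_uncertainty(freqs: Sequence[float]) -> float:
    """Shannon uncertainty in bits of four nucleotide frequencies.

    The frequencies may sum to less than one (the remainder being gap
    mass); gap mass contributes nothing to the sum.  ``0*log2(0) = 0``.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < -_TOL):
        raise ValueError(f"negative frequency in {list(freqs)}")
    if f.sum() > 1.0 + _TOL:
        raise ValueError(f"frequencies sum to {f.sum():.6g} > 1")
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def total_information(h: float, gap_fraction: float) -> float:
    """Gap-penalized information content on a 0–1 scale.

    ``T = (1 - H/H_max) * (1 - gap_fraction)``.  The multiplicative gap
    penalty keeps T within [0, 1] for any gap fraction.
    """
    if not -_TOL <= h <= H_MAX + _TOL:
        raise ValueError(f"H must be in [0, {H_MAX}] bits, got {h}")
    if not -_TOL <= gap_fraction <= 1.0 + _TOL:
        raise ValueError(f"gap fraction must be in [0, 1], got {gap_fraction}")
    return (1.0 - h / H_MAX) * (1.0 - gap_fraction)


def average_information(t_values: Iterable[float]) -> float:
    """Arithmetic mean of T over retained sites for one group."""
    t = np.asarray(list(t_values), dtype=float)
    if t.size == 0:
        raise ValueError("cannot average an empty set of sites")
    return float(t.mean())


def relative_information(t: float, t_avg: float) -> float:
    """Site information normalized by the group mean: ``R = T / T_avg``."""
    if t_avg <= 0:
        raise ValueError("group carries no information (T_avg = 0)")
    return t / t_avg


def group_difference(
    r_in: Sequence[float], r_out: Sequence[float]
) -> np.ndarray:
    """Between-group difference ``D = R_out - R_in`` per site.

    D is positive where the site is less conserved (faster evolving) in the
    in-group than the out-group.
    """
    a_in = np.asarray(r_in, dtype=float)
    a_out = np.asarray(r_out, dtype=float)
    if a_in.shape != a_out.shape:
        raise ValueError(
            f"mismatched columns: {a_in.shape} vs {a_out.shape}"
        )
    return a_out - a_in


def _group_frequency_matrix(
    mat: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies (4 x n_columns) and gap fraction per column for one group."""
    sub = mat[mask]
    n = sub.shape[0]
    freqs = np.stack([(sub == nt).sum(axis=0) / n for nt in NUCLEOTIDES])
    gaps = 1.0 - freqs.sum(axis=0)
    return freqs, np.clip(gaps, 0.0, 1.0)


def site_profiles(
    aln: LabeledAlignment, columns: Sequence[int] | None = None
) -> list[SiteProfile]:
    """Per-column, per-group nucleotide frequencies.

    ``columns`` gives the 1-based original indices to report (defaults to
    all columns of ``aln``, numbered 1..n).
    """
    mask_in = aln.group_mask(IN)
    mask_out = aln.group_mask(OUT)
    if not mask_in.any():
        raise ValueError("in-group is empty")
    if not mask_out.any():
        raise ValueError("out-group is empty")
    mat = aln.to_matrix()
    f_in, g_in = _group_frequency_matrix(mat, mask_in)
    f_out, g_out = _group_frequency_matrix(mat, mask_out)
    cols = list(columns) if columns is not None else list(range(1, aln.n_columns + 1))
    if len(cols) != aln.n_columns:
        raise ValueError("column index list does not match alignment width")
    return [
        SiteProfile(
            column=col,
            freq_in={nt: float(f_in[k, j]) for k, nt in enumerate(NUCLEOTIDES)},
            freq_out={nt: float(f_out[k, j]) for k, nt in enumerate(NUCLEOTIDES)},
            gap_in=float(g_in[j]),
            gap_out=float(g_out[j]),
        )
        for j, col in enumerate(cols)
    ]


def call_signature_sites(
    profiles: Iterable[SiteProfile],
    in_min: float = 0.90,
    out_max: float = 0.10,
) -> list[SignatureCall]:
    """Columns with a nucleotide at >=``in_min`` in-group and <=``out_max`` out.

    Both thresholds are inclusive.  A call is emitted for every qualifying
    (column, nucleotide) pair.
    """
    for name, v in (("in_min", in_min), ("out_max", out_max)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    calls = []
    for p in profiles:
        for nt in NUCLEOTIDES:
            if p.freq_in[nt] >= in_min and p.freq_out[nt] <= out_max:
                calls.append(
                    SignatureCall(p.column, nt, p.freq_in[nt], p.freq_out[nt])
                )
    return calls


def score_sites(
    aln: LabeledAlignment, columns: Sequence[int] | None = None
) -> SiteScoreTable:
    """Compute H, T, T_avg, R and D for every column of ``aln``.

    The gap fraction entering each group's T is that group's own gap
    fraction.  ``aln`` is normally the gap-filtered alignment and
    ``columns`` its ``kept_columns``, so scores carry original indices.
    """
    profiles = site_profiles(aln, columns)
    rows = []
    for p in profiles:
        h_in = shannon_uncertainty([p.freq_in[nt] for nt in NUCLEOTIDES])
        h_out = shannon_uncertainty([p.freq_out[nt] for nt in NUCLEOTIDES])
        rows.append(
            (
                p.column,
                h_in,
                h_out,
                p.gap_in,
                p.gap_out,
                total_information(h_in, p.gap_in),
                total_information(h_out, p.gap_out),
            )
        )
    df = pd.DataFrame(
        rows, columns=["column", "H_in", "H_out", "gap_in", "gap_out", "T_in", "T_out"]
    )
    t_avg_in = average_information(df["T_in"])
    t_avg_out = average_information(df["T_out"])
    df["R_in"] = df["T_in"].map(lambda t: relative_information(t, t_avg_in))
    df["R_out"] = df["T_out"].map(lambda t: relative_information(t, t_avg_out))
    df["D"] = group_difference(df["R_in"].to_numpy(), df["R_out"].to_numpy())
    return SiteScoreTable(scores=df, t_avg_in=t_avg_in, t_avg_out=t_avg_out)


def signature_calls_to_frame(calls: list[SignatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.column, c.nucleotide, c.freq_in, c.freq_out) for c in calls],
        columns=["column", "nucleotide", "freq_in", "freq_out"],
    )
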