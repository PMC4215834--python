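"""Absolute RT-qPCR quantification and transcript-pool partitioning.

A dilution series of a calibrated standard gives a straight line of Cq on
log10(copies); inverting the line converts Cq values to absolute copy
numbers.  Nested amplicons — PCR products sharing a reverse primer with
progressively upstream forward primers — partition a transcript pool by
5' extent, and the per-class percentages of the total attribute
transcripts to candidate promoters.

Percentages are reported with half-up rounding (the convention of the
printed tables this arithmetic reproduces).  A printed total, when
supplied, takes precedence over the column sum: published totals are
sometimes computed from unrounded underlying values and may differ from
the sum of the rounded per-class counts by one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats


@dataclass
class StandardCurve:
    """Linear fit of Cq on log10(copies) for a dilution series.

    ``slope`` is in Cq per tenfold dilution (about −3.32 at 100% PCR
    efficiency), ``intercept`` the Cq extrapolated to a single copy.
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = perfect)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class AmpliconTable:
    """Per-product transcript copy counts for one strain.

    ``copies`` maps each product class (ordered by 5' extent) to copies
    per ng of RNA template.  When ``total`` is None the column sum is
    used.
    """

    strain: str
    classes: list[str]
    copies: dict[str, float]
    total: float | None = None

    def __post_init__(self) -> None:
        for cls in self.classes:
            if cls not in self.copies:
                raise ValueError(f"class {cls!r} has no copy count")
            if self.copies[cls] < 0:
                raise ValueError(f"negative copy count for {cls!r}")

    @property
    def effective_total(self) -> float:
        return self.total if self.total is not None else sum(self.copies.values())


def fit_standard_curve(dilutions: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares line of Cq on log10(copies).

    ``dilutions`` is a list of (known copies, measured Cq) pairs; at least
    three distinct copy numbers are required.
    """
    if len(dilutions) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    copies = np.array([c for c, _ in dilutions], dtype=float)
    cq = np.array([q for _, q in dilutions], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    log_copies = np.log10(copies)
    if np.ptp(log_copies) == 0:
        raise ValueError("dilution series has zero variance in copy number")
    fit = stats.linregress(log_copies, cq)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def cq_from_copies(curve: StandardCurve, copies: float) -> float:
    """Predicted Cq for a given absolute copy number."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return curve.slope * np.log10(copies) + curve.intercept


def copies_from_cq(curve: StandardCurve, cq: float, template_ng: float = 1.0) -> float:
    """Absolute copies per ng of template from a measured Cq."""
    if template_ng <= 0:
        raise ValueError("template mass must be positive")
    if curve.slope >= 0:
        raise ValueError("invalid standard curve: slope must be negative")
    return 10.0 ** ((cq - curve.intercept) / curve.slope) / template_ng


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def partition_transcripts(
    table: AmpliconTable, rounding: int = 1
) -> dict[str, float]:
    """Percentage of the total transcript pool per product class.

    Uses the supplied (printed) total when given, else the computed sum;
    half-up rounds to ``rounding`` decimals.
    """
    total = table.effective_total
    if total <= 0:
        raise ValueError("total transcript count must be positive")
    return {
        cls: round_half_up(100.0 * table.copies[cls] / total, rounding)
        for cls in table.classes
    }


def long_transcript_fraction(
    table: AmpliconTable, long_classes: set[str] | list[str]
) -> float:
    """Unrounded percentage of the pool in the given long-product classes."""
    unknown = set(long_classes) - set(table.classes)
    if unknown:
        raise ValueError(f"unknown class label(s): {', '.join(sorted(unknown))}")
    total = table.effective_total
    if total <= 0:
        raise ValueError("total transcript count must be positive")
    return 100.0 * sum(table.copies[c] for c in long_classes) / total


def nested_differences(table: AmpliconTable) -> dict[str, float]:
    """Exact-length transcript counts from nested "at-least-this-long" counts.

    An explicitly separate mode: interprets each class as counting
    transcripts at least as long as its amplicon (classes ordered from
    shortest to longest) and differences successive counts.  The default
    partition makes no such correction and reproduces the printed
    arithmetic directly.
    """
    diffs: dict[str, float] = {}
    for i, cls in enumerate(table.classes):
        nxt = table.copies[table.classes[i + 1]] if i + 1 < len(table.classes) else 0.0
        diffs[cls] = table.copies[cls] - nxt
    return diffs
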