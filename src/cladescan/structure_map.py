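"""Project per-site scores onto reference secondary-structure coordinates.

Scores computed in alignment-column space are carried through a
:class:`~cladescan.alignment_io.CoordinateMap` onto reference residue
numbers, masked where the site is absent in more than half of the
sequences, annotated with helix membership from a helix-range table
(e.g. helices 1–101 of the *E. coli* 23S secondary-structure model), and
summarized per helical stem to rank stems by how much faster they evolve
in the in-group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import CoordinateMap

MASK_ABSENT = "absent_gt50"

HELIX_COLUMNS = ["helix_id", "start", "end", "domain"]


@dataclass
class ResidueAnnotation:
    """Difference score (or mask) attached to one reference residue."""

    ref_residue: int
    d: float | None  # None when masked
    mask_reason: str | None = None

    @property
    def masked(self) -> bool:
        return self.d is None


def read_helix_table(path: str) -> pd.DataFrame:
    """Read a helix-range table: TSV with helix_id, start, end[, domain].

    A helix may span several rows (one per strand interval); intervals are
    1-based inclusive reference-residue ranges.
    """
    df = pd.read_csv(path, sep="\t", dtype={"helix_id": str})
    missing = [c for c in ("helix_id", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"helix table missing column(s): {', '.join(missing)}")
    if "domain" not in df.columns:
        df["domain"] = ""
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "helix_id"].tolist()
        raise ValueError(f"helix interval with start > end: {bad}")
    return df[HELIX_COLUMNS]


def write_helix_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def map_scores_to_reference(
    scores: pd.DataFrame,
    cmap: CoordinateMap,
    gap_fractions: dict[int, float] | pd.Series,
    mask_gap: float = 0.5,
) -> list[ResidueAnnotation]:
    """Attach each column's difference score D to its reference residue.

    ``scores`` needs columns ``column`` (1-based original index) and ``D``.
    ``gap_fractions`` gives the pooled gap fraction per original column.
    Residues whose column is gapped in more than ``mask_gap`` of the
    sequences are emitted as masked (sites absent in most of the taxa);
    such columns are normally removed before scoring, so masking only
    matters when scoring ran on an unfiltered alignment.

    Columns where the reference itself is gapped have no residue number and
    are silently dropped.
    """
    if "column" not in scores.columns or "D" not in scores.columns:
        raise ValueError("scores must have 'column' and 'D' columns")
    gap = dict(gap_fractions) if not isinstance(gap_fractions, dict) else gap_fractions
    annotations: list[ResidueAnnotation] = []
    for col, d in zip(scores["column"].astype(int), scores["D"].astype(float)):
        ref = cmap.col_to_ref.get(col)
        if ref is None:
            continue
        g = gap.get(col, 0.0)
        if g > mask_gap:
            annotations.append(ResidueAnnotation(ref, None, MASK_ABSENT))
        else:
            annotations.append(ResidueAnnotation(ref, d))
    annotations.sort(key=lambda a: a.ref_residue)
    return annotations


def annotations_to_frame(annotations: list[ResidueAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.ref_residue, np.nan if a.masked else a.d, a.mask_reason or "")
            for a in annotations
        ],
        columns=["ref_residue", "D", "mask_reason"],
    )


def summarize_by_helix(
    annotations: list[ResidueAnnotation], helices: pd.DataFrame
) -> pd.DataFrame:
    """Mean and max difference score per helical stem.

    Masked residues are excluded from the statistics but counted in
    ``n_masked``.  Helices are ranked by mean D descending; a helix with no
    unmasked residues reports NA.
    """
    by_res: dict[int, ResidueAnnotation] = {a.ref_residue: a for a in annotations}
    rows = []
    for helix_id, group in helices.groupby("helix_id", sort=False):
        ds: list[float] = []
        n_masked = 0
        n_res = 0
        for _, iv in group.iterrows():
            for r in range(int(iv["start"]), int(iv["end"]) + 1):
                a = by_res.get(r)
                if a is None:
                    continue
                n_res += 1
                if a.masked:
                    n_masked += 1
                else:
                    ds.append(a.d)
        rows.append(
            (
                helix_id,
                n_res,
                n_masked,
                float(np.mean(ds)) if ds else np.nan,
                float(np.max(ds)) if ds else np.nan,
            )
        )
    out = pd.DataFrame(
        rows, columns=["helix_id", "n_residues", "n_masked", "mean_D", "max_D"]
    )
    return out.sort_values("mean_D", ascending=False, na_position="last").reset_index(
        drop=True
    )


def color_layer(
    annotations: list[ResidueAnnotation], cmap_name: str = "RdBu_r"
) -> pd.DataFrame:
    """Residue -> hex color export for external structure-diagram tools.

    Bounds are data-driven and symmetric about zero so that the neutral
    midpoint of the diverging map sits at D = 0; masked residues are black.
    """
    from matplotlib import colormaps
    from matplotlib.colors import Normalize, to_hex

    ds = [a.d for a in annotations if not a.masked]
    bound = max(abs(min(ds)), abs(max(ds))) if ds else 1.0
    norm = Normalize(vmin=-bound, vmax=bound)
    cm = colormaps[cmap_name]
    rows = []
    for a in annotations:
        color = "#000000" if a.masked else to_hex(cm(norm(a.d)))
        rows.append((a.ref_residue, color))
    return pd.DataFrame(rows, columns=["ref_residue", "color"])
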