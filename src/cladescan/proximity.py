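"""RNA–protein proximity from a 3D structure.

Given a PDB-format structure containing an rRNA chain and a ribosomal
protein chain, compute for every nucleotide the distance (Å) from its
phosphate phosphorus (atom ``P``) to the nearest α-carbon (atom ``CA``)
of the protein, flag nucleotides that were not resolved in the crystal
(no P atom), and intersect protein-proximal helices with the helices that
evolve fastest in the in-group.

The parser reads ATOM/HETATM records directly at fixed columns: the
contract here needs line-numbered parse errors and a keep-first altloc
policy, which the usual structure readers do not expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isfinite

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_PROXIMITY_ANGSTROM = 15.0


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, tuple[float, float, float]] = field(default_factory=dict)


@dataclass
class StructureModel:
    """Two chains of interest (RNA and protein) from one structure."""

    chains: dict[str, list[Residue]]

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise ValueError(f"chain {chain_id!r} not present in structure")
        return self.chains[chain_id]


@dataclass
class ProximityRecord:
    """Distance from one nucleotide's P atom to the nearest protein CA.

    ``distance`` is None for nucleotides without a P atom (unresolved in
    the crystal structure).
    """

    rna_residue: int
    distance: float | None
    nearest_protein_residue: int | None = None

    @property
    def unresolved(self) -> bool:
        return self.distance is None


def parse_structure(
    path: str, rna_chain: str, protein_chain: str
) -> StructureModel:
    """Parse ATOM/HETATM records of a PDB file, keeping two chains.

    For alternate-location atoms the first-listed conformer is kept.
    Parsing stops at the first MODEL's ENDMDL so NMR-style multi-model
    files contribute one model only.
    """
    wanted = {rna_chain, protein_chain}
    chains: dict[str, dict[int, Residue]] = {c: {} for c in wanted}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM", "HETATM"):
                continue
            chain_id = line[21:22]
            if chain_id not in wanted:
                continue
            try:
                atom_name = line[12:16].strip()
                res_name = line[17:20].strip()
                res_num = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable ATOM record ({exc})"
                ) from None
            if not all(isfinite(v) for v in (x, y, z)):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            res = chains[chain_id].setdefault(res_num, Residue(res_num, res_name))
            if atom_name not in res.atoms:  # keep first-listed altloc
                res.atoms[atom_name] = (x, y, z)
    for c in (rna_chain, protein_chain):
        if not chains[c]:
            raise ValueError(f"chain {c!r} not present in {path}")
    return StructureModel(
        chains={c: [chains[c][k] for k in sorted(chains[c])] for c in wanted}
    )


def nearest_protein_distances(
    model: StructureModel, rna_chain: str, protein_chain: str
) -> list[ProximityRecord]:
    """P-to-nearest-CA distance for every RNA residue.

    RNA residues lacking a P atom are reported as unresolved.  A k-d tree
    over the CA coordinates makes the query O(n log m); results are
    identical to the all-pairs minimum.
    """
    protein = model.chain(protein_chain)
    ca_coords = []
    ca_residues = []
    for res in protein:
        if "CA" in res.atoms:
            ca_coords.append(res.atoms["CA"])
            ca_residues.append(res.number)
    if not ca_coords:
        raise ValueError(
            f"protein chain {protein_chain!r} has no CA (alpha-carbon) atoms"
        )
    tree = cKDTree(np.asarray(ca_coords))
    records: list[ProximityRecord] = []
    for res in model.chain(rna_chain):
        p = res.atoms.get("P")
        if p is None:
            records.append(ProximityRecord(res.number, None))
            continue
        dist, idx = tree.query(np.asarray(p))
        records.append(
            ProximityRecord(res.number, float(dist), ca_residues[int(idx)])
        )
    return records


def records_to_frame(records: list[ProximityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.rna_residue,
                np.nan if r.unresolved else round(r.distance, 3),
                "" if r.nearest_protein_residue is None else r.nearest_protein_residue,
            )
            for r in records
        ],
        columns=["rna_residue", "distance_A", "nearest_protein_residue"],
    )


def proximal_helices(
    records: list[ProximityRecord],
    helices: pd.DataFrame,
    threshold: float = DEFAULT_PROXIMITY_ANGSTROM,
) -> pd.DataFrame:
    """Per-helix distance summary with a proximity flag.

    A helix is proximal when its minimum resolved P-to-CA distance is at
    most ``threshold`` Å.  Unresolved nucleotides are ignored.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    by_res = {r.rna_residue: r for r in records}
    rows = []
    for helix_id, group in helices.groupby("helix_id", sort=False):
        dists: list[float] = []
        for _, iv in group.iterrows():
            for resnum in range(int(iv["start"]), int(iv["end"]) + 1):
                rec = by_res.get(resnum)
                if rec is not None and not rec.unresolved:
                    dists.append(rec.distance)
        rows.append(
            (
                helix_id,
                len(dists),
                float(np.min(dists)) if dists else np.nan,
                float(np.mean(dists)) if dists else np.nan,
                bool(dists) and min(dists) <= threshold,
            )
        )
    return pd.DataFrame(
        rows, columns=["helix_id", "n_resolved", "min_distance_A", "mean_distance_A", "proximal"]
    )


def cross_reference(
    helix_summary: pd.DataFrame,
    proximal: pd.DataFrame,
    top_k: int = 5,
) -> pd.DataFrame:
    """Helices that are both fast-evolving in-group and protein-proximal.

    ``helix_summary`` comes from
    :func:`cladescan.structure_map.summarize_by_helix` (ranked by mean D);
    ``proximal`` from :func:`proximal_helices`.  The report lists helices
    in the top ``top_k`` by mean D whose proximal flag is set.
    """
    ids_fast = set(helix_summary["helix_id"])
    ids_prox = set(proximal["helix_id"])
    if not ids_fast & ids_prox:
        raise ValueError("helix id sets of the two summaries are disjoint")
    top = helix_summary.dropna(subset=["mean_D"]).head(top_k)
    merged = top.merge(proximal, on="helix_id", how="left")
    hits = merged[merged["proximal"].fillna(False)]
    return hits.reset_index(drop=True)
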