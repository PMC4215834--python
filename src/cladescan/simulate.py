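"""Synthetic data with declared ground truth for every pipeline input.

The generators emulate the study conditions of a two-clade rRNA survey:
a star phylogeny of descendants from one uniform-random ancestor, with
Jukes–Cantor-like substitutions (uniform choice among the three
alternative nucleotides), planted clade-signature columns (one fixed
state per group), planted fast-evolving columns (elevated substitution
probability in the in-group only) and i.i.d. per-cell gaps.  A star tree
rather than a genealogy keeps the ground truth of the column-wise
statistics analytic.

Also provided: toy PDB structures with known nearest P-to-CA distances,
synthetic Cq tables driven through a standard curve, upstream regions
with a planted promoter motif, and a one-call bundle writer that emits a
coherent fixture set (alignment + labels + helix table + structure +
ground-truth sidecar) for end-to-end runs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import IN, OUT, LabeledAlignment
from .qpcr import StandardCurve, cq_from_copies

RNA = ("A", "C", "G", "U")


@dataclass
class CladeSimConfig:
    """Parameters of the two-clade alignment simulator.

    Defaults mirror the survey scale exercised throughout the package:
    50 sequences per clade, 1500 alignment columns, 5% background
    per-site substitution probability from the shared ancestor, 30
    planted signature columns at full fixation, 25 planted fast columns
    with in-group substitution probability 0.5, and 2% i.i.d. gaps.
    """

    n_in: int = 50
    n_out: int = 50
    length: int = 1500
    background_rate: float = 0.05
    planted_signature: list[tuple[int, str, str]] = field(default_factory=list)
    planted_fast: list[tuple[int, float]] = field(default_factory=list)
    gap_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (
            ("background_rate", self.background_rate),
            ("gap_rate", self.gap_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        sig_cols = {c for c, _, _ in self.planted_signature}
        fast_cols = {c for c, _ in self.planted_fast}
        if len(sig_cols) != len(self.planted_signature) or len(fast_cols) != len(
            self.planted_fast
        ):
            raise ValueError("duplicate planted column")
        if sig_cols & fast_cols:
            raise ValueError(
                f"planted column collision: {sorted(sig_cols & fast_cols)}"
            )
        for c in sig_cols | fast_cols:
            if not 1 <= c <= self.length:
                raise ValueError(f"planted column {c} outside 1..{self.length}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    signature_columns: set[int] = field(default_factory=set)
    fast_columns: set[int] = field(default_factory=set)
    ancestor: str = ""
    planted_helix: str | None = None
    planted_promoter_offsets: dict[str, int] = field(default_factory=dict)
    true_qpcr_fractions: dict[str, float] = field(default_factory=dict)
    structure_nearest: dict[int, float | None] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "signature_columns": sorted(self.signature_columns),
                "fast_columns": sorted(self.fast_columns),
                "ancestor": self.ancestor,
                "planted_helix": self.planted_helix,
                "planted_promoter_offsets": self.planted_promoter_offsets,
                "true_qpcr_fractions": self.true_qpcr_fractions,
                "structure_nearest": {
                    str(k): v for k, v in self.structure_nearest.items()
                },
            },
            indent=1,
            sort_keys=True,
        )


def default_signature_plan(
    columns: list[int], rng: np.random.Generator
) -> list[tuple[int, str, str]]:
    """Assign a random (in-state, out-state) pair, in != out, per column."""
    plan = []
    for c in columns:
        i, j = rng.choice(4, size=2, replace=False)
        plan.append((c, RNA[i], RNA[j]))
    return plan


def simulate_two_clade_alignment(
    config: CladeSimConfig,
) -> tuple[LabeledAlignment, GroundTruth]:
    """Star-phylogeny two-clade alignment with planted sites and gaps.

    Per column: the ancestor state is uniform over {A,C,G,U}; each
    descendant substitutes with ``background_rate`` (uniformly among the
    3 alternatives).  Planted signature columns overwrite both groups
    with their configured fixed states; planted fast columns substitute
    with the elevated rate in the in-group only.  Gaps overwrite cells
    i.i.d. with ``gap_rate`` last.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_in + config.n_out
    length = config.length
    anc = rng.integers(0, 4, size=length)
    mat = np.tile(anc, (n, 1))

    # background substitutions: shift by 1..3 mod 4 = uniform alternative
    sub_mask = rng.random((n, length)) < config.background_rate
    shift = rng.integers(1, 4, size=(n, length))
    mat = np.where(sub_mask, (mat + shift) % 4, mat)

    idx = {nt: k for k, nt in enumerate(RNA)}
    for col, nt_in, nt_out in config.planted_signature:
        mat[: config.n_in, col - 1] = idx[nt_in.upper()]
        mat[config.n_in :, col - 1] = idx[nt_out.upper()]
    for col, rate in config.planted_fast:
        fast_mask = rng.random(config.n_in) < rate
        fast_shift = rng.integers(1, 4, size=config.n_in)
        j = col - 1
        mat[: config.n_in, j] = np.where(
            fast_mask, (anc[j] + fast_shift) % 4, anc[j]
        )

    chars = np.array(RNA, dtype="U1")[mat]
    gap_mask = rng.random((n, length)) < config.gap_rate
    chars = np.where(gap_mask, "-", chars)

    ids = [f"in_{k:03d}" for k in range(config.n_in)] + [
        f"out_{k:03d}" for k in range(config.n_out)
    ]
    group_of = {i: (IN if i.startswith("in_") else OUT) for i in ids}
    seqs = ["".join(row) for row in chars]
    truth = GroundTruth(
        signature_columns={c for c, _, _ in config.planted_signature},
        fast_columns={c for c, _ in config.planted_fast},
        ancestor="".join(np.array(RNA, dtype="U1")[anc]),
    )
    return LabeledAlignment(ids, seqs, group_of), truth


def _pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_num: int,
    xyz: tuple[float, float, float],
    element: str,
) -> str:
    # short atom names start at column 14 per PDB convention
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5} {name_field} {res_name:>3} {chain}{res_num:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2}\n"
    )


def simulate_toy_structure(
    n_rna: int = 10,
    n_protein: int = 5,
    geometry: str = "random",
    seed: int = 0,
    rna_chain: str = "A",
    protein_chain: str = "B",
    near_rna_residues: set[int] | None = None,
    near_distance: float = 8.0,
    far_distance: float = 60.0,
) -> tuple[str, GroundTruth]:
    """Toy PDB text with RNA P atoms and protein CA atoms plus true distances.

    Geometries:

    * ``"triangle"`` — one P at the origin, one CA at (3, 4, 0): a 3-4-5
      triangle with true distance 5 Å.
    * ``"unresolved"`` — as triangle, plus a second RNA residue carrying
      only a C1' atom (no phosphate), marked unresolved in the truth.
    * ``"random"`` — ``n_rna`` P atoms and ``n_protein`` CA atoms uniform
      in a 50 Å box.
    * ``"planted"`` — CA atoms clustered near the origin; RNA residues in
      ``near_rna_residues`` placed ~``near_distance`` Å from the cluster,
      all others at least ``far_distance`` Å away.

    Ground-truth nearest distances are computed by all-pairs enumeration
    at generation time.
    """
    if n_rna < 1 or n_protein < 1:
        raise ValueError("need at least one RNA and one protein residue")
    rng = np.random.default_rng(seed)
    rna_atoms: list[tuple[int, str, tuple[float, float, float] | None]] = []
    prot_ca: list[tuple[int, tuple[float, float, float]]] = []

    if geometry == "triangle":
        rna_atoms = [(1, "P", (0.0, 0.0, 0.0))]
        prot_ca = [(1, (3.0, 4.0, 0.0))]
    elif geometry == "unresolved":
        rna_atoms = [(1, "P", (0.0, 0.0, 0.0)), (2, "C1'", None)]
        prot_ca = [(1, (3.0, 4.0, 0.0))]
    elif geometry == "random":
        for r in range(1, n_rna + 1):
            rna_atoms.append((r, "P", tuple(rng.uniform(0, 50, 3))))
        for r in range(1, n_protein + 1):
            prot_ca.append((r, tuple(rng.uniform(0, 50, 3))))
    elif geometry == "planted":
        near = near_rna_residues or set()
        for r in range(1, n_protein + 1):
            prot_ca.append((r, tuple(rng.uniform(-2, 2, 3))))
        for r in range(1, n_rna + 1):
            if r in near:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = tuple(direction * near_distance)
            else:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = tuple(direction * (far_distance + rng.uniform(0, 40)))
            rna_atoms.append((r, "P", pos))
    else:
        raise ValueError(f"unknown geometry preset {geometry!r}")

    lines = []
    serial = 1
    for res_num, atom, xyz in rna_atoms:
        if xyz is None:
            # emit a placeholder sugar atom so the residue exists without a P
            lines.append(
                _pdb_atom_line(serial, "C1'", "U", rna_chain, res_num, (0.0, 0.0, 9.0), "C")
            )
        else:
            lines.append(
                _pdb_atom_line(serial, atom, "U", rna_chain, res_num, xyz, "P")
            )
        serial += 1
    for res_num, xyz in prot_ca:
        lines.append(
            _pdb_atom_line(serial, "CA", "ALA", protein_chain, res_num, xyz, "C")
        )
        serial += 1
    pdb_text = "".join(lines) + "END\n"

    ca = np.array([xyz for _, xyz in prot_ca])
    truth = GroundTruth()
    for res_num, atom, xyz in rna_atoms:
        if xyz is None:
            truth.structure_nearest[res_num] = None
        else:
            d = np.sqrt(((ca - np.asarray(xyz)) ** 2).sum(axis=1))
            truth.structure_nearest[res_num] = float(d.min())
    return pdb_text, truth


def simulate_qpcr(
    true_fractions: dict[str, float],
    total_copies: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, float, float]], GroundTruth]:
    """Cq table for a transcript pool with known class fractions.

    Returns rows of (class, true copies, Cq) where Cq is the curve
    prediction plus Gaussian noise of ``noise_sd`` cycles.  Classes with
    zero copies get no Cq (reported as NaN — below detection).
    """
    s = sum(true_fractions.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {s})")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, frac in true_fractions.items():
        copies = frac * total_copies
        if copies > 0:
            cq = cq_from_copies(curve, copies) + rng.normal(0.0, noise_sd)
        else:
            cq = float("nan")
        rows.append((cls, copies, float(cq)))
    truth = GroundTruth(true_qpcr_fractions=dict(true_fractions))
    return rows, truth


def simulate_upstream_regions(
    n_sequences: int = 18,
    length: int = 120,
    motif: str = "TATAAT",
    offset: int = 80,
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """Random DNA upstream regions with a promoter motif planted at one offset."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    truth = GroundTruth()
    for k in range(n_sequences):
        seq = list(bases[rng.integers(0, 4, size=length)])
        seq[offset - 1 : offset - 1 + len(motif)] = list(motif)
        sid = f"upstream_{k:02d}"
        seqs[sid] = "".join(seq)
        truth.planted_promoter_offsets[sid] = offset
    return seqs, truth


@dataclass
class SurveyBundle:
    """Paths and ground truth of a complete synthetic fixture set."""

    alignment: Path
    labels: Path
    helix_table: Path
    structure: Path
    truth_file: Path
    truth: GroundTruth
    reference_id: str
    rna_chain: str
    protein_chain: str


def simulate_survey_bundle(
    outdir: str | Path,
    seed: int = 42,
    n_in: int = 50,
    n_out: int = 50,
    length: int = 1500,
    background_rate: float = 0.05,
    n_signature: int = 30,
    n_fast: int = 25,
    fast_rate: float = 0.5,
    gap_rate: float = 0.02,
    helix_size: int = 30,
    reference_id: str = "REF",
) -> SurveyBundle:
    """Write a coherent end-to-end fixture set and its ground truth.

    The alignment carries ``n_signature`` planted signature columns
    scattered outside one designated helix and ``n_fast`` fast columns
    concentrated inside it; the helix table tiles the reference into
    ``helix_size``-residue stems; the toy structure places exactly the
    designated helix's residues within contact range of the protein.  An
    ungapped reference row (labeled OUT, like the *E. coli* outlier of a
    cyanobacterial survey) pins reference numbering to column numbering.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_helices = length // helix_size
    helix_ids = [str(h) for h in range(1, n_helices + 1)]
    planted_helix = helix_ids[n_helices // 2]
    h0 = (n_helices // 2) * helix_size + 1  # planted helix start column
    fast_cols = sorted(
        rng.choice(np.arange(h0, h0 + helix_size), size=n_fast, replace=False).tolist()
    )
    outside = np.setdiff1d(np.arange(1, length + 1), np.arange(h0, h0 + helix_size))
    sig_cols = sorted(rng.choice(outside, size=n_signature, replace=False).tolist())
    sig_plan = default_signature_plan(sig_cols, rng)

    config = CladeSimConfig(
        n_in=n_in,
        n_out=n_out,
        length=length,
        background_rate=background_rate,
        planted_signature=sig_plan,
        planted_fast=[(c, fast_rate) for c in fast_cols],
        gap_rate=gap_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    aln, truth = simulate_two_clade_alignment(config)
    truth.planted_helix = planted_helix

    # ungapped reference row = the ancestor, so residue == column
    ids = aln.ids + [reference_id]
    seqs = aln.seqs + [truth.ancestor]
    group_of = dict(aln.group_of)
    group_of[reference_id] = OUT
    aln = LabeledAlignment(ids, seqs, group_of)

    alignment_path = outdir / "alignment.fasta"
    labels_path = outdir / "labels.tsv"
    with open(alignment_path, "w") as fh:
        for i, s in zip(aln.ids, aln.seqs):
            fh.write(f">{i}\n{s}\n")
    with open(labels_path, "w") as fh:
        for i in aln.ids:
            fh.write(f"{i}\t{aln.group_of[i]}\n")

    helix_path = outdir / "helices.tsv"
    with open(helix_path, "w") as fh:
        fh.write("helix_id\tstart\tend\tdomain\n")
        for k, hid in enumerate(helix_ids):
            fh.write(f"{hid}\t{k * helix_size + 1}\t{(k + 1) * helix_size}\t\n")

    near = set(range(h0, h0 + helix_size))
    pdb_text, struct_truth = simulate_toy_structure(
        n_rna=length,
        n_protein=30,
        geometry="planted",
        seed=int(rng.integers(0, 2**31 - 1)),
        near_rna_residues=near,
    )
    truth.structure_nearest = struct_truth.structure_nearest
    structure_path = outdir / "structure.pdb"
    structure_path.write_text(pdb_text)

    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(truth.to_json() + "\n")

    return SurveyBundle(
        alignment=alignment_path,
        labels=labels_path,
        helix_table=helix_path,
        structure=structure_path,
        truth_file=truth_path,
        truth=truth,
        reference_id=reference_id,
        rna_chain="A",
        protein_chain="B",
    )
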