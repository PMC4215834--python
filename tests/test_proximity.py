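"""PDB parsing, nearest P-to-CA distances and helix proximity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from cladescan.proximity import (
    cross_reference,
    nearest_protein_distances,
    parse_structure,
    proximal_helices,
)
from cladescan.simulate import simulate_toy_structure


def helix_frame(rows):
    return pd.DataFrame(rows, columns=["helix_id", "start", "end", "domain"])


def atom_line(serial, name, resname, chain, resnum, x, y, z, altloc=" "):
    """Fixed-column ATOM record, written independently of the package."""
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"ATOM  {serial:>5} {name_field}{altloc}{resname:>3} {chain}{resnum:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {name[0]:>2}\n"
    )


def load(tmp_path, pdb_text, rna="A", protein="B"):
    path = tmp_path / "toy.pdb"
    path.write_text(pdb_text)
    return parse_structure(path, rna, protein)


class TestParseStructure:
    def test_two_chains_retained(self, tmp_path):
        text, _ = simulate_toy_structure(3, 2, geometry="random", seed=1)
        model = load(tmp_path, text)
        assert sorted(model.chains) == ["A", "B"]
        assert len(model.chain("A")) == 3
        assert len(model.chain("B")) == 2

    def test_missing_chain_named_in_error(self, tmp_path):
        text, _ = simulate_toy_structure(1, 1, geometry="triangle")
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        with pytest.raises(ValueError, match="'Z'"):
            parse_structure(path, "A", "Z")

    def test_unparseable_atom_record_reports_line(self, tmp_path):
        text, _ = simulate_toy_structure(1, 1, geometry="triangle")
        broken = text.replace("  3.000", "  x.000")
        path = tmp_path / "toy.pdb"
        path.write_text(broken)
        with pytest.raises(ValueError, match=r":2: unparseable"):
            parse_structure(path, "A", "B")

    def test_first_listed_altloc_kept(self, tmp_path):
        pdb = (
            atom_line(1, "P", "U", "A", 1, 0.0, 0.0, 0.0, altloc="A")
            + atom_line(2, "P", "U", "A", 1, 9.0, 9.0, 9.0, altloc="B")
            + atom_line(3, "CA", "ALA", "B", 1, 3.0, 4.0, 0.0)
        )
        model = load(tmp_path, pdb)
        (res,) = model.chain("A")
        assert res.atoms["P"] == (0.0, 0.0, 0.0)


class TestNearestDistances:
    def test_three_four_five_triangle(self, tmp_path):
        text, _ = simulate_toy_structure(geometry="triangle")
        model = load(tmp_path, text)
        (rec,) = nearest_protein_distances(model, "A", "B")
        assert rec.distance == pytest.approx(5.0)
        assert rec.nearest_protein_residue == 1

    def test_residue_without_phosphate_unresolved(self, tmp_path):
        text, truth = simulate_toy_structure(geometry="unresolved")
        model = load(tmp_path, text)
        records = nearest_protein_distances(model, "A", "B")
        assert records[1].unresolved
        assert truth.structure_nearest[2] is None

    def test_no_alpha_carbons_rejected(self, tmp_path):
        pdb = atom_line(1, "P", "U", "A", 1, 0.0, 0.0, 0.0) + atom_line(
            2, "CB", "ALA", "B", 1, 3.0, 4.0, 0.0
        )
        model = load(tmp_path, pdb)
        with pytest.raises(ValueError, match="no CA"):
            nearest_protein_distances(model, "A", "B")

    @pytest.mark.parametrize("n_rna,n_protein,seed", [(50, 30, 7), (1000, 1000, 19)])
    def test_matches_all_pairs_minimum(self, tmp_path, n_rna, n_protein, seed):
        """k-d tree result equals the brute-force pairwise distance minimum."""
        text, truth = simulate_toy_structure(n_rna, n_protein, "random", seed=seed)
        model = load(tmp_path, text)
        records = nearest_protein_distances(model, "A", "B")
        p = np.array([r.atoms["P"] for r in model.chain("A")])
        ca = np.array([r.atoms["CA"] for r in model.chain("B")])
        oracle = cdist(p, ca).min(axis=1)
        got = np.array([r.distance for r in records])
        assert np.allclose(got, oracle, atol=1e-9)
        # and the generator's own truth agrees up to coordinate rounding
        truth_arr = np.array([truth.structure_nearest[r.rna_residue] for r in records])
        assert np.allclose(got, truth_arr, atol=5e-3)

    def test_invariant_under_rigid_motion(self, tmp_path):
        """Distances are unchanged by a rotation plus translation of all atoms."""
        text, _ = simulate_toy_structure(20, 10, "random", seed=3)
        model = load(tmp_path, text)
        base = [r.distance for r in nearest_protein_distances(model, "A", "B")]
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = np.array([12.0, -5.0, 30.0])
        for chain in model.chains.values():
            for res in chain:
                for name, xyz in res.atoms.items():
                    res.atoms[name] = tuple(q @ np.asarray(xyz) + shift)
        moved = [r.distance for r in nearest_protein_distances(model, "A", "B")]
        assert np.allclose(base, moved, atol=1e-9)


class TestProximalHelices:
    def test_threshold_flags(self, tmp_path):
        text, _ = simulate_toy_structure(
            6, 4, "planted", seed=2, near_rna_residues={1, 2, 3}, near_distance=8.0
        )
        model = load(tmp_path, text)
        records = nearest_protein_distances(model, "A", "B")
        helices = helix_frame([("near", 1, 3, ""), ("far", 4, 6, "")])
        out = proximal_helices(records, helices, threshold=15.0)
        flags = dict(zip(out["helix_id"], out["proximal"]))
        assert flags == {"near": True, "far": False}

    def test_unresolved_only_helix_not_proximal(self, tmp_path):
        text, _ = simulate_toy_structure(geometry="unresolved")
        model = load(tmp_path, text)
        records = nearest_protein_distances(model, "A", "B")
        out = proximal_helices(records, helix_frame([("h", 2, 2, "")]), threshold=100.0)
        row = out.iloc[0]
        assert row["n_resolved"] == 0 and not row["proximal"]

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            proximal_helices([], helix_frame([("h", 1, 1, "")]), threshold=0.0)


class TestCrossReference:
    def test_requires_both_fast_and_proximal(self):
        summary = pd.DataFrame(
            {"helix_id": ["A", "B"], "n_residues": [5, 5], "n_masked": [0, 0],
             "mean_D": [0.9, 0.8], "max_D": [1.0, 0.9]}
        )
        prox = pd.DataFrame(
            {"helix_id": ["A", "B"], "n_resolved": [5, 5],
             "min_distance_A": [8.0, 40.0], "mean_distance_A": [9.0, 50.0],
             "proximal": [True, False]}
        )
        hits = cross_reference(summary, prox, top_k=2)
        assert hits["helix_id"].tolist() == ["A"]

    def test_empty_proximal_set_gives_empty_report(self):
        summary = pd.DataFrame(
            {"helix_id": ["A"], "n_residues": [5], "n_masked": [0],
             "mean_D": [0.9], "max_D": [1.0]}
        )
        prox = pd.DataFrame(
            {"helix_id": ["A"], "n_resolved": [5], "min_distance_A": [40.0],
             "mean_distance_A": [50.0], "proximal": [False]}
        )
        assert cross_reference(summary, prox).empty

    def test_disjoint_ids_rejected(self):
        summary = pd.DataFrame({"helix_id": ["A"], "mean_D": [0.9]})
        prox = pd.DataFrame({"helix_id": ["B"], "proximal": [True]})
        with pytest.raises(ValueError, match="disjoint"):
            cross_reference(summary, prox)
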