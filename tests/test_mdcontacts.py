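"""Contact occupancy, protonation assignment and site geometry."""

import numpy as np
import pandas as pd
import pytest

from asicca.mdcontacts import (SIDE_CHAIN_ATOMS, Trajectory,
                               assign_protonation, contact_occupancy,
                               site_distances)
from asicca.synthetic import build_toy_atoms, gen_trajectory

#: the thirteen acidic residues protonated in the pH 5.5-mimicking condition
PH55_PROTONATED = ["D78", "E79", "E221", "E231", "E235", "E247", "E322",
                   "D351", "D358", "D414", "E418", "E423", "D439"]


def brute_force_occupancy(traj, cutoff=2.5):
    """O(frames x ions x atoms) oracle with explicit Python loops."""
    atoms = traj.atoms
    ions = [i for i in range(len(atoms))
            if atoms["resname"].iloc[i] in {"CA", "CAL", "CA2"}]
    out = {}
    residues = atoms[~atoms.index.isin(ions)][["resname", "resid", "segid"]]
    for key in residues.drop_duplicates().itertuples(index=False):
        names = SIDE_CHAIN_ATOMS.get(key.resname)
        if names is None:
            continue
        idx = [i for i in range(len(atoms))
               if atoms["resname"].iloc[i] == key.resname
               and atoms["resid"].iloc[i] == key.resid
               and atoms["segid"].iloc[i] == key.segid
               and atoms["name"].iloc[i] in names]
        hits = 0
        for f in range(traj.n_frames):
            found = False
            for i in ions:
                for j in idx:
                    d = np.sqrt(((traj.coords[f, i] - traj.coords[f, j]) ** 2
                                 ).sum())
                    if d < cutoff:
                        found = True
            hits += found
        out[(key.resname, key.resid, key.segid)] = hits / traj.n_frames
    return out


class TestContactOccupancy:
    def test_matches_brute_force_on_toy_trajectory(self):
        traj = gen_trajectory({"E81": 0.3, "D439": 0.8, "N421:B": 0.5},
                              20, seed=1)
        oracle = brute_force_occupancy(traj)
        result = contact_occupancy(traj)
        for row in result.table.itertuples():
            assert row.fraction == oracle[(row.resname, row.resid, row.segid)]

    def test_rotation_translation_invariance(self):
        traj = gen_trajectory({"E81": 0.5, "T90": 0.2}, 50, seed=2)
        base = contact_occupancy(traj).table
        # proper rotation + translation applied to every frame
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = Trajectory(traj.coords @ q.T + np.array([5.0, -3.0, 12.0]),
                           traj.atoms)
        assert np.allclose(contact_occupancy(moved).table["fraction"],
                           base["fraction"])

    def test_monotone_in_cutoff(self):
        traj = gen_trajectory({"E81": 0.5, "D282": 0.3}, 200, seed=4)
        fr = [contact_occupancy(traj, cutoff=c).table["fraction"].to_numpy()
              for c in (1.5, 2.5, 4.0)]
        assert np.all(fr[0] <= fr[1]) and np.all(fr[1] <= fr[2])

    def test_explicit_residue_selection(self):
        traj = gen_trajectory({"E81": 1.0, "D439": 1.0}, 10, seed=5)
        res = contact_occupancy(traj, selection=[(81, "A")])
        assert len(res.table) == 1
        assert res.table["resid"].iloc[0] == 81

    def test_no_ions_rejected(self):
        atoms, xyz = build_toy_atoms(["E81"])
        with pytest.raises(ValueError, match="no Ca2"):
            contact_occupancy(Trajectory(xyz[None], atoms))

    def test_empty_selection_rejected(self):
        traj = gen_trajectory({"E81": 1.0}, 5, seed=0)
        with pytest.raises(ValueError, match="no designated"):
            contact_occupancy(traj, selection=[(999, "Z")])


class TestTrajectoryIO:
    def test_pdb_round_trip_preserves_occupancy(self, tmp_path):
        traj = gen_trajectory({"E81": 0.6, "D439:B": 0.4}, 25, seed=6)
        path = tmp_path / "toy.pdb"
        traj.to_pdb(path)
        back = Trajectory.from_pdb(path)
        assert back.n_frames == traj.n_frames
        a = contact_occupancy(traj).table.sort_values(["resid", "segid"])
        b = contact_occupancy(back).table.sort_values(["resid", "segid"])
        assert np.allclose(a["fraction"].to_numpy(), b["fraction"].to_numpy())

    def test_xyz_reader_with_atom_table(self, tmp_path):
        traj = gen_trajectory({"E81": 1.0}, 3, seed=7)
        lines = []
        for f in range(traj.n_frames):
            lines.append(f"{len(traj.atoms)}")
            lines.append(f"frame {f}")
            for (el, xyz) in zip(traj.atoms["name"], traj.coords[f]):
                lines.append(f"{el[:1]} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}")
        (tmp_path / "toy.xyz").write_text("\n".join(lines) + "\n")
        back = Trajectory.from_xyz(tmp_path / "toy.xyz", traj.atoms)
        assert np.allclose(back.coords, traj.coords, atol=1e-3)

    def test_frame_shape_validation(self):
        atoms, xyz = build_toy_atoms(["E81"])
        with pytest.raises(ValueError, match="match"):
            Trajectory(np.zeros((2, len(atoms) + 1, 3)), atoms)


class TestProtonation:
    def make_table(self):
        rows = [{"resname": ("GLU" if r[0] == "E" else "ASP"),
                 "resid": int(r[1:]), "pka": 6.0} for r in PH55_PROTONATED]
        rows += [{"resname": "GLU", "resid": 212, "pka": 4.2},
                 {"resname": "ASP", "resid": 282, "pka": 3.9},
                 {"resname": "HIS", "resid": 73, "pka": 6.5}]
        return pd.DataFrame(rows)

    def test_rule_application(self):
        t = pd.DataFrame([{"resname": "GLU", "resid": 1, "pka": 6.0},
                          {"resname": "GLU", "resid": 2, "pka": 4.0},
                          {"resname": "ASP", "resid": 3, "pka": 5.5}])
        state = assign_protonation(t, ph_mimic=5.5)
        flags = state.table.set_index("resid")["protonated"]
        assert bool(flags[1]) and not bool(flags[2])
        assert bool(flags[3])     # boundary pKa == pH counts as protonated

    def test_reproduces_ph55_residue_list(self):
        state = assign_protonation(self.make_table(), ph_mimic=5.5)
        assert state.protonated_residues() == PH55_PROTONATED

    def test_his_always_neutral(self):
        state = assign_protonation(self.make_table(), ph_mimic=5.5)
        his = state.table[state.table["resname"] == "HIS"]
        assert not his["protonated"].any()

    def test_missing_residue_listed_in_error(self):
        atoms = pd.DataFrame([
            {"name": "OE1", "resname": "GLU", "resid": 500, "segid": "A"}])
        with pytest.raises(ValueError, match="E500"):
            assign_protonation(self.make_table(), structure_atoms=atoms)

    def test_rule_direction_configurable(self):
        t = pd.DataFrame([{"resname": "GLU", "resid": 1, "pka": 6.0}])
        inv = assign_protonation(t, ph_mimic=5.5, rule="pka_lt_ph")
        assert not inv.table["protonated"].iloc[0]


class TestSiteDistances:
    @staticmethod
    def place(entries):
        """entries: (resname, resid, segid, {atom: xyz})"""
        rows, xyz = [], []
        for resname, resid, segid, atom_pos in entries:
            for name, pos in atom_pos.items():
                rows.append({"name": name, "resname": resname,
                             "resid": resid, "segid": segid})
                xyz.append(pos)
        return Trajectory(np.asarray(xyz, float)[None], pd.DataFrame(rows))

    def test_two_atoms_known_distance(self):
        traj = self.place([
            ("GLU", 435, "A", {"OE1": (0, 0, 0), "OE2": (0.5, 0, 0)}),
            ("ASP", 439, "A", {"OD1": (4.0, 0, 0), "OD2": (7.0, 0, 0)}),
        ])
        table = site_distances(traj, [("GLU", 435, "A"), ("ASP", 439, "A")])
        assert table["min_distance_A"].iloc[0] == pytest.approx(3.5)

    def test_equilateral_triad_above_open_pore_threshold(self):
        # three D439 copies on an equilateral triangle with 12.5 A sides:
        # too far apart to coordinate a single Ca2+ between them
        s = 12.5
        pts = [(0.0, 0.0, 0.0), (s, 0.0, 0.0), (s / 2, s * np.sqrt(3) / 2, 0.0)]
        traj = self.place([
            ("ASP", 439, seg, {"OD1": p}) for seg, p in zip("ABC", pts)])
        table = site_distances(traj, [("ASP", 439)])
        assert len(table) == 3
        assert np.allclose(table["min_distance_A"], s)
        assert (table["min_distance_A"] > 12).all()

    def test_self_pairs_skipped(self):
        traj = self.place([
            ("ASP", 439, "A", {"OD1": (0, 0, 0), "OD2": (1, 0, 0)})])
        table = site_distances(traj, [("ASP", 439, "A"), ("ASP", 439, "A")])
        assert table.empty

    def test_missing_atoms_flagged(self):
        traj = self.place([
            ("GLU", 435, "A", {"CB": (0, 0, 0)}),        # no carboxylate O
            ("ASP", 439, "A", {"OD1": (4, 0, 0)}),
        ])
        table = site_distances(traj, [("GLU", 435, "A"), ("ASP", 439, "A")])
        assert table["missing_atoms"].iloc[0]
        assert np.isnan(table["min_distance_A"].iloc[0])
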