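"""Ca2+ contact occupancy, protonation assignment and site geometry from
structures and trajectories.

Occupancy is the fraction of frames in which any Ca2+ ion lies strictly
within a distance cutoff (default 2.5 A) of a residue's designated
side-chain atoms, reported per (residue, subunit).  Side-chain atom sets for
the screened residue types are the polar/charged tips: Glu OE1/OE2, Asp
OD1/OD2, Asn OD1/ND2, Thr OG1, His ND1/NE2; backbone and carbonyl atoms are
excluded.

File I/O (multi-model PDB, XYZ, and anything else MDAnalysis can read) is
delegated to MDAnalysis; the analysis itself operates on plain numpy frames
so that toy fixtures can be built in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SIDE_CHAIN_ATOMS",
    "CARBOXYLATE_ATOMS",
    "ION_RESNAMES",
    "Trajectory",
    "OccupancyResult",
    "ProtonationState",
    "contact_occupancy",
    "assign_protonation",
    "site_distances",
]

SIDE_CHAIN_ATOMS = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "ASN": ("OD1", "ND2"),
    "THR": ("OG1",),
    "HIS": ("ND1", "NE2"),
}

CARBOXYLATE_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}

#: residue names recognized as Ca2+ ions
ION_RESNAMES = {"CA", "CAL", "CA2"}

_ATOM_COLUMNS = ["name", "resname", "resid", "segid"]


@dataclass
class Trajectory:
    """Frames of coordinates plus an atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atoms`` is a
    DataFrame with columns name, resname, resid, segid.  Ca2+ ions are the
    atoms whose resname is in :data:`ION_RESNAMES`.
    """

    coords: np.ndarray
    atoms: pd.DataFrame

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table lacks columns: {missing}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def ion_indices(self) -> np.ndarray:
        return np.flatnonzero(self.atoms["resname"].isin(ION_RESNAMES))

    @classmethod
    def from_pdb(cls, path) -> "Trajectory":
        """Load a (multi-model) PDB file via MDAnalysis."""
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        atoms = pd.DataFrame({
            "name": u.atoms.names,
            "resname": u.atoms.resnames,
            "resid": u.atoms.resids,
            "segid": _segids(u.atoms),
        })
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        return cls(coords, atoms)

    @classmethod
    def from_xyz(cls, path, atoms: pd.DataFrame) -> "Trajectory":
        """Load an XYZ trajectory; XYZ carries no topology, so the atom table
        (same order as the file) must be supplied."""
        import MDAnalysis as mda

        u = mda.Universe(str(path), format="XYZ")
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        return cls(coords, atoms.reset_index(drop=True))

    def to_pdb(self, path):
        """Write all frames as a multi-model PDB via MDAnalysis."""
        import MDAnalysis as mda

        n = len(self.atoms)
        segids = self.atoms["segid"].astype(str).to_numpy()
        u = mda.Universe.empty(
            n, n_residues=n, n_segments=len(np.unique(segids)),
            atom_resindex=np.arange(n),
            residue_segindex=np.searchsorted(np.unique(segids), segids),
            trajectory=True,
        )
        u.add_TopologyAttr("names", self.atoms["name"].to_numpy())
        u.add_TopologyAttr("resnames", self.atoms["resname"].to_numpy())
        u.add_TopologyAttr("resids", self.atoms["resid"].to_numpy())
        u.add_TopologyAttr("segids", np.unique(segids))
        from MDAnalysis.coordinates.memory import MemoryReader

        u.trajectory = MemoryReader(self.coords.astype(np.float32), order="fac")
        import warnings

        with warnings.catch_warnings():
            # the writer warns about absent occupancy/element metadata our
            # toy systems intentionally lack
            warnings.simplefilter("ignore", UserWarning)
            with mda.Writer(str(path), n, multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


def _segids(atomgroup):
    try:
        return atomgroup.segids
    except Exception:
        return np.array([""] * len(atomgroup))


@dataclass
class OccupancyResult:
    """Per-(residue, subunit) Ca2+ contact fractions."""

    table: pd.DataFrame          # resname, resid, segid, fraction
    cutoff: float
    n_frames: int
    provenance: dict = field(default_factory=dict)

    def fraction(self, resid, segid=None) -> float:
        t = self.table
        sel = t["resid"] == resid
        if segid is not None:
            sel &= t["segid"] == segid
        vals = t.loc[sel, "fraction"]
        if vals.empty:
            raise KeyError(f"residue {resid} (segid={segid}) not in result")
        return float(vals.mean())


def _resolve_selection(atoms: pd.DataFrame, selection):
    """Return the designated side-chain atom indices, grouped by residue."""
    if selection is None:
        selection = sorted(SIDE_CHAIN_ATOMS)
    protein = atoms[~atoms["resname"].isin(ION_RESNAMES)]
    if isinstance(selection, dict):  # explicit resname -> atom names map
        atom_map = selection
        wanted = protein[protein["resname"].isin(atom_map)]
    elif all(isinstance(s, str) for s in selection):
        atom_map = SIDE_CHAIN_ATOMS
        wanted = protein[protein["resname"].isin(selection)]
    else:  # explicit (resname/resid/segid) triples or (resid, segid) pairs
        atom_map = SIDE_CHAIN_ATOMS
        keys = {tuple(s) if not np.isscalar(s) else (s,) for s in selection}
        def match(row):
            return ((row.resid,) in keys or (row.resid, row.segid) in keys
                    or (row.resname, row.resid, row.segid) in keys)
        wanted = protein[[match(r) for r in protein.itertuples()]]
    groups = {}
    for key, sub in wanted.groupby(["resname", "resid", "segid"], sort=True):
        names = atom_map.get(key[0])
        if names is None:
            continue
        idx = sub.index[sub["name"].isin(names)].to_numpy()
        if len(idx):
            groups[key] = idx
    if not groups:
        raise ValueError("selection resolves to no designated side-chain atoms")
    return groups


def contact_occupancy(traj: Trajectory, selection=None,
                      cutoff: float = 2.5) -> OccupancyResult:
    """Fraction of frames in which a Ca2+ ion is closer than ``cutoff`` (A)
    to each selected residue's designated side-chain atoms.

    ``selection`` may be None (all Glu/Asp/Asn/Thr/His residues), a list of
    residue type names, a list of (resid[, segid]) identifiers, or a mapping
    resname -> atom-name tuple overriding the defaults.  The inequality is
    strict, matching the "distance of less than 2.5 A" convention.
    """
    ions = traj.ion_indices
    if len(ions) == 0:
        raise ValueError("trajectory contains no Ca2+ ions")
    groups = _resolve_selection(traj.atoms, selection)

    ion_xyz = traj.coords[:, ions, :]                 # (F, I, 3)
    rows = []
    for (resname, resid, segid), idx in groups.items():
        res_xyz = traj.coords[:, idx, :]              # (F, A, 3)
        d = np.linalg.norm(ion_xyz[:, :, None, :] - res_xyz[:, None, :, :],
                           axis=-1)                   # (F, I, A)
        hit = (d < cutoff).any(axis=(1, 2))
        rows.append({"resname": resname, "resid": int(resid),
                     "segid": segid, "fraction": float(hit.mean())})
    table = pd.DataFrame(rows, columns=["resname", "resid", "segid", "fraction"])
    return OccupancyResult(table=table, cutoff=cutoff, n_frames=traj.n_frames,
                           provenance={"n_ions": int(len(ions))})


@dataclass
class ProtonationState:
    """Protonation assignment for acidic residues at a pH-mimicking condition."""

    table: pd.DataFrame          # resname, resid, segid, pka, protonated
    ph_mimic: float
    rule: str
    provenance: dict = field(default_factory=dict)

    def protonated_residues(self):
        t = self.table[self.table["protonated"]]
        return [f"{_one_letter(rn)}{rid}" for rn, rid in
                zip(t["resname"], t["resid"])]


_ONE = {"GLU": "E", "ASP": "D", "HIS": "H", "ASN": "N", "THR": "T"}


def _one_letter(resname):
    return _ONE.get(resname, resname)


def assign_protonation(pka_table: pd.DataFrame, ph_mimic: float = 5.5,
                       rule: str = "pka_ge_ph",
                       structure_atoms: pd.DataFrame | None = None
                       ) -> ProtonationState:
    """Assign protonation flags to Glu/Asp residues for a pH-mimicking run.

    ``pka_table`` needs columns resname, resid and pka (segid optional).
    With the default rule a residue is protonated iff its pKa >= ``ph_mimic``
    (a side chain whose pKa lies above the ambient pH holds its proton);
    ``rule="pka_lt_ph"`` inverts the direction.  His residues are always
    recorded as neutral.  If ``structure_atoms`` is given, every acidic
    residue present in the structure must appear in the table; missing ones
    raise with the full list.
    """
    t = pka_table.copy()
    for col in ("resname", "resid", "pka"):
        if col not in t.columns:
            raise ValueError(f"pKa table lacks column {col!r}")
    if "segid" not in t.columns:
        t["segid"] = ""
    if structure_atoms is not None:
        acidic = structure_atoms[structure_atoms["resname"].isin(["GLU", "ASP"])]
        have = set(zip(t["resname"], t["resid"]))
        missing = sorted({(rn, int(ri)) for rn, ri in
                          zip(acidic["resname"], acidic["resid"])
                          if (rn, ri) not in have})
        if missing:
            names = [f"{_one_letter(rn)}{ri}" for rn, ri in missing]
            raise ValueError(f"pKa table misses acidic residues: {names}")
    if rule == "pka_ge_ph":
        prot = t["pka"] >= ph_mimic
    elif rule == "pka_lt_ph":
        prot = t["pka"] < ph_mimic
    else:
        raise ValueError(f"unknown rule {rule!r}")
    prot = prot & t["resname"].isin(["GLU", "ASP"])   # His fixed neutral
    t["protonated"] = prot
    return ProtonationState(
        table=t[["resname", "resid", "segid", "pka", "protonated"]],
        ph_mimic=ph_mimic, rule=rule,
    )


def site_distances(traj: Trajectory, residues, atom_class: str = "carboxylate",
                   frame: int = 0) -> pd.DataFrame:
    """Pairwise minimum side-chain atom distances between candidate-site
    residues, intra- and inter-subunit.

    ``residues`` is a list of (resname, resid) or (resname, resid, segid);
    without a segid the residue is taken in every subunit where it occurs.
    ``atom_class`` selects the atom set: "carboxylate" (Glu OE1/OE2, Asp
    OD1/OD2) or "side_chain" (the occupancy defaults).  Self-pairs are
    skipped; pairs with missing atoms are flagged and get NaN distance.
    """
    atom_map = (CARBOXYLATE_ATOMS if atom_class == "carboxylate"
                else SIDE_CHAIN_ATOMS)
    atoms = traj.atoms
    xyz = traj.coords[frame]
    entries = []
    for spec in residues:
        resname, resid = spec[0], spec[1]
        segids = ([spec[2]] if len(spec) > 2 else
                  sorted(atoms.loc[(atoms["resname"] == resname)
                                   & (atoms["resid"] == resid), "segid"]
                         .unique()))
        if not segids:
            segids = [None]
        for segid in segids:
            sel = (atoms["resname"] == resname) & (atoms["resid"] == resid)
            if segid is not None:
                sel &= atoms["segid"] == segid
            names = atom_map.get(resname, ())
            idx = atoms.index[sel & atoms["name"].isin(names)].to_numpy()
            entries.append((resname, resid, segid, idx))
    rows = []
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            rn_a, ri_a, sg_a, ia = entries[a]
            rn_b, ri_b, sg_b, ib = entries[b]
            if (ri_a, sg_a) == (ri_b, sg_b):
                continue
            if len(ia) == 0 or len(ib) == 0:
                dist, missing = float("nan"), True
            else:
                d = np.linalg.norm(xyz[ia][:, None, :] - xyz[ib][None, :, :],
                                   axis=-1)
                dist, missing = float(d.min()), False
            rows.append({"res_a": f"{rn_a}{ri_a}", "segid_a": sg_a,
                         "res_b": f"{rn_b}{ri_b}", "segid_b": sg_b,
                         "min_distance_A": dist, "missing_atoms": missing})
    return pd.DataFrame(rows, columns=["res_a", "segid_a", "res_b", "segid_b",
                                       "min_distance_A", "missing_atoms"])
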