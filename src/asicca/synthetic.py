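"""Synthetic TEVC cells, sweeps, activation datasets and toy trajectories.

The generator reproduces the statistical structure the downstream analysis
assumes for ASIC3-expressing Xenopus oocytes:

* per-cell Hill parameters (pH50, nH, I_max) drawn from per-condition
  Normal distributions (the wild-type defaults are pH50 7.48 +/- 0.14 at
  80 nM free Ca2+ and 6.14 +/- 0.11 at 2 mM, nH 2.08);
* transient ASIC current kinetics: fast activation (tau 0.2 s), slower
  desensitization (tau 2 s) and an optional sustained fraction, so the peak
  falls within the first second after the solution change;
* a slowly developing, acid-inhibited endogenous current (oocyte connexin
  hemichannels; amplitude class 93 +/- 50 nA, acid-inhibition pH50
  5.41 +/- 0.41, suppressed by Ca2+ with IC50 100 uM) whose magnitude still
  grows at the end of a 10 s application;
* Gaussian recording noise at 20 ms sampling;
* toy trajectories with Ca2+ ions planted near chosen residues at target
  contact occupancies.

Inward currents are negative.  Every generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .doseresponse import hill_activation
from .mdcontacts import SIDE_CHAIN_ATOMS, Trajectory
from .traces import ProtocolStep, Trace

__all__ = [
    "ConditionParams",
    "ConstructSpec",
    "CellParams",
    "wt_asic3",
    "construct_like",
    "gen_cell",
    "gen_cells",
    "gen_trace",
    "gen_activation_dataset",
    "build_toy_atoms",
    "gen_trajectory",
]

# endogenous (connexin-hemichannel) current model constants
ENDO_AMP_MEAN_NA = 93.0
ENDO_AMP_SD_NA = 50.0
ENDO_PH50_MEAN = 5.41
ENDO_PH50_SD = 0.41
ENDO_NH = 1.0
ENDO_TAU_S = 8.0
ENDO_CA_IC50_M = 100e-6

#: pore-block factor: I_max at 2 mM Ca2+ relative to 80 nM (35% block at pH 5)
PORE_BLOCK_FACTOR = 0.65


@dataclass(frozen=True)
class ConditionParams:
    """Generative per-condition parameters of one construct."""

    ca_free_m: float
    ph50_mean: float
    ph50_sd: float
    nh_mean: float = 2.08
    nh_sd: float = 0.15
    imax_mean_ua: float = 4.0
    imax_sd_ua: float = 1.0

    def __post_init__(self):
        if min(self.ph50_sd, self.nh_sd, self.imax_sd_ua) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 3.0 <= self.ph50_mean <= 9.0:
            raise ValueError("mean pH50 must lie in [3, 9]")
        if self.ca_free_m <= 0:
            raise ValueError("free Ca2+ must be positive")


@dataclass(frozen=True)
class ConstructSpec:
    """A channel construct with generative parameters per Ca2+ condition."""

    name: str
    conditions: dict          # label -> ConditionParams
    sustained_fraction: float = 0.0
    rundown: bool = False

    def __post_init__(self):
        if not 0.0 <= self.sustained_fraction <= 1.0:
            raise ValueError("sustained_fraction must lie in [0, 1]")
        if not self.conditions:
            raise ValueError("at least one Ca2+ condition is required")

    def condition_for_ca(self, ca_free_m: float) -> str:
        """Label of the condition nearest in log10 [Ca2+]."""
        labels = list(self.conditions)
        dist = [abs(np.log10(self.conditions[l].ca_free_m / ca_free_m))
                for l in labels]
        return labels[int(np.argmin(dist))]


def wt_asic3() -> ConstructSpec:
    """Wild-type ASIC3 generative defaults at 80 nM and 2 mM free Ca2+."""
    return ConstructSpec(
        name="ASIC3-WT",
        conditions={
            "80nM": ConditionParams(ca_free_m=80e-9, ph50_mean=7.48,
                                    ph50_sd=0.14, nh_mean=2.08,
                                    imax_mean_ua=4.0, imax_sd_ua=1.0),
            "2mM": ConditionParams(ca_free_m=2e-3, ph50_mean=6.14,
                                   ph50_sd=0.11, nh_mean=2.08,
                                   imax_mean_ua=4.0 * PORE_BLOCK_FACTOR,
                                   imax_sd_ua=1.0 * PORE_BLOCK_FACTOR),
        },
    )


def construct_like(name, ph50_80nm, sd_80nm=0.14, ph50_2mm=6.14, sd_2mm=0.11,
                   nh=2.08, sustained_fraction=0.0, rundown=False
                   ) -> ConstructSpec:
    """Convenience factory for mutant-like constructs that differ from the
    wild type mainly in their low-Ca2+ pH dependence."""
    base = wt_asic3()
    conds = {
        "80nM": replace(base.conditions["80nM"], ph50_mean=ph50_80nm,
                        ph50_sd=sd_80nm, nh_mean=nh),
        "2mM": replace(base.conditions["2mM"], ph50_mean=ph50_2mm,
                       ph50_sd=sd_2mm, nh_mean=nh),
    }
    return ConstructSpec(name=name, conditions=conds,
                         sustained_fraction=sustained_fraction,
                         rundown=rundown)


@dataclass
class CellParams:
    """Realized parameters of one simulated oocyte."""

    cell_id: str
    construct: str
    params: dict              # condition label -> dict(ph50, nh, imax_ua, ca_free_m)
    tau_act_s: float = 0.2
    tau_des_s: float = 2.0
    sustained_fraction: float = 0.0
    endo_amp_na: float = ENDO_AMP_MEAN_NA
    endo_ph50: float = ENDO_PH50_MEAN
    endo_nh: float = ENDO_NH
    noise_sd_na: float = 5.0

    def __post_init__(self):
        if not self.tau_act_s < self.tau_des_s:
            raise ValueError("activation must be faster than desensitization")
        if any(p["imax_ua"] <= 0 for p in self.params.values()):
            raise ValueError("I_max must be positive")
        if self.noise_sd_na < 0:
            raise ValueError("noise s.d. must be >= 0")

    def for_ca(self, ca_free_m: float) -> dict:
        labels = list(self.params)
        dist = [abs(np.log10(self.params[l]["ca_free_m"] / ca_free_m))
                for l in labels]
        return self.params[labels[int(np.argmin(dist))]]


def gen_cell(spec: ConstructSpec, seed, condition=None, noise_sd_na=5.0,
             cell_id=None) -> CellParams:
    """Draw one cell's realized parameters from a construct spec.

    With ``condition`` given, only that condition is realized; otherwise all.
    I_max across conditions shares one standard-normal deviate per cell, so
    the within-cell amplitude ratio between conditions concentrates at the
    ratio of the condition means (the pore-block factor for the WT defaults).
    """
    rng = np.random.default_rng(seed)
    labels = [condition] if condition is not None else list(spec.conditions)
    for lab in labels:
        if lab not in spec.conditions:
            raise KeyError(f"condition {lab!r} not in spec {spec.name!r}")
    z_imax = rng.standard_normal()
    params = {}
    for lab in labels:
        c = spec.conditions[lab]
        params[lab] = {
            "ph50": float(rng.normal(c.ph50_mean, c.ph50_sd)),
            "nh": float(max(rng.normal(c.nh_mean, c.nh_sd), 0.3)),
            "imax_ua": float(max(c.imax_mean_ua + z_imax * c.imax_sd_ua, 0.05)),
            "ca_free_m": c.ca_free_m,
        }
    return CellParams(
        cell_id=cell_id or f"{spec.name}-c{int(seed) % 10 ** 6}",
        construct=spec.name, params=params,
        sustained_fraction=spec.sustained_fraction,
        endo_amp_na=float(abs(rng.normal(ENDO_AMP_MEAN_NA, ENDO_AMP_SD_NA))),
        endo_ph50=float(rng.normal(ENDO_PH50_MEAN, ENDO_PH50_SD)),
        noise_sd_na=noise_sd_na,
    )


def non_injected_cell(seed, noise_sd_na=0.0, cell_id="non-injected") -> CellParams:
    """A control oocyte without ASIC expression: only the endogenous
    low-Ca2+-activated current (and recording noise) remains."""
    rng = np.random.default_rng(seed)
    params = {lab: {"ph50": c.ph50_mean, "nh": c.nh_mean,
                    "imax_ua": 1e-6, "ca_free_m": c.ca_free_m}
              for lab, c in wt_asic3().conditions.items()}
    return CellParams(
        cell_id=cell_id, construct="non-injected", params=params,
        endo_amp_na=float(abs(rng.normal(ENDO_AMP_MEAN_NA, ENDO_AMP_SD_NA))),
        endo_ph50=float(rng.normal(ENDO_PH50_MEAN, ENDO_PH50_SD)),
        noise_sd_na=noise_sd_na,
    )


def gen_cells(spec: ConstructSpec, n_cells: int, seed, condition=None,
              noise_sd_na=5.0) -> list:
    """Draw ``n_cells`` independent cells, deterministically from ``seed``."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_cells)
    return [gen_cell(spec, s, condition=condition, noise_sd_na=noise_sd_na,
                     cell_id=f"{spec.name}-c{i:03d}")
            for i, s in enumerate(seeds)]


def _ca_gate(ca_m):
    # fractional activation of the endogenous current by Ca2+ removal
    return ENDO_CA_IC50_M / (ENDO_CA_IC50_M + ca_m)


def _acid_gate(ph, ph50, nh):
    # endogenous current is acid-INHIBITED: full at alkaline pH
    return 1.0 / (1.0 + 10.0 ** ((ph50 - ph) * nh))


def gen_trace(cell: CellParams, step: ProtocolStep, seed=0,
              sampling_s: float = 0.02, pre_switch_s: float = 2.0) -> Trace:
    """Simulate one sweep of current (nA) for a cell under a protocol step.

    The ASIC component is driven by the change in Hill activation between the
    conditioning and the stimulation solution (so an identical solution
    produces exactly zero ASIC current) and follows
    ``(1 - exp(-t/tau_act)) * ((1 - s) exp(-t/tau_des) + s)``.
    The endogenous component is a slow saturating ramp
    ``A (1 - exp(-t/8 s))`` gated by acid inhibition and by the drop of the
    Ca2+ suppression between the two solutions.  Gaussian noise is added at
    every sample.
    """
    if sampling_s <= 0:
        raise ValueError("sampling interval must be positive")
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_switch_s / sampling_s))
    n_post = int(round(step.duration_s / sampling_s)) + 1
    t = (np.arange(-n_pre, n_post) * sampling_s)
    i = np.zeros_like(t)
    post = t >= 0
    tp = t[post]

    p_stim = cell.for_ca(step.stimulation_ca_m)
    p_cond = cell.for_ca(step.conditioning_ca_m)
    f_stim = hill_activation(step.stimulation_ph, p_stim["ph50"], p_stim["nh"])
    f_cond = hill_activation(step.conditioning_ph, p_cond["ph50"], p_cond["nh"])
    drive = float(np.clip(f_stim - f_cond, 0.0, 1.0))
    s = cell.sustained_fraction
    kin = (1.0 - np.exp(-tp / cell.tau_act_s)) * (
        (1.0 - s) * np.exp(-tp / cell.tau_des_s) + s)
    i[post] -= p_stim["imax_ua"] * 1000.0 * drive * kin

    endo_drive = max(_ca_gate(step.stimulation_ca_m)
                     - _ca_gate(step.conditioning_ca_m), 0.0)
    endo_gate = _acid_gate(step.stimulation_ph, cell.endo_ph50, cell.endo_nh)
    i[post] -= (cell.endo_amp_na * endo_drive * endo_gate
                * (1.0 - np.exp(-tp / ENDO_TAU_S)))

    if cell.noise_sd_na > 0:
        i = i + rng.normal(0.0, cell.noise_sd_na, size=i.shape)
    return Trace(t, i, step, cell_id=cell.cell_id, construct=cell.construct)


def gen_activation_dataset(spec: ConstructSpec, condition: str, ph_list,
                           n_cells: int, seed, noise_sd: float = 0.02,
                           via_traces: bool = False,
                           conditioning_ph: float = 7.4,
                           conditioning_ca_m: float = 2e-3) -> pd.DataFrame:
    """Per-cell normalized pH-activation datasets as a tidy DataFrame.

    Each cell's responses are divided by its largest observed peak (the
    plotting convention for relative currents).  In the default direct mode
    the response at each pH is the cell's Hill activation value plus Gaussian
    noise of s.d. ``noise_sd`` (relative units); with ``via_traces=True`` full
    sweeps are simulated and peak amplitudes extracted.

    Columns: cell_id, construct, condition, ph, ca_free_M, response.
    """
    ph_list = list(ph_list)
    if len(ph_list) == 0:
        raise ValueError("pH list is empty")
    if len(ph_list) < 4:
        raise ValueError("need >= 4 pH points spanning the activation curve")
    if condition not in spec.conditions:
        raise KeyError(f"condition {condition!r} not in spec {spec.name!r}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    # cells reproduce gen_cells(spec, n_cells, seed); noise uses a distinct
    # stream so the two draws cannot collide
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    ca_m = spec.conditions[condition].ca_free_m
    cells = gen_cells(spec, n_cells, seed, condition=None)
    rows = []
    for cell in cells:
        if via_traces:
            from .traces import extract_features

            peaks = []
            for ph in ph_list:
                step = ProtocolStep(conditioning_ph=conditioning_ph,
                                    conditioning_ca_m=conditioning_ca_m,
                                    stimulation_ph=ph, stimulation_ca_m=ca_m)
                tr = gen_trace(cell, step, seed=rng.integers(2 ** 31))
                peaks.append(abs(extract_features(tr).peak_na))
            resp = np.asarray(peaks)
        else:
            p = cell.params[condition]
            resp = hill_activation(np.asarray(ph_list, dtype=float),
                                   p["ph50"], p["nh"])
            if noise_sd > 0:
                resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
        top = np.max(np.abs(resp))
        if top > 0:
            resp = resp / top
        for ph, r in zip(ph_list, resp):
            rows.append({"cell_id": cell.cell_id, "construct": spec.name,
                         "condition": condition, "ph": float(ph),
                         "ca_free_M": ca_m, "response": float(r)})
    return pd.DataFrame(rows)


# --- toy trajectories -------------------------------------------------------

_RES_BY_LETTER = {"E": "GLU", "D": "ASP", "N": "ASN", "T": "THR", "H": "HIS"}

# local side-chain atom offsets (A) around each residue anchor point
_LOCAL_GEOMETRY = {
    "GLU": {"CA": (0, 0, 0), "CD": (1.5, 0, 0),
            "OE1": (2.2, 0.9, 0), "OE2": (2.2, -0.9, 0)},
    "ASP": {"CA": (0, 0, 0), "CG": (1.4, 0, 0),
            "OD1": (2.1, 0.9, 0), "OD2": (2.1, -0.9, 0)},
    "ASN": {"CA": (0, 0, 0), "CG": (1.4, 0, 0),
            "OD1": (2.1, 0.9, 0), "ND2": (2.1, -0.9, 0)},
    "THR": {"CA": (0, 0, 0), "CB": (1.4, 0, 0), "OG1": (2.1, 0.7, 0)},
    "HIS": {"CA": (0, 0, 0), "CG": (1.4, 0, 0),
            "ND1": (2.2, 0.8, 0), "NE2": (2.9, -0.5, 0)},
}

_RESIDUE_SPACING_A = 20.0


def _parse_residue_key(key):
    """Accept 'E81', 'E81:A', ('GLU', 81) or ('GLU', 81, 'A')."""
    if isinstance(key, str):
        segid = "A"
        if ":" in key:
            key, segid = key.split(":")
        resname = _RES_BY_LETTER.get(key[0].upper())
        if resname is None:
            raise ValueError(f"unknown residue letter in {key!r}")
        return resname, int(key[1:]), segid
    if len(key) == 2:
        return key[0], int(key[1]), "A"
    return key[0], int(key[1]), key[2]


def build_toy_atoms(residues) -> tuple:
    """Lay out toy residues on a widely spaced line; returns (atoms, coords).

    ``residues`` is a list of residue keys (see :func:`gen_trajectory`).
    Residue anchors are 20 A apart so a Ca2+ near one residue can never sit
    within two cutoffs of another.
    """
    rows, xyz = [], []
    for i, key in enumerate(residues):
        resname, resid, segid = _parse_residue_key(key)
        base = np.array([i * _RESIDUE_SPACING_A, 0.0, 0.0])
        for name, off in _LOCAL_GEOMETRY[resname].items():
            rows.append({"name": name, "resname": resname,
                         "resid": resid, "segid": segid})
            xyz.append(base + np.asarray(off, dtype=float))
    return pd.DataFrame(rows), np.asarray(xyz)


def gen_trajectory(plan: dict, n_frames: int, seed, residues=None,
                   cutoff: float = 2.5) -> Trajectory:
    """Toy trajectory with Ca2+ ions planted at target contact occupancies.

    ``plan`` maps residue keys ('E81', 'D439:B', or (resname, resid[, segid])
    tuples) to target occupancies in [0, 1].  Each planted residue gets a
    dedicated Ca2+ ion: in a Bernoulli(occupancy) fraction of frames the ion
    sits strictly within ``cutoff`` of one of the residue's designated
    side-chain atoms; in the remaining frames it is parked more than twice
    the cutoff away from every side-chain atom.  ``residues`` may list extra
    (unbound) residues to include.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    keys = [_parse_residue_key(k) for k in plan]
    if len(set(keys)) != len(keys):
        raise ValueError("plan contains overlapping residue entries")
    for k, occ in plan.items():
        if not 0.0 <= occ <= 1.0:
            raise ValueError(f"occupancy for {k!r} must lie in [0, 1]")
    all_res = list(plan) + [r for r in (residues or [])
                            if _parse_residue_key(r) not in keys]
    if not all_res:
        raise ValueError("no residues to build the system from")
    atoms, base_xyz = build_toy_atoms(all_res)
    rng = np.random.default_rng(seed)

    # with an empty plan a single spectator ion is parked far from everything
    # so occupancy is well defined (and zero) for every residue
    n_ions = max(len(plan), 1)
    ion_rows = [{"name": "CA", "resname": "CA", "resid": 9000 + j,
                 "segid": "ION"} for j in range(n_ions)]
    atoms = pd.concat([atoms, pd.DataFrame(ion_rows)], ignore_index=True)

    coords = np.empty((n_frames, len(atoms), 3))
    coords[:, : len(base_xyz), :] = base_xyz[None]
    if not plan:
        coords[:, len(base_xyz), :] = np.array([-40.0 * cutoff, 0.0, 0.0])
    for j, (key, occ) in enumerate(plan.items()):
        resname, resid, segid = _parse_residue_key(key)
        sel = ((atoms["resname"] == resname) & (atoms["resid"] == resid)
               & (atoms["segid"] == segid)
               & atoms["name"].isin(SIDE_CHAIN_ATOMS[resname]))
        sc_idx = atoms.index[sel].to_numpy()
        anchor = base_xyz[sc_idx].mean(axis=0)
        bound = rng.random(n_frames) < occ
        direction = rng.standard_normal((n_frames, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        near_atom = base_xyz[rng.choice(sc_idx, size=n_frames)]
        r_in = rng.uniform(0.4, 0.95, n_frames) * cutoff
        r_out = rng.uniform(2.8, 3.6, n_frames) * cutoff
        pos = np.where(bound[:, None],
                       near_atom + direction * r_in[:, None],
                       anchor + direction * r_out[:, None])
        coords[:, len(base_xyz) + j, :] = pos
    return Trajectory(coords, atoms)
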