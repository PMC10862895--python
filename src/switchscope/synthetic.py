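"""Seeded synthetic inputs for every analysis stage.

Forward models mirror the fitted equations (Boltzmann melt sigmoid,
one-phase association, saturation-transfer integral attenuation) and a
toy-trajectory constructor realizes prescribed H-bond occupancies,
closest-residue contact fractions and positional jitter by explicit
geometric placement. These are fixtures: no force field, no thermostat,
no solvent.

Scheduled occupancies are realized by exact frame counting
(``round(f * n_frames)``) with deterministic frame assignment, so
detector tests can assert equality rather than statistical closeness;
a stochastic per-frame mode is available for replica-variability
studies. Bonded H-bond geometry is placed at 2.0 A / 180 deg and broken
geometry at 4.0 A, leaving margin to the 2.4 A / 120 deg detection
cutoffs for small jitter (<= ~0.1 A; larger jitter can flip frames
across the distance cutoff).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConstructionError, SpecValidationError
from .kinetics import KineticTrace, one_phase_association
from .stdnmr import STDIntegralRecord, SampleContext
from .thermostability import MeltingCurve, boltzmann
from .traj.topology import Atom, Topology, Trajectory

__all__ = [
    "MeltGenSpec", "KineticGenSpec", "STDGenSpec", "ToyTrajectorySpec",
    "STDTable", "generate_melting_curves", "generate_kinetic_trace",
    "generate_std_table", "generate_toy_trajectories", "make_toy_topology",
    "write_spec_json", "read_spec_json",
]

# geometry constants for scheduled H-bonds: formed well inside the
# 2.4 A / 120 deg detection cutoffs, broken well outside
HBOND_ON_DISTANCE = 2.0
HBOND_OFF_DISTANCE = 4.0
PROXIMITY_CONTACT_DISTANCE = 2.5
RESIDUE_SPACING = 30.0
PROTON_SPACING = 12.0
NUCLEOTIDE_X = -60.0


# ---------------------------------------------------------------------------
# Generator specs

@dataclass(frozen=True)
class MeltGenSpec:
    """Parameters of a synthetic melting-curve set (temperatures in deg C)."""

    tm_true: float
    slope_true: float
    top: float = 1.0
    bottom: float = 0.0
    t_start: float = 25.0
    t_stop: float = 89.0
    t_step: float = 1.0
    noise_sd: float = 0.0  # fraction of |top - bottom|
    replicates: int = 1
    seed: int = 0
    variant: str = ""
    nucleotide: str = ""

    def __post_init__(self):
        if not (self.t_start < self.tm_true < self.t_stop):
            raise SpecValidationError(
                "tm_true", f"must lie inside ({self.t_start}, {self.t_stop})")
        if self.slope_true <= 0:
            raise SpecValidationError("slope_true", "must be > 0")
        if self.t_step <= 0:
            raise SpecValidationError("t_step", "must be > 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")
        if self.replicates < 1:
            raise SpecValidationError("replicates", "must be >= 1")


@dataclass(frozen=True)
class KineticGenSpec:
    """Synthetic one-phase association trace.

    ``k_true`` is in 1/min; the output trace carries time in seconds
    (acquisition cadence ``t_step`` seconds over ``t_total`` minutes).
    ``noise_sd`` is in absolute intensity units.
    """

    y0: float
    plateau: float
    k_true: float
    t_step: float = 12.0
    t_total: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0
    variant: str = ""

    def __post_init__(self):
        if self.t_step <= 0:
            raise SpecValidationError("t_step", "must be > 0")
        if self.t_total <= 0:
            raise SpecValidationError("t_total", "must be > 0")
        if self.k_true <= 0:
            raise SpecValidationError("k_true", "must be > 0")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd", "must be >= 0")


@dataclass(frozen=True)
class STDGenSpec:
    """Forward model inputs for a saturation-transfer integral table.

    ``epitope_weights`` are per-proton transfer efficiencies in [0, 1];
    Isat = I0 * (1 - w) plus Gaussian noise of sd I0/snr.
    """

    epitope_weights: dict
    i0: dict
    snr: dict
    ligand_conc: float = 2000.0
    protein_conc: float = 40.0
    seed: int = 0
    nucleotide: str = "GDP"
    variant: str = ""

    def __post_init__(self):
        for label, w in self.epitope_weights.items():
            if not (0.0 <= w <= 1.0):
                raise SpecValidationError(
                    "epitope_weights", f"weight for {label!r} outside [0, 1]: {w}")
        for label in self.epitope_weights:
            if label not in self.i0:
                raise SpecValidationError("i0", f"missing integral for {label!r}")
            if label not in self.snr:
                raise SpecValidationError("snr", f"missing SNR for {label!r}")
            if self.i0[label] <= 0:
                raise SpecValidationError("i0", f"{label!r} must be > 0")
            if self.snr[label] <= 0:
                raise SpecValidationError("snr", f"{label!r} must be > 0")
        if self.ligand_conc <= 0:
            raise SpecValidationError("ligand_conc", "must be > 0")
        if self.protein_conc <= 0:
            raise SpecValidationError("protein_conc", "must be > 0")


@dataclass(frozen=True)
class ToyTrajectorySpec:
    """Prescription for geometric toy trajectories over a toy topology.

    ``hbond_schedule`` maps (donor_residue, acceptor_residue) to a target
    occupancy; ``proximity_schedule`` maps (proton_key, residue_id) to a
    target closest-residue fraction, where ``proton_key`` is a label
    ("a") or a label.atom-index ("d.0") for one of several equivalent
    protons. With ``exact_counts`` targets are realized by exact frame
    counting; otherwise by independent per-frame draws.
    """

    topology: Topology
    hbond_schedule: dict = field(default_factory=dict)
    proximity_schedule: dict = field(default_factory=dict)
    jitter_sd: float = 0.0
    n_frames: int = 100
    n_replicas: int = 100
    seed: int = 0
    exact_counts: bool = True
    frame_interval_ps: float = 1.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SpecValidationError("n_frames", "must be >= 1")
        if self.n_replicas < 1:
            raise SpecValidationError("n_replicas", "must be >= 1")
        if self.jitter_sd < 0:
            raise SpecValidationError("jitter_sd", "must be >= 0")
        for pair, f in self.hbond_schedule.items():
            if not (0.0 <= f <= 1.0):
                raise SpecValidationError(
                    "hbond_schedule", f"occupancy for {pair} outside [0, 1]: {f}")
        sums: dict = {}
        for (key, res), f in self.proximity_schedule.items():
            if not (0.0 <= f <= 1.0):
                raise SpecValidationError(
                    "proximity_schedule", f"fraction for ({key}, {res}) outside [0, 1]: {f}")
            sums[key] = sums.get(key, 0.0) + f
        for key, total in sums.items():
            if total > 1.0 + 1e-9:
                raise SpecValidationError(
                    "proximity_schedule",
                    f"fractions for proton {key!r} sum to {total} > 1")


# ---------------------------------------------------------------------------
# Curve / trace / table generators

def generate_melting_curves(spec: MeltGenSpec) -> list[MeltingCurve]:
    """Replicate sigmoidal melting curves differing only by iid noise."""
    rng = np.random.default_rng(spec.seed)
    grid = np.arange(spec.t_start, spec.t_stop + spec.t_step / 2, spec.t_step)
    clean = boltzmann(grid, spec.tm_true, spec.slope_true, spec.top, spec.bottom)
    amplitude = abs(spec.top - spec.bottom)
    curves = []
    for rep in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd * amplitude, size=grid.shape) \
            if spec.noise_sd > 0 else np.zeros_like(grid)
        curves.append(MeltingCurve(grid, clean + noise, variant=spec.variant,
                                   nucleotide=spec.nucleotide, replicate=rep))
    return curves


def generate_kinetic_trace(spec: KineticGenSpec) -> KineticTrace:
    """Single-exponential fluorescence rise (or fall) with Gaussian noise.

    Time axis in seconds; the generating rate ``k_true`` (1/min) is
    applied as ``k_true / 60`` per second.
    """
    rng = np.random.default_rng(spec.seed)
    t_s = np.arange(0.0, spec.t_total * 60.0 + spec.t_step / 2, spec.t_step)
    clean = one_phase_association(t_s, spec.y0, spec.plateau, spec.k_true / 60.0)
    noise = rng.normal(0.0, spec.noise_sd, size=t_s.shape) if spec.noise_sd > 0 \
        else np.zeros_like(t_s)
    return KineticTrace(t_s, clean + noise, variant=spec.variant)


@dataclass(frozen=True)
class STDTable:
    """Generated integral records plus the sample context they belong to."""

    records: tuple
    context: SampleContext


def generate_std_table(spec: STDGenSpec) -> STDTable:
    """Integral records with Isat = I0 (1 - w) + N(0, I0/snr)."""
    rng = np.random.default_rng(spec.seed)
    ctx = SampleContext(spec.ligand_conc, spec.protein_conc,
                        nucleotide=spec.nucleotide, variant=spec.variant)
    records = []
    for label in sorted(spec.epitope_weights):
        i0 = spec.i0[label]
        snr = spec.snr[label]
        isat = i0 * (1.0 - spec.epitope_weights[label]) + rng.normal(0.0, i0 / snr)
        records.append(STDIntegralRecord(label, i0, float(isat), snr))
    return STDTable(tuple(records), ctx)


# ---------------------------------------------------------------------------
# Toy topology and trajectories

def make_toy_topology(protein_residues, proton_labels: Mapping[str, int] | None = None,
                      nucleotide_residue_id: int = 900, n_side_h: int = 2) -> Topology:
    """Minimal explicit-H topology for toy trajectories.

    Each protein residue gets a backbone donor group (N, H), a carbon
    anchor (CA), an acceptor oxygen (O) and ``n_side_h`` side hydrogens
    (HG0.., bonded to carbon so they never act as H-bond donor
    hydrogens); side hydrogens let one residue be the closest contact of
    several nucleotide protons in the same frame. The nucleotide residue
    gets one carbon anchor and hydrogen per labeled proton atom;
    ``proton_labels`` maps label -> number of equivalent atoms (default
    ``{"a": 1, "b": 1, "c": 1, "d": 2}``).
    """
    if proton_labels is None:
        proton_labels = {"a": 1, "b": 1, "c": 1, "d": 2}
    atoms, bonds = [], []
    next_id = 1
    for res in protein_residues:
        res = int(res)
        n_id, h_id, ca_id, o_id = range(next_id, next_id + 4)
        atoms += [
            Atom(n_id, "N", "N", res, "ALA"),
            Atom(h_id, "H", "H", res, "ALA"),
            Atom(ca_id, "CA", "C", res, "ALA"),
            Atom(o_id, "O", "O", res, "ALA"),
        ]
        bonds += [(n_id, h_id), (n_id, ca_id), (ca_id, o_id)]
        next_id += 4
        for k in range(n_side_h):
            atoms.append(Atom(next_id, f"HG{k}", "H", res, "ALA"))
            bonds.append((ca_id, next_id))
            next_id += 1
    labels: dict = {}
    for label in sorted(proton_labels):
        labels[label] = []
        for j in range(proton_labels[label]):
            c_id, h_id = next_id, next_id + 1
            atoms += [
                Atom(c_id, f"C{label}{j}", "C", nucleotide_residue_id, "NUC"),
                Atom(h_id, f"H{label}{j}", "H", nucleotide_residue_id, "NUC"),
            ]
            bonds.append((c_id, h_id))
            labels[label].append(h_id)
            next_id += 2
    return Topology(atoms, bonds=bonds, nucleotide_protons=labels)


def _base_coords(topology: Topology) -> np.ndarray:
    """Reference frame: residues on a sparse grid, nucleotide set apart."""
    coords = np.zeros((len(topology), 3))
    protein_residues = sorted({a.residue_id for a in topology.atoms
                               if a.residue_id not in _ligand_residues(topology)})
    res_x = {res: i * RESIDUE_SPACING for i, res in enumerate(protein_residues)}
    offsets = {"N": (0.0, 0.0, 0.0), "H": (1.0, 0.0, 0.0), "CA": (0.0, 4.0, 0.0),
               "O": (0.0, 0.0, 3.0)}
    proton_slot = 0
    for i, a in enumerate(topology.atoms):
        if a.residue_id in res_x:
            if a.name.startswith("HG"):
                k = int(a.name[2:] or 0)
                off = (1.0, 4.0 + 0.8 * k, 0.0)
            else:
                off = offsets.get(a.name, (0.0, -3.0, 0.0))
            coords[i] = (res_x[a.residue_id] + off[0], off[1], off[2])
        else:  # nucleotide: anchors/protons stacked with wide vertical spacing
            if a.element == "C":
                coords[i] = (NUCLEOTIDE_X, proton_slot * PROTON_SPACING, 0.0)
            else:
                coords[i] = (NUCLEOTIDE_X + 1.09, proton_slot * PROTON_SPACING, 0.0)
                proton_slot += 1
    return coords


def _ligand_residues(topology: Topology) -> set:
    return {topology.atoms[topology.index_of(aid)].residue_id
            for ids in topology.nucleotide_protons.values() for aid in ids}


def _atom_of(topology: Topology, residue_id: int, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.residue_id == residue_id and a.name == name:
            return i
    raise ConstructionError(
        f"topology lacks atom {name!r} in residue {residue_id}")


def _resolve_proximity_schedule(spec: ToyTrajectorySpec) -> dict:
    """Expand schedule keys to per-proton-atom target lists.

    Returns atom_index -> list of (residue_id, fraction) sorted by
    residue id. A bare label applies the same fraction to each of its
    equivalent atoms; ``label.j`` addresses one atom.
    """
    topo = spec.topology
    per_atom: dict = {}
    for (key, res), f in spec.proximity_schedule.items():
        if "." in str(key):
            label, j = str(key).rsplit(".", 1)
            if label not in topo.nucleotide_protons:
                raise ConstructionError(f"unknown proton label {label!r} in schedule")
            ids = topo.nucleotide_protons[label]
            try:
                targets = [ids[int(j)]]
            except (IndexError, ValueError):
                raise ConstructionError(
                    f"proton key {key!r} does not address an atom of label {label!r}")
        else:
            if key not in topo.nucleotide_protons:
                raise ConstructionError(f"unknown proton label {key!r} in schedule")
            targets = topo.nucleotide_protons[key]
        for aid in targets:
            per_atom.setdefault(topo.index_of(aid), []).append((int(res), float(f)))
    return {idx: sorted(pairs) for idx, pairs in per_atom.items()}


def _frame_blocks(pairs, n_frames: int, exact: bool, rng) -> list:
    """Assign each frame a residue id (or None) matching target fractions."""
    assignment: list = [None] * n_frames
    if exact:
        start = 0
        for res, f in pairs:
            n = round(f * n_frames)
            for i in range(start, min(start + n, n_frames)):
                assignment[i] = res
            start += n
    else:
        residues = [res for res, _ in pairs]
        probs = [f for _, f in pairs]
        probs.append(max(0.0, 1.0 - sum(probs)))
        choices = rng.choice(len(probs), size=n_frames, p=np.array(probs) / sum(probs))
        for i, c in enumerate(choices):
            assignment[i] = residues[c] if c < len(residues) else None
    return assignment


def generate_toy_trajectories(spec: ToyTrajectorySpec) -> list[Trajectory]:
    """Construct replica trajectories realizing the scheduled geometry.

    Frames satisfy each scheduled H-bond (2.0 A / 180 deg) in its target
    fraction of frames and break it (4.0 A) otherwise; each scheduled
    proton-residue pair is made the unique closest protein proton within
    radius in its target fraction of frames. Gaussian jitter of sd
    ``jitter_sd`` is then added to every coordinate. Identical spec and
    seed give identical output.
    """
    topo = spec.topology
    base = _base_coords(topo)
    ligand = _ligand_residues(topo)

    # resolve H-bond schedule -> (donor H index, acceptor O index, fraction)
    donors_used: dict = {}
    acceptors_used: dict = {}
    hb = []
    for (d_res, a_res), f in sorted(spec.hbond_schedule.items()):
        if d_res in ligand or a_res in ligand:
            raise ConstructionError(
                f"H-bond schedule references ligand residue in pair ({d_res}, {a_res})")
        if d_res in donors_used:
            raise ConstructionError(
                "conflicting H-bond schedule: residue cannot donate its single "
                f"backbone H to both {donors_used[d_res]} and {a_res}",
                conflicts=[(d_res, donors_used[d_res]), (d_res, a_res)])
        if a_res in acceptors_used:
            raise ConstructionError(
                "conflicting H-bond schedule: residue cannot accept on its single "
                f"O from both {acceptors_used[a_res]} and {d_res}",
                conflicts=[(acceptors_used[a_res], a_res), (d_res, a_res)])
        donors_used[d_res] = a_res
        acceptors_used[a_res] = d_res
        hb.append((_atom_of(topo, d_res, "H"), _atom_of(topo, a_res, "O"), f))

    prox = _resolve_proximity_schedule(spec)
    side_h: dict = {}
    for pairs in prox.values():
        for res, _f in pairs:
            if res not in side_h:
                side_h[res] = sorted(
                    topo.index_of(a.atom_id) for a in topo.atoms
                    if a.residue_id == res and a.name.startswith("HG"))
                if not side_h[res]:
                    raise ConstructionError(
                        f"residue {res} has no side hydrogens for proximity placement")

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_replicas)
    trajectories = []
    for rep in range(spec.n_replicas):
        rng = np.random.default_rng(seeds[rep])
        hb_assign = [(h_idx, o_idx,
                      _frame_blocks([(1, f)], spec.n_frames, spec.exact_counts, rng))
                     for h_idx, o_idx, f in hb]
        prox_assign = {p_idx: _frame_blocks(pairs, spec.n_frames,
                                            spec.exact_counts, rng)
                       for p_idx, pairs in prox.items()}

        # a residue has a fixed number of side hydrogens: a frame where more
        # proton atoms claim it than it has hydrogens is unsatisfiable
        conflicts = []
        placements: list = []  # (frame, proton_atom_idx, side_h_idx)
        for fidx in range(spec.n_frames):
            claims: dict = {}
            for p_idx, assignment in sorted(prox_assign.items()):
                res = assignment[fidx]
                if res is not None:
                    claims.setdefault(res, []).append(p_idx)
            for res, claimants in claims.items():
                if len(claimants) > len(side_h[res]):
                    conflicts.append((fidx, res, tuple(claimants)))
                else:
                    placements.extend(
                        (fidx, p_idx, side_h[res][j])
                        for j, p_idx in enumerate(claimants))
        if conflicts:
            raise ConstructionError(
                "unsatisfiable proximity schedule: residue claimed by more "
                f"proton atoms than it has side hydrogens, e.g. {conflicts[:5]}"
                + ("..." if len(conflicts) > 5 else ""),
                conflicts=conflicts)

        coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
        for h_idx, o_idx, assignment in hb_assign:
            h_pos = base[h_idx]
            on = np.array([a is not None for a in assignment])
            # donor N->H axis is +x; place acceptor along it for a 180 deg bond
            coords[on, o_idx] = h_pos + np.array([HBOND_ON_DISTANCE, 0.0, 0.0])
            coords[~on, o_idx] = h_pos + np.array([HBOND_OFF_DISTANCE, 0.0, 0.0])
        contact_offset = np.array([0.0, 0.0, PROXIMITY_CONTACT_DISTANCE])
        for fidx, p_idx, h_idx in placements:
            coords[fidx, h_idx] = base[p_idx] + contact_offset
        if spec.jitter_sd > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sd, size=coords.shape)
        trajectories.append(Trajectory(topo, coords,
                                       frame_interval_ps=spec.frame_interval_ps,
                                       replica_id=rep))
    return trajectories


# ---------------------------------------------------------------------------
# Spec (de)serialization

_SPEC_TYPES = {"MeltGenSpec": MeltGenSpec, "KineticGenSpec": KineticGenSpec,
               "STDGenSpec": STDGenSpec}


def write_spec_json(spec, path) -> None:
    """Serialize a melt/kinetic/STD generator spec to JSON."""
    name = type(spec).__name__
    if name not in _SPEC_TYPES:
        raise SpecValidationError("spec", f"{name} is not JSON-serializable")
    payload = {"spec_type": name, **asdict(spec)}
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=2)


def read_spec_json(path):
    with open(path) as fh:
        payload = json.load(fh)
    name = payload.pop("spec_type", None)
    if name not in _SPEC_TYPES:
        raise SpecValidationError("spec_type", f"unknown spec type {name!r}")
    return _SPEC_TYPES[name](**payload)
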