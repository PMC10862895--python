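"""Topology and trajectory containers with multi-model PDB serialization.

Coordinates are in Angstrom throughout. Residue numbering follows the
1-based author numbering of the source structure; no renumbering is
performed. Nucleotide protons of interest are labeled in the topology
(a label may map to several chemically equivalent atoms, e.g. the two
'd' protons).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from ..errors import ConfigurationError, InputError

__all__ = ["Atom", "Topology", "Trajectory", "write_trajectory_pdb",
           "read_trajectory_pdb"]


@dataclass(frozen=True)
class Atom:
    atom_id: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str = "A"


@dataclass
class Topology:
    """Atom identities plus optional bonds and labeled nucleotide protons.

    ``nucleotide_protons`` maps a proton label to the atom_ids of its
    (possibly several equivalent) hydrogen atoms. All atom_ids must be
    unique and every labeled proton must be a hydrogen.
    """

    atoms: list
    bonds: list | None = None
    nucleotide_protons: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise InputError("atom_ids must be unique")
        self._index = {a.atom_id: i for i, a in enumerate(self.atoms)}
        for label, atom_ids in self.nucleotide_protons.items():
            for aid in atom_ids:
                if aid not in self._index:
                    raise ConfigurationError(
                        f"labeled proton {label!r} references unknown atom_id {aid}")
                if self.atoms[self._index[aid]].element != "H":
                    raise ConfigurationError(
                        f"labeled proton {label!r} atom_id {aid} is not hydrogen")

    def __len__(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        return self._index[atom_id]

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([a.residue_id for a in self.atoms])

    def bonded_neighbors(self, atom_id: int) -> list[int]:
        if self.bonds is None:
            return []
        out = []
        for a, b in self.bonds:
            if a == atom_id:
                out.append(b)
            elif b == atom_id:
                out.append(a)
        return out


@dataclass
class Trajectory:
    """Frames of coordinates (n_frames, n_atoms, 3) over a fixed topology."""

    topology: Topology
    coords: np.ndarray
    frame_interval_ps: float = 1.0
    replica_id: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise InputError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology size {len(self.topology)}")
        if self.coords.shape[0] < 1:
            raise InputError("trajectory needs >= 1 frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _to_atom_array(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = len(topology)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain for a in topology.atoms])
    arr.res_id = np.array([a.residue_id for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.array([a.residue_name in ("GDP", "GTP", "NUC", "LIG")
                           for a in topology.atoms])
    return arr


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write as MODEL/ENDMDL multi-model PDB with populated element column.

    Labels and bonds are written to a JSON sidecar ``<path>.labels.json``
    since the PDB format cannot carry them losslessly.
    """
    frames = [_to_atom_array(traj.topology, traj.coords[i])
              for i in range(traj.n_frames)]
    stack = struc.stack(frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    sidecar = {
        "nucleotide_protons": {
            label: [int(i) for i in ids]
            for label, ids in traj.topology.nucleotide_protons.items()
        },
        "bonds": [[int(a), int(b)] for a, b in (traj.topology.bonds or [])],
        "atom_ids": [int(a.atom_id) for a in traj.topology.atoms],
        "frame_interval_ps": traj.frame_interval_ps,
        "replica_id": traj.replica_id,
    }
    Path(f"{path}.labels.json").write_text(json.dumps(sidecar, sort_keys=True))


def read_trajectory_pdb(path, nucleotide_protons: Mapping[str, Sequence[int]] | None = None
                        ) -> Trajectory:
    """Read a multi-model PDB trajectory (plus JSON sidecar when present).

    Frames with missing atoms are rejected by the underlying reader
    (model atom counts must agree). ``nucleotide_protons`` overrides the
    sidecar labels when given.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    n_atoms = stack.array_length()

    sidecar_path = Path(f"{path}.labels.json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    atom_ids = sidecar.get("atom_ids", list(range(1, n_atoms + 1)))
    if len(atom_ids) != n_atoms:
        raise InputError("sidecar atom_id count does not match PDB atom count")
    labels = nucleotide_protons or sidecar.get("nucleotide_protons", {})
    bonds = [tuple(b) for b in sidecar.get("bonds", [])] or None

    atoms = [Atom(int(atom_ids[i]), str(stack.atom_name[i]), str(stack.element[i]),
                  int(stack.res_id[i]), str(stack.res_name[i]), str(stack.chain_id[i]))
             for i in range(n_atoms)]
    topo = Topology(atoms, bonds=bonds,
                    nucleotide_protons={k: list(v) for k, v in labels.items()})
    return Trajectory(topo, np.asarray(stack.coord, dtype=float),
                      frame_interval_ps=float(sidecar.get("frame_interval_ps", 1.0)),
                      replica_id=int(sidecar.get("replica_id", 0)))
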