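"""Closest-residue proximity profiles for labeled nucleotide protons.

For each labeled proton and each frame, the nearest protein hydrogen
within a radius (default < 6 A) attributes the frame to its residue;
frames with no protein hydrogen inside the radius accrue to a
"none-in-radius" bucket, so per-proton frequencies always sum to one.
Labels mapping to several equivalent protons are reported as the
arithmetic average of the independent per-atom profiles. An alternative
"any-within-radius" residence mode is provided; its per-residue
fractions are independent and do not sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .topology import Trajectory

__all__ = ["ProximityProfile", "proton_proximity_profile", "DEFAULT_RADIUS"]

DEFAULT_RADIUS = 6.0


@dataclass(frozen=True)
class ProximityProfile:
    """Per-proton closest-residue frequencies plus the none-in-radius share."""

    frequencies: dict     # label -> {residue_id: fraction}
    none_fraction: dict   # label -> fraction
    per_atom: dict        # label -> list of ({residue_id: fraction}, none) per atom
    radius: float
    mode: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label in sorted(self.frequencies):
            for res, f in sorted(self.frequencies[label].items()):
                rows.append({"proton": label, "residue": res, "frequency": f})
            rows.append({"proton": label, "residue": "none",
                         "frequency": self.none_fraction[label]})
        return pd.DataFrame(rows)


def _profile_for_atom(dists: np.ndarray, h_res: np.ndarray, radius: float,
                      mode: str) -> tuple[dict, float]:
    n_frames = dists.shape[0]
    if mode == "closest":
        counts: dict = {}
        none = 0
        # candidate columns are pre-sorted by atom_id, so argmin's
        # first-occurrence behaviour breaks ties on the lowest atom_id
        nearest = np.argmin(dists, axis=1)
        within = dists[np.arange(n_frames), nearest] < radius
        for f in range(n_frames):
            if within[f]:
                res = int(h_res[nearest[f]])
                counts[res] = counts.get(res, 0) + 1
            else:
                none += 1
        return ({r: c / n_frames for r, c in counts.items()}, none / n_frames)
    if mode == "any_within":
        freqs = {}
        for res in np.unique(h_res):
            cols = h_res == res
            freqs[int(res)] = float(np.mean(np.any(dists[:, cols] < radius, axis=1)))
        none = float(np.mean(np.all(dists >= radius, axis=1)))
        return freqs, none
    raise ConfigurationError(f"unknown proximity mode {mode!r}")


def proton_proximity_profile(traj: Trajectory, radius: float = DEFAULT_RADIUS,
                             mode: str = "closest") -> ProximityProfile:
    """Closest-protein-proton residue frequencies for each labeled proton."""
    topo = traj.topology
    if not topo.nucleotide_protons:
        raise ConfigurationError(
            "topology has no labeled nucleotide protons; label them to profile proximity")
    if radius <= 0:
        raise ConfigurationError("radius must be > 0")

    ligand_residues = {topo.atoms[topo.index_of(aid)].residue_id
                       for ids in topo.nucleotide_protons.values() for aid in ids}
    h_atoms = sorted(
        (a for a in topo.atoms
         if a.element == "H" and a.residue_id not in ligand_residues),
        key=lambda a: a.atom_id)
    if not h_atoms:
        raise ConfigurationError("no protein hydrogens found outside the ligand residue")
    h_idx = np.array([topo.index_of(a.atom_id) for a in h_atoms])
    h_res = np.array([a.residue_id for a in h_atoms])
    h_coords = traj.coords[:, h_idx, :]  # (n_frames, n_H, 3)

    frequencies, none_fraction, per_atom = {}, {}, {}
    for label, atom_ids in sorted(topo.nucleotide_protons.items()):
        profiles = []
        for aid in atom_ids:
            p = traj.coords[:, topo.index_of(aid), :]
            dists = np.linalg.norm(h_coords - p[:, None, :], axis=2)
            profiles.append(_profile_for_atom(dists, h_res, radius, mode))
        per_atom[label] = profiles
        all_res = sorted({r for freqs, _ in profiles for r in freqs})
        frequencies[label] = {
            r: float(np.mean([freqs.get(r, 0.0) for freqs, _ in profiles]))
            for r in all_res}
        none_fraction[label] = float(np.mean([none for _, none in profiles]))
    return ProximityProfile(frequencies, none_fraction, per_atom, radius, mode)
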