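"""Geometric hydrogen-bond detection and inter-region occupancy matrices.

A donor-H...acceptor triplet qualifies when the H...acceptor distance is
below the cutoff (default 2.4 A) and the donor-H...acceptor angle exceeds
the cutoff (default 120 deg). Occupancy matrices report, for every
residue pair spanning two different named regions, the fraction of frames
with at least one qualifying H-bond in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .topology import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "RegionMap",
    "default_switch_regions",
    "OccupancyMatrix",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "persistence_mask",
]

#: default occurrence thresholds for persistence masking
DEFAULT_THRESHOLDS = (0.1, 0.25, 0.5, 0.75)

#: max covalent H-donor distance used when no bond list is available
COVALENT_H_CUTOFF = 1.2


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria plus donor/acceptor element policy.

    Donors are N/O/S heavy atoms with a covalently attached hydrogen;
    acceptors are N/O atoms (covers backbone, side chains and the
    nucleotide phosphate oxygens).
    """

    max_ha_distance: float = 2.4
    min_dha_angle: float = 120.0
    donor_elements: frozenset = frozenset({"N", "O", "S"})
    acceptor_elements: frozenset = frozenset({"N", "O"})

    def __post_init__(self):
        if self.max_ha_distance <= 0:
            raise ConfigurationError("max_ha_distance must be > 0")
        if not (0 < self.min_dha_angle <= 180):
            raise ConfigurationError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class RegionMap:
    """Named, disjoint residue-id ranges (inclusive bounds)."""

    regions: dict  # name -> (start, end)

    def __post_init__(self):
        covered = {}
        for name, (start, end) in self.regions.items():
            if start > end:
                raise ConfigurationError(f"region {name!r} is empty ({start} > {end})")
            for r in range(start, end + 1):
                if r in covered:
                    raise ConfigurationError(
                        f"regions {covered[r]!r} and {name!r} overlap at residue {r}")
                covered[r] = name

    def region_of(self, residue_id: int) -> str | None:
        for name, (start, end) in self.regions.items():
            if start <= residue_id <= end:
                return name
        return None


def default_switch_regions() -> RegionMap:
    # default switch-region ranges for the stimulatory G-alpha subunit
    # (author numbering of the reference crystal structure); editable config
    return RegionMap({
        "SwitchI": (197, 207),
        "SwitchII": (225, 235),
        "SwitchIII": (252, 268),
    })


@dataclass(frozen=True)
class OccupancyMatrix:
    """Occurrence fractions per inter-region residue pair, optionally masked.

    ``entries`` maps an unordered residue pair (low_id, high_id) to its
    frame fraction in [0, 1]; ``region_pairs`` carries the region names.
    ``mask[threshold][pair]`` is True when occupancy >= threshold.
    """

    entries: dict
    region_pairs: dict
    thresholds: tuple = ()
    mask: dict = field(default_factory=dict)

    def levels(self, pair) -> int:
        """Number of thresholds passed by ``pair`` (colour-intensity level)."""
        return sum(bool(self.mask[t].get(pair, False)) for t in self.thresholds)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair, occ in sorted(self.entries.items()):
            rows.append({
                "donor_res": pair[0], "acceptor_res": pair[1],
                "region_a": self.region_pairs[pair][0],
                "region_b": self.region_pairs[pair][1],
                "occupancy": occ,
                "levels_passed": self.levels(pair) if self.thresholds else None,
            })
        return pd.DataFrame(rows)


def _donor_for_hydrogen(h_idx: int, coords: np.ndarray, topology: Topology,
                        heavy_idx: np.ndarray) -> int | None:
    atom = topology.atoms[h_idx]
    if topology.bonds is not None:
        neighbors = [topology.index_of(a) for a in topology.bonded_neighbors(atom.atom_id)]
        neighbors = [i for i in neighbors if topology.atoms[i].element != "H"]
        if neighbors:
            return neighbors[0]
        return None
    if len(heavy_idx) == 0:
        return None
    d = np.linalg.norm(coords[heavy_idx] - coords[h_idx], axis=1)
    j = int(np.argmin(d))
    return int(heavy_idx[j]) if d[j] <= COVALENT_H_CUTOFF else None


def detect_hbonds_frame(coords: np.ndarray, topology: Topology,
                        criteria: HBondCriteria = HBondCriteria()) -> set:
    """Hydrogen bonds in one frame as (donor_id, hydrogen_id, acceptor_id).

    Raises a configuration error when the topology carries no hydrogens
    (an explicit-hydrogen model is required).
    """
    coords = np.asarray(coords, dtype=float)
    elements = topology.elements
    h_indices = np.flatnonzero(elements == "H")
    if len(h_indices) == 0:
        raise ConfigurationError(
            "topology contains no hydrogens; H-bond geometry needs explicit-H input")
    heavy_idx = np.flatnonzero(elements != "H")
    acceptor_idx = np.flatnonzero(np.isin(elements, sorted(criteria.acceptor_elements)))

    found = set()
    for hi in h_indices:
        di = _donor_for_hydrogen(int(hi), coords, topology, heavy_idx)
        if di is None or elements[di] not in criteria.donor_elements:
            continue
        cand = acceptor_idx[acceptor_idx != di]
        if len(cand) == 0:
            continue
        ha = coords[cand] - coords[hi]
        dist = np.linalg.norm(ha, axis=1)
        close = dist < criteria.max_ha_distance
        if not np.any(close):
            continue
        hd = coords[di] - coords[hi]
        hd_norm = np.linalg.norm(hd)
        for ci, ok in zip(cand[close], dist[close]):
            denom = hd_norm * np.linalg.norm(coords[ci] - coords[hi])
            if denom == 0:
                continue
            cosang = float(np.dot(hd, coords[ci] - coords[hi]) / denom)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > criteria.min_dha_angle:
                found.add((topology.atoms[di].atom_id,
                           topology.atoms[hi].atom_id,
                           topology.atoms[ci].atom_id))
    return found


def hbond_occupancy(traj: Trajectory, regions: RegionMap,
                    criteria: HBondCriteria = HBondCriteria()) -> OccupancyMatrix:
    """Inter-region residue-pair H-bond occurrence fractions over a trajectory.

    A frame counts for a pair when any qualifying H-bond connects atoms
    of the two residues in either direction; residue pairs within the
    same region are excluded.
    """
    if not regions.regions:
        raise ConfigurationError("region map is empty")
    res_of = {a.atom_id: a.residue_id for a in traj.topology.atoms}
    counts: dict = {}
    region_pairs: dict = {}
    for f in range(traj.n_frames):
        frame_pairs = set()
        for donor_id, _h, acceptor_id in detect_hbonds_frame(
                traj.coords[f], traj.topology, criteria):
            r1, r2 = res_of[donor_id], res_of[acceptor_id]
            if r1 == r2:
                continue
            reg1, reg2 = regions.region_of(r1), regions.region_of(r2)
            if reg1 is None or reg2 is None or reg1 == reg2:
                continue
            pair = (min(r1, r2), max(r1, r2))
            frame_pairs.add(pair)
            region_pairs[pair] = tuple(sorted((reg1, reg2)))
        for pair in frame_pairs:
            counts[pair] = counts.get(pair, 0) + 1
    entries = {pair: n / traj.n_frames for pair, n in counts.items()}
    return OccupancyMatrix(entries, region_pairs)


def persistence_mask(matrix: OccupancyMatrix,
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> OccupancyMatrix:
    """Attach boolean persistence masks at each occurrence threshold.

    Thresholds must be strictly ascending within (0, 1]. The mask is
    monotone by construction: a pair passing a threshold passes all
    lower ones.
    """
    thresholds = tuple(thresholds)
    if not thresholds or any(not (0 < t <= 1) for t in thresholds) \
            or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ConfigurationError(
            f"thresholds must be strictly ascending within (0, 1], got {thresholds}")
    mask = {t: {pair: occ >= t for pair, occ in matrix.entries.items()}
            for t in thresholds}
    return replace(matrix, thresholds=thresholds, mask=mask)
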