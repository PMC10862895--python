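"""Per-residue backbone root-mean-square fluctuation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError
from .topology import Trajectory

__all__ = ["RMSFProfile", "compute_rmsf", "DEFAULT_BACKBONE"]

DEFAULT_BACKBONE = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class RMSFProfile:
    """Fluctuation about the trajectory-average position, in Angstrom."""

    per_residue: dict  # residue_id -> rmsf (mean over selected atoms)
    per_atom: dict     # atom_id -> rmsf
    selection: tuple

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"residue": r, "rmsf_A": v} for r, v in sorted(self.per_residue.items())])


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation superposing mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, rc - rot @ mc


def compute_rmsf(traj: Trajectory, selection: Sequence[str] = DEFAULT_BACKBONE,
                 superpose: bool = False) -> RMSFProfile:
    """RMSF per selected atom, averaged per residue.

    RMSF_i = sqrt(mean_t ||x_i(t) - <x_i>||^2). With ``superpose`` each
    frame is first least-squares fitted (on the selection) to the
    trajectory-average structure; off by default for trajectories that
    already share a laboratory frame.
    """
    sel = set(selection)
    if not sel:
        raise ConfigurationError("atom-name selection must be non-empty")
    idx = [i for i, a in enumerate(traj.topology.atoms) if a.name in sel]
    if not idx:
        raise ConfigurationError(f"no atoms match selection {sorted(sel)}")
    coords = traj.coords[:, idx, :]
    if traj.n_frames == 1:
        warnings.warn("single-frame trajectory: RMSF degenerate (all zeros)",
                      stacklevel=2)
    if superpose and traj.n_frames > 1:
        # two-pass fit: first to frame 0 (the raw mean of arbitrarily
        # rotated frames is a degenerate reference), then to the mean
        for ref in (coords[0], None):
            if ref is None:
                ref = coords.mean(axis=0)
            aligned = np.empty_like(coords)
            for f in range(coords.shape[0]):
                rot, trans = _kabsch(coords[f], ref)
                aligned[f] = coords[f] @ rot.T + trans
            coords = aligned

    mean_pos = coords.mean(axis=0)
    sq_dev = np.sum((coords - mean_pos) ** 2, axis=2)  # (n_frames, n_sel)
    rmsf = np.sqrt(sq_dev.mean(axis=0))

    per_atom = {traj.topology.atoms[i].atom_id: float(v) for i, v in zip(idx, rmsf)}
    by_res: dict = {}
    for i, v in zip(idx, rmsf):
        by_res.setdefault(traj.topology.atoms[i].residue_id, []).append(float(v))
    per_residue = {r: float(np.mean(vs)) for r, vs in by_res.items()}
    return RMSFProfile(per_residue, per_atom, tuple(sorted(sel)))
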