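"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: the melt oracle
is an exhaustive grid search, the rate oracle a 1-D golden-section
search with the linear parameters solved in closed form, and the H-bond
oracle an exhaustive triplet enumeration in pure Python.
"""

from __future__ import annotations

import math

import numpy as np


def grid_search_tm(t: np.ndarray, y: np.ndarray,
                   v50_range=(25.0, 89.0), v50_step=0.01,
                   slope_range=(0.1, 20.0), slope_step=0.1) -> tuple[float, float]:
    """Exhaustive (v50, slope) grid minimizing SSE with top/bottom solved
    by linear least squares at each grid point. Returns (v50, slope)."""
    v50s = np.arange(v50_range[0], v50_range[1] + v50_step / 2, v50_step)
    slopes = np.arange(slope_range[0], slope_range[1] + slope_step / 2, slope_step)
    best = (math.inf, None, None)
    for slope in slopes:
        # basis (n_v50, n_t): logistic response for every v50 at this slope
        f = 1.0 / (1.0 + np.exp((v50s[:, None] - t[None, :]) / slope))
        # solve y ~ bottom + (top-bottom) f  per row via normal equations
        n = len(t)
        sf = f.sum(axis=1)
        sff = (f * f).sum(axis=1)
        sy = y.sum()
        sfy = f @ y
        det = n * sff - sf * sf
        with np.errstate(divide="ignore", invalid="ignore"):
            amp = (n * sfy - sf * sy) / det
            off = (sy - amp * sf) / n
        resid = y[None, :] - (off[:, None] + amp[:, None] * f)
        sse = np.einsum("ij,ij->i", resid, resid)
        i = int(np.nanargmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(v50s[i]), float(slope))
    return best[1], best[2]


def golden_section_k(t: np.ndarray, y: np.ndarray,
                     k_lo: float = 1e-6, k_hi: float = 10.0,
                     tol: float = 1e-10) -> float:
    """Best single-exponential rate by golden-section on k; (y0, plateau)
    solved in closed form by linear regression on [1, 1 - exp(-k t)]."""

    def sse(k: float) -> float:
        basis = 1.0 - np.exp(-k * t)
        a = np.column_stack([np.ones_like(t), basis])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        r = y - a @ coef
        return float(r @ r)

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = k_lo, k_hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = sse(c), sse(d)
    while abs(b - a) > tol * (abs(a) + abs(b)):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = sse(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = sse(d)
    return (a + b) / 2.0


def brute_force_hbonds(coords: np.ndarray, topology, max_ha: float = 2.4,
                       min_angle: float = 120.0,
                       donor_elements=("N", "O", "S"),
                       acceptor_elements=("N", "O"),
                       covalent_cutoff: float = 1.2) -> set:
    """Enumerate every (donor, hydrogen, acceptor) triplet and test it.

    Mirrors the detection contract: the donor is the hydrogen's bonded
    heavy atom (or its nearest heavy atom within the covalent cutoff
    when no bond list exists) and must have a donor element; the
    acceptor must have an acceptor element and differ from the donor.
    """
    atoms = topology.atoms
    n = len(atoms)
    found = set()
    for hi in range(n):
        if atoms[hi].element != "H":
            continue
        for di in range(n):
            if di == hi or atoms[di].element == "H":
                continue
            if topology.bonds is not None:
                if atoms[di].atom_id not in topology.bonded_neighbors(atoms[hi].atom_id):
                    continue
            else:
                # donor must be the unique nearest heavy atom within cutoff
                dd = math.dist(coords[hi], coords[di])
                if dd > covalent_cutoff:
                    continue
                nearest = min(
                    (math.dist(coords[hi], coords[j]), j)
                    for j in range(n) if atoms[j].element != "H")[1]
                if nearest != di:
                    continue
            if atoms[di].element not in donor_elements:
                continue
            for ai in range(n):
                if ai in (hi, di) or atoms[ai].element not in acceptor_elements:
                    continue
                ha = math.dist(coords[hi], coords[ai])
                if ha >= max_ha:
                    continue
                v1 = coords[di] - coords[hi]
                v2 = coords[ai] - coords[hi]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = float(np.dot(v1, v2) / denom)
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle > min_angle:
                    found.add((atoms[di].atom_id, atoms[hi].atom_id,
                               atoms[ai].atom_id))
    return found


def closest_proton_scan(coords: np.ndarray, topology, proton_atom_id: int,
                        radius: float = 6.0) -> int | None:
    """Brute-force nearest protein hydrogen within radius for one frame.

    Returns the residue id of the closest qualifying hydrogen or None.
    """
    ligand_residues = {
        topology.atoms[topology.index_of(a)].residue_id
        for ids in topology.nucleotide_protons.values() for a in ids}
    p = coords[topology.index_of(proton_atom_id)]
    best = (math.inf, None)
    for i, a in enumerate(topology.atoms):
        if a.element != "H" or a.residue_id in ligand_residues:
            continue
        d = math.dist(p, coords[i])
        if d < best[0]:
            best = (d, a.residue_id)
    return best[1] if best[0] < radius else None
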