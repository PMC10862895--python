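"""One-phase association fitting of nucleotide-exchange fluorescence traces."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, NoSignalError

__all__ = [
    "KineticTrace",
    "KineticFit",
    "one_phase_association",
    "fit_one_phase_association",
    "read_traces_csv",
    "write_traces_csv",
]

MIN_POINTS = 20
MIN_AMPLITUDE_OVER_NOISE = 5.0


def one_phase_association(x: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    """``y0 + (plateau - y0) * (1 - exp(-k x))``.

    ``k`` is expressed in the reciprocal of the time-axis unit; at x=0
    the model equals ``y0`` and tends to ``plateau`` at long times.
    """
    x = np.asarray(x, dtype=float)
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * x))


@dataclass(frozen=True)
class KineticTrace:
    """Fluorescence-vs-time trace; time increasing, >= 20 points."""

    time: np.ndarray
    intensity: np.ndarray
    variant: str = ""
    nucleotide: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise InputError("time and intensity must be 1-D arrays of equal length")
        if len(t) < MIN_POINTS:
            raise InputError(f"kinetic trace needs >= {MIN_POINTS} points, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise InputError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InputError("kinetic trace contains non-finite values")


@dataclass(frozen=True)
class KineticFit:
    """Fit result; ``k`` in reciprocal time-axis units, ``half_time = ln2/k``."""

    y0: float
    plateau: float
    k: float
    half_time: float
    sse: float
    converged: bool
    stderr: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "y0": self.y0, "plateau": self.plateau, "k": self.k,
            "half_time": self.half_time, "sse": self.sse,
            "converged": self.converged, "stderr": dict(self.stderr),
        }


def _noise_scale(y: np.ndarray) -> float:
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def fit_one_phase_association(trace: KineticTrace) -> KineticFit:
    """Least-squares (y0, plateau, k) fit of a single-exponential trace.

    Decreasing traces (plateau < y0, negative amplitude) are supported;
    a non-positive fitted rate yields ``converged=False``. The first
    recorded point is treated as x=0 (no dead-time correction).
    """
    t = trace.time - trace.time[0]
    y = trace.intensity
    # baseline difference between first and last deciles: robust to the
    # growth of max-min with trace length under pure noise
    k = max(3, len(y) // 10)
    amplitude = abs(float(np.median(y[-k:]) - np.median(y[:k])))
    noise = _noise_scale(y)
    if amplitude < MIN_AMPLITUDE_OVER_NOISE * noise or amplitude == 0.0:
        raise NoSignalError(
            f"trace amplitude {amplitude:.3g} below {MIN_AMPLITUDE_OVER_NOISE}x "
            f"noise scale {noise:.3g}"
        )

    # deterministic initialization: y0 from the first point, plateau from
    # the mean of the final 5%, k from the half-amplitude crossing time
    y0_init = float(y[0])
    tail = max(1, len(y) // 20)
    plateau_init = float(np.mean(y[-tail:]))
    half_level = y0_init + 0.5 * (plateau_init - y0_init)
    cross = np.argmin(np.abs(y - half_level))
    t_half = float(t[cross]) if t[cross] > 0 else float(t[1])
    k_init = math.log(2.0) / t_half

    try:
        popt, pcov = curve_fit(one_phase_association, t, y,
                               p0=[y0_init, plateau_init, k_init], maxfev=10000)
        ok = np.all(np.isfinite(popt))
    except RuntimeError:
        popt = np.array([y0_init, plateau_init, k_init])
        pcov = np.full((3, 3), np.nan)
        ok = False

    y0, plateau, k = (float(v) for v in popt)
    resid = y - one_phase_association(t, y0, plateau, k)
    sse = float(resid @ resid)
    converged = bool(ok and k > 0)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    stderr = {n: float(e) for n, e in zip(["y0", "plateau", "k"], perr)}
    half_time = math.log(2.0) / k if k > 0 else float("inf")
    return KineticFit(y0, plateau, k, half_time, sse, converged, stderr)


def write_traces_csv(traces: Sequence[KineticTrace], path) -> None:
    rows = []
    for tr in traces:
        for t, y in zip(tr.time, tr.intensity):
            rows.append({"time_s": t, "intensity": y, "variant": tr.variant,
                         "nucleotide": tr.nucleotide})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    required = {"time_s", "intensity", "variant"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"traces CSV missing columns: {sorted(missing)}")
    if "nucleotide" not in df.columns:
        df["nucleotide"] = ""
    df["nucleotide"] = df["nucleotide"].fillna("")
    traces = []
    for (variant, nucleotide), grp in df.groupby(["variant", "nucleotide"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(KineticTrace(grp["time_s"].to_numpy(), grp["intensity"].to_numpy(),
                                   variant=str(variant), nucleotide=str(nucleotide)))
    return traces
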