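"""Thermal-melt fitting and phenotype classification.

Variable-temperature ellipticity traces are fitted to a Boltzmann
sigmoid, triplicate melting temperatures are aggregated, and each
variant x nucleotide pair is classified against wild-type references as
nucleotide-responsive, GDP-like, GTP-like or indeterminate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    AggregationError,
    ConfigurationError,
    InputError,
    NoTransitionError,
)

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "TmSummary",
    "ThermalCategory",
    "ThermalPhenotype",
    "boltzmann",
    "fit_melting_curve",
    "summarize_tm",
    "classify_thermal_phenotype",
    "classify_vs_references",
    "read_curves_csv",
    "write_curves_csv",
]

#: backbone atom count guard — melting fits need a minimum of 10 points
MIN_POINTS = 10

#: amplitude must exceed this multiple of the noise scale to count as a transition
MIN_AMPLITUDE_OVER_NOISE = 5.0


def boltzmann(x: np.ndarray, v50: float, slope: float, top: float = 1.0,
              bottom: float = 0.0) -> np.ndarray:
    """Sigmoidal melt model ``bottom + (top - bottom) / (1 + exp((v50 - x)/slope))``.

    ``v50`` is the midpoint temperature (the melting temperature T_m),
    ``slope`` the transition width in the same units as ``x``.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip((v50 - x) / slope, -700.0, 700.0)  # avoid exp overflow
    return bottom + (top - bottom) / (1.0 + np.exp(z))


@dataclass(frozen=True)
class MeltingCurve:
    """One ellipticity-vs-temperature trace.

    ``temperature`` must be strictly increasing; ``signal`` the same
    length with no missing values. ``signal`` may be raw ellipticity or a
    pre-normalized folded fraction.
    """

    temperature: np.ndarray
    signal: np.ndarray
    variant: str = ""
    nucleotide: str = ""
    replicate: int = 0

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise InputError("temperature and signal must be 1-D arrays of equal length")
        if len(t) < MIN_POINTS:
            raise InputError(f"melting curve needs >= {MIN_POINTS} points, got {len(t)}")
        if not np.all(np.diff(t) > 0):
            raise InputError("temperature must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise InputError("melting curve contains non-finite values")


@dataclass(frozen=True)
class MeltingFit:
    """Boltzmann fit result. ``v50`` is the melting temperature in deg C."""

    v50: float
    slope: float
    top: float
    bottom: float
    sse: float
    converged: bool
    stderr: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "v50": self.v50,
            "slope": self.slope,
            "top": self.top,
            "bottom": self.bottom,
            "sse": self.sse,
            "converged": self.converged,
            "stderr": dict(self.stderr),
        }


@dataclass(frozen=True)
class TmSummary:
    """Replicate-aggregated melting temperature: mean, sample SD, n."""

    tm_mean: float
    tm_sd: float | None
    n_replicates: int

    def to_dict(self) -> dict:
        return {
            "tm_mean": self.tm_mean,
            "tm_sd": self.tm_sd,
            "n_replicates": self.n_replicates,
        }


class ThermalCategory(str, Enum):
    NUCLEOTIDE_RESPONSIVE = "nucleotide_responsive"
    GDP_LIKE = "gdp_like"
    GTP_LIKE = "gtp_like"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ThermalPhenotype:
    delta_tm: float | None
    category: ThermalCategory
    references: dict

    def to_dict(self) -> dict:
        return {
            "delta_tm": self.delta_tm,
            "category": self.category.value,
            "references": dict(self.references),
        }


def _noise_scale(signal: np.ndarray) -> float:
    # robust noise estimate from first differences; /sqrt(2) undoes the
    # variance doubling of differencing, 1.4826 scales MAD to sigma
    d = np.diff(signal)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def _robust_amplitude(signal: np.ndarray) -> float:
    # baseline difference between the first and last deciles: insensitive
    # to the noise-driven growth of max-min with trace length
    k = max(3, len(signal) // 10)
    return abs(float(np.median(signal[-k:]) - np.median(signal[:k])))


def fit_melting_curve(curve: MeltingCurve, fix_normalization: bool = False) -> MeltingFit:
    """Least-squares Boltzmann fit of a melting curve.

    With ``fix_normalization`` the plateaus are pinned at top=1, bottom=0
    and only (v50, slope) are fitted; the signal must then already be
    scaled to folded fraction. The fit is flagged non-converged rather
    than silently extrapolated when v50 falls outside the temperature
    range or the fitted slope is non-positive (signal ordered
    unfolded -> folded).
    """
    t, y = curve.temperature, curve.signal
    amplitude = float(y.max() - y.min())
    transition = _robust_amplitude(y)
    noise = _noise_scale(y)
    if transition < MIN_AMPLITUDE_OVER_NOISE * noise or amplitude == 0.0:
        raise NoTransitionError(
            f"signal amplitude {transition:.3g} below {MIN_AMPLITUDE_OVER_NOISE}x "
            f"noise scale {noise:.3g}; no transition to fit"
        )

    # deterministic initialization: v50 at the half-amplitude crossing,
    # slope one tenth of the scanned range
    y_half = y.min() + amplitude / 2.0
    crossing = np.argmin(np.abs(y - y_half))
    p0_v50 = float(t[crossing])
    p0_slope = float((t[-1] - t[0]) / 10.0)

    if fix_normalization:
        def model(x, v50, slope):
            return boltzmann(x, v50, slope, 1.0, 0.0)

        p0 = [p0_v50, p0_slope]
    else:
        def model(x, v50, slope, top, bottom):
            return boltzmann(x, v50, slope, top, bottom)

        p0 = [p0_v50, p0_slope, float(y.max()), float(y.min())]

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=10000)
        ok = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, pcov = np.asarray(p0), np.full((len(p0), len(p0)), np.nan)
        ok = False

    if fix_normalization:
        v50, slope = popt
        top, bottom = 1.0, 0.0
        names = ["v50", "slope"]
    else:
        v50, slope, top, bottom = popt
        names = ["v50", "slope", "top", "bottom"]

    resid = y - model(t, *popt)
    sse = float(resid @ resid)
    # orientation contract: unfolding runs folded -> unfolded, so the fit
    # must be increasing (slope > 0, top > bottom) with v50 inside the data
    converged = bool(ok and slope > 0 and top > bottom and t[0] < v50 < t[-1])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    stderr = {n: float(e) for n, e in zip(names, perr)}
    return MeltingFit(float(v50), float(slope), float(top), float(bottom),
                      sse, converged, stderr)


def summarize_tm(fits: Sequence[MeltingFit]) -> TmSummary:
    """Mean and sample SD (ddof=1) of v50 over converged fits.

    SD is reported as ``None`` for a single replicate.
    """
    tms = [f.v50 for f in fits if f.converged]
    if not tms:
        raise AggregationError("no converged fits to summarize")
    mean = float(np.mean(tms))
    sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else None
    return TmSummary(mean, sd, len(tms))


def default_threshold(*summaries: TmSummary) -> float:
    """Classification threshold: max(3 deg C, 2 x pooled replicate SD)."""
    sds = [s.tm_sd for s in summaries if s.tm_sd is not None]
    pooled = math.sqrt(float(np.mean([sd ** 2 for sd in sds]))) if sds else 0.0
    return max(3.0, 2.0 * pooled)


def classify_vs_references(tm: float, wt_gdp: TmSummary, wt_gtp: TmSummary,
                           threshold: float) -> ThermalCategory:
    """Attribute a single T_m to the nearer wild-type reference state.

    Within ``threshold`` of both references, or exactly equidistant,
    the call is indeterminate.
    """
    d_gdp = abs(tm - wt_gdp.tm_mean)
    d_gtp = abs(tm - wt_gtp.tm_mean)
    if (d_gdp <= threshold and d_gtp <= threshold) or d_gdp == d_gtp:
        return ThermalCategory.INDETERMINATE
    return ThermalCategory.GDP_LIKE if d_gdp < d_gtp else ThermalCategory.GTP_LIKE


def classify_thermal_phenotype(gdp: TmSummary, gtp: TmSummary,
                               wt_gdp: TmSummary, wt_gtp: TmSummary,
                               threshold: float | None = None) -> ThermalPhenotype:
    """Classify a variant's thermal phenotype against wild-type references.

    ``nucleotide_responsive`` when the GTP-state T_m exceeds the
    GDP-state T_m by more than ``threshold``; otherwise the (pooled)
    T_m is attributed to the nearer wild-type reference, or called
    indeterminate when it sits within threshold of both.
    """
    if wt_gtp.tm_mean <= wt_gdp.tm_mean:
        raise ConfigurationError(
            f"wild-type references overlap or are inverted: "
            f"GTP {wt_gtp.tm_mean} <= GDP {wt_gdp.tm_mean}"
        )
    if threshold is None:
        threshold = default_threshold(gdp, gtp, wt_gdp, wt_gtp)
    delta = gtp.tm_mean - gdp.tm_mean
    refs = {
        "wt_gdp_tm": wt_gdp.tm_mean,
        "wt_gtp_tm": wt_gtp.tm_mean,
        "threshold": threshold,
    }
    if delta > threshold:
        return ThermalPhenotype(delta, ThermalCategory.NUCLEOTIDE_RESPONSIVE, refs)
    pooled_tm = 0.5 * (gdp.tm_mean + gtp.tm_mean)
    return ThermalPhenotype(delta, classify_vs_references(pooled_tm, wt_gdp, wt_gtp, threshold), refs)


# ---------------------------------------------------------------------------
# CSV interface: columns temperature_C, signal, variant, nucleotide, replicate

def write_curves_csv(curves: Sequence[MeltingCurve], path) -> None:
    rows = []
    for c in curves:
        for t, y in zip(c.temperature, c.signal):
            rows.append({
                "temperature_C": t, "signal": y, "variant": c.variant,
                "nucleotide": c.nucleotide, "replicate": c.replicate,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_curves_csv(path) -> list[MeltingCurve]:
    df = pd.read_csv(path)
    required = {"temperature_C", "signal", "variant", "nucleotide", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"curves CSV missing columns: {sorted(missing)}")
    if df[["temperature_C", "signal"]].isna().any().any():
        raise InputError("curves CSV contains missing temperature/signal values")
    df[["variant", "nucleotide"]] = df[["variant", "nucleotide"]].fillna("")
    curves = []
    for (variant, nucleotide, rep), grp in df.groupby(
            ["variant", "nucleotide", "replicate"], sort=True):
        grp = grp.sort_values("temperature_C")
        curves.append(MeltingCurve(
            grp["temperature_C"].to_numpy(), grp["signal"].to_numpy(),
            variant=str(variant), nucleotide=str(nucleotide), replicate=int(rep)))
    return curves
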