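"""STD-NMR amplification factors, error propagation and fingerprint binning.

Peak integrals from reference (I0) and difference (I0 - Isat) spectra are
converted to amplification factors

    A_STD = ((I0 - Isat) / I0) * ([L] / [P])

with per-signal error sigma = A_STD / SNR_diff, normalized to a reference
proton and binned into the interaction-strength categories used for
epitope-map colouring. Integrals are assumed background-corrected;
spectral processing is out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, SpecValidationError

__all__ = [
    "STDIntegralRecord",
    "SampleContext",
    "STDAmplification",
    "FingerprintBin",
    "NormalizedFingerprint",
    "compute_std_af",
    "compute_std_table",
    "normalize_fingerprint",
    "bin_fingerprint_value",
    "select_saturation_time",
    "read_std_csv",
    "write_std_csv",
]

logger = logging.getLogger(__name__)

#: half-width of the band (relative units) treated as equivalent to the reference
REFERENCE_TOLERANCE = 0.02


@dataclass(frozen=True)
class STDIntegralRecord:
    """Integrals of one ligand signal: reference i0, difference isat, SNR.

    ``usable=False`` marks signals overlapped with residual protein
    background; they are excluded from fingerprints.
    """

    proton_label: str
    i0: float
    isat: float
    snr_diff: float
    usable: bool = True

    def __post_init__(self):
        if self.i0 <= 0:
            raise SpecValidationError("i0", "reference integral must be > 0")
        if self.usable and self.snr_diff <= 0:
            raise SpecValidationError("snr_diff", "SNR must be > 0 for usable records")


@dataclass(frozen=True)
class SampleContext:
    ligand_conc: float  # uM
    protein_conc: float  # uM
    nucleotide: str = "GDP"
    variant: str = ""

    def __post_init__(self):
        if self.ligand_conc <= 0:
            raise SpecValidationError("ligand_conc", "must be > 0")
        if self.protein_conc <= 0:
            raise SpecValidationError("protein_conc", "must be > 0")

    @property
    def excess(self) -> float:
        return self.ligand_conc / self.protein_conc


@dataclass(frozen=True)
class STDAmplification:
    proton_label: str
    a_std: float
    sigma: float


class FingerprintBin(str, Enum):
    WEAK = "weak"                         # < 50% of reference
    WEAK_MODERATE = "weak_moderate"       # 50-99%
    REFERENCE = "reference"               # ~100% (within tolerance)
    MODERATE = "moderate"                 # 101-150%
    STRONG = "strong"                     # > 150%
    EXCLUDED = "excluded"                 # unusable (overlapped) signal
    ARTIFACT = "artifact"                 # negative ratio (subtraction artifact)


@dataclass(frozen=True)
class FingerprintEntry:
    proton_label: str
    ratio: float
    sigma: float
    bin: FingerprintBin


@dataclass(frozen=True)
class NormalizedFingerprint:
    reference_label: str
    entries: tuple  # of FingerprintEntry

    def ratios(self) -> dict:
        return {e.proton_label: e.ratio for e in self.entries}

    def to_dict(self) -> dict:
        return {
            "reference_label": self.reference_label,
            "entries": [
                {"proton": e.proton_label, "ratio": e.ratio,
                 "sigma": e.sigma, "bin": e.bin.value}
                for e in self.entries
            ],
        }


def compute_std_af(rec: STDIntegralRecord, ctx: SampleContext) -> STDAmplification:
    """Amplification factor of one signal with its SNR-derived error.

    ``a_std = ((i0 - isat)/i0) * excess``; ``sigma = a_std / snr_diff``
    (zero when the transfer is zero). ``isat > i0`` yields a preserved
    negative a_std with a warning, flagging a subtraction artifact.
    """
    if not rec.usable:
        raise InputError(f"record {rec.proton_label!r} marked unusable; skip upstream")
    a_std = ((rec.i0 - rec.isat) / rec.i0) * ctx.excess
    if a_std < 0:
        warnings.warn(
            f"proton {rec.proton_label!r}: isat > i0 gives negative a_std "
            f"({a_std:.4g}); possible subtraction artifact", stacklevel=2)
    sigma = abs(a_std) / rec.snr_diff
    return STDAmplification(rec.proton_label, float(a_std), float(sigma))


def compute_std_table(records: Sequence[STDIntegralRecord],
                      ctx: SampleContext) -> list[STDAmplification]:
    """Amplification factors for all usable records; unusable ones are
    skipped with a logged reason."""
    out = []
    for rec in records:
        if not rec.usable:
            logger.info("skipping proton %r: marked unusable (background overlap)",
                        rec.proton_label)
            continue
        out.append(compute_std_af(rec, ctx))
    return out


def bin_fingerprint_value(ratio: float,
                          reference_tolerance: float = REFERENCE_TOLERANCE) -> FingerprintBin:
    """Interaction-strength category of a reference-normalized ratio.

    Half-open intervals: <0.50 weak; [0.50, 1.00) weak-moderate;
    1.00 within ``reference_tolerance`` reference-equivalent;
    (1.00, 1.50] moderate; >1.50 strong. Negative ratios are flagged
    as artifacts.
    """
    if not np.isfinite(ratio):
        raise InputError(f"ratio must be finite, got {ratio}")
    if ratio < 0:
        return FingerprintBin.ARTIFACT
    if abs(ratio - 1.0) <= reference_tolerance:
        return FingerprintBin.REFERENCE
    if ratio < 0.50:
        return FingerprintBin.WEAK
    if ratio < 1.00:
        return FingerprintBin.WEAK_MODERATE
    if ratio <= 1.50:
        return FingerprintBin.MODERATE
    return FingerprintBin.STRONG


def normalize_fingerprint(afs: Sequence[STDAmplification], reference: str = "a",
                          reference_tolerance: float = REFERENCE_TOLERANCE,
                          excluded: Sequence[str] = ()) -> NormalizedFingerprint:
    """Ratios of every amplification factor to the reference proton's.

    Errors propagate in quadrature of relative errors:
    ``sigma_r = r * sqrt((sigma_p/A_p)^2 + (sigma_ref/A_ref)^2)``. The
    reference proton itself is reported with ratio exactly 1, its own
    relative error, and bin "reference". Labels in ``excluded`` are
    appended with bin "excluded" and no ratio (NaN).
    """
    by_label = {af.proton_label: af for af in afs}
    if reference not in by_label:
        raise NormalizationError(f"reference proton {reference!r} absent")
    ref = by_label[reference]
    if ref.a_std <= 0:
        raise NormalizationError(
            f"reference a_std must be > 0, got {ref.a_std:.4g}; fingerprint undefined")

    entries = []
    for af in afs:
        if af.proton_label == reference:
            entries.append(FingerprintEntry(reference, 1.0, ref.sigma / ref.a_std,
                                            FingerprintBin.REFERENCE))
            continue
        r = af.a_std / ref.a_std
        rel_p = (af.sigma / af.a_std) if af.a_std != 0 else 0.0
        rel_ref = ref.sigma / ref.a_std
        sigma_r = abs(r) * float(np.hypot(rel_p, rel_ref))
        entries.append(FingerprintEntry(af.proton_label, float(r), sigma_r,
                                        bin_fingerprint_value(r, reference_tolerance)))
    for label in excluded:
        entries.append(FingerprintEntry(label, float("nan"), float("nan"),
                                        FingerprintBin.EXCLUDED))
    return NormalizedFingerprint(reference, tuple(entries))


def select_saturation_time(signal_vs_time: Mapping[float, float],
                           fraction: float = 0.05) -> float:
    """Smallest saturation time whose signal is within ``fraction`` of the max.

    On pathological input where no time qualifies (only possible with
    floating-point quirks) the argmax time is returned with a warning.
    """
    if len(signal_vs_time) < 2:
        raise InputError("need >= 2 saturation time points")
    times = sorted(signal_vs_time)
    peak = max(signal_vs_time.values())
    for t in times:
        if signal_vs_time[t] >= (1.0 - fraction) * peak:
            return t
    warnings.warn("no saturation time within tolerance of max; returning argmax",
                  stacklevel=2)
    return max(times, key=lambda t: signal_vs_time[t])


# ---------------------------------------------------------------------------
# CSV interface: proton, i0, isat, snr, usable, variant, nucleotide,
# ligand_uM, protein_uM

def write_std_csv(records: Sequence[STDIntegralRecord], ctx: SampleContext, path) -> None:
    rows = [{
        "proton": r.proton_label, "i0": r.i0, "isat": r.isat, "snr": r.snr_diff,
        "usable": r.usable, "variant": ctx.variant, "nucleotide": ctx.nucleotide,
        "ligand_uM": ctx.ligand_conc, "protein_uM": ctx.protein_conc,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_std_csv(path) -> list[tuple[list[STDIntegralRecord], SampleContext]]:
    """Read grouped (records, context) pairs, one per variant x nucleotide."""
    df = pd.read_csv(path)
    required = {"proton", "i0", "isat", "snr", "usable", "variant", "nucleotide",
                "ligand_uM", "protein_uM"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"STD CSV missing columns: {sorted(missing)}")
    tables = []
    for (variant, nucleotide), grp in df.groupby(["variant", "nucleotide"], sort=True):
        ctx = SampleContext(float(grp["ligand_uM"].iloc[0]),
                            float(grp["protein_uM"].iloc[0]),
                            nucleotide=str(nucleotide), variant=str(variant))
        records = [STDIntegralRecord(str(r.proton), float(r.i0), float(r.isat),
                                     float(r.snr), bool(r.usable))
                   for r in grp.itertuples()]
        tables.append((records, ctx))
    return tables
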