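"""Run configuration, dossier assembly and the end-to-end pipeline.

A variant dossier merges the per-stage read-outs (thermal, kinetics,
STD fingerprint, trajectory analyses) into one schema-validated JSON
document with a provenance block (config hash, seed, package version).
All outputs are deterministic for a fixed seed and configuration: no
timestamps, sorted keys, stable float formatting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .errors import ConfigurationError, MergeError
from .kinetics import fit_one_phase_association, read_traces_csv
from .stdnmr import compute_std_table, normalize_fingerprint, read_std_csv
from .thermostability import (
    classify_thermal_phenotype,
    fit_melting_curve,
    read_curves_csv,
    summarize_tm,
)
from .traj import (
    aggregate_replicas,
    compute_rmsf,
    default_switch_regions,
    hbond_occupancy,
    persistence_mask,
    proton_proximity_profile,
    read_trajectory_pdb,
    RegionMap,
)

logger = logging.getLogger(__name__)

STAGES = ("thermal", "kinetics", "std", "trajectory")
ANALYSES = ("melt", "kinetics", "std", "hbond", "rmsf", "proximity")


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration.

    ``inputs`` maps analysis names to file paths; every referenced path
    must exist at validation time. Threshold defaults are echoed at
    startup so no default is applied silently.
    """

    analyses: tuple = ()
    inputs: dict = field(default_factory=dict)
    outdir: str = "."
    seed: int = 0
    delta_tm_threshold: float | None = None
    wt_variant: str = "WT"
    fingerprint_reference: str = "a"
    reference_tolerance: float = 0.02
    radius: float = 6.0
    proximity_mode: str = "closest"
    persistence_thresholds: tuple = (0.1, 0.25, 0.5, 0.75)
    fix_normalization: bool = False
    superpose: bool = False
    regions: dict | None = None

    def __post_init__(self):
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")
        for name in self.analyses:
            key = {"hbond": "traj", "rmsf": "traj", "proximity": "traj"}.get(name, name)
            path = self.inputs.get(key)
            if path is None:
                raise ConfigurationError(f"analysis {name!r} needs input {key!r}")
            paths = path if isinstance(path, (list, tuple)) else [path]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"input path does not exist: {p}")
        if not (0 < self.radius):
            raise ConfigurationError("radius must be > 0")
        if not (0 <= self.reference_tolerance < 0.5):
            raise ConfigurationError("reference_tolerance must lie in [0, 0.5)")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        """Load config JSON; keyword overrides (CLI flags) take precedence."""
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("analyses", "persistence_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "analyses": list(self.analyses), "inputs": dict(self.inputs),
            "outdir": self.outdir, "seed": self.seed,
            "delta_tm_threshold": self.delta_tm_threshold,
            "wt_variant": self.wt_variant,
            "fingerprint_reference": self.fingerprint_reference,
            "reference_tolerance": self.reference_tolerance,
            "radius": self.radius, "proximity_mode": self.proximity_mode,
            "persistence_thresholds": list(self.persistence_thresholds),
            "fix_normalization": self.fix_normalization,
            "superpose": self.superpose, "regions": self.regions,
        }


def config_hash(config: RunConfig | dict) -> str:
    """Location-independent digest of the analytic configuration.

    The output directory and the directory parts of input paths are
    excluded so identical runs into different directories hash alike.
    """
    data = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    data.pop("outdir", None)
    inputs = data.get("inputs", {})
    data["inputs"] = {
        k: sorted(Path(p).name for p in v) if isinstance(v, (list, tuple))
        else Path(v).name
        for k, v in inputs.items()}
    blob = json.dumps(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_block(config: RunConfig | dict, seed: int) -> dict:
    return {"config_hash": config_hash(config), "seed": seed,
            "package_version": __version__}


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Dossier assembly

def assemble_dossier(variant: str, results: Iterable[tuple],
                     provenance: dict | None = None) -> dict:
    """Merge (stage, payload) pairs into one validated variant dossier.

    Absent stages are recorded as ``None`` — never imputed. The same
    stage may appear twice only with an identical payload; a conflicting
    duplicate raises a merge error.
    """
    sections: dict = {}
    n = 0
    for stage, payload in results:
        n += 1
        if stage not in STAGES:
            raise MergeError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if stage in sections and sections[stage] != payload:
            raise MergeError(
                f"conflicting duplicate {stage!r} blocks for variant {variant!r}")
        sections[stage] = payload
    if n == 0:
        raise MergeError(f"no stage outputs supplied for variant {variant!r}")
    dossier = {"variant": variant,
               **{stage: sections.get(stage) for stage in STAGES},
               "provenance": provenance or {}}
    validate_dossier(dossier)
    return dossier


def validate_dossier(dossier: dict) -> None:
    """Minimal schema check: required keys, section types, provenance."""
    required = {"variant", *STAGES, "provenance"}
    missing = required - set(dossier)
    if missing:
        raise MergeError(f"dossier missing keys: {sorted(missing)}")
    if not isinstance(dossier["variant"], str) or not dossier["variant"]:
        raise MergeError("dossier variant must be a non-empty string")
    for stage in STAGES:
        if dossier[stage] is not None and not isinstance(dossier[stage], dict):
            raise MergeError(f"dossier section {stage!r} must be a mapping or null")
    if not isinstance(dossier["provenance"], dict):
        raise MergeError("dossier provenance must be a mapping")


# ---------------------------------------------------------------------------
# Stage runners (CSV/PDB in -> plain dict out)

def run_melt_stage(curves_csv, wt_variant: str = "WT",
                   delta_tm_threshold: float | None = None,
                   fix_normalization: bool = False) -> dict:
    curves = read_curves_csv(curves_csv)
    by_group: dict = {}
    for c in curves:
        by_group.setdefault((c.variant, c.nucleotide), []).append(c)
    variants: dict = {}
    for (variant, nucleotide), group in sorted(by_group.items()):
        fits = [fit_melting_curve(c, fix_normalization=fix_normalization)
                for c in group]
        v = variants.setdefault(variant, {"fits": {}, "summaries": {}, "phenotype": None})
        v["fits"][nucleotide] = [f.to_dict() for f in fits]
        v["summaries"][nucleotide] = summarize_tm(fits).to_dict()

    from .thermostability import TmSummary
    wt = variants.get(wt_variant, {}).get("summaries", {})
    if "GDP" in wt and any(n in wt for n in ("GTP", "GTPgS", "GTPyS")):
        gtp_key = next(n for n in ("GTP", "GTPgS", "GTPyS") if n in wt)
        wt_gdp = TmSummary(**wt["GDP"])
        wt_gtp = TmSummary(**wt[gtp_key])
        for variant, v in variants.items():
            s = v["summaries"]
            if "GDP" in s and gtp_key in s:
                pheno = classify_thermal_phenotype(
                    TmSummary(**s["GDP"]), TmSummary(**s[gtp_key]),
                    wt_gdp, wt_gtp, threshold=delta_tm_threshold)
                v["phenotype"] = pheno.to_dict()
    else:
        logger.warning("no wild-type GDP/GTP reference pair found; "
                       "skipping phenotype classification")
    return {"stage": "thermal", "variants": variants}


def run_kinetics_stage(traces_csv) -> dict:
    traces = read_traces_csv(traces_csv)
    variants: dict = {}
    for tr in traces:
        fit = fit_one_phase_association(tr)
        variants.setdefault(tr.variant, {})[tr.nucleotide or "default"] = fit.to_dict()
    return {"stage": "kinetics", "variants": variants}


def run_std_stage(std_csv, reference: str = "a",
                  reference_tolerance: float = 0.02) -> dict:
    variants: dict = {}
    for records, ctx in read_std_csv(std_csv):
        afs = compute_std_table(records, ctx)
        excluded = [r.proton_label for r in records if not r.usable]
        fp = normalize_fingerprint(afs, reference=reference,
                                   reference_tolerance=reference_tolerance,
                                   excluded=excluded)
        v = variants.setdefault(ctx.variant, {})
        v[ctx.nucleotide] = {
            "amplification": [
                {"proton": a.proton_label, "a_std": a.a_std, "sigma": a.sigma}
                for a in afs],
            "fingerprint": fp.to_dict(),
        }
    return {"stage": "std", "variants": variants}


def _load_regions(regions: dict | None) -> RegionMap:
    if regions is None:
        return default_switch_regions()
    return RegionMap({name: tuple(rng) for name, rng in regions.items()})


def run_trajectory_stage(traj_paths: Sequence, analyses: Sequence[str],
                         regions: dict | None = None,
                         persistence_thresholds=(0.1, 0.25, 0.5, 0.75),
                         radius: float = 6.0, proximity_mode: str = "closest",
                         superpose: bool = False) -> dict:
    """H-bond / RMSF / proximity read-outs, replica-aggregated when >1 path."""
    trajs = [read_trajectory_pdb(p) for p in traj_paths]
    out: dict = {"stage": "trajectory", "n_replicas": len(trajs)}
    if "hbond" in analyses:
        region_map = _load_regions(regions)
        matrices = [persistence_mask(hbond_occupancy(t, region_map),
                                     persistence_thresholds) for t in trajs]
        keys = sorted({pair for m in matrices for pair in m.entries})
        per_replica = [{f"{a}-{b}": m.entries.get((a, b), 0.0) for a, b in keys}
                       for m in matrices]
        if len(trajs) > 1:
            agg = aggregate_replicas(per_replica)
            occ = {k: {"mean": agg.means[k], "sem": agg.sems[k]} for k in agg.means}
        else:
            occ = {k: {"mean": v, "sem": None} for k, v in per_replica[0].items()}
        out["hbond_occupancy"] = occ
        out["persistence_levels"] = {
            f"{a}-{b}": matrices[0].levels((a, b)) for a, b in keys}
    if "rmsf" in analyses:
        profiles = [compute_rmsf(t, superpose=superpose) for t in trajs]
        per_replica = [{str(r): v for r, v in p.per_residue.items()} for p in profiles]
        if len(trajs) > 1:
            agg = aggregate_replicas(per_replica)
            out["rmsf"] = {k: {"mean": agg.means[k], "sem": agg.sems[k]}
                           for k in agg.means}
        else:
            out["rmsf"] = {k: {"mean": v, "sem": None}
                           for k, v in per_replica[0].items()}
    if "proximity" in analyses:
        profiles = [proton_proximity_profile(t, radius=radius, mode=proximity_mode)
                    for t in trajs]
        labels = sorted(profiles[0].frequencies)
        prox: dict = {}
        for label in labels:
            keys = sorted({r for p in profiles for r in p.frequencies[label]})
            per_replica = [
                {**{str(r): p.frequencies[label].get(r, 0.0) for r in keys},
                 "none": p.none_fraction[label]}
                for p in profiles]
            if len(trajs) > 1:
                agg = aggregate_replicas(per_replica)
                prox[label] = {k: {"mean": agg.means[k], "sem": agg.sems[k]}
                               for k in agg.means}
            else:
                prox[label] = {k: {"mean": v, "sem": None}
                               for k, v in per_replica[0].items()}
        out["proximity"] = prox
    return out


# ---------------------------------------------------------------------------
# Pipeline driver

def run_pipeline(config: RunConfig) -> tuple[int, dict, list]:
    """Run the selected analyses; returns (exit_status, artifacts, errors).

    Completed stage outputs are preserved on partial failure; the
    failure list summarizes what went wrong. Empty selection is a no-op
    success with a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run configuration: %s", json.dumps(config.to_dict(), sort_keys=True))
    if not config.analyses:
        logger.warning("empty analysis selection; nothing to do")
        return 0, {}, []

    prov = provenance_block(config, config.seed)
    artifacts: dict = {}
    failures: list = []

    def _stage(name, fn):
        try:
            payload = fn()
            payload["provenance"] = prov
            path = outdir / f"{name}_report.json"
            write_json(payload, path)
            artifacts[name] = str(path)
            logger.info("stage %s: ok -> %s", name, path)
        except Exception as exc:  # noqa: BLE001 - summarize, keep going
            failures.append(f"{name}: {type(exc).__name__}: {exc}")
            logger.error("stage %s failed: %s", name, exc)

    if "melt" in config.analyses:
        _stage("thermal", lambda: run_melt_stage(
            config.inputs["melt"], wt_variant=config.wt_variant,
            delta_tm_threshold=config.delta_tm_threshold,
            fix_normalization=config.fix_normalization))
    if "kinetics" in config.analyses:
        _stage("kinetics", lambda: run_kinetics_stage(config.inputs["kinetics"]))
    if "std" in config.analyses:
        _stage("std", lambda: run_std_stage(
            config.inputs["std"], reference=config.fingerprint_reference,
            reference_tolerance=config.reference_tolerance))
    traj_analyses = [a for a in ("hbond", "rmsf", "proximity")
                     if a in config.analyses]
    if traj_analyses:
        paths = config.inputs["traj"]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        _stage("trajectory", lambda: run_trajectory_stage(
            paths, traj_analyses, regions=config.regions,
            persistence_thresholds=config.persistence_thresholds,
            radius=config.radius, proximity_mode=config.proximity_mode,
            superpose=config.superpose))

    return (1 if failures else 0), artifacts, failures
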