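"""Orchestration of the full analysis: poses -> volumes -> masses -> report.

The pipeline runs from a single configuration: load the segment manifest,
assemble each requested pose, hull every functional unit, sum to the total
C_vol, convert to mass through the calibration regression, add armour, and
assemble the comparison of volumetric estimates against limb-circumference
equations and DME-corrected values.  The inverse problem — expanding a
skeletal model isotropically until its predicted mass matches a target —
is solved in closed form for the fitted power law.

All outputs are delimited text; identical configuration and seed reproduce
them byte-for-byte.
"""

from __future__ import annotations

import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import reference
from .errors import DomainError, HullmassError, RegistryError
from .geometry import SegmentManifest, load_skeleton, read_manifest
from .hulls import SkeletonVolume, skeleton_volume
from .mass import (
    ArmourSpec,
    CalibrationDataset,
    CalibrationFit,
    MassEstimate,
    SpecimenMeasurements,
    add_components,
    dme_scale,
    fit_power_law,
    get_equation,
    limb_mass,
    load_equation_registry,
    predict_mass,
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class DMERequest:
    """One Developmental Mass Extrapolation row.

    The adult endpoint is either an explicit (mean, lower, upper) estimate
    or a limb equation evaluated on adult measurements; the result is the
    adult mass scaled by the cubed femoral-length ratio.
    """

    label: str
    adult_fl_mm: float
    sub_fl_mm: float
    adult_estimate: MassEstimate | None = None
    equation_id: str | None = None
    adult_measurements: SpecimenMeasurements | None = None


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; see ``AnalysisConfig.from_yaml``."""

    manifest_path: Path | None = None
    poses: list[str] = field(default_factory=list)
    calibration: str = "fixture"  # "fixture" or a calibration CSV path
    armour_kg: float = 0.0
    registry_path: Path | None = None
    equations: list[str] = field(default_factory=list)
    measurements: SpecimenMeasurements | None = None
    dme: list[DMERequest] = field(default_factory=list)
    rescale: dict | None = None  # {"base_pose": str, "target_kg": float}
    reference_method: str = "CE2012_b"
    pi_level: float = 0.95
    seed: int = 0
    outdir: Path = Path("hullmass_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        base = path.parent

        def _resolve(p):
            return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

        meas = None
        if doc.get("measurements"):
            m = doc["measurements"]
            meas = SpecimenMeasurements(
                specimen_id=m.get("specimen_id", "specimen"),
                humeral_circumference_mm=m.get("humeral_circumference_mm"),
                femoral_circumference_mm=m.get("femoral_circumference_mm"),
                femoral_length_mm=m.get("femoral_length_mm"),
                ontogenetic_status=m.get("ontogenetic_status", ""),
            )
        dme_reqs = []
        for d in doc.get("dme", []):
            est = None
            if "adult_mean" in d:
                est = MassEstimate(
                    mean=float(d["adult_mean"]),
                    lower=float(d.get("adult_lower", d["adult_mean"])),
                    upper=float(d.get("adult_upper", d["adult_mean"])),
                )
            am = None
            if d.get("adult_measurements"):
                a = d["adult_measurements"]
                am = SpecimenMeasurements(
                    specimen_id=a.get("specimen_id", d["label"]),
                    humeral_circumference_mm=a.get("humeral_circumference_mm"),
                    femoral_circumference_mm=a.get("femoral_circumference_mm"),
                    femoral_length_mm=a.get("femoral_length_mm"),
                )
            dme_reqs.append(
                DMERequest(
                    label=d["label"],
                    adult_fl_mm=float(d["adult_fl_mm"]),
                    sub_fl_mm=float(d["sub_fl_mm"]),
                    adult_estimate=est,
                    equation_id=d.get("equation"),
                    adult_measurements=am,
                )
            )
        calibration = doc.get("calibration", "fixture")
        if calibration != "fixture":
            calibration = str(_resolve(calibration))
        return cls(
            manifest_path=_resolve(doc.get("manifest")),
            poses=list(doc.get("poses", [])),
            calibration=calibration,
            armour_kg=float(doc.get("armour_kg", 0.0)),
            registry_path=_resolve(doc.get("registry")),
            equations=list(doc.get("equations", [])),
            measurements=meas,
            dme=dme_reqs,
            rescale=doc.get("rescale"),
            reference_method=doc.get("reference_method", "CE2012_b"),
            pi_level=float(doc.get("pi_level", 0.95)),
            seed=int(doc.get("seed", 0)),
            outdir=_resolve(doc.get("outdir")) or Path("hullmass_out"),
        )

    def load_fit(self) -> CalibrationFit:
        if self.calibration == "fixture":
            return reference.fixture_calibration_fit()
        return fit_power_law(CalibrationDataset.from_csv(self.calibration))

    def load_manifest(self) -> SegmentManifest:
        if self.manifest_path is None:
            raise DomainError("no segment manifest configured")
        manifest = read_manifest(self.manifest_path)
        manifest.validate_files()
        return manifest


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


@dataclass
class PoseResult:
    volumes: SkeletonVolume
    estimate: MassEstimate


def run_volumetric(
    config: AnalysisConfig, log: list[str] | None = None
) -> dict[str, PoseResult]:
    """Hull every pose and convert its total C_vol to a mass estimate.

    A failure in one pose is logged and the remaining poses continue.
    """
    log = log if log is not None else []
    fit = config.load_fit()
    manifest = config.load_manifest()
    armour = ArmourSpec(total_kg=config.armour_kg)
    poses = config.poses or manifest.pose_labels
    results: dict[str, PoseResult] = {}
    for pose in poses:
        t0 = time.perf_counter()
        try:
            model = load_skeleton(manifest, pose)
            vols = skeleton_volume(model)
            est = add_components(
                predict_mass(fit, vols.total, level=config.pi_level), armour
            )
            results[pose] = PoseResult(volumes=vols, estimate=est)
            log.append(
                f"run_volumetric[{pose}]: total={vols.total:.6f} m^3, "
                f"mean={est.mean:.1f} kg ({time.perf_counter() - t0:.2f}s)"
            )
        except HullmassError as exc:
            log.append(f"run_volumetric[{pose}]: FAILED: {exc}")
    return results


def rescale_to_target(
    volumes: SkeletonVolume,
    fit: CalibrationFit,
    armour: ArmourSpec,
    target_kg: float,
) -> tuple[float, SkeletonVolume, MassEstimate]:
    """Isotropic linear scale factor k so predicted mass (+armour) = target.

    For the power law mass = a V^b the solve is closed-form:
    k^3 = ((target - armour) / a)^(1/b) / total.  A non-monotone fit
    (slope <= 0) falls back to bracketed bisection on k.  Every unit
    volume is multiplied by k^3 (uniform over units — the expansion is a
    shape-preserving inflation of the whole model).
    """
    if target_kg <= armour.total_kg:
        raise DomainError(
            f"target mass {target_kg} kg must exceed armour mass {armour.total_kg} kg"
        )
    total = volumes.total
    if total <= 0:
        raise DomainError("cannot rescale a model with zero total volume")
    hull_target = target_kg - armour.total_kg
    if fit.slope > 0:
        k3 = (hull_target / fit.a) ** (1.0 / fit.slope) / total
        k = k3 ** (1.0 / 3.0)
    else:

        def f(k: float) -> float:
            return predict_mass(fit, k**3 * total).mean - hull_target

        lo, hi = 1e-6, 1e6
        if f(lo) * f(hi) > 0:
            raise DomainError(
                "cannot bracket a scale factor matching the target mass "
                "with this (non-monotone) calibration fit"
            )
        k = float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))
    scaled = volumes.scaled(k)
    est = add_components(predict_mass(fit, scaled.total), armour)
    if abs(est.mean - target_kg) > 1e-3 * target_kg:
        raise DomainError(
            f"rescale verification failed: predicted {est.mean:.3f} kg "
            f"vs target {target_kg} kg"
        )
    return k, scaled, est


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """Assembled outputs: volume table, mass table, percentage ratios.

    ``volume_table`` has segments as rows and poses as columns with a
    trailing ``total`` row (values in m^3, rounded to 4 decimals only when
    written).  ``mass_table`` has one row per method (volumetric pose, limb
    equation or DME endpoint) with mean/lower/upper in kg.  ``percentages``
    maps each volumetric method to 100 * mean / reference-method mean,
    rounded half-away-from-zero to integer percent.
    """

    volume_table: pd.DataFrame
    mass_table: pd.DataFrame
    percentages: dict[str, int]
    reference_method: str | None
    log: list[str] = field(default_factory=list)


def _percentages(
    mass_table: pd.DataFrame, reference_method: str | None
) -> dict[str, int]:
    vol_rows = mass_table[mass_table["kind"] == "volumetric"]
    if reference_method is None or len(mass_table) < 2 or vol_rows.empty:
        return {}
    if reference_method not in mass_table.index:
        raise RegistryError(
            f"reference method {reference_method!r} absent from the report; "
            f"have {list(mass_table.index)}"
        )
    ref_mean = float(mass_table.loc[reference_method, "mean"])
    return {
        method: round_half_away(100.0 * float(row["mean"]) / ref_mean)
        for method, row in vol_rows.iterrows()
    }


def run_comparison(config: AnalysisConfig) -> ComparisonReport:
    """Assemble volumetric, limb-equation and DME estimates side by side."""
    log: list[str] = []
    rows: list[dict] = []
    volume_table = pd.DataFrame()

    if config.manifest_path is not None:
        pose_results = run_volumetric(config, log)
        if pose_results:
            volume_table = pd.DataFrame(
                {p: r.volumes.unit_volumes for p, r in pose_results.items()}
            )
            volume_table.loc["total"] = [
                pose_results[p].volumes.total for p in volume_table.columns
            ]
        for pose, res in pose_results.items():
            rows.append(
                {
                    "method": f"cvol_{pose}",
                    "kind": "volumetric",
                    "mean": res.estimate.mean,
                    "lower": res.estimate.lower,
                    "upper": res.estimate.upper,
                }
            )

    if config.rescale:
        base_pose = config.rescale["base_pose"]
        target = float(config.rescale["target_kg"])
        fit = config.load_fit()
        armour = ArmourSpec(total_kg=config.armour_kg)
        base = next(
            (r for r in rows if r["method"] == f"cvol_{base_pose}"), None
        )
        if base is None:
            log.append(f"rescale: base pose {base_pose!r} unavailable, skipped")
        else:
            base_vols = SkeletonVolume(
                pose_label=base_pose,
                unit_volumes=dict(
                    volume_table[base_pose].drop("total", errors="ignore")
                ),
            )
            k, scaled, est = rescale_to_target(base_vols, fit, armour, target)
            log.append(
                f"rescale_to_target: k={k:.6f}, total={scaled.total:.4f} m^3"
            )
            volume_table[f"{base_pose}_rescaled"] = pd.Series(
                {**scaled.unit_volumes, "total": scaled.total}
            )
            rows.append(
                {
                    "method": f"cvol_{base_pose}_rescaled",
                    "kind": "volumetric",
                    "mean": est.mean,
                    "lower": est.lower,
                    "upper": est.upper,
                }
            )

    registry = None
    if config.equations or any(d.equation_id for d in config.dme):
        registry = load_equation_registry(config.registry_path)

    if config.equations:
        if config.measurements is None:
            raise DomainError("limb equations configured but no specimen measurements")
        for eq_id in config.equations:
            eq = get_equation(registry, eq_id)
            est = limb_mass(eq, config.measurements, level=config.pi_level)
            rows.append(
                {
                    "method": eq_id,
                    "kind": "limb",
                    "mean": est.mean,
                    "lower": est.lower,
                    "upper": est.upper,
                }
            )
            log.append(f"limb_mass[{eq_id}]: mean={est.mean:.1f} kg")

    for req in config.dme:
        if req.adult_estimate is not None:
            adult = req.adult_estimate
        elif req.equation_id is not None and req.adult_measurements is not None:
            eq = get_equation(registry, req.equation_id)
            adult = limb_mass(eq, req.adult_measurements, level=config.pi_level)
        else:
            raise DomainError(
                f"DME request {req.label!r} needs either an adult estimate or "
                "an equation plus adult measurements"
            )
        est = dme_scale(adult, req.adult_fl_mm, req.sub_fl_mm)
        rows.append(
            {
                "method": req.label,
                "kind": "dme",
                "mean": est.mean,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
        log.append(f"dme[{req.label}]: mean={est.mean:.1f} kg")

    if not rows:
        raise DomainError("no methods configured: nothing to compare")
    mass_table = pd.DataFrame(rows).set_index("method")
    reference_method = config.reference_method if len(mass_table) > 1 else None
    percentages = _percentages(mass_table, reference_method)
    if percentages:
        mass_table["pct_of_reference"] = [
            percentages.get(m, pd.NA) for m in mass_table.index
        ]
    return ComparisonReport(
        volume_table=volume_table,
        mass_table=mass_table,
        percentages=percentages,
        reference_method=reference_method,
        log=log,
    )


def write_report(
    report: ComparisonReport,
    outdir: str | Path,
    seed: int = 0,
    config_echo: str = "",
) -> dict[str, Path]:
    """Write the volume and mass tables plus a run log.

    Volumes are rounded to 4 decimals (m^3) at this reporting boundary
    only; masses to 1 decimal (kg).  Table files contain no timestamps, so
    re-running with the same configuration and seed reproduces them
    byte-for-byte; wall-clock timings go to the log only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if not report.volume_table.empty:
        p = outdir / "volumes.csv"
        report.volume_table.round(4).to_csv(p, index_label="segment")
        paths["volumes"] = p
    p = outdir / "masses.csv"
    report.mass_table.round(1).to_csv(p, index_label="method")
    paths["masses"] = p
    log_path = outdir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"hullmass run log\nseed: {seed}\n")
        fh.write(f"python: {sys.version.split()[0]}\n")
        fh.write(f"numpy: {np.__version__}\npandas: {pd.__version__}\n")
        if report.reference_method:
            fh.write(f"reference method: {report.reference_method}\n")
        if config_echo:
            fh.write("--- config ---\n" + config_echo.rstrip() + "\n")
        fh.write("--- stages ---\n")
        for line in report.log:
            fh.write(line + "\n")
    paths["log"] = log_path
    return paths
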