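"""Volume-to-mass calibration, limb-circumference equations, armour and DME.

The central statistical object is an ordinary least-squares fit of
log10(body mass, kg) on log10(convex-hull volume, m^3) over a calibration
set of extant taxa — a power law ``mass = a * C_vol ** b``.  Density is
never an explicit parameter: it is implicit in the calibration data, with
the assumption that the fossil's density falls within the calibration
species' range.  Prediction intervals are the standard OLS intervals for a
*new observation* in log10 space,

    t_{1-alpha/2, n-2} * s * sqrt(1 + 1/n + (x0 - xbar)^2 / Sxx),

back-transformed by ``10**x`` at the endpoints (no smearing correction —
this matches standard practice in the mass-estimation literature and
yields the familiar asymmetric intervals).  A t quantile with df = n - 2
is used because calibration samples are small.

Limb-circumference predictive equations (e.g. the bivariate equation on
summed humeral + femoral midshaft circumference) live in a configuration
registry with provenance fields: their published coefficients are facts of
the cited literature, so the registry ships unconfigured stubs that the
user fills in from the original sources, plus a documented synthetic
example.

Dermal armour (osteoderm plates and spikes) is added to each volumetric
estimate as a variance-free constant, shifting mean and both interval
bounds alike.  Developmental Mass Extrapolation (DME) rescales an adult's
estimated mass to a subadult by the cubed ratio of femoral lengths
(isometric scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import DomainError, InsufficientDataError, RegistryError

# ---------------------------------------------------------------------------
# Calibration data and power-law fit
# ---------------------------------------------------------------------------


@dataclass
class CalibrationDataset:
    """(taxon, convex-hull volume m^3, body mass kg) calibration rows."""

    taxa: list[str]
    volumes_m3: np.ndarray
    masses_kg: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.volumes_m3 = np.asarray(self.volumes_m3, dtype=float)
        self.masses_kg = np.asarray(self.masses_kg, dtype=float)
        if len(self.taxa) != len(self.volumes_m3) or len(self.taxa) != len(
            self.masses_kg
        ):
            raise ValueError("taxa, volumes and masses must have equal length")
        if (self.volumes_m3 <= 0).any() or (self.masses_kg <= 0).any():
            raise DomainError("calibration volumes and masses must be positive")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "CalibrationDataset":
        """Read delimited text with columns taxon, volume_m3, mass_kg."""
        df = pd.read_csv(path)
        required = {"taxon", "volume_m3", "mass_kg"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(
            taxa=df["taxon"].astype(str).tolist(),
            volumes_m3=df["volume_m3"].to_numpy(),
            masses_kg=df["mass_kg"].to_numpy(),
            provenance=provenance or str(path),
        )

    def to_csv(self, path: str | Path) -> Path:
        pd.DataFrame(
            {"taxon": self.taxa, "volume_m3": self.volumes_m3, "mass_kg": self.masses_kg}
        ).to_csv(path, index=False)
        return Path(path)


@dataclass
class CalibrationFit:
    """Fitted log10–log10 power law with everything needed for PIs.

    ``intercept`` is log10(a); the point prediction at volume V is
    ``10 ** (intercept + slope * log10 V)``.  ``x_mean`` and ``sxx`` are the
    mean and sum of squared deviations of the log10 calibration volumes,
    used in the prediction-interval leverage term.
    """

    slope: float
    intercept: float
    n: int
    resid_se: float
    x_mean: float
    sxx: float
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("slope", "intercept", "resid_se", "x_mean", "sxx"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite fit field {name}")
        if self.resid_se < 0:
            raise ValueError("residual standard error must be >= 0")

    @property
    def a(self) -> float:
        """Power-law coefficient in kg per (m^3)^slope."""
        return 10.0**self.intercept

    @property
    def b(self) -> float:
        """Power-law exponent (allometric slope)."""
        return self.slope

    @classmethod
    def from_two_points(
        cls,
        v1: float,
        m1: float,
        v2: float,
        m2: float,
        provenance: str = "two-point fixture",
    ) -> "CalibrationFit":
        """Exact power law through two (volume, mass) pairs.

        A consistency fixture, not a statistical fit: with zero residual
        degrees of freedom the residual SE is zero and prediction intervals
        collapse to the point prediction.
        """
        if min(v1, v2, m1, m2) <= 0:
            raise DomainError("two-point fit requires positive volumes and masses")
        if v1 == v2:
            raise DomainError("two-point fit requires distinct volumes")
        x1, x2 = math.log10(v1), math.log10(v2)
        y1, y2 = math.log10(m1), math.log10(m2)
        slope = (y2 - y1) / (x2 - x1)
        intercept = y1 - slope * x1
        x_mean = 0.5 * (x1 + x2)
        sxx = (x1 - x_mean) ** 2 + (x2 - x_mean) ** 2
        return cls(
            slope=slope,
            intercept=intercept,
            n=2,
            resid_se=0.0,
            x_mean=x_mean,
            sxx=sxx,
            provenance=provenance,
        )


def fit_power_law(data: CalibrationDataset) -> CalibrationFit:
    """OLS fit of log10 mass on log10 volume.

    Minimises squared log10 residuals; stores n, the residual standard
    error (df = n - 2) and the leverage statistics needed for prediction
    intervals.  Noise-free power-law data is reproduced exactly.
    """
    if data.n < 3:
        raise InsufficientDataError(
            f"need at least 3 calibration rows, got {data.n}"
        )
    x = np.log10(data.volumes_m3)
    y = np.log10(data.masses_kg)
    x_mean = float(x.mean())
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0.0:
        raise InsufficientDataError("all calibration volumes identical; slope undefined")
    slope = float(((x - x_mean) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    resid_se = float(np.sqrt((resid**2).sum() / (data.n - 2)))
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        n=data.n,
        resid_se=resid_se,
        x_mean=x_mean,
        sxx=sxx,
        provenance=data.provenance,
    )


# ---------------------------------------------------------------------------
# Mass estimates
# ---------------------------------------------------------------------------


@dataclass
class MassEstimate:
    """Mean mass with a prediction interval and additive components (kg)."""

    mean: float
    lower: float
    upper: float
    level: float = 0.95
    components: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError(
                f"interval ordering violated: {self.lower} <= {self.mean} <= "
                f"{self.upper} required"
            )
        if self.components:
            total = sum(v for _, v in self.components)
            if not math.isclose(total, self.mean, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"component means sum to {total}, but mean is {self.mean}"
                )


def predict_mass(fit: CalibrationFit, cvol: float, level: float = 0.95) -> MassEstimate:
    """Predict body mass (with PI) from a total convex-hull volume.

    The mean is the back-transformed linear predictor (median-unbiased; no
    smearing correction).  The PI is the OLS new-observation interval in
    log10 space, back-transformed at the endpoints, hence asymmetric about
    the mean.  With zero residual SE (or fewer than 3 calibration points)
    the interval collapses to the mean.
    """
    if cvol <= 0:
        raise DomainError(f"convex-hull volume must be positive, got {cvol}")
    if not 0 < level < 1:
        raise DomainError(f"PI level must be in (0, 1), got {level}")
    x0 = math.log10(cvol)
    yhat = fit.intercept + fit.slope * x0
    mean = 10.0**yhat
    if fit.resid_se > 0 and fit.n > 2:
        tq = float(stats.t.ppf(0.5 + level / 2.0, fit.n - 2))
        half = tq * fit.resid_se * math.sqrt(
            1.0 + 1.0 / fit.n + (x0 - fit.x_mean) ** 2 / fit.sxx
        )
        lower, upper = 10.0 ** (yhat - half), 10.0 ** (yhat + half)
    else:
        lower = upper = mean
    return MassEstimate(
        mean=mean,
        lower=lower,
        upper=upper,
        level=level,
        components=[("hull-derived", mean)],
    )


@dataclass
class ArmourSpec:
    """Dermal armour as an additive mass (kg), optionally itemised."""

    total_kg: float = 34.0
    items: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_kg < 0:
            raise DomainError(f"armour mass must be >= 0, got {self.total_kg}")
        if self.items:
            total = sum(m for _, m in self.items)
            if not math.isclose(total, self.total_kg, rel_tol=1e-9, abs_tol=1e-9):
                raise DomainError(
                    f"itemised armour sums to {total}, not {self.total_kg}"
                )


def add_components(
    estimate: MassEstimate, armour: ArmourSpec, label: str = "dermal armour"
) -> MassEstimate:
    """Add a known-constant mass component to an estimate.

    The armour is treated as variance-free: mean and both PI bounds shift
    by the same amount, preserving interval ordering exactly.
    """
    shift = armour.total_kg
    base = estimate.components or [("base", estimate.mean)]
    return MassEstimate(
        mean=estimate.mean + shift,
        lower=estimate.lower + shift,
        upper=estimate.upper + shift,
        level=estimate.level,
        components=[*base, (label, shift)],
    )


def dme_scale(
    adult: MassEstimate, adult_fl_mm: float, sub_fl_mm: float
) -> MassEstimate:
    """Developmental Mass Extrapolation: adult -> subadult by femur length.

    Isometric scaling multiplies mass by (sub_FL / adult_FL)^3; the factor
    is applied to the mean, both PI bounds and every component, so interval
    ordering and the component-sum invariant are preserved.  Composes:
    scaling to FL1 then FL2 equals scaling directly to FL2.
    """
    if adult_fl_mm <= 0 or sub_fl_mm <= 0:
        raise DomainError(
            f"femoral lengths must be positive, got {adult_fl_mm}, {sub_fl_mm}"
        )
    k = (sub_fl_mm / adult_fl_mm) ** 3
    return MassEstimate(
        mean=adult.mean * k,
        lower=adult.lower * k,
        upper=adult.upper * k,
        level=adult.level,
        components=[(lbl, v * k) for lbl, v in adult.components],
    )


# ---------------------------------------------------------------------------
# Specimen measurements and limb-circumference equations
# ---------------------------------------------------------------------------


@dataclass
class SpecimenMeasurements:
    """Linear limb measurements of one specimen (millimetres)."""

    specimen_id: str
    humeral_circumference_mm: float | None = None
    femoral_circumference_mm: float | None = None
    femoral_length_mm: float | None = None
    ontogenetic_status: str = ""

    def __post_init__(self) -> None:
        for name in (
            "humeral_circumference_mm",
            "femoral_circumference_mm",
            "femoral_length_mm",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be positive, got {v}")


#: Predictor specifications a LimbEquation may declare.
PREDICTOR_SPECS = (
    "summed_circumference",  # log10(C_h + C_f)
    "separate_circumferences",  # slopes for log10 C_h and log10 C_f
    "femur_circumference",  # log10 C_f only
)


@dataclass
class LimbEquation:
    """A configured circumference-based predictive equation.

    Log10-linear form: ``log10(mass) = intercept + sum_i slope_i * log10(p_i)``
    with predictors in millimetres and output in the declared unit (g or
    kg), converted to kg at the boundary.  The prediction-interval method is
    either ``log_se`` (a log10-space half-width parameter, optionally with a
    t-distribution df) or ``percent_error`` (a symmetric percent prediction
    error about the mean); ``pi_param = 0`` degenerates to the mean.
    """

    id: str
    predictor: str
    slopes: tuple[float, ...]
    intercept: float
    output_unit: str = "kg"
    pi_method: str = "log_se"
    pi_param: float = 0.0
    pi_df: int | None = None
    citation: str = ""

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTOR_SPECS:
            raise RegistryError(
                f"equation {self.id!r}: unknown predictor {self.predictor!r}"
            )
        self.slopes = tuple(float(s) for s in self.slopes)
        expected = 2 if self.predictor == "separate_circumferences" else 1
        if len(self.slopes) != expected:
            raise RegistryError(
                f"equation {self.id!r}: predictor {self.predictor!r} needs "
                f"{expected} slope(s), got {len(self.slopes)}"
            )
        if self.output_unit not in ("g", "kg"):
            raise RegistryError(
                f"equation {self.id!r}: output unit must be g or kg, "
                f"got {self.output_unit!r}"
            )
        if self.pi_method not in ("log_se", "percent_error", "none"):
            raise RegistryError(
                f"equation {self.id!r}: unknown PI method {self.pi_method!r}"
            )
        if self.pi_param < 0:
            raise RegistryError(f"equation {self.id!r}: PI parameter must be >= 0")

    def _predictors(self, m: SpecimenMeasurements) -> list[float]:
        ch = m.humeral_circumference_mm
        cf = m.femoral_circumference_mm
        if self.predictor == "summed_circumference":
            if ch is None or cf is None:
                missing = [
                    n
                    for n, v in (
                        ("humeral_circumference_mm", ch),
                        ("femoral_circumference_mm", cf),
                    )
                    if v is None
                ]
                raise DomainError(
                    f"equation {self.id!r} needs {missing} for specimen "
                    f"{m.specimen_id!r}"
                )
            return [ch + cf]
        if self.predictor == "separate_circumferences":
            if ch is None:
                raise DomainError(
                    f"equation {self.id!r} needs ['humeral_circumference_mm']"
                )
            if cf is None:
                raise DomainError(
                    f"equation {self.id!r} needs ['femoral_circumference_mm']"
                )
            return [ch, cf]
        if cf is None:
            raise DomainError(f"equation {self.id!r} needs ['femoral_circumference_mm']")
        return [cf]


def limb_mass(
    eq: LimbEquation, m: SpecimenMeasurements, level: float = 0.95
) -> MassEstimate:
    """Evaluate a limb-circumference equation for one specimen (kg)."""
    preds = eq._predictors(m)
    log_mass = eq.intercept + sum(s * math.log10(p) for s, p in zip(eq.slopes, preds))
    mean = 10.0**log_mass
    if eq.pi_method == "log_se" and eq.pi_param > 0:
        q = (
            float(stats.t.ppf(0.5 + level / 2.0, eq.pi_df))
            if eq.pi_df
            else float(stats.norm.ppf(0.5 + level / 2.0))
        )
        half = q * eq.pi_param
        lower, upper = 10.0 ** (log_mass - half), 10.0 ** (log_mass + half)
    elif eq.pi_method == "percent_error" and eq.pi_param > 0:
        lower = mean * (1.0 - eq.pi_param / 100.0)
        upper = mean * (1.0 + eq.pi_param / 100.0)
        if lower < 0:
            lower = 0.0
    else:
        lower = upper = mean
    unit_factor = 1e-3 if eq.output_unit == "g" else 1.0
    mean, lower, upper = mean * unit_factor, lower * unit_factor, upper * unit_factor
    return MassEstimate(
        mean=mean,
        lower=lower,
        upper=upper,
        level=level,
        components=[(eq.id, mean)],
    )


# ---------------------------------------------------------------------------
# Equation registry
# ---------------------------------------------------------------------------


def _registry_default_path() -> Path:
    from importlib import resources

    return Path(str(resources.files("hullmass").joinpath("data/equation_registry.yaml")))


def load_equation_registry(path: str | Path | None = None) -> dict[str, LimbEquation]:
    """Load limb equations from a YAML registry.

    Entries whose ``coefficients`` block is absent or null are *stubs*:
    placeholders carrying provenance for published equations whose
    coefficients must be supplied by the user from the cited sources.
    Stubs are skipped here; requesting one by id through
    :func:`get_equation` raises :class:`RegistryError` with the citation.
    """
    path = Path(path) if path is not None else _registry_default_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    equations: dict[str, LimbEquation] = {}
    stubs: dict[str, str] = {}
    for entry in doc.get("equations", []):
        eq_id = entry["id"]
        coeffs = entry.get("coefficients")
        if not coeffs:
            stubs[eq_id] = entry.get("citation", "")
            continue
        slopes = coeffs.get("slopes", coeffs.get("slope"))
        if slopes is None:
            raise RegistryError(f"equation {eq_id!r}: coefficients lack slopes")
        if not isinstance(slopes, (list, tuple)):
            slopes = [slopes]
        pi = entry.get("pi", {}) or {}
        equations[eq_id] = LimbEquation(
            id=eq_id,
            predictor=entry["predictor"],
            slopes=tuple(slopes),
            intercept=float(coeffs["intercept"]),
            output_unit=entry.get("output_unit", "kg"),
            pi_method=pi.get("method", "none"),
            pi_param=float(pi.get("param", 0.0)),
            pi_df=pi.get("df"),
            citation=entry.get("citation", ""),
        )
    load_equation_registry._stubs = stubs  # type: ignore[attr-defined]
    return equations


def get_equation(
    registry: dict[str, LimbEquation], eq_id: str
) -> LimbEquation:
    if eq_id in registry:
        return registry[eq_id]
    stubs = getattr(load_equation_registry, "_stubs", {})
    if eq_id in stubs:
        raise RegistryError(
            f"equation {eq_id!r} is a stub: supply its coefficients from "
            f"{stubs[eq_id] or 'the cited source'} in the registry file"
        )
    raise RegistryError(f"unknown equation id {eq_id!r}")
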