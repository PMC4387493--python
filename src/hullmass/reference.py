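"""Packaged reference tables for the Stegosaurus (NHMUK R36730) case study.

Two published tables ship with the package as plain CSV:

* per-segment convex-hull volumes (m^3) of the four pose variants of the
  NHMUK R36730 skeletal model — ``pref`` (preferred articulation), ``min``
  and ``max`` (rearticulation sensitivity bounds) and ``ce`` (the model
  expanded until its predicted mass matches the bivariate
  limb-circumference estimate);
* the published mass estimates (kg, with 95% prediction intervals) for the
  volumetric models, the limb-circumference equations and the two
  DME-corrected values.

They serve as inputs and consistency fixtures: the calibration that
produced the published masses is in literature supplements, so the package
also provides a *two-point fixture fit* — the exact power law through the
(total volume, hull-derived mass) pairs of the preferred and expanded
models.  It reproduces the published means closely but is a documented
fixture, not the published calibration regression.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .hulls import SkeletonVolume
from .mass import ArmourSpec, CalibrationFit

#: Published dermal-armour mass for NHMUK R36730 (kg).
ARMOUR_KG = 34.0

POSE_COLUMNS = ("pref", "min", "max", "ce")

#: Published total C_vol per pose (m^3).  The per-segment columns are
#: printed to 4 decimals, so their sums can differ from these totals by a
#: few 1e-4 for pref/min/max; the ce column sums exactly.
PUBLISHED_TOTALS = {"pref": 1.2800, "min": 1.0558, "max": 1.5848, "ce": 3.3781}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("hullmass").joinpath(f"data/{name}")))


def segment_volume_table() -> pd.DataFrame:
    """Per-segment hull volumes (m^3), segments as index, poses as columns."""
    df = pd.read_csv(_data_path("stegosaurus_segment_volumes.csv"))
    return df.set_index("segment")


def segment_volumes(pose: str) -> SkeletonVolume:
    """One pose column of the packaged volume table as a SkeletonVolume."""
    table = segment_volume_table()
    if pose not in table.columns:
        raise KeyError(f"unknown pose {pose!r}; have {list(table.columns)}")
    return SkeletonVolume(
        pose_label=pose, unit_volumes=dict(table[pose].items())
    )


def published_estimates() -> pd.DataFrame:
    """Published mass estimates (kg): method, kind, mean, lower, upper."""
    return pd.read_csv(_data_path("stegosaurus_published_estimates.csv")).set_index(
        "method"
    )


def default_armour() -> ArmourSpec:
    return ArmourSpec(total_kg=ARMOUR_KG)


def fixture_calibration_fit() -> CalibrationFit:
    """Two-point power law through the preferred and expanded models.

    Anchored at the (total C_vol, hull-derived mass) pairs of the ``pref``
    and ``ce`` models, i.e. published mean minus armour.  Exponent ~0.916,
    coefficient ~1.22e3 kg m^-3b.  Residual SE is zero, so prediction
    intervals collapse to the mean; the published intervals come from the
    literature calibration, which is configured separately when available.
    """
    est = published_estimates()
    return CalibrationFit.from_two_points(
        v1=PUBLISHED_TOTALS["pref"],
        m1=float(est.loc["cvol_pref", "mean"] - ARMOUR_KG),
        v2=PUBLISHED_TOTALS["ce"],
        m2=float(est.loc["cvol_ce", "mean"] - ARMOUR_KG),
        provenance="two-point fixture through the pref and ce models",
    )
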