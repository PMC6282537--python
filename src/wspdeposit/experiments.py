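"""Validation experiments for DepositScan-style card analysis.

Three scripted analyses:

* :func:`run_spread_factor_comparison` — artificial circular stains run
  through both spread-factor models, tabulating droplet diameters,
  their percent difference, and per-stain volumes (analytic areas, or
  rasterized images measured back through the segmentation pipeline).
* :func:`run_touching_test` — pairs of equal stains, tangent versus
  separated, quantifying how much deposition is overestimated when a
  merged pair is treated as a single larger deposit.  Under the
  constant power-law model the analytic overestimation is exactly
  ``2**(3*0.455 - 1) - 1`` (about 28.85%) for any diameter.
* :func:`compare_methods` — the leaf-vs-card calibration: exclude
  high-coverage cards, convert deposition to residue via the tank mix,
  fit the empirical correction factor, and summarize both arms before
  and after correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import card_imaging as ci
from .field_summary import exclusion_filter, group_summary
from .residue_model import (
    CorrectionFactorModel,
    TankMix,
    deposit_from_deposition,
    fit_correction_factor,
)
from .stain_geometry import (
    BinnedSpreadFactor,
    ConstantSpreadFactor,
    droplet_volume,
    percent_difference,
    stain_diameter_from_area,
)

__all__ = [
    "TABLE4_GRID_UM",
    "ExperimentReport",
    "run_spread_factor_comparison",
    "run_touching_test",
    "compare_methods",
]

#: Reference grid of hypothetical stain diameters (µm) for model comparison.
TABLE4_GRID_UM = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0)

#: Diameter range (µm) of the artificial-stain experiments.
ARTIFICIAL_RANGE_UM = (95.5, 1438.0)


@dataclass
class ExperimentReport:
    """Per-stain table plus summary dict and the config that produced them."""

    table: pd.DataFrame
    summary: dict
    config: dict = field(default_factory=dict)


def _measure_rasterized_areas(diameters_um, dpi, seg=None):
    """Rasterize each stain alone and measure its area via segmentation."""
    seg = ci.SegmentationConfig() if seg is None else seg
    areas = []
    for d in diameters_um:
        pitch = ci.UM_PER_INCH / dpi
        r_px = 0.5 * d / pitch
        side = int(math.ceil(2 * r_px)) + 10
        card = ci.blank_card(side, side, dpi)
        ci.rasterize_circle(card, ((side - 1) / 2, (side - 1) / 2), d)
        _, stains = ci.segment_card(card, seg)
        if len(stains) != 1:
            raise RuntimeError(f"expected one stain for d={d} µm, found {len(stains)}")
        areas.append(stains[0].area_um2)
    return np.asarray(areas)


def _bootstrap_ratio_pct(vol_a, vol_b, rng, n_boot=2000):
    """Percentile bootstrap CI of 100*(mean(a)/mean(b) - 1) over paired rows."""
    n = len(vol_a)
    idx = rng.integers(0, n, size=(n_boot, n))
    ratios = 100.0 * (vol_a[idx].mean(axis=1) / vol_b[idx].mean(axis=1) - 1.0)
    return float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5))


def run_spread_factor_comparison(
    stain_diameters=TABLE4_GRID_UM,
    mode: str = "analytic",
    dpi: float = 600.0,
    seed: int | None = None,
    constant: ConstantSpreadFactor | None = None,
    binned: BinnedSpreadFactor | None = None,
) -> ExperimentReport:
    """Compare the two spread-factor models on a set of circular stains.

    ``analytic`` mode uses exact circle areas pi*(d/2)²; ``rasterized``
    mode draws each stain at ``dpi``, segments it, and uses the measured
    pixel area.  The summary reports mean per-stain volume under each
    model and the percent excess of the constant model's mean volume,
    with a seeded bootstrap CI.
    """
    if mode not in ("analytic", "rasterized"):
        raise ValueError(f"unknown mode {mode!r}")
    constant = ConstantSpreadFactor() if constant is None else constant
    binned = BinnedSpreadFactor() if binned is None else binned
    diam = np.asarray(stain_diameters, dtype=float)
    if np.any(diam <= 0):
        raise ValueError("stain diameters must be > 0")
    if mode == "analytic":
        areas = math.pi * (diam / 2.0) ** 2
    else:
        areas = _measure_rasterized_areas(diam, dpi)
    d_const = np.atleast_1d(constant.transform(areas))
    d_binned = np.atleast_1d(binned.transform(areas))
    vol_const = np.atleast_1d(droplet_volume(d_const))
    vol_binned = np.atleast_1d(droplet_volume(d_binned))
    table = pd.DataFrame(
        {
            "stain_diameter_um": diam,
            "measured_stain_diameter_um": stain_diameter_from_area(areas),
            "area_um2": areas,
            "d_constant_um": d_const,
            "d_binned_um": d_binned,
            "pct_difference": percent_difference(d_const, d_binned),
            "vol_constant_uL": vol_const,
            "vol_binned_uL": vol_binned,
        }
    )
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_ratio_pct(vol_const, vol_binned, rng)
    summary = {
        "n_stains": int(diam.size),
        "mean_vol_constant_uL": float(vol_const.mean()),
        "mean_vol_binned_uL": float(vol_binned.mean()),
        "mean_vol_excess_pct": 100.0 * (float(vol_const.mean()) / float(vol_binned.mean()) - 1.0),
        "mean_vol_excess_pct_ci95": (lo, hi),
        "mean_diameter_pct_difference": float(np.mean(table["pct_difference"])),
        "deposition_range_constant_uL": (float(vol_const.min()), float(vol_const.max())),
        "deposition_range_binned_uL": (float(vol_binned.min()), float(vol_binned.max())),
    }
    config = {
        "mode": mode,
        "dpi": dpi,
        "seed": seed,
        "constant": constant.get_params(),
        "binned": binned.get_params(),
    }
    return ExperimentReport(table=table, summary=summary, config=config)


def run_touching_test(
    stain_diameters=TABLE4_GRID_UM,
    mode: str = "rasterized",
    dpi: float = 600.0,
    seed: int | None = None,
    model: ConstantSpreadFactor | None = None,
) -> ExperimentReport:
    """Deposition from tangent versus separated equal-stain pairs.

    For each diameter, two images are analysed: a pair of tangent
    stains (which segmentation merges into one deposit of roughly
    double area) and a pair with clear background between them.  The
    per-image deposition is the summed droplet volume in µL.  Analytic
    mode replaces the images with exact areas (merged pair = one stain
    of area 2A), for which the constant model overestimates by exactly
    ``2**0.365 - 1``.
    """
    if mode not in ("analytic", "rasterized"):
        raise ValueError(f"unknown mode {mode!r}")
    model = ConstantSpreadFactor() if model is None else model
    diam = np.asarray(stain_diameters, dtype=float)
    if np.any(diam <= 0):
        raise ValueError("stain diameters must be > 0")
    rows = []
    for d in diam:
        if mode == "analytic":
            area = math.pi * (d / 2.0) ** 2
            dep_sep = 2.0 * droplet_volume(model.droplet_diameter(area))
            dep_touch = float(droplet_volume(model.droplet_diameter(2.0 * area)))
            n_sep, n_touch = 2, 1
        else:
            dep = {}
            ncomp = {}
            for touching in (True, False):
                card = ci.generate_touching_pair(d, dpi=dpi, touching=touching)
                _, stains = ci.segment_card(card)
                areas = np.array([s.area_um2 for s in stains])
                dep[touching] = float(np.sum(droplet_volume(model.transform(areas))))
                ncomp[touching] = len(stains)
            dep_touch, dep_sep = dep[True], dep[False]
            n_touch, n_sep = ncomp[True], ncomp[False]
        rows.append(
            {
                "stain_diameter_um": d,
                "n_components_touching": n_touch,
                "n_components_separated": n_sep,
                "deposition_touching_uL": dep_touch,
                "deposition_separated_uL": dep_sep,
                "overestimation_pct": 100.0 * (dep_touch / dep_sep - 1.0),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_diameters": int(diam.size),
        "mean_deposition_touching_uL": float(table["deposition_touching_uL"].mean()),
        "mean_deposition_separated_uL": float(table["deposition_separated_uL"].mean()),
        "mean_overestimation_pct": float(table["overestimation_pct"].mean()),
    }
    config = {"mode": mode, "dpi": dpi, "seed": seed, "model": model.get_params()}
    return ExperimentReport(table=table, summary=summary, config=config)


def compare_methods(
    leaf_table: pd.DataFrame,
    card_summaries: pd.DataFrame,
    tank: TankMix,
    coverage_threshold: float = 30.0,
    cf: float | None = None,
) -> dict:
    """Leaf-residue versus WSP-residue calibration report.

    ``leaf_table`` needs ``residue_ug`` and ``area_cm2`` columns (or a
    precomputed ``residue_ug_per_cm2``); ``card_summaries`` needs
    ``coverage_pct`` and ``deposition_uL_per_cm2``.  High-coverage
    cards are excluded, card deposition converts to residue via the
    tank concentration, and the correction factor is fitted (or a fixed
    ``cf`` applied).  Returns a JSON-serializable report.
    """
    if len(leaf_table) == 0 or len(card_summaries) == 0:
        raise ValueError("both tables must be non-empty")
    if "residue_ug_per_cm2" in leaf_table.columns:
        leaf = leaf_table["residue_ug_per_cm2"].to_numpy(dtype=float)
    elif {"residue_ug", "area_cm2"} <= set(leaf_table.columns):
        leaf = leaf_table["residue_ug"].to_numpy(dtype=float) / leaf_table["area_cm2"].to_numpy(dtype=float)
    else:
        raise ValueError("leaf table needs residue_ug_per_cm2 or residue_ug + area_cm2 columns")
    missing = {"coverage_pct", "deposition_uL_per_cm2"} - set(card_summaries.columns)
    if missing:
        raise ValueError(f"card summaries missing columns: {sorted(missing)}")
    retained, report = exclusion_filter(card_summaries, coverage_threshold)
    wsp = deposit_from_deposition(tank, retained["deposition_uL_per_cm2"].to_numpy(dtype=float))
    wsp = np.atleast_1d(wsp)
    if wsp.size == 0:
        raise ValueError("no cards retained after coverage exclusion")
    if cf is None:
        model = fit_correction_factor(leaf, wsp)
    else:
        model = CorrectionFactorModel()
        model.fit(wsp, leaf)
        model.cf_ = float(cf)
    corrected = np.atleast_1d(model.transform(wsp))
    s_leaf, s_wsp, s_corr = group_summary(leaf), group_summary(wsp), group_summary(corrected)

    def _s(s):
        return {"n": s.n, "mean": s.mean, "ci95": (s.ci95_lower, s.ci95_upper), "cv_pct": s.cv_pct}

    return {
        "tank_concentration_ug_per_uL": tank.concentration,
        "coverage_threshold_pct": coverage_threshold,
        "n_cards_total": report.n_total,
        "n_cards_excluded": report.n_excluded,
        "cf": round(model.cf_, 4),
        "leaf_arm": _s(s_leaf),
        "wsp_arm_uncorrected": _s(s_wsp),
        "wsp_arm_corrected": _s(s_corr),
        "uncorrected_ratio_wsp_to_leaf": s_wsp.mean / s_leaf.mean,
        "corrected_mean_difference": s_corr.mean - s_leaf.mean,
    }
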