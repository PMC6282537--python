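"""Residue arithmetic linking leaf chemistry, tank mix and WSP deposits.

Leaf residues measured analytically (µg per leaf) convert to a surface
basis as ``R_area = R_leaf / A`` with ``A`` the upper leaf area in cm²
(all residue is assumed to sit on the upper surface).  Card-derived
deposits convert as ``R = C * D`` where ``C`` is the tank-mix active
ingredient concentration (µg µL⁻¹) and ``D`` the liquid deposition
(µL cm⁻²).

Because stains overspread and fine droplets are over-counted, the
WSP-derived residue systematically overestimates the leaf residue; the
:class:`CorrectionFactorModel` calibrates an empirical multiplicative
correction factor ``CF = mean(leaf) / mean(wsp)`` (a ratio of unpaired
arm means) and applies it per data point, ``R_corrected = R * CF``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TankMix",
    "LeafResidue",
    "CorrectionFactorModel",
    "residue_per_area",
    "deposit_from_deposition",
    "fit_correction_factor",
    "apply_correction",
    "simulate_paired_residues",
]


@dataclass(frozen=True)
class TankMix:
    """Spray-tank mixture; ``concentration`` is µg of a.i. per µL."""

    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


#: Study tank mix: penconazole at 0.18 g L⁻¹ = 0.18 µg µL⁻¹.
DEFAULT_TANK = TankMix(concentration=0.18)


@dataclass(frozen=True)
class LeafResidue:
    """One leaf: mass (g), upper-surface area (cm²) and residue (µg)."""

    mass_g: float
    leaf_area_cm2: float
    residue_ug: float

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.leaf_area_cm2 <= 0:
            raise ValueError("leaf_area_cm2 must be > 0")
        if self.residue_ug < 0:
            raise ValueError("residue_ug must be >= 0")

    @property
    def residue_mg_per_kg(self) -> float:
        """Mass-based residue; µg/g is numerically mg/kg."""
        return self.residue_ug / self.mass_g

    @property
    def residue_ug_per_cm2(self) -> float:
        return residue_per_area(self.residue_ug, self.leaf_area_cm2)


def residue_per_area(residue_ug, leaf_area_cm2):
    """Area-based residue ``R_area = R_leaf / A`` in µg cm⁻²."""
    area = np.asarray(leaf_area_cm2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("leaf area must be > 0")
    r = np.asarray(residue_ug, dtype=float) / area
    return r if r.ndim else float(r)


def deposit_from_deposition(tank: TankMix, deposition_uL_per_cm2):
    """WSP residue estimate ``R = C * D`` in µg cm⁻²."""
    dep = np.asarray(deposition_uL_per_cm2, dtype=float)
    if np.any(dep < 0):
        raise ValueError("deposition must be >= 0")
    r = tank.concentration * dep
    return r if r.ndim else float(r)


class CorrectionFactorModel(BaseEstimator, TransformerMixin):
    """Empirical correction factor aligning WSP residues with leaf residues.

    ``fit(X, y)`` takes the WSP-derived residues as ``X`` and the
    analytically measured leaf residues as ``y`` (both µg cm⁻²,
    unpaired arms of possibly different length); WSP samples flagged
    by ``exclude`` (e.g. coverage > 30%) are dropped before averaging.
    ``transform`` multiplies residues by the fitted factor.

    Attributes
    ----------
    cf_ : float
        Fitted factor, ``mean(leaf) / mean(wsp)`` (full precision;
        reports round to 4 dp).
    mean_leaf_, mean_wsp_ : float
        Arm means after exclusions (µg cm⁻²).
    n_leaf_, n_wsp_, n_excluded_ : int
        Sample counts per arm and WSP samples excluded.
    """

    def fit(self, X, y, exclude=None) -> "CorrectionFactorModel":
        wsp = np.asarray(X, dtype=float).ravel()
        leaf = np.asarray(y, dtype=float).ravel()
        if exclude is not None:
            keep = ~np.asarray(exclude, dtype=bool).ravel()
            if keep.shape != wsp.shape:
                raise ValueError("exclude flags must match the WSP arm length")
            self.n_excluded_ = int((~keep).sum())
            wsp = wsp[keep]
        else:
            self.n_excluded_ = 0
        if wsp.size == 0 or leaf.size == 0:
            raise ValueError("both arms must be non-empty after exclusions")
        mean_wsp = float(np.mean(wsp))
        if mean_wsp == 0:
            raise ValueError("WSP arm mean is zero; correction factor undefined")
        self.mean_leaf_ = float(np.mean(leaf))
        self.mean_wsp_ = mean_wsp
        self.n_leaf_ = int(leaf.size)
        self.n_wsp_ = int(wsp.size)
        self.cf_ = self.mean_leaf_ / self.mean_wsp_
        return self

    def transform(self, X):
        check_is_fitted(self, "cf_")
        r = np.asarray(X, dtype=float) * self.cf_
        return r if r.ndim else float(r)

    def report(self) -> dict:
        """Calibration summary; CF rounded to 4 dp for reporting."""
        check_is_fitted(self, "cf_")
        return {
            "cf": round(self.cf_, 4),
            "n_leaf": self.n_leaf_,
            "n_wsp": self.n_wsp_,
            "n_excluded": self.n_excluded_,
            "mean_leaf_ug_per_cm2": self.mean_leaf_,
            "mean_wsp_ug_per_cm2": self.mean_wsp_,
            "wsp_to_leaf_ratio": self.mean_wsp_ / self.mean_leaf_ if self.mean_leaf_ else math.nan,
        }


def fit_correction_factor(leaf_set, wsp_set, coverage_flags=None) -> CorrectionFactorModel:
    """Fit ``CF = mean(leaf_set)/mean(wsp_set)`` after exclusions."""
    return CorrectionFactorModel().fit(wsp_set, leaf_set, exclude=coverage_flags)


def apply_correction(wsp_residue, model: CorrectionFactorModel):
    """Per-data-point corrected residue ``R_corrected = R * CF``."""
    return model.transform(wsp_residue)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean 1 and the given coefficient of variation."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv**2)
    return rng.lognormal(-0.5 * s2, math.sqrt(s2), size=size)


def simulate_paired_residues(
    gamma: float,
    n_leaf: int = 90,
    n_wsp: int = 61,
    mean_leaf: float = 0.039,
    leaf_cv: float = 0.50,
    wsp_cv: float = 0.44,
    deposit_cv: float = 0.42,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic co-located leaf/WSP residue arms with true factor ``gamma``.

    Emulates a calibration study in which leaves and cards sample the
    same heterogeneous spray field: each location carries a latent
    deposit with coefficient of variation ``deposit_cv`` shared between
    the leaf and the card at that location, on top of which each arm
    has independent multiplicative measurement noise sized so the arm
    totals hit ``leaf_cv`` and ``wsp_cv``.  Where the arms differ in
    length the surplus locations carry one substrate only.  The WSP arm
    mean is ``mean_leaf / gamma``, so the fitted correction factor
    estimates ``gamma``.
    """
    if not 0 < gamma:
        raise ValueError("gamma must be > 0")
    for name, arm_cv in (("leaf_cv", leaf_cv), ("wsp_cv", wsp_cv)):
        if arm_cv <= deposit_cv:
            raise ValueError(f"{name} must exceed deposit_cv (shared variation)")
    rng = np.random.default_rng(rng)
    n_loc = max(n_leaf, n_wsp)
    deposit = _lognormal_unit_mean(rng, deposit_cv, n_loc)
    # residual per-arm noise: (1+cv_arm²) = (1+cv_dep²)(1+cv_noise²)
    noise_leaf_cv = math.sqrt((1 + leaf_cv**2) / (1 + deposit_cv**2) - 1)
    noise_wsp_cv = math.sqrt((1 + wsp_cv**2) / (1 + deposit_cv**2) - 1)
    leaf = mean_leaf * deposit[:n_leaf] * _lognormal_unit_mean(rng, noise_leaf_cv, n_leaf)
    wsp = (mean_leaf / gamma) * deposit[:n_wsp] * _lognormal_unit_mean(rng, noise_wsp_cv, n_wsp)
    return leaf, wsp
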