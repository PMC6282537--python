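"""Stain-to-droplet geometry for water-sensitive-paper (WSP) spray analysis.

A droplet that lands on WSP spreads before it dries, so the stain it
leaves is larger than the droplet that made it.  This module converts
measured stain areas back to droplet diameters and spherical volumes
under two spread-factor models, and aggregates per-stain volumes into
per-card spray metrics (coverage, droplet density, liquid deposition).

Two models are provided as scikit-learn style transformers:

``ConstantSpreadFactor``
    The power law ``d = SF * A**q`` mapping stain area ``A`` (µm²)
    directly to droplet diameter ``d`` (µm), with ``SF = 1.06`` and
    ``q = 0.455`` by default (the DepositScan convention).

``BinnedSpreadFactor``
    Divides the equivalent-circle stain diameter ``d_s = 2*sqrt(A/pi)``
    by a spread factor looked up in a stain-diameter-binned table
    (manufacturer values for water, 1.7 at 100 µm rising to 2.1 at
    500–600 µm).

Both expose ``transform(areas_um2) -> droplet diameters (µm)`` so they
are interchangeable downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "UL_PER_UM3",
    "DEFAULT_SF",
    "DEFAULT_EXPONENT",
    "DEFAULT_BINS",
    "InvalidModelError",
    "StainRecord",
    "CardMetrics",
    "SpreadFactorModel",
    "ConstantSpreadFactor",
    "BinnedSpreadFactor",
    "stain_diameter_from_area",
    "droplet_diameter_constant",
    "droplet_diameter_binned",
    "droplet_volume",
    "card_metrics",
    "percent_difference",
    "write_stain_table",
    "read_stain_table",
    "write_card_summaries",
    "read_card_summaries",
]

#: 1 µL = 1 mm³ = 1e9 µm³, so a sphere volume in µm³ scales by 1e-9.
UL_PER_UM3 = 1e-9

DEFAULT_SF = 1.06
DEFAULT_EXPONENT = 0.455

#: (upper stain-diameter bound µm, spread factor); half-open bins
#: (0,100] -> 1.7, (100,200] -> 1.8, ..., (500,600] -> 2.1; larger
#: stains clamp to the 2.1 plateau.
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (100.0, 1.7),
    (200.0, 1.8),
    (300.0, 1.9),
    (400.0, 2.0),
    (500.0, 2.1),
    (600.0, 2.1),
)


class InvalidModelError(ValueError):
    """A spread-factor model of the wrong kind or with invalid parameters."""


@dataclass(frozen=True)
class StainRecord:
    """One detected stain on a card.

    Attributes
    ----------
    pixel_count : int
        Number of mask pixels in the connected component (>= 1).
    area_um2 : float
        Physical stain area, ``pixel_count * pitch_um**2``.
    stain_diameter_um : float
        Equivalent-circle diameter ``2*sqrt(area/pi)``.
    centroid : (float, float)
        (x, y) centroid in pixel coordinates.
    """

    pixel_count: int
    area_um2: float
    stain_diameter_um: float
    centroid: tuple[float, float] = (math.nan, math.nan)

    @classmethod
    def from_pixels(
        cls, pixel_count: int, pitch_um: float, centroid: tuple[float, float] = (math.nan, math.nan)
    ) -> "StainRecord":
        if pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        area = pixel_count * pitch_um**2
        return cls(
            pixel_count=int(pixel_count),
            area_um2=area,
            stain_diameter_um=float(stain_diameter_from_area(area)),
            centroid=centroid,
        )


@dataclass(frozen=True)
class CardMetrics:
    """Per-card spray metrics.

    ``high_coverage_flag`` marks cards whose coverage exceeds the
    exclusion threshold (default 30%); volume estimates on such cards
    are unreliable because stains increasingly touch and merge.
    """

    coverage_pct: float
    density_per_cm2: float
    deposition_uL_per_cm2: float
    n_stains: int
    high_coverage_flag: bool
    card_id: str = ""


class SpreadFactorModel(BaseEstimator, TransformerMixin):
    """Base class for stain-area -> droplet-diameter transformers.

    Stateless: ``fit`` only validates parameters. ``transform`` accepts
    a 1-D array of stain areas in µm² and returns droplet diameters in
    µm on the same scale.
    """

    kind: str = ""

    def _validate_params(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X=None, y=None) -> "SpreadFactorModel":
        self._validate_params()
        return self

    def droplet_diameter(self, area_um2):  # pragma: no cover - overridden
        raise NotImplementedError

    def transform(self, X):
        areas = np.asarray(X, dtype=float).ravel()
        return self.droplet_diameter(areas)


class ConstantSpreadFactor(SpreadFactorModel):
    """Power-law spread factor ``d = sf * A**exponent`` (A in µm², d in µm)."""

    kind = "constant_powerlaw"

    def __init__(self, sf: float = DEFAULT_SF, exponent: float = DEFAULT_EXPONENT):
        self.sf = sf
        self.exponent = exponent

    def _validate_params(self) -> None:
        if not self.sf > 0:
            raise InvalidModelError(f"sf must be > 0, got {self.sf}")
        if not 0.0 < self.exponent < 1.0:
            raise InvalidModelError(f"exponent must be in (0, 1), got {self.exponent}")

    def droplet_diameter(self, area_um2):
        self._validate_params()
        area = np.asarray(area_um2, dtype=float)
        if np.any(area < 0):
            raise ValueError("stain area must be >= 0")
        d = self.sf * np.power(area, self.exponent)
        return d if d.ndim else float(d)


class BinnedSpreadFactor(SpreadFactorModel):
    """Diameter-binned spread factor ``d = d_s / SF(d_s)``.

    ``bins`` is an ordered sequence of ``(upper stain-diameter bound µm,
    factor)``; a stain diameter falls in the first bin whose upper bound
    it does not exceed, and diameters beyond the last bound clamp to the
    last factor.
    """

    kind = "binned"

    def __init__(self, bins: Sequence[tuple[float, float]] = DEFAULT_BINS):
        self.bins = tuple((float(b), float(f)) for b, f in bins)

    def _validate_params(self) -> None:
        if not self.bins:
            raise InvalidModelError("bins must be non-empty")
        uppers = [b for b, _ in self.bins]
        if any(b2 <= b1 for b1, b2 in zip(uppers, uppers[1:])):
            raise InvalidModelError("bin bounds must be strictly increasing")
        if any(f < 1.0 for _, f in self.bins):
            raise InvalidModelError("spread factors must be >= 1")

    def factor(self, stain_diameter_um):
        """Spread factor for one or more stain diameters (must be > 0)."""
        self._validate_params()
        ds = np.asarray(stain_diameter_um, dtype=float)
        if np.any(ds <= 0):
            raise ValueError("stain diameter must be > 0")
        uppers = np.array([b for b, _ in self.bins])
        factors = np.array([f for _, f in self.bins])
        idx = np.minimum(np.searchsorted(uppers, ds, side="left"), len(factors) - 1)
        out = factors[idx]
        return out if out.ndim else float(out)

    def droplet_diameter_from_stain(self, stain_diameter_um):
        ds = np.asarray(stain_diameter_um, dtype=float)
        d = ds / self.factor(ds)
        return d if d.ndim else float(d)

    def droplet_diameter(self, area_um2):
        self._validate_params()
        area = np.asarray(area_um2, dtype=float)
        if np.any(area < 0):
            raise ValueError("stain area must be >= 0")
        ds = 2.0 * np.sqrt(area / math.pi)
        d = np.where(ds > 0, ds / self.factor(np.where(ds > 0, ds, 1.0)), 0.0)
        return d if d.ndim else float(d)


def stain_diameter_from_area(area_um2):
    """Equivalent-circle stain diameter ``d_s = 2*sqrt(A/pi)`` in µm."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area < 0):
        raise ValueError("stain area must be >= 0")
    d = 2.0 * np.sqrt(area / math.pi)
    return d if d.ndim else float(d)


def droplet_diameter_constant(area_um2, model: ConstantSpreadFactor | None = None):
    """Droplet diameter (µm) from stain area under the power-law model."""
    model = ConstantSpreadFactor() if model is None else model
    if getattr(model, "kind", None) != "constant_powerlaw":
        raise InvalidModelError(f"expected a constant_powerlaw model, got {model!r}")
    return model.droplet_diameter(area_um2)


def droplet_diameter_binned(stain_diameter_um, model: BinnedSpreadFactor | None = None):
    """Droplet diameter (µm) from stain diameter under the binned model."""
    model = BinnedSpreadFactor() if model is None else model
    if getattr(model, "kind", None) != "binned":
        raise InvalidModelError(f"expected a binned model, got {model!r}")
    return model.droplet_diameter_from_stain(stain_diameter_um)


def droplet_volume(droplet_diameter_um):
    """Spherical droplet volume in µL, ``(pi/6) d^3 * 1e-9`` with d in µm."""
    d = np.asarray(droplet_diameter_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("droplet diameter must be >= 0")
    v = (math.pi / 6.0) * d**3 * UL_PER_UM3
    return v if v.ndim else float(v)


def percent_difference(d_constant, d_binned):
    """Relative difference ``100*(d_constant - d_binned)/d_binned``, 2 dp.

    Note the constant and binned droplet diameters for the same stain
    disagree by 6–14% over 100–600 µm stains; this reports the directly
    computed value.
    """
    dc = np.asarray(d_constant, dtype=float)
    db = np.asarray(d_binned, dtype=float)
    if np.any(db <= 0):
        raise ValueError("d_binned must be > 0")
    out = np.round(100.0 * (dc - db) / db, 2)
    return out if out.ndim else float(out)


def card_metrics(
    stains: Sequence[StainRecord],
    card_area_cm2: float,
    stained_pixels: int,
    total_pixels: int,
    model: SpreadFactorModel | None = None,
    coverage_threshold: float = 30.0,
    card_id: str = "",
) -> CardMetrics:
    """Coverage (%), droplet density (cm⁻²) and deposition (µL cm⁻²).

    Deposition sums the spherical volume of every stain's estimated
    droplet over the card area; an empty stain list yields zero metrics.
    """
    if total_pixels <= 0:
        raise ValueError("total_pixels must be > 0")
    if card_area_cm2 <= 0:
        raise ValueError("card_area_cm2 must be > 0")
    model = ConstantSpreadFactor() if model is None else model
    coverage = 100.0 * stained_pixels / total_pixels
    n = len(stains)
    if n:
        areas = np.array([s.area_um2 for s in stains], dtype=float)
        volumes = droplet_volume(model.transform(areas))
        deposition = float(np.sum(volumes)) / card_area_cm2
    else:
        deposition = 0.0
    return CardMetrics(
        coverage_pct=coverage,
        density_per_cm2=n / card_area_cm2,
        deposition_uL_per_cm2=deposition,
        n_stains=n,
        high_coverage_flag=coverage > coverage_threshold,
        card_id=card_id,
    )


# ---------------------------------------------------------------------------
# CSV interfaces

STAIN_TABLE_COLUMNS = [
    "stain_id",
    "pixel_count",
    "area_um2",
    "stain_diameter_um",
    "droplet_diameter_um",
    "volume_uL",
]

CARD_SUMMARY_COLUMNS = [
    "card_id",
    "coverage_pct",
    "density_per_cm2",
    "deposition_uL_per_cm2",
    "n_stains",
    "high_coverage_flag",
]


def stain_table(stains: Sequence[StainRecord], model: SpreadFactorModel | None = None) -> pd.DataFrame:
    """Per-stain table with droplet diameters/volumes under ``model``."""
    model = ConstantSpreadFactor() if model is None else model
    if not stains:
        return pd.DataFrame(columns=STAIN_TABLE_COLUMNS)
    areas = np.array([s.area_um2 for s in stains], dtype=float)
    d = np.atleast_1d(model.transform(areas))
    return pd.DataFrame(
        {
            "stain_id": np.arange(len(stains)),
            "pixel_count": [s.pixel_count for s in stains],
            "area_um2": areas,
            "stain_diameter_um": [s.stain_diameter_um for s in stains],
            "droplet_diameter_um": d,
            "volume_uL": np.atleast_1d(droplet_volume(d)),
        }
    )


def write_stain_table(stains, path, model: SpreadFactorModel | None = None) -> None:
    stain_table(stains, model).to_csv(Path(path), index=False)


def read_stain_table(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(STAIN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stain table missing columns: {sorted(missing)}")
    return df


def card_summary_table(cards: Sequence[CardMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "card_id": c.card_id,
                "coverage_pct": c.coverage_pct,
                "density_per_cm2": c.density_per_cm2,
                "deposition_uL_per_cm2": c.deposition_uL_per_cm2,
                "n_stains": c.n_stains,
                "high_coverage_flag": c.high_coverage_flag,
            }
            for c in cards
        ],
        columns=CARD_SUMMARY_COLUMNS,
    )


def write_card_summaries(cards: Sequence[CardMetrics], path) -> None:
    card_summary_table(cards).to_csv(Path(path), index=False)


def read_card_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(CARD_SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"card summary missing columns: {sorted(missing)}")
    return df
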