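"""Dose-uncertainty statistics over a phantom series.

For the doses D_i computed on the N statistical phantoms at one (energy,
geometry) cell, the spread is summarized by the population standard
deviation SD = sqrt(sum (D_i - Dbar)^2 / N) (denominator N, matching the
printed definition) and the coefficient of variation CV = SD / Dbar.  The
reference comparison follows the same convention as the source tables:
a reference value is "inside the interval" when it lies within one SD of
the series mean — not a formal confidence interval, hence the field name
``within_one_sd``.

The per-value Monte Carlo errors give a noise floor (their RMS): the
anatomical CV is only meaningful when it clearly exceeds that floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def series_sd(values) -> float:
    """Population standard deviation (denominator N)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values for an SD, got {v.size}")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def series_cv(values) -> float:
    """Coefficient of variation SD / mean (dimensionless)."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for a non-positive mean")
    return series_sd(v) / mean


def mc_noise_floor(relative_errors) -> float:
    """Expected CV contribution of MC noise alone: RMS of the rel. errors."""
    r = np.asarray(relative_errors, dtype=float)
    if r.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(r**2)))


@dataclass
class SeriesDoses:
    """Ordered per-phantom doses for one (energy, geometry) cell."""

    energy_mev: float
    geometry: str
    values: np.ndarray
    relative_errors: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")
        if self.relative_errors is not None:
            self.relative_errors = np.asarray(self.relative_errors, dtype=float)
            if self.relative_errors.shape != self.values.shape:
                raise ValueError("relative_errors must match values in shape")


@dataclass
class UncertaintyReport:
    energy_mev: float
    geometry: str
    n: int
    mean: float
    sd: float
    cv: float
    hist_edges: list[float]
    hist_counts: list[int]
    noise_floor: float | None = None
    noise_dominated: bool = False
    reference: float | None = None
    within_one_sd: bool | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "UncertaintyReport":
        return cls(**json.loads(text))


def summarize_series(doses: SeriesDoses, reference: float | None = None,
                     n_bins: int = 12) -> UncertaintyReport:
    """Mean, SD, CV, normalized D_i/Dbar histogram and reference flag."""
    v = doses.values
    mean = float(v.mean())
    sd = series_sd(v)
    cv = series_cv(v)
    norm = v / mean
    lo, hi = float(norm.min()), float(norm.max())
    if hi <= lo:
        hi = lo + 1e-12
    counts, edges = np.histogram(norm, bins=n_bins, range=(lo, hi))
    floor = None
    dominated = False
    if doses.relative_errors is not None:
        floor = mc_noise_floor(doses.relative_errors)
        dominated = bool(cv < 3.0 * floor)
    within = None
    if reference is not None:
        within = bool(abs(reference - mean) <= sd)
    return UncertaintyReport(
        energy_mev=doses.energy_mev, geometry=doses.geometry, n=int(v.size),
        mean=mean, sd=sd, cv=cv,
        hist_edges=[float(e) for e in edges], hist_counts=[int(c) for c in counts],
        noise_floor=floor, noise_dominated=dominated,
        reference=reference, within_one_sd=within,
    )


def reports_to_frame(reports: list[UncertaintyReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "energy_MeV": r.energy_mev,
                "geometry": r.geometry,
                "n": r.n,
                "mean": r.mean,
                "sd": r.sd,
                "cv": r.cv,
                "noise_floor": r.noise_floor,
                "reference": r.reference,
                "within_one_sd": r.within_one_sd,
            }
            for r in reports
        ]
    )
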