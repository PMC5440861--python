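"""Statistical lung-mass population and mass-to-volume planning.

The population model is a Gaussian over total lung mass (default
1246 +/- 322 g, the autopsy-based adult-male distribution), sampled N
times with a fixed seed.  Masses convert to target volumes through the
whole-lung relative density rho_re = M_ref / V_ref, with M_ref = 1208.37 g
and V_ref = 2911.190 cm^3 from the reference lung inventory; rho_re is
always recomputed from these inputs, never hard-coded.

Draws are truncated to [max(mu - 3 sigma, 300 g), mu + 3 sigma]: the tails
beyond 3 sigma are anatomically implausible and would not be buildable as
voxel lungs; clipped draws are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REFERENCE_TOTAL_MASS_G = 1208.37
REFERENCE_TOTAL_VOLUME_CM3 = 2911.190
REFERENCE_RIGHT_VOLUME_CM3 = 1586.02
REFERENCE_LEFT_VOLUME_CM3 = 1325.17

# Reference lung inventory (g): tissue and blood masses per lobe.  The
# tissue/blood split is held fixed in proportion across the series so the
# vessel volume scales with the lung volume.
RIGHT_TISSUE_MASS_G = 580.08
LEFT_TISSUE_MASS_G = 477.74
RIGHT_BLOOD_MASS_G = 71.54
LEFT_BLOOD_MASS_G = 79.01
REFERENCE_TISSUE_MASS_G = 1057.82
REFERENCE_BLOOD_MASS_G = 150.55

HARD_MASS_FLOOR_G = 300.0


def relative_density(total_mass_g: float, total_volume_cm3: float) -> float:
    """Whole-organ mass over whole-organ volume, g/cm^3."""
    if total_volume_cm3 <= 0:
        raise ValueError(f"total volume must be positive, got {total_volume_cm3}")
    return total_mass_g / total_volume_cm3


@dataclass
class MassDistribution:
    """Gaussian lung-mass model with truncation bounds and a fixed seed."""

    mean_g: float = 1246.0
    sd_g: float = 322.0
    n: int = 100
    seed: int = 0
    reference_mass_g: float = REFERENCE_TOTAL_MASS_G
    reference_volume_cm3: float = REFERENCE_TOTAL_VOLUME_CM3

    def __post_init__(self):
        if self.mean_g <= 0:
            raise ValueError("mean mass must be positive")
        if self.sd_g < 0:
            raise ValueError("mass SD must be non-negative")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")

    @property
    def rho_re(self) -> float:
        """Relative density recomputed from the reference mass and volume."""
        return relative_density(self.reference_mass_g, self.reference_volume_cm3)

    @property
    def bounds(self) -> tuple[float, float]:
        lo = max(self.mean_g - 3.0 * self.sd_g, HARD_MASS_FLOOR_G)
        hi = self.mean_g + 3.0 * self.sd_g
        return lo, hi


def sample_masses(dist: MassDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Draw N masses (g) and a per-draw truncation flag, reproducibly.

    Draws come from Normal(mean, sd^2); the few draws outside the
    physiological bounds are clipped to the bound and flagged.
    """
    rng = np.random.default_rng(dist.seed)
    raw = rng.normal(dist.mean_g, dist.sd_g, size=dist.n)
    lo, hi = dist.bounds
    truncated = (raw < lo) | (raw > hi)
    return np.clip(raw, lo, hi), truncated


@dataclass
class LungSpec:
    """Per-phantom geometric targets derived from one sampled mass."""

    index: int
    target_mass_g: float
    target_volume_cm3: float
    scale_factor: float            # linear scale vs the reference lung
    right_volume_cm3: float
    left_volume_cm3: float
    vessel_volume_factor: float    # = volume ratio vs reference
    truncated: bool = False


def plan_series(dist: MassDistribution,
                reference_right_cm3: float = REFERENCE_RIGHT_VOLUME_CM3,
                reference_left_cm3: float = REFERENCE_LEFT_VOLUME_CM3) -> list[LungSpec]:
    """Sample the population and derive one LungSpec per phantom.

    Volumes follow V = m / rho_re; the lobar split keeps the reference
    right:left proportion; the linear scale is the cube root of the volume
    ratio; vessel volume scales by the same volume factor.
    """
    ref_total = reference_right_cm3 + reference_left_cm3
    if ref_total <= 0:
        raise ValueError("reference lung volume must be positive")
    masses, truncated = sample_masses(dist)
    rho = dist.rho_re
    specs = []
    for i, (m, tr) in enumerate(zip(masses, truncated)):
        v = m / rho
        factor = v / dist.reference_volume_cm3
        specs.append(
            LungSpec(
                index=i,
                target_mass_g=float(m),
                target_volume_cm3=float(v),
                scale_factor=float(np.cbrt(factor)),
                right_volume_cm3=float(v * reference_right_cm3 / ref_total),
                left_volume_cm3=float(v * reference_left_cm3 / ref_total),
                vessel_volume_factor=float(factor),
                truncated=bool(tr),
            )
        )
    return specs


def spec_for_mass(mass_g: float, dist: MassDistribution, index: int = 0) -> LungSpec:
    """A single LungSpec at a prescribed mass (e.g. the largest-lung case)."""
    rho = dist.rho_re
    v = mass_g / rho
    factor = v / dist.reference_volume_cm3
    ref_total = REFERENCE_RIGHT_VOLUME_CM3 + REFERENCE_LEFT_VOLUME_CM3
    return LungSpec(
        index=index,
        target_mass_g=float(mass_g),
        target_volume_cm3=float(v),
        scale_factor=float(np.cbrt(factor)),
        right_volume_cm3=float(v * REFERENCE_RIGHT_VOLUME_CM3 / ref_total),
        left_volume_cm3=float(v * REFERENCE_LEFT_VOLUME_CM3 / ref_total),
        vessel_volume_factor=float(factor),
    )


def series_to_frame(specs: list[LungSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": s.index,
                "target_mass_g": s.target_mass_g,
                "target_volume_cm3": s.target_volume_cm3,
                "scale_factor": s.scale_factor,
                "truncated_flag": s.truncated,
            }
            for s in specs
        ]
    )
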