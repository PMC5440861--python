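"""Labeled voxel phantoms and organ bookkeeping.

The phantom is a 3D grid of organ labels (0 = ambient air outside the
body) on a uniform rectangular lattice.  Coordinates follow the reference
voxel-phantom convention: x increases right-to-left, y anterior-to-
posterior, z feet-to-head, all lengths in cm, with voxel centers at
``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .materials import MaterialTable

DEFAULT_SPACING = (0.2137, 0.2137, 0.8)

# Canonical organ label scheme used by the template builder.  Labels are
# uint16 with 0 reserved for ambient air; the lung is the union of four
# labels so tissue/vessel and right/left splits stay queryable.
L_AIR = 0
L_SKIN = 1
L_MUSCLE = 2
L_RESIDUAL = 3
L_RIBS = 4
L_SPINE = 5
L_HEART = 6
L_LIVER = 7
L_RLUNG = 8
L_LLUNG = 9
L_RVESSEL = 10
L_LVESSEL = 11

RIGHT_LOBE_LABELS = frozenset({L_RLUNG, L_RVESSEL})
LEFT_LOBE_LABELS = frozenset({L_LLUNG, L_LVESSEL})
LUNG_LABELS = RIGHT_LOBE_LABELS | LEFT_LOBE_LABELS
VESSEL_LABELS = frozenset({L_RVESSEL, L_LVESSEL})


@dataclass
class LabeledVolume:
    """3D organ-label grid with spacing, origin and organ/material bindings.

    ``organ_map`` maps each nonzero label to ``(name, material_id)``.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    organ_map: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.labels.dtype != np.uint16:
            if np.any(self.labels < 0) or np.any(self.labels > np.iinfo(np.uint16).max):
                raise ValueError("labels must fit in uint16")
            self.labels = self.labels.astype(np.uint16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be strictly positive, got {self.spacing}")
        present = set(np.unique(self.labels)) - {0}
        missing = sorted(present - set(self.organ_map))
        if missing:
            raise ValueError(f"labels present without organ_map entry: {missing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.labels.copy(), self.spacing, self.origin,
                             dict(self.organ_map))

    def mask(self, organ_ids: Iterable[int]) -> np.ndarray:
        ids = _check_ids(self, organ_ids)
        return np.isin(self.labels, list(ids))

    def voxel_centers(self):
        """Per-axis arrays of voxel-center coordinates in cm."""
        return tuple(
            self.origin[a] + (np.arange(self.labels.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


@dataclass
class OrganSummary:
    organ_id: int
    name: str
    volume_cm3: float
    mass_g: float
    centroid: tuple[float, float, float]


def _check_ids(phantom: LabeledVolume, organ_ids: Iterable[int]) -> set[int]:
    ids = set(int(i) for i in organ_ids)
    unknown = sorted(ids - set(phantom.organ_map))
    if unknown:
        raise KeyError(f"unknown organ ID(s): {unknown}")
    return ids


def volume_of(phantom: LabeledVolume, organ_ids: Iterable[int]) -> float:
    """Total volume (cm^3) of the voxels carrying any of ``organ_ids``."""
    ids = _check_ids(phantom, organ_ids)
    if not ids:
        return 0.0
    count = int(np.isin(phantom.labels, list(ids)).sum())
    return count * phantom.voxel_volume


def mass_of(phantom: LabeledVolume, organ_ids: Iterable[int],
            materials: MaterialTable) -> float:
    """Total mass (g): per-label volume times the bound material density."""
    ids = _check_ids(phantom, organ_ids)
    total = 0.0
    for oid in ids:
        _, mat_id = phantom.organ_map[oid]
        if mat_id not in materials.materials:
            raise KeyError(
                f"organ {oid} bound to material {mat_id} which is not in the table"
            )
        total += volume_of(phantom, {oid}) * materials.density_of(mat_id)
    return total


def centroid_of(phantom: LabeledVolume, organ_ids: Iterable[int]):
    """Unweighted mean of voxel-center coordinates (cm) over the organ."""
    ids = _check_ids(phantom, organ_ids)
    mask = np.isin(phantom.labels, list(ids)) if ids else np.zeros(phantom.shape, bool)
    n = mask.sum()
    if n == 0:
        raise ValueError(f"centroid undefined: organ set {sorted(ids)} occupies no voxels")
    idx = np.nonzero(mask)
    return tuple(
        phantom.origin[a] + (idx[a].mean() + 0.5) * phantom.spacing[a] for a in range(3)
    )


def volume_from_mass(mass_g: float, density_g_cm3: float) -> float:
    """Convert a mass to a volume, cm^3 = g / (g/cm^3)."""
    if density_g_cm3 <= 0:
        raise ValueError(f"density must be positive, got {density_g_cm3}")
    if mass_g < 0:
        raise ValueError(f"mass must be non-negative, got {mass_g}")
    return mass_g / density_g_cm3


def summarize_organs(phantom: LabeledVolume, materials: MaterialTable) -> list[OrganSummary]:
    out = []
    for oid in sorted(phantom.organ_map):
        name, _ = phantom.organ_map[oid]
        vol = volume_of(phantom, {oid})
        mass = mass_of(phantom, {oid}, materials)
        cent = centroid_of(phantom, {oid}) if vol > 0 else (np.nan,) * 3
        out.append(OrganSummary(oid, name, vol, mass, cent))
    return out


def summaries_to_frame(summaries: list[OrganSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "organ_id": s.organ_id,
                "name": s.name,
                "volume_cm3": s.volume_cm3,
                "mass_g": s.mass_g,
                "cx": s.centroid[0],
                "cy": s.centroid[1],
                "cz": s.centroid[2],
            }
            for s in summaries
        ]
    )
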