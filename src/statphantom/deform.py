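"""Deformation of the template into statistical phantoms.

A statistical phantom is the template with its lung lobes uniformly
rescaled about their (fixed) centroids to a sampled target volume, the
vessel volume matched proportionally, the rib cage refit with the same
linear factor, overlaps with heart/liver resolved by policy, and
deflation voids backfilled with residual tissue.

Rescaling resamples the binary organ mask under the inverse uniform
scaling with trilinear interpolation and a 0.5 threshold, and corrects the
linear factor by bisection until the clipped, voxelized organ matches its
target volume — the automatable equivalent of a mesh rescale/revoxelize
round trip, since only the re-binarized voxel result matters.

Two overlap-resolution modes exist for inflated lungs: ``lung_wins``
(conflicted heart/liver voxels become lung, giving a smaller heart/liver
for large lungs) and ``organ_wins`` (the lung is truncated at heart and
liver, and its achieved volume is re-measured and reported).  At the
reference size the two modes coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (binary_closing, binary_dilation, binary_fill_holes,
                           distance_transform_edt, map_coordinates)

from . import grid as g
from . import materials as mat
from .series import LungSpec
from . import vessels as ves

LUNG_WINS = "lung_wins"
ORGAN_WINS = "organ_wins"


@dataclass
class DeformationPolicy:
    overlap_mode: str = LUNG_WINS
    volume_tol: float = 0.01
    max_iter: int = 25
    rib_coupling: bool = True
    vessel_adjustment: bool = True

    def __post_init__(self):
        if self.overlap_mode not in (LUNG_WINS, ORGAN_WINS):
            raise ValueError(
                f"unknown overlap mode {self.overlap_mode!r}; "
                f"expected {LUNG_WINS!r} or {ORGAN_WINS!r}"
            )
        if not (0.0 < self.volume_tol <= 0.05):
            raise ValueError("volume tolerance must lie in (0, 0.05]")


class ConvergenceError(RuntimeError):
    """Volume matching failed; carries the best achieved volume."""

    def __init__(self, message: str, achieved_cm3: float):
        super().__init__(message)
        self.achieved_cm3 = achieved_cm3


def scale_mask(mask: np.ndarray, s: float, fixed_point_cm, spacing, origin,
               order: int = 1) -> np.ndarray:
    """Resample a binary mask under uniform scaling about a fixed point.

    Trilinear interpolation of the 0/1 field under the inverse map,
    re-binarized at 0.5 (``order=1``, right for bulky organs), or
    nearest-neighbour (``order=0``, right for thin shells such as the rib
    cage, which trilinear thresholding would erode).  ``s = 1`` is exact.
    """
    if s <= 0:
        raise ValueError("scale factor must be positive")
    if s == 1.0:
        return mask.copy()
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    # fixed point in (fractional) index space
    f_idx = (np.asarray(fixed_point_cm, float) - origin) / spacing - 0.5
    idx = np.argwhere(mask)
    if idx.size == 0:
        return mask.copy()
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    out_lo = np.floor(f_idx + (lo - f_idx) * s).astype(int) - 2
    out_hi = np.ceil(f_idx + (hi - f_idx) * s).astype(int) + 2
    out_lo = np.maximum(out_lo, 0)
    out_hi = np.minimum(out_hi, np.asarray(mask.shape) - 1)
    axes = [np.arange(out_lo[a], out_hi[a] + 1) for a in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    coords = [f_idx[a] + (grid_a - f_idx[a]) / s
              for a, grid_a in enumerate((gi, gj, gk))]
    vals = map_coordinates(mask.astype(np.float32), coords, order=order,
                           mode="constant", cval=0.0, prefilter=False)
    out = np.zeros_like(mask)
    out[out_lo[0]:out_hi[0] + 1, out_lo[1]:out_hi[1] + 1, out_lo[2]:out_hi[2] + 1] = vals >= 0.5
    return out


def _match_volume(mask, target_vox, fixed_point, spacing, origin, s0,
                  clip=None, max_iter=25, tol_rel=0.01):
    """Bisection on the linear factor until the clipped scaled mask hits
    ``target_vox`` voxels (to within quantization).  Returns (mask, s, iters).
    """
    def count_at(s):
        m = scale_mask(mask, s, fixed_point, spacing, origin)
        if clip is not None:
            m &= clip
        return m, int(m.sum())

    s_lo = s_hi = float(s0)
    m, n = count_at(s0)
    it = 1
    # expand a bracket around the target
    while n < target_vox and it < max_iter:
        s_hi *= 1.05
        m, n = count_at(s_hi)
        it += 1
    if n < target_vox:
        raise ConvergenceError(
            "volume target not reachable by inflation within iteration budget",
            n * np.prod(spacing),
        )
    while True:
        m_lo, n_lo = count_at(s_lo)
        if n_lo <= target_vox or s_lo < 0.05:
            break
        s_lo *= 0.95
        it += 1
    best_m, best_n = m, n
    for _ in range(40):
        if abs(best_n - target_vox) <= max(2, int(2e-4 * target_vox)):
            break
        s_mid = 0.5 * (s_lo + s_hi)
        m_mid, n_mid = count_at(s_mid)
        it += 1
        if abs(n_mid - target_vox) < abs(best_n - target_vox):
            best_m, best_n = m_mid, n_mid
        if n_mid < target_vox:
            s_lo = s_mid
        else:
            s_hi = s_mid
        if s_hi - s_lo < 1e-7:
            break
    if abs(best_n - target_vox) / max(target_vox, 1) > tol_rel:
        raise ConvergenceError(
            f"volume matching stopped at {best_n} voxels vs target {target_vox}",
            best_n * float(np.prod(spacing)),
        )
    return best_m, 0.5 * (s_lo + s_hi), it


def rescale_organ(phantom: g.LabeledVolume, organ_ids, s: float, fixed_point_cm,
                  policy: DeformationPolicy | None = None,
                  fill_label: int = g.L_RESIDUAL):
    """Uniformly rescale one organ about a fixed point on the voxel grid.

    The organ claims vacated/soft-tissue voxels and leaves every other
    label untouched; deflation voids are backfilled with ``fill_label``.
    Returns ``(phantom', achieved_volume_cm3)``.
    """
    policy = policy or DeformationPolicy()
    if s <= 0:
        raise ValueError("scale factor must be positive")
    out = phantom.copy()
    mask = phantom.mask(organ_ids)
    n0 = int(mask.sum())
    if n0 == 0:
        raise ValueError(f"organ set {sorted(set(organ_ids))} occupies no voxels")
    if s == 1.0:
        return out, n0 * phantom.voxel_volume
    target = int(round(n0 * s**3))
    claim = mask | np.isin(out.labels, [g.L_RESIDUAL, g.L_MUSCLE]) | (out.labels == 0)
    new_mask, _, _ = _match_volume(mask, target, fixed_point_cm, phantom.spacing,
                                   phantom.origin, s, clip=claim,
                                   max_iter=policy.max_iter, tol_rel=policy.volume_tol)
    first = sorted(set(int(i) for i in organ_ids))[0]
    out.labels[mask & ~new_mask] = fill_label
    out.labels[new_mask] = first
    return out, int(new_mask.sum()) * phantom.voxel_volume


def fill_voids(phantom: g.LabeledVolume, region_before: np.ndarray,
               region_after: np.ndarray,
               fill_label: int = g.L_RESIDUAL) -> g.LabeledVolume:
    """Assign residual tissue to voxels vacated by a deflated organ."""
    out = phantom.copy()
    vacated = region_before & ~region_after
    sel = vacated & (out.labels == 0)
    out.labels[sel] = fill_label
    return out


def resolve_overlaps(phantom: g.LabeledVolume, policy: DeformationPolicy,
                     conflicts: dict[int, np.ndarray] | None = None) -> g.LabeledVolume:
    """Resolve lung/heart and lung/liver conflicts per the overlap mode.

    ``conflicts`` maps a lung tissue label to the mask of voxels where the
    scaled lobe intersected heart or liver.  ``lung_wins``: those voxels
    become lung; ``organ_wins``: they stay heart/liver (the lung is
    truncated).  No conflicts means identity.
    """
    out = phantom.copy()
    if not conflicts:
        return out
    if policy.overlap_mode == LUNG_WINS:
        for lung_label, mask in conflicts.items():
            out.labels[mask] = lung_label
    return out


def shell_thickness_cm(mask: np.ndarray, spacing) -> float:
    """Largest inscribed diameter of a shell-like mask (thickness proxy)."""
    if not mask.any():
        return 0.0
    return 2.0 * float(distance_transform_edt(mask, sampling=spacing).max())


def _cage_bands(cage: np.ndarray) -> np.ndarray:
    return np.any(cage, axis=(0, 1))


def refit_ribcage(phantom: g.LabeledVolume, s: float,
                  policy: DeformationPolicy | None = None) -> g.LabeledVolume:
    """Rescale the rib cage rigidly about its own centroid by factor ``s``.

    The cage mask is resampled like any organ; vacated bone becomes
    residual tissue and the new cage claims only soft tissue, never lung,
    heart, liver, spine or skin.
    """
    policy = policy or DeformationPolicy()
    if not policy.rib_coupling or s == 1.0:
        return phantom.copy()
    cage = phantom.labels == g.L_RIBS
    if not cage.any():
        raise ValueError("rib labels absent; cannot refit the rib cage")
    centroid = g.centroid_of(phantom, {g.L_RIBS})
    new_cage = scale_mask(cage, s, centroid, phantom.spacing, phantom.origin,
                          order=0)
    out = phantom.copy()
    out.labels[cage] = g.L_RESIDUAL
    claim = np.isin(out.labels, [g.L_RESIDUAL, g.L_MUSCLE]) | (out.labels == 0)
    out.labels[new_cage & claim] = g.L_RIBS
    return out


def adjust_vessels(phantom: g.LabeledVolume, volume_factor: float,
                   policy: DeformationPolicy | None = None,
                   reference_counts: dict[int, int] | None = None) -> g.LabeledVolume:
    """Match the per-lobe vessel voxel count to ``reference x factor``.

    Excess distal vessel voxels are pruned farthest-from-hilum (the main
    trunk survives); deficits grow the distal front into vessel-free lung.
    ``reference_counts`` maps vessel label -> template voxel count; when
    omitted the current counts serve as reference (factor 1 = identity).
    """
    policy = policy or DeformationPolicy()
    if not policy.vessel_adjustment:
        return phantom.copy()
    if volume_factor <= 0:
        raise ValueError("volume factor must be positive")
    out = phantom.copy()
    pairs = ((g.L_RVESSEL, g.L_RLUNG), (g.L_LVESSEL, g.L_LLUNG))
    try:
        c_r = g.centroid_of(phantom, g.RIGHT_LOBE_LABELS)
        c_l = g.centroid_of(phantom, g.LEFT_LOBE_LABELS)
        mid = 0.5 * (np.asarray(c_r) + np.asarray(c_l))
    except ValueError as exc:
        raise ValueError("vessel adjustment requires lung labels") from exc
    for v_label, t_label in pairs:
        vessel = out.labels == v_label
        n = int(vessel.sum())
        if n == 0 and (reference_counts or {}).get(v_label, 0) == 0:
            continue
        lobe = (out.labels == t_label) | vessel
        ref = (reference_counts or {}).get(v_label, n)
        target = int(round(ref * volume_factor))
        if target > int(lobe.sum()):
            raise ValueError(
                f"vessel target {target} exceeds lobe volume for label {v_label}"
            )
        if n == 0:
            raise ValueError(f"vessel label {v_label} absent but target is nonzero")
        hilum = ves.hilum_voxel(vessel, mid, phantom.spacing, phantom.origin)
        hilum_cm = np.asarray(phantom.origin) + (np.asarray(hilum) + 0.5) * np.asarray(phantom.spacing)
        matched = ves.match_count(vessel, lobe, target, hilum_cm,
                                  phantom.spacing, phantom.origin)
        out.labels[vessel & ~matched] = t_label
        out.labels[matched] = v_label
    return out


@dataclass
class Provenance:
    """Per-phantom record of the deformation actually achieved."""

    index: int
    target_mass_g: float
    target_volume_cm3: float
    scale_factor: float
    achieved_volume_cm3: float = np.nan
    achieved_mass_g: float = np.nan
    conflict_voxels_heart: int = 0
    conflict_voxels_liver: int = 0
    iterations: int = 0
    overlap_mode: str = LUNG_WINS
    truncated_volume_cm3: float = 0.0

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (np.floating, float)) else v)
                for k, v in vars(self).items()}


def build_statistical_phantom(template: g.LabeledVolume, spec: LungSpec,
                              policy: DeformationPolicy | None = None,
                              materials: mat.MaterialTable | None = None):
    """Template + LungSpec -> statistical phantom, with provenance.

    Pipeline order: remove old ribs, rescale each lobe (with its vessels)
    about its fixed centroid, resolve heart/liver overlaps by policy, refit
    the rib cage with the lung's linear factor, match the vessel volume,
    and fill deflation voids with residual tissue.  The in-body voxel count
    is conserved exactly.
    """
    policy = policy or DeformationPolicy()
    materials = materials or mat.default_materials()
    out = template.copy()
    spacing, origin = template.spacing, template.origin
    vv = template.voxel_volume
    body = template.labels != 0
    prov = Provenance(index=spec.index, target_mass_g=spec.target_mass_g,
                      target_volume_cm3=spec.target_volume_cm3,
                      scale_factor=spec.scale_factor,
                      overlap_mode=policy.overlap_mode)

    cage = template.labels == g.L_RIBS
    out.labels[cage] = g.L_RESIDUAL

    heart = template.labels == g.L_HEART
    liver = template.labels == g.L_LIVER
    hard = np.isin(template.labels, [g.L_SKIN, g.L_SPINE]) | ~body

    lung_before = np.isin(template.labels, list(g.LUNG_LABELS))
    lobes = (
        (g.RIGHT_LOBE_LABELS, g.L_RLUNG, g.L_RVESSEL, spec.right_volume_cm3),
        (g.LEFT_LOBE_LABELS, g.L_LLUNG, g.L_LVESSEL, spec.left_volume_cm3),
    )
    placed = {}
    scaled_vessels = {}
    conflicts = {}
    iters_total = 0
    other_lobe_new = np.zeros_like(body)
    for lobe_labels, t_label, v_label, target_cm3 in lobes:
        lobe_old = np.isin(template.labels, list(lobe_labels))
        vessel_old = template.labels == v_label
        centroid = g.centroid_of(template, lobe_labels)
        target_vox = int(round(target_cm3 / vv))
        clip = body & ~hard & ~other_lobe_new
        try:
            new_lobe, s_eff, iters = _match_volume(
                lobe_old, target_vox, centroid, spacing, origin,
                spec.scale_factor, clip=clip, max_iter=policy.max_iter,
                tol_rel=policy.volume_tol)
        except ConvergenceError as exc:
            raise ConvergenceError(
                f"stage rescale ({t_label}): {exc}", exc.achieved_cm3) from exc
        iters_total += iters
        placed[t_label] = new_lobe
        scaled_vessels[v_label] = (
            scale_mask(vessel_old, s_eff, centroid, spacing, origin)
            if vessel_old.any() else vessel_old.copy()
        )
        conflicts[t_label] = new_lobe & (heart | liver)
        other_lobe_new |= new_lobe

    prov.conflict_voxels_heart = int(sum((m & heart).sum() for m in conflicts.values()))
    prov.conflict_voxels_liver = int(sum((m & liver).sum() for m in conflicts.values()))
    prov.iterations = iters_total

    # vacate the old lung, then place the scaled lobes
    out.labels[lung_before] = 0
    for t_label, new_lobe in placed.items():
        body_soft = new_lobe & ~conflicts[t_label]
        out.labels[body_soft] = t_label
    out = resolve_overlaps(out, policy, conflicts)
    if policy.overlap_mode == ORGAN_WINS:
        kept = sum(int(m.sum()) for m in conflicts.values())
        prov.truncated_volume_cm3 = kept * vv

    # rib cage refit: the original cage scaled by the lung's linear factor,
    # placed on soft tissue only (lung, heart, liver, spine, skin keep)
    if cage.any():
        s_cage = spec.scale_factor if policy.rib_coupling else 1.0
        cage_centroid = g.centroid_of(template, {g.L_RIBS})
        new_cage = scale_mask(cage, s_cage, cage_centroid, spacing, origin,
                              order=0)
        claim = (np.isin(out.labels, [g.L_RESIDUAL, g.L_MUSCLE])
                 | (out.labels == 0)) & body
        out.labels[new_cage & claim] = g.L_RIBS

    # vessels: proportional volume, then voids
    if policy.vessel_adjustment:
        for v_label, mask in scaled_vessels.items():
            t_label = g.L_RLUNG if v_label == g.L_RVESSEL else g.L_LLUNG
            sel = mask & (out.labels == t_label)
            out.labels[sel] = v_label
        ref_counts = {v: int((template.labels == v).sum())
                      for v in (g.L_RVESSEL, g.L_LVESSEL)}
        out = adjust_vessels(out, spec.vessel_volume_factor, policy, ref_counts)

    lung_after = np.isin(out.labels, list(g.LUNG_LABELS))
    out = fill_voids(out, lung_before | cage, lung_after)
    out.labels[body & (out.labels == 0)] = g.L_RESIDUAL

    prov.achieved_volume_cm3 = g.volume_of(out, g.LUNG_LABELS)
    prov.achieved_mass_g = g.mass_of(out, g.LUNG_LABELS, materials)
    return out, prov
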