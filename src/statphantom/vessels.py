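"""Procedural pulmonary vessel trees on the voxel grid.

The tree is a recursive bifurcation: from a hilum point a trunk grows into
the lobe, each branch spawning two children with randomly perturbed
directions, decaying length and radius.  Branches are rasterized as
voxel tubes clipped to the lobe mask.  Exact voxel-count targets are met
by trimming the most distal voxels (farthest from the hilum, so the main
trunk survives) or by growing the distal front into vessel-free lung.
"""

from __future__ import annotations

import numpy as np


def _ball_offsets(radius_cm: float, spacing) -> np.ndarray:
    """Integer index offsets covering a sphere of ``radius_cm``."""
    r = [max(int(np.floor(radius_cm / s)), 0) for s in spacing]
    ax = [np.arange(-ri, ri + 1) for ri in r]
    ox, oy, oz = np.meshgrid(*ax, indexing="ij")
    d2 = (ox * spacing[0]) ** 2 + (oy * spacing[1]) ** 2 + (oz * spacing[2]) ** 2
    keep = d2 <= max(radius_cm, min(spacing) * 0.51) ** 2
    return np.stack([ox[keep], oy[keep], oz[keep]], axis=1)


def rasterize_tree(lobe_mask: np.ndarray, spacing, origin, hilum_cm, seed: int,
                   trunk_dir, trunk_length_cm: float,
                   root_radius_cm: float = 0.42, depth: int = 7,
                   length_decay: float = 0.74, radius_decay: float = 0.76,
                   jitter: float = 0.55) -> np.ndarray:
    """Grow and rasterize one bifurcating tree inside ``lobe_mask``."""
    rng = np.random.default_rng(seed)
    mask = np.zeros_like(lobe_mask, dtype=bool)
    shape = lobe_mask.shape
    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    d0 = np.asarray(trunk_dir, float)
    d0 = d0 / np.linalg.norm(d0)
    stack = [(np.asarray(hilum_cm, float), d0, float(trunk_length_cm),
              float(root_radius_cm), 0)]
    step = 0.45 * min(spacing[0], spacing[1])
    while stack:
        p0, d, length, radius, lvl = stack.pop()
        n_pts = max(int(length / step), 2)
        ts = np.linspace(0.0, length, n_pts)
        pts = p0[None, :] + ts[:, None] * d[None, :]
        offs = _ball_offsets(radius, spacing)
        idx = np.floor((pts - origin) / spacing).astype(np.int64)
        vox = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        vox = vox[ok]
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        if lvl + 1 < depth:
            tip = p0 + length * d
            for _ in range(2):
                child = d + jitter * rng.standard_normal(3)
                child /= np.linalg.norm(child)
                stack.append((tip, child, length * length_decay,
                              radius * radius_decay, lvl + 1))
    return mask & lobe_mask


def hilum_voxel(vessel_mask: np.ndarray, hilum_cm, spacing, origin):
    """Index of the vessel voxel closest to the hilum point."""
    idx = np.argwhere(vessel_mask)
    if idx.size == 0:
        raise ValueError("vessel mask is empty")
    centers = origin + (idx + 0.5) * np.asarray(spacing)
    d2 = np.sum((centers - np.asarray(hilum_cm)) ** 2, axis=1)
    return tuple(idx[int(np.argmin(d2))])


def trim_to_count(vessel_mask: np.ndarray, target: int, hilum_cm,
                  spacing, origin) -> np.ndarray:
    """Remove the voxels farthest from the hilum until ``target`` remain."""
    out = vessel_mask.copy()
    excess = int(out.sum()) - int(target)
    if excess <= 0:
        return out
    idx = np.argwhere(out)
    centers = origin + (idx + 0.5) * np.asarray(spacing)
    d2 = np.sum((centers - np.asarray(hilum_cm)) ** 2, axis=1)
    order = np.argsort(d2)[::-1][:excess]
    far = idx[order]
    out[far[:, 0], far[:, 1], far[:, 2]] = False
    return out


def grow_to_count(vessel_mask: np.ndarray, lobe_mask: np.ndarray, target: int,
                  hilum_cm, spacing, origin, max_rounds: int = 200) -> np.ndarray:
    """Extend the distal vessel front into vessel-free lung up to ``target``."""
    from scipy.ndimage import binary_dilation

    out = vessel_mask.copy()
    struct = np.ones((3, 3, 3), bool)
    rounds = 0
    while int(out.sum()) < target and rounds < max_rounds:
        cand = binary_dilation(out, structure=struct) & lobe_mask & ~out
        n_cand = int(cand.sum())
        if n_cand == 0:
            raise ValueError(
                "vessel volume target unreachable: no room left inside the lung"
            )
        deficit = int(target) - int(out.sum())
        if n_cand <= deficit:
            out |= cand
        else:
            idx = np.argwhere(cand)
            centers = origin + (idx + 0.5) * np.asarray(spacing)
            d2 = np.sum((centers - np.asarray(hilum_cm)) ** 2, axis=1)
            pick = idx[np.argsort(d2)[::-1][:deficit]]  # distal first
            out[pick[:, 0], pick[:, 1], pick[:, 2]] = True
        rounds += 1
    return out


def match_count(vessel_mask: np.ndarray, lobe_mask: np.ndarray, target: int,
                hilum_cm, spacing, origin) -> np.ndarray:
    """Trim or grow a vessel mask to exactly ``target`` voxels."""
    if int(target) > int(lobe_mask.sum()):
        raise ValueError("vessel target exceeds the lung volume")
    n = int(vessel_mask.sum())
    if n > target:
        return trim_to_count(vessel_mask, target, hilum_cm, spacing, origin)
    if n < target:
        return grow_to_count(vessel_mask, lobe_mask, target, hilum_cm, spacing, origin)
    return vessel_mask.copy()
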