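"""Shared fixtures: materials, a coarse test template, toy phantoms.

Transport- and deformation-heavy tests run on a template built at twice
the reference in-plane voxel pitch; the geometry, targets and physics are
identical and every measured quantity is recomputed from the voxel grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from statphantom import grid as g
from statphantom import materials as mat
from statphantom.template import TemplateConfig, build_template

COARSE_SPACING = (0.4274, 0.4274, 0.8)


@pytest.fixture(scope="session")
def materials():
    return mat.default_materials()


@pytest.fixture(scope="session")
def coarse_config():
    return TemplateConfig(spacing=COARSE_SPACING)


@pytest.fixture(scope="session")
def coarse_template(coarse_config, materials):
    return build_template(coarse_config, materials)


@pytest.fixture()
def toy_phantom():
    """10x8x6 grid with two organs of known voxel counts."""
    labels = np.zeros((10, 8, 6), dtype=np.uint16)
    labels[2:4, 1:6, 0] = 1          # 10 voxels
    labels[7, 2:7, 3] = 2            # 5 voxels
    organ_map = {1: ("organ A", mat.MUSCLE), 2: ("organ B", mat.BONE)}
    return g.LabeledVolume(labels, spacing=(0.5, 0.5, 0.4), origin=(1.0, -2.0, 3.0),
                           organ_map=organ_map)


def water_block(shape, spacing, origin=(0.0, 0.0, 0.0)):
    """Homogeneous soft-tissue block with a token lung voxel at a corner."""
    labels = np.full(shape, 2, dtype=np.uint16)
    labels[0, 0, 0] = g.L_RLUNG
    return g.LabeledVolume(
        labels, spacing=spacing, origin=origin,
        organ_map={2: ("water", mat.MUSCLE),
                   g.L_RLUNG: ("right lung tissue", mat.LUNG_TISSUE)})
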