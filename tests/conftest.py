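"""Shared fixtures: canonical synthetic scenes with exact ground truth."""

import numpy as np
import pytest

from flipquant import BeadSpec, SceneSpec, render_scene

# canonical ringed bead: with the default rim parameters (15% of radius,
# 1 px guard) the measured rim band falls entirely inside the true rim
# and the measured body entirely inside the true body, so region means
# are exact
RINGED = dict(radius=20.0, body_intensity=200.0, rim_intensity=1000.0, rim_thickness=3.0)


def ringed_bead(center, **overrides):
    return BeadSpec(center=center, **{**RINGED, **overrides})


@pytest.fixture
def single_bead_scene():
    """One ringed bead (true rim-body difference 800) on background 10."""
    spec = SceneSpec(
        image_shape=(128, 128),
        background_intensity=10.0,
        beads=(ringed_bead((64, 64)),),
    )
    return spec, *render_scene(spec)


@pytest.fixture
def three_bead_scene():
    """Three disjoint ringed beads of radius 15, 20, 25."""
    beads = tuple(
        BeadSpec(center=c, radius=r, body_intensity=200, rim_intensity=1000, rim_thickness=t)
        for c, r, t in [((60, 60), 15, 3), ((60, 160), 20, 3), ((160, 110), 25, 4)]
    )
    spec = SceneSpec(image_shape=(224, 224), background_intensity=10.0, beads=beads)
    return spec, *render_scene(spec)


def distance_masks(shape, center, radius, rim_thickness):
    """Brute-force ground-truth region masks from pixel-centre distances."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    body = d <= radius - rim_thickness
    rim = (d > radius - rim_thickness) & (d <= radius)
    return rim, body
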