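"""Shared fixtures: small synthetic fields with known ground truth."""

import numpy as np
import pytest

from nanocurve.gridutil import lattice_nodes
from nanocurve.registration import NanostructureLattice
from nanocurve.synth import ChannelSpec, LatticeSpec


@pytest.fixture
def bar_lattice():
    return LatticeSpec(origin=(30.0, 30.0))


@pytest.fixture
def pillar_lattice():
    return LatticeSpec(structure_kind="pillar", pillar_diameter_um=1.0, origin=(30.0, 30.0))


@pytest.fixture
def bar_channels():
    return [
        ChannelSpec(role="registration"),
        ChannelSpec(role="membrane", base_intensity=150.0),
        ChannelSpec(role="integrin", base_intensity=200.0),
    ]


def known_lattice(spec: LatticeSpec) -> NanostructureLattice:
    """Bypass detection: the analysis-side lattice at the generator's truth."""
    return NanostructureLattice(
        origin_xy=spec.origin,
        pitch_um=spec.pitch_um,
        orientation_deg=spec.orientation_deg,
        pixel_size_um=spec.pixel_size_um,
    )


def n_nodes(spec: LatticeSpec, shape) -> int:
    return len(lattice_nodes(spec.origin, spec.pitch_px, spec.orientation_deg, shape))


@pytest.fixture
def cell_disc():
    def make(shape, centre=None, radius=None):
        h, w = shape
        cy, cx = centre or (h // 2, w // 2)
        radius = radius or 0.46 * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        return np.hypot(yy - cy, xx - cx) <= radius

    return make
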