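"""Shared fixtures: the reference chip and a small fast chip for solver tests."""

import numpy as np
import pytest

from serpmix.chip_geometry import (
    ChipSpec,
    SegmentSpec,
    build_chip,
    generate_mesh,
    locate_sections,
)


@pytest.fixture(scope="session")
def reference_spec():
    """The reference glass serpentine chip (dimension-table defaults)."""
    return ChipSpec()


@pytest.fixture(scope="session")
def reference_chip(reference_spec):
    return build_chip(reference_spec)


@pytest.fixture(scope="session")
def small_chip_spec():
    """A short serpentine (4 straights) for fast end-to-end runs."""
    import math

    seq = (
        SegmentSpec(kind="straight", length=800.0),
        SegmentSpec(kind="bend", radius=300.0, angle=math.pi / 2, turn=1),
        SegmentSpec(kind="straight", length=1000.0),
        SegmentSpec(kind="bend", radius=300.0, angle=math.pi, turn=-1),
        SegmentSpec(kind="straight", length=1000.0),
        SegmentSpec(kind="bend", radius=300.0, angle=math.pi, turn=1),
        SegmentSpec(kind="straight", length=1000.0),
    )
    return ChipSpec(
        L1=500.0, L2=800.0, L3=1000.0, L4=1000.0, R1=300.0, R2=300.0,
        d=200.0, h=100.0, n_straight=4, segment_sequence=seq,
    )


@pytest.fixture(scope="session")
def small_chip(small_chip_spec):
    return build_chip(small_chip_spec)


@pytest.fixture(scope="session")
def small_mesh(small_chip):
    return generate_mesh(small_chip, 10.0)


@pytest.fixture(scope="session")
def small_sections(small_chip, small_mesh):
    return locate_sections(small_chip, small_mesh, n=4)


@pytest.fixture(scope="session")
def straight_duct():
    """A single straight channel (4 mm x 200 um) and its mesh."""
    seq = (SegmentSpec(kind="straight", length=4000.0),)
    spec = ChipSpec(segment_sequence=seq, n_straight=1)
    chip = build_chip(spec)
    mesh = generate_mesh(chip, 10.0)
    return spec, chip, mesh
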