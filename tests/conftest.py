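"""Shared phantom/cohort fixtures.

The geometry fixtures are session-scoped: phantom voxelization and
skeletonization dominate the suite's runtime, and the resulting objects are
read-only for every consumer.
"""

from __future__ import annotations

import pytest

import vesselmorph as vm

SPACING = (0.7, 0.7, 1.0)


@pytest.fixture(scope="session")
def cylinder_case():
    """Straight vertical tube, r = 15 mm, length 60 mm."""
    spec = vm.PhantomSpec("cylinder", 15.0, length_mm=60.0, spacing_mm=SPACING)
    mask, truth = vm.make_phantom(spec)
    sg = vm.skeletonize(mask)
    cl = vm.main_path(sg, truth.anchor_mm)
    return spec, mask, truth, sg, cl


@pytest.fixture(scope="session")
def arc_case():
    """Curved tube, r = 12 mm on a 40 mm arc of 80 degrees (aorta-like)."""
    spec = vm.PhantomSpec(
        "arc_tube", 12.0, arc_radius_mm=40.0, arc_angle_deg=80.0, spacing_mm=SPACING
    )
    mask, truth = vm.make_phantom(spec)
    sg = vm.skeletonize(mask)
    cl = vm.main_path(sg, truth.anchor_mm)
    return spec, mask, truth, sg, cl


@pytest.fixture(scope="session")
def bifurcation_case():
    """Trunk r = 13.9 mm splitting into two daughters (PA-like)."""
    spec = vm.PhantomSpec(
        "bifurcation", 13.9, length_mm=45.0, branch_length_mm=32.0,
        spacing_mm=SPACING,
    )
    mask, truth = vm.make_phantom(spec)
    sg = vm.skeletonize(mask)
    bif = vm.detect_bifurcation(sg)
    cl = vm.main_path(sg, truth.anchor_mm).with_bifurcation(bif)
    return spec, mask, truth, sg, cl


@pytest.fixture(scope="session")
def vessel_pair():
    """Default aorta/PA phantom pair realising the cohort-mean ratio 0.8."""
    return vm.make_vessel_pair()


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the published size and marginals."""
    return vm.simulate_cohort(vm.default_cohort_params())
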