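import numpy as np
import pytest

from canalfill.core import RigidTransform, VoxelVolume
from canalfill.morphometry import ResectionPlane, default_resection_plane
from canalfill.phantom import (HumerusGeometry, ImplantSpec,
                               generate_humerus_phantom)


def tube_geometry(canal_radius: float = 4.0, cortical: float = 4.0,
                  length: float = 50.0) -> HumerusGeometry:
    """Degenerate phantom: a plain cortical tube (no metaphysis, no head),
    for analytic-oracle tests."""
    return HumerusGeometry(
        canal_radius=canal_radius, cortical_thickness=cortical,
        diaphysis_outer_radius=canal_radius + cortical,
        diaphysis_length=length, metaphysis_length=0.0,
        metaphysis_outer_radius=canal_radius + cortical,
        head_radius=0.0, margin_xy=3.0, margin_z=2.0)


def cylinder_implant(radius: float, length: float = 40.0,
                     stem_type: str = "short") -> ImplantSpec:
    """Constant-diameter stem without a cup: a plain cylinder."""
    return ImplantSpec(stem_type=stem_type, stem_length=length,
                       proximal_diameter=2 * radius,
                       distal_diameter=2 * radius,
                       cup_diameter=0.0, cup_height=0.0)


def flat_plane(z: float) -> ResectionPlane:
    """Transverse plane (normal +z) for cylinder fixtures."""
    return ResectionPlane(np.array([0.0, 0.0, z]),
                          np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def tube_phantom():
    """Noise-free cortical tube at 0.5 mm: canal R = 4 mm over 50 mm."""
    return generate_humerus_phantom(tube_geometry(), noise_sd=0.0,
                                    spacing=0.5, seed=0)


@pytest.fixture(scope="session")
def humerus_phantom():
    """Full anatomic phantom, noise-free, 0.5 mm."""
    return generate_humerus_phantom(noise_sd=0.0, spacing=0.5, seed=1)


@pytest.fixture(scope="session")
def humerus_phantom_coarse():
    """Full anatomic phantom at 1 mm for the expensive registration and
    planning tests."""
    return generate_humerus_phantom(noise_sd=0.0, spacing=1.0, seed=3)


@pytest.fixture(scope="session")
def resected_coarse(humerus_phantom_coarse):
    from canalfill.morphometry import resect_head, segment_canal
    ph = humerus_phantom_coarse
    plane = default_resection_plane(ph.geometry)
    plane, masks = resect_head(ph.masks, ph.volume, plane)
    canal = segment_canal(masks=masks, method="ground_truth")
    return ph, plane, masks, canal
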