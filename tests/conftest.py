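import numpy as np
import pytest

from sectmorph import (
    PhantomSpec,
    SectionPlane,
    axis_aligned_plane,
    generate_phase_volume,
    render_grayscale,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """64-voxel cube phantom at scanner pitch, default composition."""
    return PhantomSpec(shape=(64, 64, 64), seed=1)


@pytest.fixture(scope="session")
def small_phase(small_spec):
    return generate_phase_volume(small_spec)


@pytest.fixture(scope="session")
def small_gray(small_phase, small_spec):
    return render_grayscale(small_phase, small_spec)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Noiseless, blur-free rendering: segmentation should be invertible."""
    return PhantomSpec(shape=(48, 48, 48), seed=5, noise_sd=0.0, blur_sigma=0.0,
                       histology_perturbation=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def clean_phase(clean_spec):
    return generate_phase_volume(clean_spec)


@pytest.fixture(scope="session")
def clean_gray(clean_phase, clean_spec):
    return render_grayscale(clean_phase, clean_spec)


@pytest.fixture
def mid_plane(small_phase) -> SectionPlane:
    return axis_aligned_plane(small_phase, "z", 32)


def make_plane(extent=(8, 8), pitch=19.75, origin=(0.0, 0.0, 0.0)) -> SectionPlane:
    """Canonical z-normal plane for hand-built map fixtures."""
    return SectionPlane(
        origin=np.asarray(origin, dtype=float),
        normal=np.array([0.0, 0.0, 1.0]),
        u_axis=np.array([1.0, 0.0, 0.0]),
        v_axis=np.array([0.0, 1.0, 0.0]),
        pixel_pitch=pitch,
        extent=extent,
    )
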