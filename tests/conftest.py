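"""Shared phantom fixtures (generated at test time, no stored data)."""

import pytest

from corokit.phantom import OCTPhantomSpec, StrutSpec, synth_oct_pullback


@pytest.fixture(scope="session")
def small_frame_spec():
    """Compact speckled frame: 180 A-lines x 300 depth px at 10 um/px."""
    return OCTPhantomSpec(n_frames=1, n_alines=180, n_depth=300,
                          radial_spacing=0.01, lumen_radius_mm=1.2,
                          wall_thickness_mm=0.6, noise_seed=42)


@pytest.fixture(scope="session")
def small_pullback(small_frame_spec):
    return synth_oct_pullback(small_frame_spec)


@pytest.fixture(scope="session")
def noiseless_frame():
    spec = OCTPhantomSpec(n_frames=1, n_alines=180, n_depth=300,
                          radial_spacing=0.01, lumen_radius_mm=1.2,
                          wall_thickness_mm=0.6, noise_seed=0, speckle=False)
    frames, truth = synth_oct_pullback(spec)
    return frames[0], truth


@pytest.fixture(scope="session")
def strut_frame():
    """One frame with 8 metallic struts on the lumen, 45 degrees apart."""
    struts = [StrutSpec(frame=0, angle_deg=a) for a in range(0, 360, 45)]
    spec = OCTPhantomSpec(n_frames=1, noise_seed=3, struts=struts)
    return synth_oct_pullback(spec), spec
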