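import numpy as np
import pytest

import focusqc as fq


@pytest.fixture
def reference_curve():
    """11-point unimodal curve with gently rising tails and linear flanks."""
    return fq.generate_fixture_curve("reference_R")


@pytest.fixture
def tent_curve():
    """Flat-zero tails with a linear peak: exact corner cutoffs at k = 4, 8."""
    return fq.generate_fixture_curve("tent")


@pytest.fixture
def plateau_curve():
    """Curve that never falls to half maximum (FWHM undefined)."""
    return fq.generate_fixture_curve("plateau")


@pytest.fixture(scope="session")
def texture128():
    """Fixed seeded 128x128 filtered-noise texture on the 0-255 scale."""
    return fq.synthetic.generate_texture(
        fq.SyntheticStackConfig(seed=7, size=(128, 128))
    )


@pytest.fixture(scope="session")
def stack41():
    """The default 41-frame clean synthetic sweep (focus at frame 21)."""
    return fq.generate_focal_stack(fq.SyntheticStackConfig(seed=1))


@pytest.fixture(scope="session")
def stack21():
    """Short 21-frame sweep for noise-robustness checks."""
    return fq.generate_focal_stack(
        fq.SyntheticStackConfig(seed=3, n_frames=21, k0=11, size=(128, 128), rate=0.3)
    )


@pytest.fixture(scope="session")
def seeded_images():
    """20 seeded random 16x16 gray images for oracle-equivalence checks."""
    rng = np.random.default_rng(1234)
    return [rng.uniform(0.0, 255.0, (16, 16)) for _ in range(20)]
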