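"""Shared fixtures: small, fast phantoms reused across test modules.

The test grid is 64x64x76 voxels at 0.3 mm — the same thorax anatomy as
the default phantom, coarsened so a full phantom builds in well under a
second.
"""

from __future__ import annotations

import pytest

from pulmoquant.phantom import PhantomSpec, generate_phantom

FAST_SHAPE = (64, 64, 76)
FAST_SPACING = 0.3


def fast_spec(**overrides) -> PhantomSpec:
    base = dict(shape=FAST_SHAPE, spacing_mm=FAST_SPACING, seed=1)
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def phantom_plain():
    """Tumour-free phantom with default blur and noise."""
    return generate_phantom(fast_spec())


@pytest.fixture(scope="session")
def phantom_diffuse():
    """Diffuse multifocal tumour phantom (10 nodules)."""
    return generate_phantom(fast_spec(tumour_model="diffuse", nodule_count=10, seed=2))


@pytest.fixture(scope="session")
def phantom_circumscribed_clean():
    """Circumscribed tumour, blur on, counting noise off."""
    return generate_phantom(
        fast_spec(tumour_model="circumscribed", pet_noise_counts=0.0, seed=3)
    )
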