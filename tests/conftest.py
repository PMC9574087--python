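"""Shared phantom fixtures.

Arch phantoms are expensive (~5 s each), so the canonical ones are generated
once per session and shared; tests must not mutate them.
"""

import numpy as np
import pytest

from alignfit.phantom import PhantomConfig, generate_arch_phantom


@pytest.fixture(scope="session")
def arch_noisy():
    """Default study conditions: noise sd 10, six implanted voids, identity offset."""
    return generate_arch_phantom(PhantomConfig(seed=3))


@pytest.fixture(scope="session")
def arch_clean_gaps():
    """Noiseless phantom with the default voids (construction-identity checks)."""
    return generate_arch_phantom(PhantomConfig(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def arch_clean_nogaps():
    """Noiseless, gap-free phantom (subtraction/shell identity checks)."""
    return generate_arch_phantom(PhantomConfig(seed=0, noise_sd=0.0, gaps=()))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
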