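import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from alscape.compound_data import ActivityClass, Compound, Fingerprint
from alscape.synthetic_data import SyntheticClassSpec, generate_activity_class


def make_fp(bits_on, length=16) -> Fingerprint:
    bits = np.zeros(length, dtype=bool)
    bits[list(bits_on)] = True
    return Fingerprint(bits)


def make_class(potencies, name="toy", length=16, seed=0) -> ActivityClass:
    """Class of near-identical fingerprints with prescribed potencies."""
    rng = np.random.default_rng(seed)
    base = rng.random(length) < 0.5
    compounds = []
    for i, p in enumerate(potencies):
        bits = base.copy()
        bits[i % length] = ~bits[i % length]
        compounds.append(Compound(f"{name}{i:03d}", Fingerprint(bits), float(p)))
    return ActivityClass(name=name, compounds=compounds)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_class():
    return generate_activity_class(
        SyntheticClassSpec(n_compounds=40, n_clusters=3, seed=7, name="small")
    )


@pytest.fixture(scope="session")
def rendered_color_image():
    """One small full-pipeline render shared across imaging tests."""
    from alscape.imaging import ViewSpec, render_landscape
    from alscape.synthetic_data import SurfaceFixtureSpec, generate_surface_fixture

    surf = generate_surface_fixture(SurfaceFixtureSpec(grid_size=48, n_peaks=3, seed=2))
    return render_landscape(surf, ViewSpec(90, 35), size=(600, 400))
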