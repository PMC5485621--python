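import numpy as np
import pytest

from synctplan.phantom import PhantomSpec, build_phantom, make_phantom, simulate_dixon


def small_spec(**overrides) -> PhantomSpec:
    """A coarse (48^3 @ 5 mm) noiseless phantom spec: fast, same anatomy."""
    defaults = dict(
        shape=(48, 48, 48),
        spacing=(5.0, 5.0, 5.0),
        mr_spacing=(5.0, 5.0, 5.0),
        hu_noise_sd=0.0,
        mr_noise_sd=0.0,
        ptv_size_class="small",
        ptv_volume_cm3=11.9,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return build_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_dixon(noiseless_spec, noiseless_phantom):
    labels, _, _ = noiseless_phantom
    return simulate_dixon(labels, noiseless_spec)


@pytest.fixture(scope="session")
def planning_phantom():
    """Finer phantom (64^3 @ 3.75 mm) used by dose/DVH integration tests."""
    spec = small_spec(
        shape=(64, 64, 64), spacing=(3.75, 3.75, 3.75),
        mr_spacing=(3.75, 3.75, 3.75), ptv_size_class="medium",
        ptv_volume_cm3=83.5, seed=11,
    )
    return spec, make_phantom(spec)


def rasterized_ball_volume_cm3(structures, spacing) -> float:
    return float(structures.array("PTV").sum() * np.prod(spacing) / 1000.0)
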