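import numpy as np
import pytest

from us2ct.phantoms import (
    Inclusion,
    PhantomConfig,
    material_table,
    realize_phantom,
    sample_inclusions,
)
from us2ct.us_sim import desk_probe, scan
from us2ct.rf_chain import run_chain


def make_phantom(flavour, inclusions=None, seed=0, grid_spacing=0.4, **cfg_kw):
    """Phantom with explicitly placed inclusions (or sampled when None)."""
    cfg = PhantomConfig(grid_spacing=grid_spacing, flavour=flavour, **cfg_kw)
    rng = np.random.default_rng(seed)
    if inclusions is None:
        inclusions = sample_inclusions(cfg, rng)
    return realize_phantom(cfg, inclusions, rng)


def inclusion(centre, radius, material, flavour):
    table = material_table(flavour)
    echo = "anechoic" if material == "water" else "hyperechoic"
    return Inclusion(
        centre=centre, radius=radius, material=material, echo_class=echo,
        ct_visible=table[material].rho0 != table["background"].rho0,
    )


@pytest.fixture(scope="session")
def probe():
    return desk_probe()


@pytest.fixture(scope="session")
def lesion_phantom_visible():
    """ct_visible phantom with one water and one muscle inclusion."""
    incs = [
        inclusion((12.0, 20.0), 4.0, "water", "ct_visible"),
        inclusion((25.0, 38.0), 5.0, "muscle", "ct_visible"),
    ]
    return make_phantom("ct_visible", incs, seed=11)


@pytest.fixture(scope="session")
def lesion_phantom_invisible():
    incs = [
        inclusion((12.0, 20.0), 4.0, "water", "ct_invisible"),
        inclusion((25.0, 38.0), 5.0, "muscle", "ct_invisible"),
    ]
    return make_phantom("ct_invisible", incs, seed=11)


@pytest.fixture(scope="session")
def scanned_stages(lesion_phantom_visible, probe):
    rf = scan(lesion_phantom_visible, probe, np.random.default_rng(5))
    return run_chain(rf)
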