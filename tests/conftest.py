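import numpy as np
import pytest

from cartimech import (CompositionField, LocalComposition,
                       MaterialParameters, arcade_directions, build_column)


@pytest.fixture
def params():
    return MaterialParameters.default()


@pytest.fixture
def ref_field():
    return CompositionField.from_reference()


@pytest.fixture
def mid_composition():
    """Mid-depth composition of the idealized reference profiles."""
    return LocalComposition(phi_f=0.8125, phi_co=0.1375, phi_pg=0.05)


@pytest.fixture
def mid_arch(params):
    return arcade_directions(0.5, dispersion=params.w)


@pytest.fixture
def ref_mesh(ref_field, params):
    return build_column(ref_field, params, thickness_mm=4.2, n_layers=12)


def random_admissible_composition(rng):
    """Random composition with dominant fluid, as in cartilage."""
    phi_f = rng.uniform(0.60, 0.88)
    phi_co = rng.uniform(0.05, min(0.35, 0.98 - phi_f))
    return LocalComposition(phi_f, phi_co, 1.0 - phi_f - phi_co)
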