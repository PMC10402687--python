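import numpy as np
import pytest

from dectspr import (NoiseModel, PhantomLayout, generate_bragg_curve,
                     generate_calibration_set, generate_insert_phantom)
from dectspr.materials import MaterialSpec, PMMA


@pytest.fixture(scope="session")
def beam_curve_65():
    """Water depth-dose curve with R80 = 65 mm (head-slab beam)."""
    return generate_bragg_curve(65.0, 1.2, 0.1)


@pytest.fixture(scope="session")
def beam_curve_150():
    """Longer-range water curve for water-column simulations."""
    return generate_bragg_curve(150.0, 1.2, 0.1, depth_max=260.0)


@pytest.fixture(scope="session")
def calibration():
    """(surrogate materials, forward CTN dict) for HLUT calibration."""
    return generate_calibration_set()


@pytest.fixture
def small_layout():
    """Downscaled insert phantom that keeps all geometric features."""
    return PhantomLayout(cylinder_radius=20.0, cylinder_height=60.0,
                         insert_spacing=5.0, insert_length=10.0,
                         voxel_spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def two_materials():
    solid = MaterialSpec(name="solid", red_nominal=1.3, ean_nominal=9.0,
                         md_nominal=1.35, spr_truth=1.28, outer_diameter=20.0)
    cored = MaterialSpec(name="metalcore", red_nominal=3.9, ean_nominal=16.0,
                         md_nominal=4.4, spr_truth=3.2, outer_diameter=20.0,
                         core_diameter=10.0, z_max=40)
    return [solid, cored]


@pytest.fixture
def clean_phantom(small_layout, two_materials):
    """Noise-free two-insert phantom with truth labels."""
    return generate_insert_phantom(small_layout, two_materials,
                                   NoiseModel(seed=0), technique="DLCT")
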