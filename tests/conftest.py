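"""Shared phantom fixtures for the test suite.

Expensive phantoms are session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from dgemric.phantom import (
    AcquisitionSpec,
    PhantomSpec,
    assign_t1_and_gd_fields,
    build_condyle_geometry,
)


@pytest.fixture(scope="session")
def table_spec() -> PhantomSpec:
    """Phantom with the exercise-group medial parameters: WB 2.90 mm /
    NWB 1.81 mm thickness, layer T1 1141/627 (WB) and 1084/737 (NWB) ms,
    superficial [Gd] 0.29 / 0.37 mM."""
    return PhantomSpec(
        thickness_by_segment={"WB": 2.90, "NWB": 1.81},
        t1_superficial_ms={"WB": 1141.0, "NWB": 1084.0},
        t1_deep_ms={"WB": 627.0, "NWB": 737.0},
        gd_superficial_mM={"WB": 0.29, "NWB": 0.37},
    )


@pytest.fixture(scope="session")
def table_truth(table_spec):
    """Fully populated ground truth for the table-parameter phantom."""
    return assign_t1_and_gd_fields(build_condyle_geometry(table_spec))


@pytest.fixture(scope="session")
def noiseless_acq() -> AcquisitionSpec:
    return AcquisitionSpec(noise_sigma=0.0)


def make_slab(
    n_thick_px: int = 6,
    n_wide_px: int = 20,
    pixel_size: float = 0.47,
    margin_px: int = 3,
):
    """A flat cartilage slab with horizontal surface/bone polylines.

    The surface runs along y = (margin - 0.5) px, the bone interface along
    y = (margin + n_thick - 0.5) px, so the slab contains exactly
    ``n_thick_px`` pixel rows and its true thickness is
    ``n_thick_px * pixel_size``.
    """
    ny = n_thick_px + 2 * margin_px
    nx = n_wide_px + 2 * margin_px
    mask = np.zeros((ny, nx), dtype=bool)
    mask[margin_px:margin_px + n_thick_px, margin_px:margin_px + n_wide_px] = True
    y_surface = (margin_px - 0.5) * pixel_size
    y_bone = (margin_px + n_thick_px - 0.5) * pixel_size
    x0 = (margin_px - 0.5) * pixel_size
    x1 = (margin_px + n_wide_px - 0.5) * pixel_size
    surface = np.array([[x0, y_surface], [x1, y_surface]])
    bone = np.array([[x0, y_bone], [x1, y_bone]])
    return mask, surface, bone
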