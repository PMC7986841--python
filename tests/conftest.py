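import numpy as np
import pytest

from implantheat.phantom import ImplantSpec, TissueModel, make_phantom
from implantheat.properties import COCRMO, LABEL_METAL, LABEL_MUSCLE, MUSCLE


@pytest.fixture(scope="session")
def small_phantom() -> TissueModel:
    """Coarse (4 mm) phantom with the default implant, for fast pipeline tests."""
    return make_phantom((26, 26, 82), spacing=0.004, spec=ImplantSpec())


def disk_model(radius: float, thickness: float, spacing: float) -> TissueModel:
    """CoCrMo disk (axis along z) centered at the isocenter, metal only."""
    n = int(2 * radius / spacing) + 4
    nz = int(round(thickness / spacing)) + 2  # one air slice on each z face
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    labels = np.zeros((n, n, nz), dtype=np.int16)
    labels[(X**2 + Y**2 <= radius**2), 1:-1] = LABEL_METAL
    return TissueModel(
        spacing=spacing,
        labels=labels,
        implant_mask=labels == LABEL_METAL,
        property_table={LABEL_METAL: COCRMO},
        origin=np.array([ax[0], ax[0], -(nz - 1) / 2 * spacing]),
    )


def uniform_block(shape, spacing=0.002, props=MUSCLE, air_margin=0) -> TissueModel:
    """Homogeneous tissue block, optionally padded with air on all faces."""
    labels = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(air_margin, s - air_margin or None) for s in shape)
    labels[sl] = LABEL_MUSCLE
    origin = -(np.array(shape) - 1) / 2 * spacing  # grid centered on isocenter
    return TissueModel(
        spacing=spacing,
        labels=labels,
        implant_mask=np.zeros(shape, dtype=bool),
        property_table={LABEL_MUSCLE: props},
        origin=origin,
    )
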