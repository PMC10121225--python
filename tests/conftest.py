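import numpy as np
import pytest

from synaptoscreen import FieldSpec, generate_field
from synaptoscreen.pipeline import max_project, rescale_intensity


@pytest.fixture(scope="session")
def default_field():
    """One default synthetic field with its ground truth (session-cached)."""
    return generate_field(FieldSpec(seed=42))


@pytest.fixture(scope="session")
def plating_field():
    """A nuclei-rich field for plating-QC tests: 10 neuronal + 20 astrocytic
    nuclei, sparse neurites for the somas, no puncta."""
    spec = FieldSpec(
        seed=1,
        image_shape=(384, 384),
        n_on_puncta=0,
        n_off_puncta=0,
        n_neurite_segments=3,
        n_neuronal_nuclei=10,
        n_astrocyte_nuclei=20,
    )
    return generate_field(spec)


def projected(stack, channel):
    return rescale_intensity(max_project(stack.channels[channel]))
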