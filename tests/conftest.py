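import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from matescreen.screen_model import StrainRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20)


def make_strain(
    strain_id,
    aa,
    kind="pMHC",
    group_id=None,
    barcodes=("ACGTACGTACGTACG",),
):
    """Small helper: a StrainRecord from an amino-acid payload."""
    from matescreen.screen_model import reverse_translate

    return StrainRecord(
        strain_id=strain_id,
        mating_type="a" if kind == "TCR" else "alpha",
        payload_kind=kind,
        payload_dna=reverse_translate(aa),
        group_id=group_id or strain_id,
        barcodes=tuple(barcodes),
    )


@pytest.fixture()
def make_record():
    return make_strain
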