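import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    """The packaged Cuora amboinensis cytb oligo panel, keyed by label."""
    from probesense import load_reference_panel

    return load_reference_panel()


@pytest.fixture
def toy_msa():
    """A small hand-written alignment: target plus three nontargets.

    Columns 5-35 (0-based) of each nontarget carry a known number of
    substitutions relative to the target; elsewhere the rows are identical.
    """
    from probesense import AlignedSet
    from probesense.synthetic import MsaSpec, generate_msa

    spec = MsaSpec(
        alignment_length=120,
        window_start=40,
        per_species_window_mismatches={"sp2": 6, "sp3": 14, "sp4": 9},
        background_divergence=0.03,
        seed=11,
    )
    return generate_msa(spec)


@pytest.fixture
def replicate_currents():
    """Four replicate peak currents (uA) from a published reproducibility assay."""
    return [19.84, 20.06, 20.51, 19.33]
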