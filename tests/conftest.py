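import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_family():
    """A four-member paralog family at 80% nt identity (session-cached)."""
    from maltpipe.synthetic import FamilyParams, simulate_gene_family

    genes, ancestor = simulate_gene_family(FamilyParams(seed=7))
    return genes, ancestor


@pytest.fixture(scope="session")
def chimera_scenario(small_family):
    """Known-truth chimera: donor tract (500, 729) on the MALT4 backbone."""
    from maltpipe.core_seq import GeneSequence
    from maltpipe.synthetic import apply_gene_conversion

    genes, _ = small_family
    recipient, donor = genes[3], genes[2]
    tract = (500, 729)
    chim = apply_gene_conversion(recipient, donor, tract)
    candidate = GeneSequence("MALT434", chim.seq, is_cds=True)
    return candidate, genes, recipient, donor, tract
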