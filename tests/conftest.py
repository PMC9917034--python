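import pytest

from degradomics import mbp_substrate
from degradomics.io_tables import SubstrateRecord
from degradomics.mapping import LocatedPeptide


@pytest.fixture(scope="session")
def mbp():
    return mbp_substrate()


@pytest.fixture
def toy_substrate():
    return SubstrateRecord(id="toy", sequence="AAKFAA")


def make_located(substrate, start, end, *, sample="s1", intensity=None,
                 deamidation_sites=(), observed=None, rel=None):
    """Construct a LocatedPeptide consistent with the substrate coordinates."""
    germline = substrate.sequence[start - 1:end]
    if observed is None:
        chars = list(germline)
        for pos in deamidation_sites:
            chars[pos - start] = {"Q": "E", "N": "D"}[chars[pos - start]]
        observed = "".join(chars)
    return LocatedPeptide(
        substrate_id=substrate.id, start=start, end=end,
        observed_sequence=observed, germline_sequence=germline,
        deamidation_sites=tuple(deamidation_sites),
        intensity=intensity, sample_id=sample, relative_abundance=rel,
    )


@pytest.fixture
def located_factory():
    return make_located
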