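import pytest

from epilipid.epilipidome import enumerate_oxidized_species
from epilipid.synthetic import default_parent_panel


@pytest.fixture(scope="session")
def oxidized_candidates():
    """Chain-resolved oxidized candidates from the standard parent panel."""
    cands = []
    for parent in default_parent_panel():
        cands.extend(enumerate_oxidized_species(parent))
    return cands
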