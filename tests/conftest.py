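import logging

import pytest
from hypothesis import settings

from onsetnlp import synth

logging.getLogger("onsetnlp").setLevel(logging.ERROR)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_bundle():
    """A 100-patient synthetic corpus shared by structural tests."""
    return synth.generate(synth.GenConfig(n_patients=100, seed=11))


@pytest.fixture(scope="session")
def small_refs(small_bundle):
    refs, labels = synth.emit_gold_reference(small_bundle.ground_truth)
    return refs
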