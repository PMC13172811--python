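import random

import pytest
from hypothesis import HealthCheck, settings

from probemine.probes import Probe, ProbePanel

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture
def two_probe_panel() -> ProbePanel:
    """Two unrelated 20-mers (a human beta-actin primer and a CRFK cell
    marker), convenient for spike-in fixtures."""
    return ProbePanel((
        Probe.from_sequence("actin", "AGAGATGGCCACGGCTGCTT"),
        Probe.from_sequence("crfk", "CCTGTGAAAAGCCACTCAGA"),
    ))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
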