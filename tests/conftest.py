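import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, max_examples=60)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lcdscope.proteome import ProteinRecord, Proteome
from lcdscope.simulate import StudyConfig, generate_study


def random_sequence(rng: np.random.Generator, length: int,
                    freqs: dict[str, float] | None = None) -> str:
    from lcdscope.classes import CANONICAL_AA
    if freqs is None:
        return "".join(rng.choice(list(CANONICAL_AA), size=length))
    aas = list(freqs)
    p = np.array([freqs[a] for a in aas])
    return "".join(rng.choice(aas, size=length, p=p / p.sum()))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_proteome():
    return Proteome("TINY01", [
        ProteinRecord("t1", "M" + "Q" * 59),
        ProteinRecord("t2", "M" + "HQ" * 15 + "L" * 30),
        ProteinRecord("t3", "MACDEFGHIKLMNPQRSTVWY" * 3),
    ])


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Default miniature survey, shared across tests (read-only)."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_study(StudyConfig(), out, seed=11)
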