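import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lzrep import build_graph, synth_repertoire

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def branching_graph():
    """Hand-countable amino-acid positional graph with one branch point."""
    return build_graph(["CASF", "CASG", "CATF"], "aap")


@pytest.fixture(scope="session")
def two_path_graph():
    return build_graph(["CASF", "CASG"], "aap")


@pytest.fixture(scope="session")
def prefix_stop_graph():
    """Graph where one sequence is a strict prefix of the other."""
    return build_graph(["CAS", "CASF"], "aap")


@pytest.fixture(scope="session")
def aa_repertoire():
    """Mid-sized annotated amino-acid synthetic repertoire."""
    return synth_repertoire(n_sequences=600, n_unique=300, seed=11)


@pytest.fixture(scope="session")
def nt_repertoire():
    return synth_repertoire(
        n_sequences=400, n_unique=200, scope="nucleotide", seed=12
    )


def random_repertoire(rng: np.random.Generator, scope: str = "amino_acid"):
    """Small random synthetic repertoire with an rng-derived seed."""
    return synth_repertoire(
        n_sequences=int(rng.integers(20, 60)),
        n_unique=int(rng.integers(10, 20)),
        scope=scope,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
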