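import numpy as np
import pytest

from kinrank import GeneSetLibrary


@pytest.fixture
def small_library():
    """Three fixed kinase sets over a tiny symbol universe."""
    return GeneSetLibrary(
        name="small",
        source_type="KSI",
        sets={
            "KINA": ["G1", "G2", "G3", "G4", "G5"],
            "KINB": ["G4", "G5", "G6", "G7", "G8"],
            "KINC": ["G9", "G10", "G11", "G12", "G13"],
        },
    )


@pytest.fixture
def random_library_factory():
    """Seeded factory for random libraries with configurable shape."""

    def make(seed, n_sets=10, set_size=20, universe_size=500, name="rand",
             source_type="KSI"):
        rng = np.random.default_rng(seed)
        universe = np.array([f"G{i:06d}" for i in range(1, universe_size + 1)])
        sets = {
            f"KIN{i:03d}": rng.choice(universe, size=set_size, replace=False).tolist()
            for i in range(1, n_sets + 1)
        }
        return GeneSetLibrary(name=name, source_type=source_type, sets=sets)

    return make
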