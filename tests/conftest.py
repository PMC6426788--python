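import numpy as np
import pytest

from caspmine.profiles import SeedAlignment, build_profile


@pytest.fixture(scope="session")
def uniform_bg():
    return np.full(20, 0.05)


@pytest.fixture(scope="session")
def tiny_profile():
    """5-column profile from a nearly invariant toy seed with an HC dyad."""
    rows = (
        ("r1", "AHCDE"),
        ("r2", "AHCDE"),
        ("r3", "AHCDE"),
        ("r4", "GHCDE"),
    )
    return build_profile(SeedAlignment(rows), 1, 5, name="tiny")


@pytest.fixture(scope="session")
def small_proteome():
    """A small noise-free synthetic proteome shared across tests."""
    from caspmine.simulate import SynthSpec, generate_proteome

    spec = SynthSpec(
        seed=11,
        n_per_class={
            "orthocaspase": 30,
            "metacaspase_I": 6,
            "metacaspase_II": 4,
            "metacaspase_III": 3,
            "paracaspase": 3,
            "ambiguous": 2,
        },
        n_decoys=6,
    )
    return generate_proteome(spec)
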