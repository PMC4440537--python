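import numpy as np
import pytest

from repeatscape import synthetic as syn


@pytest.fixture(scope="session")
def trna_set():
    return syn.default_trna_set()


@pytest.fixture(scope="session")
def protein_library():
    return syn.default_protein_library()


@pytest.fixture(scope="session")
def trim_element():
    """A TRIM-like element: 375-bp LTRs, 1148-bp non-coding internal."""
    return syn.build_te_consensus(
        "ltr_rt_trim",
        {"ltr_length": 375, "internal_length": 1148, "element_id": "TRIM1", "trna_id": "Met"},
        seed=2,
    )


@pytest.fixture(scope="session")
def autonomous_element():
    """An autonomous element: 215-bp LTRs, 4702-bp coding internal."""
    return syn.build_te_consensus(
        "ltr_rt_autonomous",
        {"ltr_length": 215, "internal_length": 4702, "element_id": "AUTO1", "trna_id": "Lys"},
        seed=1,
    )


def plant_one(element, anatomy, *, bg_len=20_000, pos=10_000, age=0.0, tsd=5, seed=3, bg_seed=7):
    """Plant a single element copy and return (genome, truth record)."""
    bg = syn.generate_background(bg_len, 0.46, bg_seed)
    genome, truth = syn.plant_insertions(
        bg,
        {element.entry_id: (element, anatomy)},
        [syn.InsertionSpec(element.entry_id, anatomy["kind"], pos, age_years=age, tsd_length=tsd)],
        seed=seed,
    )
    return genome, truth[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
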