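import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from barrelforge import connectors, fixtures, registers

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def heptamer():
    """Ideal all-parallel 7-helix barrel, 4 heptads per helix."""
    return fixtures.make_barrel(fixtures.CrickParams(n=7), n_heptads=4)


@pytest.fixture(scope="session")
def ap_hexamer():
    """Ideal antiparallel (alternating up/down) 6-helix barrel."""
    return fixtures.make_barrel(fixtures.CrickParams.antiparallel(6), n_heptads=4)


@pytest.fixture(scope="session")
def trimer():
    """Collapsed three-helix bundle (no open lumen)."""
    return fixtures.make_barrel(fixtures.CrickParams(n=3), n_heptads=4)


@pytest.fixture(scope="session")
def dimer():
    """Parallel coiled-coil dimer with a canonical a/d core."""
    return fixtures.make_barrel(fixtures.CrickParams(n=2), n_heptads=4)


@pytest.fixture(scope="session")
def loop_library():
    return fixtures.make_loop_library(n_entries=5, seed=1)


@pytest.fixture(scope="session")
def hth_unit_7():
    return fixtures.make_hth_unit("right", fixtures.HTHGeometry(n=7))


@pytest.fixture(scope="session")
def default_seq_4h():
    rule = registers.SeedRule("A", ("L",), ("I",), "A")
    return registers.build_seed_peptide(rule, registers.BackgroundSpec.default(4))


@pytest.fixture(scope="session")
def grafted_hexamer_chain(ap_hexamer):
    """Antiparallel hexamer fused into a single chain by five grafted loops."""
    model = ap_hexamer
    results = []
    for k in range(5):
        hi, hj = model.helices[k], model.helices[k + 1]
        entry = fixtures.make_connectable_entry(
            model, hi, hj, loop_len=4, source_id=f"bridge_{k}", seed=k)
        query = connectors.stub_pair_from_helices(model, hi, hj)
        hits = connectors.search_connectors(
            query, connectors.FragmentLibrary([entry]), rmsd_cutoff=1.0)
        result = connectors.graft_connector(model, hits[0], hi, hj)
        results.append(result)
        model = result.model
    return model, results


def random_rotation(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
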