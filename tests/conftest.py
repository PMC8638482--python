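import numpy as np
import pytest

import ktjoint as kj


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale phantom acquisition shared across tests: 48x48, 8 frames,
    3 coils, r1=2, r2=2, 12 ACS lines, seeded."""
    spec = kj.PhantomSpec(nx=48, ny=48, n_frames=8, n_coils=3, seed=1)
    data, plan, truth, sens = kj.make_default_dataset(
        spec, r1=2, r2=2, n_acs=12, seed=1
    )
    return {"spec": spec, "data": data, "plan": plan, "truth": truth, "sens": sens}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
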