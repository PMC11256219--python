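import numpy as np
import pytest

import floatnr as F


@pytest.fixture
def d2o():
    return F.NAMED_CONTRASTS["D2O"]


@pytest.fixture
def h2o():
    return F.NAMED_CONTRASTS["H2O"]


@pytest.fixture
def ground_truth():
    """Fresh copy of the resolved-structure ground truth per test."""
    return F.default_ground_truth()


@pytest.fixture
def small_instrument():
    """Reduced-binning instrument for cheap simulated datasets."""
    return F.InstrumentSpec("INTER-lite", (1.0, 16.0), (0.7, 2.3), n_bins=60)


def simulate_joint(truth, instrument, seed, conditions=("Ca",), bare=True,
                   contrasts=("D2O", "AuMW", "PrMW", "H2O"), **kwargs):
    """Bare + membrane datasets from a ground truth, seeded reproducibly."""
    n = (2 if bare else 0) + len(conditions) * len(contrasts)
    seeds = np.random.SeedSequence(seed).generate_state(n)
    out, i = [], 0
    if bare:
        for c in ("D2O", "H2O"):
            out.append(
                F.simulate_dataset(truth.underlayers, None, instrument, c,
                                   int(seeds[i]), **kwargs)
            )
            i += 1
    for cond in conditions:
        for c in contrasts:
            out.append(
                F.simulate_dataset(truth.underlayers, truth.membranes[cond],
                                   instrument, c, int(seeds[i]),
                                   condition=cond, **kwargs)
            )
            i += 1
    return out
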