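import numpy as np
import pytest

import transientcmr as tc
from transientcmr.encounter import EncounterDataset, Individual


@pytest.fixture
def tiny_dataset() -> EncounterDataset:
    """Six individuals, two groups, four occasions; hand-checkable."""
    inds = [
        Individual("a", "3", (1, 0, 1, 1)),
        Individual("b", "3", (1, 0, 0, 0)),
        Individual("c", "4", (0, 1, 1, 0)),
        Individual("d", "4", (0, 1, 0, 0)),
        Individual("e", "7plus", (0, 0, 1, 1)),
        Individual("f", "3", (1, 1, 1, 1)),
    ]
    return EncounterDataset(("1988", "1989", "1990", "1991"), inds)


@pytest.fixture
def medium_sim():
    """A moderately sized transient simulation with known truth."""
    cfg = tc.SimulationConfig(
        n_occasions=12, releases=80, phi_resident=0.9, p_detect=0.6,
        tau=0.3, groups=("a", "b"), seed=20,
    )
    data, truth = tc.simulate(cfg)
    return cfg, data, truth


def exhaustive_history_nll(individuals, phi, p, tau):
    """Independent likelihood oracle: enumerate each individual's latent
    fates (transient flag, death interval) and sum the exact probability
    of its history conditional on first release."""
    total = 0.0
    for ind in individuals:
        det = ind.detections
        K = len(det)
        occs = [i for i, d in enumerate(det) if d]
        f, last = occs[0], occs[-1]
        p_trans = tau if len(occs) == 1 else 0.0
        p_res = 0.0
        for death_after in range(last, K):
            pp = 1.0
            for i in range(f, death_after):
                pp *= phi[i]
            if death_after < K - 1:
                pp *= 1.0 - phi[death_after]
            for o in range(f + 1, death_after + 1):
                pp *= p[o - 1] if det[o] else (1.0 - p[o - 1])
            p_res += pp
        total += -np.log(p_trans + (1.0 - tau) * p_res)
    return total
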