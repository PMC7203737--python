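import itertools

import numpy as np
import pytest

from admotif import ADM, seq_probability
from admotif.alphabet import revcomp


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def rand_adm():
    """Factory of random valid ADMs with a dedicated, seeded stream."""

    def make(length: int, seed: int = 0) -> ADM:
        r = np.random.default_rng(seed)
        init = r.dirichlet(np.ones(4))
        trans = r.dirichlet(np.ones(4), size=(length - 1, 4))
        return ADM(init, trans)

    return make


def all_seqs(length: int):
    for tup in itertools.product("ACGT", repeat=length):
        yield "".join(tup)


def brute_force_zoops_ll(model, reads):
    """Independent ZOOPS log-likelihood by direct enumeration of every
    (component, start, strand) placement, in plain Python."""
    bgp = model.background.stationary()

    def bg_prob(s):
        p = 1.0
        for ch in s:
            p *= bgp["ACGT".index(ch)]
        return p

    total = 0.0
    for r in reads:
        L = len(r)
        acc = model.lam_bg * bg_prob(r)
        for key in model.component_keys():
            lam = model.component_lambda(key)
            adm = model.component_adm(key)
            w = adm.length
            S = L - w + 1
            n_place = 2 * S
            for j in range(S):
                win = r[j : j + w]
                flank = bg_prob(r[:j]) * bg_prob(r[j + w :])
                acc += lam / n_place * flank * (
                    seq_probability(adm, win) + seq_probability(adm, revcomp(win))
                )
        total += np.log(acc)
    return float(total)
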