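import numpy as np
import pytest

from ciconia import synthgen
from ciconia.popstats import SFS


@pytest.fixture(scope="session")
def neutral_bg_20() -> SFS:
    return synthgen.neutral_sfs(20)


@pytest.fixture(scope="session")
def neutral_bg_40() -> SFS:
    return synthgen.neutral_sfs(40)


@pytest.fixture(scope="session")
def track_params() -> synthgen.TrackSimParams:
    return synthgen.TrackSimParams()


def enumerate_sweep_pmf(n: int, pe: float, bg: SFS) -> np.ndarray:
    """Brute-force unconditioned pmf of the escape-model derived count.

    Enumerates every escape indicator vector, the swept haplotype's allelic
    state, and every allele assignment of the escapees; independent of the
    closed-form implementation.
    """
    from itertools import product

    pmf = np.zeros(n + 1)
    for freq, w in zip(bg.freqs, bg.probs):
        for esc in product([0, 1], repeat=n):
            p_esc = np.prod([pe if e else 1 - pe for e in esc])
            escapees = [i for i, e in enumerate(esc) if e]
            n_non = n - len(escapees)
            for swept_derived in (0, 1):
                p_swept = freq if swept_derived else 1 - freq
                for alleles in product([0, 1], repeat=len(escapees)):
                    p_all = np.prod([freq if a else 1 - freq for a in alleles])
                    b = sum(alleles) + swept_derived * n_non
                    pmf[b] += w * p_esc * p_swept * p_all
    return pmf
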