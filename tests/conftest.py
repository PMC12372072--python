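import numpy as np
import pytest

import presschain as pc


@pytest.fixture(scope="session")
def lengths():
    return pc.calibrate_from_printed_heights()


@pytest.fixture(scope="session")
def bench_chain(lengths):
    l1, l2 = lengths
    return pc.build_chain(l1, l2, M=pc.BENCH_MASS)


@pytest.fixture(scope="session")
def overhead_chain(lengths):
    l1, l2 = lengths
    return pc.build_chain(l1, l2, M=pc.OVERHEAD_MASS)


@pytest.fixture(scope="session")
def bench_max_trajectory(bench_chain):
    """Just-completing bench lift with k = 1/2 (the maximal-lift condition)."""
    tau_lim = pc.critical_tau1(bench_chain, pc.bench_press(k=0.5), criterion="completion")
    return pc.simulate_lift(bench_chain, pc.bench_press(tau1=tau_lim + 2e-5, k=0.5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
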