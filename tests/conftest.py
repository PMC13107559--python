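import numpy as np
import pytest

from looptopo.core import Interval, Loop, canonicalize_loop
from looptopo.simulate import CONDITIONS, SimConfig, simulate_study

SMALL_SIM = dict(
    chrS_length=8_000_000,
    chrG_length=8_000_000,
    n_ctcf_loops=80,
    n_h3k27ac_interactions=400,
    n_genes=600,
    n_background_windows=300,
    n_weak_sites=30,
    n_nonlooping_h3k27ac=100,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, **SMALL_SIM)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


def random_interval(rng: np.random.Generator, chrom="chr1", lo=0, hi=100_000,
                    max_width=2_000) -> Interval:
    start = int(rng.integers(lo, hi - 1))
    width = int(rng.integers(1, max_width))
    return Interval(chrom, start, start + width)


def random_loop(rng: np.random.Generator, lid: str, chrom="chr1", hi=1_000_000,
                conditions=CONDITIONS) -> Loop:
    a = random_interval(rng, chrom, 0, hi)
    b = random_interval(rng, chrom, 0, hi)
    counts = {c: int(rng.integers(0, 200)) for c in conditions}
    return canonicalize_loop(
        Loop(id=lid, anchorL=a, anchorR=b, counts=counts,
             strength=float(rng.lognormal(1.0, 0.8))))
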