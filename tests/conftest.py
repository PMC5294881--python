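import warnings
from pathlib import Path

import pytest

from adaptci import AdaptiveDesign, enumerate_space, generate_design

EXTERNAL_DIR = Path(__file__).parent / "data" / "external"


@pytest.fixture
def toy_design():
    """Smallest useful design: one continuation value, one-point G1 and G3."""
    return AdaptiveDesign(
        n1=2,
        r1_futility=0,
        r1_efficacy=2,
        n2={1: 2},
        r={1: 2},
        pi0=0.5,
        pi1=0.7,
        alpha=0.05,
        beta=0.2,
    )


@pytest.fixture
def toy_space(toy_design):
    return enumerate_space(toy_design)


@pytest.fixture(scope="session")
def generated_designs():
    """A deterministic batch of valid random designs (seeds 0..49)."""
    return [generate_design(seed) for seed in range(50)]


@pytest.fixture(scope="session")
def tiny_designs():
    """Very small designs (n1 <= 6) for brute-force oracle comparisons."""
    return [generate_design(seed, n1_range=(3, 6), n2_max=4) for seed in range(12)]


@pytest.fixture(autouse=True)
def _silence_fallback_warnings():
    # the non-monotone orderings (RR-LR/RR-Score on some shapes) legitimately
    # trigger the first-crossing fallback warning; keep test output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def point(space, x1, x2=None):
    matches = [p for p in space.points if p.x1 == x1 and p.x2 == x2]
    assert len(matches) == 1, f"({x1},{x2}) not unique in space"
    return matches[0]
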