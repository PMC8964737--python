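"""Shared fixtures: the two tissue-scale optimizations are expensive, so they
run once per session and are shared by the optimizer and acceptance tests."""

from __future__ import annotations

import pytest

from hiertissue import DriverSpec, TissueSpec, build_hierarchy, find_minimal_hierarchy
from hiertissue.optimize import _RiskCache

BLOOD = dict(N0=1e4, N=1e15, threshold=0.02)
COLON = dict(N0=1e8, N=1e14, threshold=0.04)
T_LIFE = 80.0


@pytest.fixture(scope="session")
def blood_opt():
    """Hematopoietic optimum at the representative point (mu=2.5e-6, s=0.1)."""
    return find_minimal_hierarchy(BLOOD["N0"], BLOOD["N"],
                                  DriverSpec(s=0.1, mu=2.5e-6),
                                  BLOOD["threshold"], T_LIFE)


@pytest.fixture(scope="session")
def colon_cache():
    return _RiskCache()


@pytest.fixture(scope="session")
def colon_opt(colon_cache):
    """Colon optimum at the representative point (mu=1e-5, s=0.1)."""
    return find_minimal_hierarchy(COLON["N0"], COLON["N"],
                                  DriverSpec(s=0.1, mu=1e-5),
                                  COLON["threshold"], T_LIFE, cache=colon_cache)


@pytest.fixture(scope="session")
def colon_opts_by_threshold(colon_cache, colon_opt):
    """Colon optima across drift-barrier thresholds (risk cache shared)."""
    spec = DriverSpec(s=0.1, mu=1e-5)
    out = {COLON["threshold"]: colon_opt}
    for thr in (0.001, 0.01, 0.1):
        out[thr] = find_minimal_hierarchy(COLON["N0"], COLON["N"], spec, thr,
                                          T_LIFE, cache=colon_cache)
    return out


@pytest.fixture(scope="session")
def blood_matched_opt():
    """Hematopoietic optimum at the colon's (mu, s) for the cross-tissue contrast."""
    return find_minimal_hierarchy(BLOOD["N0"], BLOOD["N"],
                                  DriverSpec(s=0.1, mu=1e-5),
                                  BLOOD["threshold"], T_LIFE)


@pytest.fixture
def small_hierarchy():
    """Desk-scale tissue used by solver unit tests."""
    return build_hierarchy(TissueSpec(N0=10, N=1000, n=3, gamma=3.0, t_life=1.0))
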