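"""Shared fixtures.

Multi-year system runs are expensive, so the four-site pasture-only /
supplemented simulations and the capacity estimates are computed once per
session and shared across test modules.  All randomness is seeded.
"""

from __future__ import annotations

import pytest

import cowcalf as cc
from cowcalf.management import CapacityConfig
from cowcalf.simulate import RunConfig, run_simulation

SEED = 7
SIM_YEARS = 25
SIM_DISCARD = 8
CAP_YEARS = 20
CAP_DISCARD = 5


@pytest.fixture(scope="session")
def sites():
    return {name: cc.builtin_site(name) for name in cc.BUILTIN_SITES}


@pytest.fixture(scope="session")
def met_by_site(sites):
    return {name: cc.synthesize_weather(site.climate, SIM_YEARS, SEED)
            for name, site in sites.items()}


@pytest.fixture(scope="session")
def system_runs(sites, met_by_site):
    """(site, mode) -> (annual summaries, diagnostics) for all four sites."""
    out = {}
    for name, site in sites.items():
        for mode in (False, True):
            rc = RunConfig(site=site, met=met_by_site[name],
                           total_years=SIM_YEARS, discard_years=SIM_DISCARD,
                           supplement_mode=mode)
            out[(name, mode)] = run_simulation(rc, return_diagnostics=True)
    return out


@pytest.fixture(scope="session")
def capacities(sites, met_by_site):
    """site -> {"raw": cows/ha, "rounded": cows/ha to 0.1} capacity estimates."""
    from cowcalf.simulate import run_capacity

    cfg = CapacityConfig(run_years=CAP_YEARS, discard_years=CAP_DISCARD)
    out = {}
    for name, site in sites.items():
        steers = run_capacity(site, met_by_site[name][:365 * CAP_YEARS], cfg)
        raw = steers / cfg.conversion
        out[name] = {"raw": raw,
                     "rounded": round(round(raw / cfg.rounding) * cfg.rounding, 10)}
    return out
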