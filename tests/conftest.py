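"""Shared simulation fixtures.

The expensive runs (growth-factor comparison pairs, single-factor runs,
sensitivity variants) are computed once per session and shared across unit
and acceptance tests; every run is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from chondrosim.scenarios import ScenarioSpec, run_scenario, sweep


@pytest.fixture(scope="session")
def none_traj():
    """No-growth-factor baseline, 12 months, quarter-month sampling."""
    return run_scenario(ScenarioSpec(name="none", gf_config="none",
                                     duration_months=12.0,
                                     output_cadence_months=0.25))


@pytest.fixture(scope="session")
def both_traj():
    """Both growth factors enabled, 12 months, quarter-month sampling."""
    return run_scenario(ScenarioSpec(name="both", gf_config="both",
                                     duration_months=12.0,
                                     output_cadence_months=0.25))


@pytest.fixture(scope="session")
def single_factor_trajs():
    """FGF-1-only and BMP-2-only runs to just past 2 months."""
    spec = ScenarioSpec(duration_months=2.2, output_cadence_months=0.2)
    return {
        gf: run_scenario(spec.replace(name=gf, gf_config=gf))
        for gf in ("fgf_only", "bmp_only")
    }


@pytest.fixture(scope="session")
def sensitivity_runs():
    """Base (both growth factors) and the four threshold-pathway variants."""
    base_spec = ScenarioSpec(name="base", gf_config="both",
                             duration_months=2.2, output_cadence_months=0.2)
    runs = {"base": run_scenario(base_spec)}
    for param, value in [("p12", 267.0), ("p13", 0.154),
                         ("CS0_min", 0.28), ("alpha", 1.0)]:
        runs[param] = sweep(base_spec, param, [value])[value]
    return runs
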