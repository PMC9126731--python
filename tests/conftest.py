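import numpy as np
import pytest

import ruesim as rs


@pytest.fixture(scope="session")
def cfg():
    return rs.default_configs()


@pytest.fixture(scope="session")
def weather3():
    """Three seeded synthetic years — cheap fixture for season tests."""
    return rs.generate_weather(rs.ClimateSpec(n_years=3, seed=123))


@pytest.fixture(scope="session")
def weather31():
    """The full 31-year study climate."""
    return rs.generate_weather(rs.ClimateSpec(n_years=31, seed=1))


@pytest.fixture(scope="session")
def experiment(weather31):
    """Calibrated baseline + full 19-scenario experiment (session-cached)."""
    cal = rs.calibrate_baseline(rs.default_configs(), weather31)
    table = rs.run_experiment(rs.build_scenarios(), cal, weather31)
    synergy = rs.synergy_metrics(table)
    return {"cfg": cal, "weather": weather31, "table": table, "synergy": synergy}


def leaf_layer(cfg, sln=2.0):
    """Leaf biochemistry and conductances of a layer at a given leaf N."""
    import dataclasses

    profile = rs.make_profile(cfg.canopy, GAI=1.0, leaf_fraction=1.0, N_canopy=sln - cfg.canopy.nb)
    p = rs.biochem_from_sln(sln, profile, cfg.leaf)
    cond = dataclasses.replace(cfg.cond, gm=cfg.canopy.chi_gm * (sln - cfg.canopy.nb))
    return p, cond
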