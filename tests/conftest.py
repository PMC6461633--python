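import pandas as pd
import pytest

from lipidshift import FilterConfig, RunConfig, run_pipeline
from lipidshift.synthetic_data import preset_glucocorticoid_study, simulate_experiment


@pytest.fixture(scope="session")
def preset_cfg():
    return preset_glucocorticoid_study(seed=7)


@pytest.fixture(scope="session")
def preset_sim(preset_cfg):
    return simulate_experiment(preset_cfg)


@pytest.fixture(scope="session")
def preset_result(preset_cfg, preset_sim):
    rc = RunConfig(filter=FilterConfig(override_species=preset_cfg.override_species))
    return run_pipeline(preset_sim.areas, preset_sim.metadata, preset_sim.istd_map, rc)


@pytest.fixture
def toy_table():
    """Two samples x two species + one ISTD each, minimal quantifiable table."""
    rows = []
    for sample, (a1, a2, istd) in {
        "s1": (1000.0, 300.0, 1000.0),
        "s2": (500.0, 600.0, 2000.0),
    }.items():
        rows.append(dict(sample_id=sample, species="PC 34:1", panel="PL_CE_DG", area=a1, is_istd=False))
        rows.append(dict(sample_id=sample, species="PC 38:4", panel="PL_CE_DG", area=a2, is_istd=False))
        rows.append(dict(sample_id=sample, species="ISTD PC", panel="PL_CE_DG", area=istd, is_istd=True))
    return pd.DataFrame(rows)


@pytest.fixture
def toy_istd_map():
    return pd.DataFrame(
        {"istd_id": ["ISTD PC", "ISTD PC"], "istd_conc_umol_per_l": [2.0, 2.0]},
        index=pd.Index(["PC 34:1", "PC 38:4"], name="species"),
    )
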