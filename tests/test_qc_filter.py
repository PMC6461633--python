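import numpy as np
import pandas as pd
import pytest

from lipidshift import FilterConfig, RunConfig, run_pipeline
from lipidshift.qc_filter import QCError, apply_qc, cv_filter, pqc_cv
from lipidshift.quantify import correct_s1p_interference, quantify_table


def test_pqc_cv_values():
    assert pqc_cv([1.0, 1.0, 1.0]) == 0.0
    assert pqc_cv([0.9, 1.0, 1.1]) == pytest.approx(10.0)
    assert np.isnan(pqc_cv([0.0, 0.0]))
    with pytest.raises(QCError):
        pqc_cv([1.0])


def test_cv_filter_rules():
    cvs = pd.DataFrame(
        {
            "A": [26.0, 10.0, 25.0, np.nan],
            "B": [10.0, 10.0, 25.0, np.nan],
        },
        index=["x", "y", "z", "w"],
    )
    d = cv_filter(cvs, FilterConfig())
    assert d["x"] == "excluded_cv"
    assert d["y"] == "kept"
    assert d["z"] == "kept"  # strictly-greater comparison: 25.0 passes
    assert d["w"] == "excluded_missing"


def test_cv_filter_override_retention():
    """High-CV species on the override list stay in the dataset so the two
    treatment arms remain comparable (CV quartet 27.8/30.1 vs 7.3/10.9%)."""
    cvs = pd.DataFrame(
        {
            "tetracosactide": [27.8, 30.1],
            "prednisolone": [7.3, 10.9],
        },
        index=["Cer d18:1/18:0", "Hex1Cer d18:1/24:1"],
    )
    cfg = FilterConfig(override_species=("Cer d18:1/18:0", "Hex1Cer d18:1/24:1"))
    assert (cv_filter(cvs, cfg) == "kept_by_override").all()
    # without the override both are dropped
    assert (cv_filter(cvs, FilterConfig()) == "excluded_cv").all()


def _mini_experiment(pqc_areas_by_species, blank_area=10.0, n_study=2):
    """One-group toy with controllable PQC areas (ISTD fixed at 1000)."""
    rows, meta = [], []
    samples = (
        [(f"d{i}_{tp}", "study", f"d{i}", tp) for i in range(1, n_study + 1) for tp in ("before", "after")]
        + [(f"G_PQC{j}", "PQC", "", "") for j in range(1, 4)]
        + [("G_BLANK1", "blank", "", "")]
    )
    for sid, role, subj, tp in samples:
        meta.append(dict(sample_id=sid, subject_id=subj, group="G", timepoint=tp, role=role, sex="M"))
        for sp, pqc_areas in pqc_areas_by_species.items():
            if role == "PQC":
                area = pqc_areas[int(sid[-1]) - 1]
            elif role == "blank":
                area = blank_area
            else:
                area = float(np.mean(pqc_areas))
            rows.append(dict(sample_id=sid, species=sp, panel="PL_CE_DG", area=area, is_istd=False))
        rows.append(dict(sample_id=sid, species="ISTD PC", panel="PL_CE_DG", area=1000.0, is_istd=True))
    table = pd.DataFrame(rows)
    istd = pd.DataFrame(
        {"istd_id": "ISTD PC", "istd_conc_umol_per_l": 1.0},
        index=pd.Index(list(pqc_areas_by_species), name="species"),
    )
    return table, pd.DataFrame(meta), istd


def test_cascade_reason_order_and_thresholds():
    table, meta, istd = _mini_experiment(
        {
            "PC 34:1": [200.0, 200.0, 200.0],      # under the 250 floor
            "PC 36:2": [40.0, 40.0, 40.0],         # both floor and blank fail -> floor reported
            "PC 38:4": [2000.0, 2000.0, 2000.0],   # ratio 2000/10 -> passes
            "PC 32:0": [45.0, 45.0, 45.0],
        },
        blank_area=10.0,
    )
    # make PC 32:0 pass the floor but fail the 5x blank ratio
    table.loc[table.species == "PC 32:0", "area"] = 400.0
    table.loc[(table.species == "PC 32:0") & (table.sample_id == "G_BLANK1"), "area"] = 100.0
    q = quantify_table(table, istd)
    report = apply_qc(table, q, meta, FilterConfig())
    d = report.decisions["G"]
    assert d["PC 34:1"] == "excluded_area_floor"
    assert d["PC 36:2"] == "excluded_area_floor"  # floor outranks blank in reporting
    assert d["PC 38:4"] == "kept"
    assert d["PC 32:0"] == "excluded_blank_ratio"


def test_zero_blank_is_pass():
    table, meta, istd = _mini_experiment({"PC 34:1": [2000.0, 2000.0, 2000.0]}, blank_area=0.0)
    q = quantify_table(table, istd)
    report = apply_qc(table, q, meta, FilterConfig())
    assert report.decisions.loc["PC 34:1", "G"] == "kept"
    assert np.isinf(report.species.loc["PC 34:1", "blank_ratio_G"])


def test_filter_monotonicity(preset_cfg, preset_sim):
    """Raising the area floor or blank ratio never grows the kept set;
    raising the CV ceiling never shrinks it."""
    corrected = correct_s1p_interference(preset_sim.areas)
    quant = quantify_table(corrected, preset_sim.istd_map)
    ov = preset_cfg.override_species

    def kept(cfg):
        rep = apply_qc(corrected, quant, preset_sim.metadata, cfg)
        return {
            g: set(rep.reporting_species[g]) for g in rep.decisions.columns
        }

    base = kept(FilterConfig(override_species=ov))
    stricter_area = kept(FilterConfig(area_floor=5000.0, override_species=ov))
    stricter_blank = kept(FilterConfig(blank_ratio_min=50.0, override_species=ov))
    looser_cv = kept(FilterConfig(cv_max_pct=60.0, override_species=ov))
    for g in base:
        assert stricter_area[g] <= base[g]
        assert stricter_blank[g] <= base[g]
        assert looser_cv[g] >= base[g]


def test_decisions_partition_and_final_set(preset_result):
    dec = preset_result.qc_report.decisions
    assert dec.notna().all().all()
    kept = dec.isin(["kept", "kept_by_override"])
    final = set(preset_result.final_species)
    assert final == set(dec.index[kept.all(axis=1)])
    # final species have finite concentrations in every study sample
    assert np.isfinite(preset_result.combined_matrix.to_numpy()).all()


def test_panel_median_cv_near_design(preset_result):
    """Panel median CVs over kept species should sit near the generator's
    panel technical CVs (PQC pools carry technical noise only)."""
    pm = preset_result.qc_report.panel_median_cv
    design = {"PL_CE_DG": 5.0, "SPHINGO": 11.5, "S1P": 10.0, "TG": 18.0}
    for panel, cv in design.items():
        for g in pm.columns:
            assert pm.loc[panel, g] == pytest.approx(cv, rel=0.5)
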