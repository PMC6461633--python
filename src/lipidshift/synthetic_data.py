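"""Seeded generator of complete synthetic targeted-lipidomics experiments.

The generator emulates the statistical structure the analysis pipeline
assumes: two independent experimental arms (8 subjects treated short-term
with prednisolone, 6 treated long-term with tetracosactide, about one
third female), paired before/after plasma sampling, per-arm pooled process
QC (PQC) samples and extraction blanks, four analytical panels, ~260 lipid
species across 20 classes, lognormal biological abundances,
class/species-specific treatment effect multipliers, panel-specific
technical noise, blank background signal, and M+2 isotope cross-talk from
S1P d18:1 into S1P d18:0 (which the pipeline must remove).

The output is the same long-format peak-area table, metadata table and
ISTD map the pipeline reads, plus a ground-truth record kept separate so
tests never leak truth into pipeline inputs.  Identical configs (seed
included) reproduce the tables exactly; different seeds share the catalog
but draw fresh noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .nomenclature import parse_lipid_name, saturation_group, SaturationGroup
from .quantify import isotope_m2_fraction

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "SimulatedExperiment",
    "build_catalog",
    "simulate_experiment",
    "preset_glucocorticoid_study",
]


class SimulationError(ValueError):
    pass


PANEL_OF_CLASS: Dict[str, str] = {
    "Cer": "SPHINGO", "Hex1Cer": "SPHINGO", "Hex2Cer": "SPHINGO",
    "GM3": "SPHINGO", "SM": "SPHINGO", "S1P": "S1P", "TG": "TG",
    "LPC": "PL_CE_DG", "LPC-O": "PL_CE_DG", "PC": "PL_CE_DG", "PC-O": "PL_CE_DG",
    "PC-P": "PL_CE_DG", "LPE": "PL_CE_DG", "PE": "PL_CE_DG", "PE-O": "PL_CE_DG",
    "PE-P": "PL_CE_DG", "PI": "PL_CE_DG", "PS": "PL_CE_DG", "DG": "PL_CE_DG",
    "CE": "PL_CE_DG",
}

#: Rough per-class plasma abundance scales (µmol/L).  Order-of-magnitude
#: placeholders; every pipeline statistic is ratio- or CV-based, so the
#: absolute scale only needs to clear the raw-area floor comfortably.
ABUNDANCE_SCALE_UMOL: Dict[str, float] = {
    "Cer": 2.0, "Hex1Cer": 1.0, "Hex2Cer": 0.5, "GM3": 0.8, "SM": 20.0,
    "S1P": 0.3, "LPC": 30.0, "LPC-O": 1.0, "PC": 100.0, "PC-O": 5.0,
    "PC-P": 3.0, "LPE": 2.0, "PE": 10.0, "PE-O": 1.0, "PE-P": 3.0,
    "PI": 10.0, "PS": 0.5, "DG": 3.0, "TG": 30.0, "CE": 80.0,
}

DEFAULT_SPECIES_PER_CLASS: Dict[str, int] = {
    "Cer": 16, "Hex1Cer": 10, "Hex2Cer": 6, "GM3": 4, "SM": 24, "S1P": 4,
    "LPC": 21, "LPC-O": 5, "PC": 40, "PC-O": 15, "PC-P": 12,
    "LPE": 6, "PE": 15, "PE-O": 1, "PE-P": 9, "PI": 12, "PS": 1,
    "DG": 8, "TG": 34, "CE": 20,
}

#: Panel-wide technical CVs (%) of normalised areas, chosen so that each
#: panel's median per-species PQC CV lands near values typical for these
#: assay types (phospholipid/CE/DG tightest, SIM-mode TG loosest).
DEFAULT_TECHNICAL_CV_PCT: Dict[str, float] = {
    "PL_CE_DG": 5.0, "SPHINGO": 11.5, "S1P": 10.0, "TG": 18.0,
}

DEFAULT_ISTD_AREA_MEAN: Dict[str, float] = {
    "PL_CE_DG": 2.0e5, "SPHINGO": 1.5e5, "S1P": 1.0e5, "TG": 8.0e4,
}


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    n_female: int
    subject_prefix: str

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SimulationError(f"group {self.label!r}: need >= 2 subjects")
        if not 0 <= self.n_female <= self.n_subjects:
            raise SimulationError(f"group {self.label!r}: invalid n_female")


def _default_groups() -> Tuple[GroupSpec, ...]:
    return (
        GroupSpec("prednisolone", 8, 3, "P"),
        GroupSpec("tetracosactide", 6, 2, "T"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults encode the study design."""

    seed: int = 0
    groups: Tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    species_per_class: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_PER_CLASS)
    )
    abundance_scale_umol: Dict[str, float] = field(
        default_factory=lambda: dict(ABUNDANCE_SCALE_UMOL)
    )
    abundance_spread_log10_sd: float = 0.5
    biological_cv_pct: float = 35.0       # between-subject baseline spread
    within_subject_cv_pct: float = 20.0   # residual before/after variation
    technical_cv_pct: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TECHNICAL_CV_PCT)
    )
    injection_cv_pct: float = 8.0         # per sample x panel, cancels via ISTD
    istd_area_mean: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISTD_AREA_MEAN)
    )
    istd_conc_umol: float = 1.0
    blank_fraction: float = 0.01          # blank signal as fraction of pool signal
    n_pqc_replicates: int = 8
    n_blanks: int = 3
    s1p_m2_fraction: Optional[float] = None  # None -> binomial default (18 C)
    #: multipliers applied to the after-treatment concentration; keys are
    #: resolved species name > "<class> db<=3"/"<class> db>=4" > class name.
    effect_multipliers: Dict[str, Dict[str, float]] = field(default_factory=dict)
    # planted QC failures (ground truth for filter-fidelity checks)
    planted_area_floor: Tuple[str, ...] = ()
    planted_blank_ratio: Tuple[str, ...] = ()
    planted_blank_fraction: float = 0.5
    planted_cv: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    planted_cv_pct: float = 80.0
    override_species: Tuple[str, ...] = ()
    override_cv_pct: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.seed < 0:
            raise SimulationError("seed must be non-negative")
        for name in ("biological_cv_pct", "within_subject_cv_pct", "injection_cv_pct"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0 <= self.blank_fraction < 1:
            raise SimulationError("blank_fraction must lie in [0, 1)")
        if self.n_pqc_replicates < 2:
            raise SimulationError("n_pqc_replicates must be >= 2")
        if self.n_blanks < 1:
            raise SimulationError("n_blanks must be >= 1")
        for g, mults in self.effect_multipliers.items():
            for k, m in mults.items():
                if m <= 0:
                    raise SimulationError(f"multiplier for ({g}, {k}) must be > 0")
        for cls in self.species_per_class:
            if cls not in PANEL_OF_CLASS:
                raise SimulationError(f"unknown lipid class in catalog spec: {cls!r}")


# --------------------------------------------------------------------------
# catalog construction

_SPHINGO_ACYLS = [
    (16, 0), (18, 0), (18, 1), (22, 0), (24, 0), (24, 1),
    (23, 0), (25, 0), (26, 0), (26, 1), (20, 0), (22, 1), (21, 0), (17, 0),
]


def _sphingo_names(cls: str, n: int, frac_d181: float = 0.65) -> List[str]:
    n1 = min(math.ceil(frac_d181 * n), len(_SPHINGO_ACYLS))
    names = [f"{cls} d18:1/{c}:{d}" for c, d in _SPHINGO_ACYLS[:n1]]
    names += [f"{cls} d18:2/{c}:{d}" for c, d in _SPHINGO_ACYLS[: n - n1]]
    return names[:n]


def _sum_names(cls: str, n: int, carbons: range, dbs: range) -> List[str]:
    names = [f"{cls} {c}:{d}" for c in carbons for d in dbs]
    if len(names) < n:
        raise SimulationError(f"cannot generate {n} unique {cls} names")
    return names[:n]


_EXPLICIT = {
    "GM3": ["GM3 d18:1/16:0", "GM3 d18:1/18:0", "GM3 d18:1/24:1", "GM3 d18:2/18:0"],
    "S1P": ["S1P d16:1", "S1P d18:0", "S1P d18:1", "S1P d18:2"],
    "LPC-O": ["LPC-O 16:0", "LPC-O 16:1", "LPC-O 17:0", "LPC-O 18:0", "LPC-O 18:1"],
    "LPE": ["LPE 16:0", "LPE 18:0", "LPE 18:1", "LPE 18:2", "LPE 20:4", "LPE 22:6"],
    "PE-O": ["PE-O 18:1/20:3"],
    "PE-P": [
        "PE-P 16:0/18:1", "PE-P 16:0/18:2", "PE-P 16:0/20:4", "PE-P 18:0/18:1",
        "PE-P 18:0/18:2", "PE-P 18:0/20:3", "PE-P 18:0/20:4", "PE-P 18:1/18:2",
        "PE-P 18:1/20:4",
    ],
    "PI": [
        "PI 32:0", "PI 32:1", "PI 34:1", "PI 34:2", "PI 36:1", "PI 36:2",
        "PI 36:3", "PI 36:4", "PI 38:2", "PI 38:3", "PI 38:4", "PI 38:5",
    ],
    "PS": ["PS 38:4"],
    "DG": [
        "DG 16:0_16:0", "DG 16:0_18:1", "DG 16:0_18:2", "DG 18:0_18:1",
        "DG 18:0_18:2", "DG 18:1_18:1", "DG 18:1_18:2", "DG 18:2_18:2",
    ],
    "CE": [
        "CE 14:0", "CE 15:0", "CE 16:0", "CE 16:1", "CE 17:0", "CE 17:1",
        "CE 18:0", "CE 18:1", "CE 18:2", "CE 18:3", "CE 20:3", "CE 20:4",
        "CE 20:5", "CE 22:4", "CE 22:5", "CE 22:6", "CE 24:4", "CE 22:0",
        "CE 24:0", "CE 24:1",
    ],
}


def _class_names(cls: str, n: int) -> List[str]:
    if cls in _EXPLICIT:
        pool = _EXPLICIT[cls]
        if n > len(pool):
            raise SimulationError(f"at most {len(pool)} {cls} species available")
        return pool[:n]
    if cls in ("Cer", "Hex1Cer", "Hex2Cer"):
        return _sphingo_names(cls, n)
    if cls == "SM":
        return _sum_names(cls, n, range(30, 44), range(0, 3))
    if cls == "LPC":
        return [f"LPC {c}:{d}" for c in range(14, 23) for d in range(0, min(7, max(1, c - 13)))][:n]
    if cls == "PC":
        return _sum_names(cls, n, range(30, 42, 2), range(0, 8))
    if cls == "PC-O":
        return _sum_names(cls, n, range(30, 40, 2), range(0, 3))
    if cls == "PC-P":
        return _sum_names(cls, n, range(32, 40, 2), range(0, 3))
    if cls == "PE":
        return _sum_names(cls, n, range(34, 42, 2), range(1, 5))
    if cls == "TG":
        return _sum_names(cls, n, range(44, 56, 2), range(0, 6))
    raise SimulationError(f"no name generator for class {cls!r}")


def build_catalog(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic species catalog and ISTD map.

    Returns ``(catalog, istd_map)``: the catalog has one row per analyte
    species (columns ``species``, ``lipid_class``, ``panel``, ``istd_id``);
    the ISTD map is indexed by species with ``istd_id`` and
    ``istd_conc_umol_per_l``.  One ISTD per class, spiked at a fixed molar
    concentration.  Every name round-trips through the shorthand parser.
    """
    config.validate()
    rows = []
    for cls, n in config.species_per_class.items():
        if n == 0:
            continue
        names = _class_names(cls, n)
        if len(set(names)) != len(names):
            raise SimulationError(f"duplicate generated names in class {cls}")
        for name in names:
            parsed = parse_lipid_name(name)  # raises on malformed output
            rows.append(
                {
                    "species": parsed.raw_name,
                    "lipid_class": cls,
                    "panel": PANEL_OF_CLASS[cls],
                    "istd_id": f"ISTD {cls}",
                }
            )
    catalog = pd.DataFrame(rows)
    if catalog["species"].duplicated().any():
        raise SimulationError("duplicate species names across classes")
    istd_map = catalog.set_index("species")[["istd_id"]].copy()
    istd_map["istd_conc_umol_per_l"] = config.istd_conc_umol
    return catalog, istd_map


# --------------------------------------------------------------------------
# experiment simulation

def _sigma_from_cv(cv_pct: float) -> float:
    """Lognormal sigma with the requested CV: CV^2 = exp(sigma^2) - 1."""
    cv = cv_pct / 100.0
    return math.sqrt(math.log1p(cv * cv))


def _lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-1 lognormal noise (mu = -sigma^2/2)."""
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def resolve_multiplier(
    multipliers: Dict[str, float], species: str, cutoff_low: int = 3, cutoff_high: int = 4
) -> float:
    """Effect multiplier for one species: exact name, then double-bond
    stratified class key, then class key, else 1."""
    if species in multipliers:
        return multipliers[species]
    parsed = parse_lipid_name(species)
    stratum = saturation_group(parsed, cutoff_low, cutoff_high)
    db_key = (
        f"{parsed.lipid_class} db<={cutoff_low}"
        if stratum is SaturationGroup.LE3
        else f"{parsed.lipid_class} db>={cutoff_high}"
    )
    if db_key in multipliers:
        return multipliers[db_key]
    return multipliers.get(parsed.lipid_class, 1.0)


@dataclass
class SimulatedExperiment:
    areas: pd.DataFrame      # long format: sample_id, species, panel, area, is_istd
    metadata: pd.DataFrame   # sample_id, subject_id, group, timepoint, role, sex
    istd_map: pd.DataFrame
    catalog: pd.DataFrame
    ground_truth: dict


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a full two-arm experiment from a validated config.

    Concentrations are lognormal around per-class scales, with
    between-subject and residual within-subject biological variation;
    effect multipliers act on the after-treatment samples only.  PQC pools
    are formed on the concentration scale as the arithmetic mean of all of
    a group's study samples (equal-volume pooling of plasma), then re-measured
    with fresh technical noise per injection replicate.  Blanks carry a
    configurable fraction of the pool signal.  S1P d18:0 areas receive the
    configured M+2 cross-talk from S1P d18:1 so the pipeline has something
    to correct.
    """
    config.validate()
    catalog, istd_map = build_catalog(config)
    rng = np.random.default_rng(config.seed)
    species = catalog["species"].to_numpy()
    classes = catalog["lipid_class"].to_numpy()
    panels = catalog["panel"].to_numpy()
    S = len(species)

    m2 = (
        config.s1p_m2_fraction
        if config.s1p_m2_fraction is not None
        else isotope_m2_fraction(18)
    )

    # species baselines are a property of the analyte, shared by both arms
    scale = np.array([config.abundance_scale_umol[c] for c in classes])
    spread = 10.0 ** rng.normal(0.0, config.abundance_spread_log10_sd, S)
    base = scale * spread
    floor_idx = np.isin(species, config.planted_area_floor)
    if floor_idx.any():
        # force raw PQC areas well below the area floor (~100 counts)
        istd_mean = np.array([config.istd_area_mean[p] for p in panels])
        base[floor_idx] = 100.0 * config.istd_conc_umol / istd_mean[floor_idx]

    blank_frac = np.full(S, config.blank_fraction)
    blank_frac[np.isin(species, config.planted_blank_ratio)] = config.planted_blank_fraction

    sigma_bio = _sigma_from_cv(config.biological_cv_pct)
    sigma_within = _sigma_from_cv(config.within_subject_cv_pct)
    sigma_inj = _sigma_from_cv(config.injection_cv_pct)

    istd_mean_by_panel = {p: config.istd_area_mean[p] for p in set(panels)}
    class_of_istd = catalog.drop_duplicates("lipid_class").set_index("lipid_class")["panel"]

    area_rows: List[pd.DataFrame] = []
    meta_rows: List[dict] = []
    truth_mult: Dict[str, Dict[str, float]] = {}
    panel_list = sorted(set(panels))

    def emit_sample(sample_id: str, group: str, conc: np.ndarray, tech_sigma: np.ndarray) -> None:
        inj = {p: float(_lognormal(rng, sigma_inj, ())) for p in panel_list}
        inj_per_species = np.array([inj[p] for p in panels])
        istd_area_base = np.array([istd_mean_by_panel[p] for p in panels])
        noise = np.exp(rng.normal(-0.5 * tech_sigma**2, tech_sigma))
        areas = conc / config.istd_conc_umol * istd_area_base * inj_per_species * noise
        # S1P M+2 cross-talk: d18:1 leaks into d18:0 two mass units up
        s_i = np.nonzero(species == "S1P d18:1")[0]
        s_t = np.nonzero(species == "S1P d18:0")[0]
        if s_i.size and s_t.size:
            areas[s_t[0]] += m2 * areas[s_i[0]]
        frame = pd.DataFrame(
            {
                "sample_id": sample_id,
                "species": species,
                "panel": panels,
                "area": areas,
                "is_istd": False,
            }
        )
        istd_frame = pd.DataFrame(
            {
                "sample_id": sample_id,
                "species": [f"ISTD {c}" for c in class_of_istd.index],
                "panel": class_of_istd.to_numpy(),
                "area": [
                    istd_mean_by_panel[p] * inj[p] for p in class_of_istd.to_numpy()
                ],
                "is_istd": True,
            }
        )
        area_rows.append(frame)
        area_rows.append(istd_frame)

    truth_planted: Dict[str, Dict[str, str]] = {}
    for grp in config.groups:
        g = grp.label
        mults_cfg = config.effect_multipliers.get(g, {})
        mult = np.array([resolve_multiplier(mults_cfg, s) for s in species])
        truth_mult[g] = {s: float(m) for s, m in zip(species, mult) if m != 1.0}

        tech_sigma = np.array(
            [_sigma_from_cv(config.technical_cv_pct[p]) for p in panels]
        )
        planted_cv = np.isin(species, config.planted_cv.get(g, ()))
        tech_sigma[planted_cv] = _sigma_from_cv(config.planted_cv_pct)
        if g in config.override_cv_pct:
            ov = np.isin(species, config.override_species)
            tech_sigma[ov] = _sigma_from_cv(config.override_cv_pct[g])

        subjects = [f"{grp.subject_prefix}{i + 1}" for i in range(grp.n_subjects)]
        sexes = ["M"] * (grp.n_subjects - grp.n_female) + ["F"] * grp.n_female

        offsets = _lognormal(rng, sigma_bio, (grp.n_subjects, S))
        eps_before = _lognormal(rng, sigma_within, (grp.n_subjects, S))
        eps_after = _lognormal(rng, sigma_within, (grp.n_subjects, S))
        conc_before = base * offsets * eps_before
        conc_after = base * offsets * eps_after * mult

        for i, subj in enumerate(subjects):
            for tp, conc in (("before", conc_before[i]), ("after", conc_after[i])):
                sid = f"{subj}_{tp}"
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subj,
                        "group": g,
                        "timepoint": tp,
                        "role": "study",
                        "sex": sexes[i],
                    }
                )
                emit_sample(sid, g, conc, tech_sigma)

        pool = np.concatenate([conc_before, conc_after]).mean(axis=0)
        for j in range(config.n_pqc_replicates):
            sid = f"{g}_PQC{j + 1}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": "",
                    "group": g,
                    "timepoint": "",
                    "role": "PQC",
                    "sex": "",
                }
            )
            emit_sample(sid, g, pool, tech_sigma)

        blank_conc = blank_frac * pool
        for j in range(config.n_blanks):
            sid = f"{g}_BLANK{j + 1}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": "",
                    "group": g,
                    "timepoint": "",
                    "role": "blank",
                    "sex": "",
                }
            )
            emit_sample(sid, g, blank_conc, tech_sigma)

        planted_g = {}
        for s in config.planted_area_floor:
            planted_g[s] = "excluded_area_floor"
        for s in config.planted_blank_ratio:
            planted_g[s] = "excluded_blank_ratio"
        for s in config.planted_cv.get(g, ()):
            planted_g[s] = "excluded_cv"
        # a high CV planted in any arm excludes the species from both
        for other in config.planted_cv:
            if other != g:
                for s in config.planted_cv[other]:
                    planted_g.setdefault(s, "excluded_cv")
        truth_planted[g] = planted_g

    areas = pd.concat(area_rows, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    ground_truth = {
        "seed": config.seed,
        "multipliers": truth_mult,
        "planted_decisions": truth_planted,
        "planted_area_floor": list(config.planted_area_floor),
        "planted_blank_ratio": list(config.planted_blank_ratio),
        "planted_cv": {g: list(v) for g, v in config.planted_cv.items()},
        "override_species": list(config.override_species),
        "s1p_m2_fraction": float(m2),
        "species_base_umol": {s: float(b) for s, b in zip(species, base)},
        "n_catalog_species": int(S),
    }
    return SimulatedExperiment(
        areas=areas,
        metadata=metadata,
        istd_map=istd_map,
        catalog=catalog,
        ground_truth=ground_truth,
    )


def preset_glucocorticoid_study(seed: int = 0) -> SimulationConfig:
    """Config encoding the headline effect pattern of glucocorticoid excess.

    Short-term prednisolone: Hex1Cer up ~2x, PI down ~2.2x, the four major
    S1P species up ~1.5x, plus single-species effects (e.g. a strongly
    increased Cer d18:2/18:0).  Long-term tetracosactide: Hex1Cer up,
    ether/plasmalogen PC and lyso-PAF down ~2x, TG up ~4x, S1P d16:1 down
    ~2x, and a saturation shift in acyl PC/PE/PI — polyunsaturated (>= 4
    double bonds) species down, (<= 3) species up.  Nine QC failures are
    planted (3 area-floor, 2 blank-ratio, 4 high-CV) together with the two
    high-CV override species retained for cross-group comparability.
    """
    base_cfg = SimulationConfig(seed=seed)
    catalog, _ = build_catalog(base_cfg)
    by_class = {
        c: list(catalog.loc[catalog["lipid_class"] == c, "species"])
        for c in catalog["lipid_class"].unique()
    }
    effect = {
        "prednisolone": {
            "Hex1Cer": 2.0,
            "PI": 0.45,
            "S1P": 1.5,
            "Cer d18:2/18:0": 2.7,
            "GM3 d18:2/18:0": 0.6,
        },
        "tetracosactide": {
            "Hex1Cer": 2.0,
            "PC-O": 0.45,
            "PC-P": 0.45,
            "LPC-O": 0.5,
            "TG": 4.0,
            "S1P d16:1": 0.48,
            "Cer d18:1/18:0": 3.3,
            "DG 18:0_18:2": 4.4,
            "GM3 d18:1/18:0": 0.45,
            "GM3 d18:2/18:0": 0.26,
            "PC db<=3": 1.6,
            "PC db>=4": 0.55,
            "PE db<=3": 1.4,
            "PE db>=4": 0.6,
            "PI db<=3": 1.5,
            "PI db>=4": 0.55,
        },
    }
    planted_area_floor = (by_class["SM"][-1], by_class["LPC"][-1], by_class["TG"][-1])
    planted_blank_ratio = (by_class["CE"][-1], by_class["PE"][-1])
    planted_cv = {
        "prednisolone": (by_class["PC"][-1], by_class["PC-O"][-1]),
        "tetracosactide": (by_class["DG"][0], by_class["Hex2Cer"][-1]),
    }
    # planted QC failures stay effect-neutral so the planted decision is
    # determined by the QC rule alone, not by treatment shifts
    planted_all = planted_area_floor + planted_blank_ratio + sum(planted_cv.values(), ())
    for mults in effect.values():
        for s in planted_all:
            mults[s] = 1.0
    return replace(
        base_cfg,
        effect_multipliers=effect,
        planted_area_floor=planted_area_floor,
        planted_blank_ratio=planted_blank_ratio,
        planted_cv=planted_cv,
        override_species=("Cer d18:1/18:0", "Hex1Cer d18:1/24:1"),
        override_cv_pct={"tetracosactide": 40.0},
    )
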