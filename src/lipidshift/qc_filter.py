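"""Species-exclusion cascade driven by pooled-QC and blank samples.

A species is retained in an experimental group only if

1. its median raw peak area over the group's PQC samples is at least the
   area floor (default 250 counts),
2. that median is at least ``blank_ratio_min`` (default 5) times the median
   blank area, and
3. its percent CV of the normalised peak area across PQC replicates does
   not exceed ``cv_max_pct`` (default 25%) in *any* group — except for
   explicitly listed override species, which are retained despite a high CV
   in one group so both groups stay comparable.

Rules 1-2 are evaluated on raw areas, rule 3 on ISTD-normalised areas.
The final cross-group dataset comprises species kept in every group with a
finite value in every sample; species kept in only one group remain in that
group's reporting set (mirroring analytes that are not quantifiable, "NQ",
in the other arm).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .quantify import Quantification

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "QCError",
    "QCReport",
    "pqc_cv",
    "area_blank_filter",
    "cv_filter",
    "apply_qc",
    "finalize_dataset",
    "panel_median_cv",
]

DECISIONS = (
    "kept",
    "kept_by_override",
    "excluded_area_floor",
    "excluded_blank_ratio",
    "excluded_cv",
    "excluded_missing",
)


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    area_floor: float = 250.0
    blank_ratio_min: float = 5.0
    cv_max_pct: float = 25.0
    override_species: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("area_floor", "blank_ratio_min", "cv_max_pct"):
            if getattr(self, name) <= 0:
                raise QCError(f"{name} must be positive")


def pqc_cv(normalized_areas: Sequence[float]) -> float:
    """Percent CV (sample sd / mean x 100) of PQC replicate values.

    Returns NaN when the mean is non-positive (the species is then flagged
    ``excluded_missing`` by the caller); requires at least two replicates.
    """
    x = np.asarray(normalized_areas, dtype=float)
    if x.size < 2:
        raise QCError(f"need >= 2 PQC replicates, got {x.size}")
    m = x.mean()
    if not np.isfinite(m) or m <= 0:
        return float("nan")
    return 100.0 * x.std(ddof=1) / m


def area_blank_filter(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    config: FilterConfig,
    group: str,
) -> pd.DataFrame:
    """Evaluate the raw-area floor and blank-ratio rules for one group.

    Returns a per-species frame with ``median_pqc_area``,
    ``median_blank_area``, ``blank_ratio`` (+inf when the blank median is
    zero: absent background cannot justify exclusion) and the first-failing
    ``reason`` among ``area_floor``/``blank_ratio`` (empty string = pass).
    """
    meta = metadata.set_index("sample_id")
    roles = meta.loc[meta["group"] == group, "role"]
    pqc_samples = roles.index[roles == "PQC"]
    blank_samples = roles.index[roles == "blank"]
    if len(pqc_samples) == 0:
        raise QCError(f"group {group!r} has no PQC samples")
    if len(blank_samples) == 0:
        raise QCError(f"group {group!r} has no blank samples")

    analytes = table.loc[~table.get("is_istd", pd.Series(False, index=table.index)).astype(bool)]
    wide = analytes.pivot(index="sample_id", columns="species", values="area")
    med_pqc = wide.reindex(pqc_samples).median(axis=0)
    med_blank = wide.reindex(blank_samples).median(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = med_pqc / med_blank
    ratio = ratio.where(med_blank > 0, np.inf)

    reason = pd.Series("", index=wide.columns, dtype=object)
    reason[med_pqc < config.area_floor] = "area_floor"
    fail_blank = (ratio < config.blank_ratio_min) & (reason == "")
    reason[fail_blank] = "blank_ratio"
    return pd.DataFrame(
        {
            "median_pqc_area": med_pqc,
            "median_blank_area": med_blank,
            "blank_ratio": ratio,
            "reason": reason,
        }
    )


def cv_filter(cv_by_group: pd.DataFrame, config: FilterConfig) -> pd.Series:
    """Cross-group CV decision per species.

    ``cv_by_group`` holds one column per group of %CVs (NaN = not
    estimable).  A species fails if its CV is *strictly* above
    ``cv_max_pct`` in at least one group; override species are retained
    with decision ``kept_by_override``.  A species with no estimable CV in
    any group is ``excluded_missing``.
    """
    decisions = pd.Series("kept", index=cv_by_group.index, dtype=object)
    all_nan = cv_by_group.isna().all(axis=1)
    fails = (cv_by_group > config.cv_max_pct).any(axis=1)
    override = cv_by_group.index.isin(config.override_species)
    decisions[fails & override] = "kept_by_override"
    decisions[fails & ~override] = "excluded_cv"
    decisions[all_nan] = "excluded_missing"
    return decisions


@dataclass
class QCReport:
    """Per-species filter decisions, CVs and per-panel median %CV summaries."""

    species: pd.DataFrame          # per species: panel + per-group metrics
    decisions: pd.DataFrame        # species x group decision labels
    reasons: pd.DataFrame          # species x group free-text reasons
    cv_by_group: pd.DataFrame      # species x group %CV of normalised areas
    panel_median_cv: pd.DataFrame  # panel x group median %CV over kept species
    final_species: List[str]
    reporting_species: Dict[str, List[str]]
    config: FilterConfig = field(default_factory=FilterConfig)

    def to_tsv(self, path) -> None:
        out = self.species.copy()
        for g in self.decisions.columns:
            out[f"decision_{g}"] = self.decisions[g]
            out[f"reason_{g}"] = self.reasons[g]
        out.insert(0, "final_kept", out.index.isin(self.final_species))
        out.to_csv(path, sep="\t", index_label="species")

    def summary(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_final_species": len(self.final_species),
            "n_reporting_species": {g: len(v) for g, v in self.reporting_species.items()},
            "decision_counts": {
                g: self.decisions[g].value_counts().to_dict() for g in self.decisions.columns
            },
            "panel_median_cv_pct": {
                g: self.panel_median_cv[g].round(2).dropna().to_dict()
                for g in self.panel_median_cv.columns
            },
            "override_species": list(self.config.override_species),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _group_samples(metadata: pd.DataFrame, group: str, role: str) -> pd.Index:
    m = metadata
    return pd.Index(m.loc[(m["group"] == group) & (m["role"] == role), "sample_id"])


def apply_qc(
    table: pd.DataFrame,
    quant: Quantification,
    metadata: pd.DataFrame,
    config: FilterConfig | None = None,
) -> QCReport:
    """Run the full exclusion cascade over every group and species.

    Per group and species the recorded decision is the first failing rule
    in the order missing -> area floor -> blank ratio -> CV; the kept /
    excluded outcome is independent of that ordering (the rules are
    conjunctive).
    """
    config = config or FilterConfig()
    groups = list(pd.unique(metadata["group"].dropna()))
    species = list(quant.concentration.columns)

    cv_by_group = pd.DataFrame(index=pd.Index(species, name="species"), columns=groups, dtype=float)
    per_group_ab: Dict[str, pd.DataFrame] = {}
    missing_by_group: Dict[str, pd.Series] = {}

    for g in groups:
        pqcs = _group_samples(metadata, g, "PQC")
        if len(pqcs) < 2:
            raise QCError(f"group {g!r} needs >= 2 PQC replicates to estimate CVs")
        pqc_norm = quant.normalized.reindex(pqcs)
        means = pqc_norm.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cvs = 100.0 * pqc_norm.std(axis=0, ddof=1) / means
        cv_by_group[g] = cvs.where(means > 0)
        per_group_ab[g] = area_blank_filter(table, metadata, config, g)
        study = _group_samples(metadata, g, "study")
        vals = quant.concentration.reindex(study)
        missing_by_group[g] = ~np.isfinite(vals).all(axis=0)

    cv_decisions = cv_filter(cv_by_group, config)

    decisions = pd.DataFrame(index=species, columns=groups, dtype=object)
    reasons = pd.DataFrame("", index=species, columns=groups, dtype=object)
    for g in groups:
        ab = per_group_ab[g].reindex(species)
        for s in species:
            if missing_by_group[g].get(s, True):
                decisions.loc[s, g] = "excluded_missing"
                reasons.loc[s, g] = "not quantified in all study samples"
            elif ab.loc[s, "reason"] == "area_floor":
                decisions.loc[s, g] = "excluded_area_floor"
                reasons.loc[s, g] = (
                    f"median PQC area {ab.loc[s, 'median_pqc_area']:.0f} < {config.area_floor:.0f}"
                )
            elif ab.loc[s, "reason"] == "blank_ratio":
                decisions.loc[s, g] = "excluded_blank_ratio"
                reasons.loc[s, g] = (
                    f"PQC/blank ratio {ab.loc[s, 'blank_ratio']:.1f} < {config.blank_ratio_min:.0f}"
                )
            elif cv_decisions[s] == "excluded_missing" or not np.isfinite(cv_by_group.loc[s, g]):
                decisions.loc[s, g] = "excluded_missing"
                reasons.loc[s, g] = "PQC CV not estimable"
            elif cv_decisions[s] == "excluded_cv":
                decisions.loc[s, g] = "excluded_cv"
                worst = cv_by_group.loc[s].max()
                reasons.loc[s, g] = f"CV {worst:.1f}% > {config.cv_max_pct:.0f}% in >=1 group"
            elif cv_decisions[s] == "kept_by_override":
                decisions.loc[s, g] = "kept_by_override"
                reasons.loc[s, g] = "override: retained for cross-group comparability"
            else:
                decisions.loc[s, g] = "kept"

    species_frame = pd.DataFrame({"panel": quant.panels.reindex(species)})
    for g in groups:
        ab = per_group_ab[g].reindex(species)
        species_frame[f"median_pqc_area_{g}"] = ab["median_pqc_area"]
        species_frame[f"median_blank_area_{g}"] = ab["median_blank_area"]
        species_frame[f"blank_ratio_{g}"] = ab["blank_ratio"]
        species_frame[f"cv_pct_{g}"] = cv_by_group[g]

    kept_mask = decisions.isin(["kept", "kept_by_override"])
    reporting = {g: [s for s in species if kept_mask.loc[s, g]] for g in groups}
    final = [s for s in species if kept_mask.loc[s].all()]
    if not final:
        raise QCError("no species survives the QC cascade in all groups")

    pm = panel_median_cv(species_frame["panel"], cv_by_group, kept_mask)
    return QCReport(
        species=species_frame,
        decisions=decisions,
        reasons=reasons,
        cv_by_group=cv_by_group,
        panel_median_cv=pm,
        final_species=final,
        reporting_species=reporting,
        config=config,
    )


def panel_median_cv(
    panels: pd.Series, cv_by_group: pd.DataFrame, kept_mask: pd.DataFrame
) -> pd.DataFrame:
    """Median %CV over kept species, per panel and group."""
    rows = {}
    for panel in pd.unique(panels.dropna()):
        in_panel = panels == panel
        rows[panel] = {}
        for g in cv_by_group.columns:
            kept = in_panel & kept_mask[g]
            if not kept.any():
                logger.warning("panel %s has no kept species in group %s", panel, g)
                rows[panel][g] = np.nan
            else:
                rows[panel][g] = float(cv_by_group.loc[kept, g].median())
    return pd.DataFrame(rows).T.rename_axis("panel")


def finalize_dataset(
    report: QCReport, quant: Quantification, metadata: pd.DataFrame
) -> Tuple[List[str], Dict[str, pd.DataFrame], pd.DataFrame]:
    """Assemble the filtered concentration matrices.

    Returns the cross-group final species list, per-group study-sample
    matrices restricted to each group's reporting set, and the combined
    study matrix over the final species.
    """
    groups = list(report.decisions.columns)
    per_group = {}
    for g in groups:
        study = _group_samples(metadata, g, "study")
        per_group[g] = quant.concentration.reindex(index=study, columns=report.reporting_species[g])
    all_study = metadata.loc[metadata["role"] == "study", "sample_id"]
    combined = quant.concentration.reindex(index=all_study, columns=report.final_species)
    return report.final_species, per_group, combined
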