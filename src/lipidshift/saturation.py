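"""Double-bond saturation-class aggregation and tests.

Within a lipid class (acyl PC, PE or PI by default) species are stratified
by total double bonds into a low-unsaturation stratum (<= 3) and a
polyunsaturated stratum (>= 4).  Per sample the two strata are summed to
total concentrations; the analysis then asks whether treatment shifts the
class composition towards saturation:

* paired t-tests on log-transformed stratum totals (before vs after),
* a paired t-test on log(GE4/LE3) — the composition ratio, insensitive to
  overall dilution of a subject's plasma,
* a two-sample Welch t-test comparing the per-species mean log2 fold
  changes between the two strata (species are the units; there is no
  pairing across strata).

Ether (-O) and plasmalogen (-P) subclasses and lyso forms carry their own
class tokens and are therefore never absorbed into the acyl-class totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import StatsError, log2fc_matrix, paired_t_log2
from .nomenclature import SaturationGroup, parse_lipid_name, saturation_group

logger = logging.getLogger(__name__)

__all__ = ["SaturationSummary", "class_db_totals", "saturation_tests", "saturation_analysis"]

DEFAULT_CLASSES = ("PC", "PE", "PI")


def class_db_totals(
    matrix: pd.DataFrame,
    lipid_class: str,
    cutoff_low: int = 3,
    cutoff_high: int = 4,
) -> pd.DataFrame:
    """Per-sample total concentration of a class, split by double-bond stratum.

    Returns a frame indexed like ``matrix`` with columns ``total_le3`` and
    ``total_ge4``.  Class membership is exact token equality, so PC-O/PC-P
    (and LPC) species never contribute to the acyl PC totals.
    """
    parsed = {s: parse_lipid_name(s) for s in matrix.columns}
    members = [s for s, p in parsed.items() if p.lipid_class == lipid_class]
    if not members:
        raise StatsError(f"no species of class {lipid_class!r} in matrix")
    strata = {
        s: saturation_group(parsed[s], cutoff_low, cutoff_high) for s in members
    }
    le3 = [s for s in members if strata[s] is SaturationGroup.LE3]
    ge4 = [s for s in members if strata[s] is SaturationGroup.GE4]
    for name, stratum in (("<=%d" % cutoff_low, le3), (">=%d" % cutoff_high, ge4)):
        if not stratum:
            logger.warning("class %s has no species in the %s stratum", lipid_class, name)
    out = pd.DataFrame(
        {
            "total_le3": matrix[le3].sum(axis=1) if le3 else 0.0,
            "total_ge4": matrix[ge4].sum(axis=1) if ge4 else 0.0,
        },
        index=matrix.index,
    )
    out.attrs["species_le3"] = le3
    out.attrs["species_ge4"] = ge4
    return out


@dataclass
class SaturationSummary:
    lipid_class: str
    group: str
    totals: pd.DataFrame  # per subject: before/after totals and ratios
    p_total_le3: float
    p_total_ge4: float
    p_ratio: float
    p_fc_contrast: float
    species_le3: list = field(default_factory=list)
    species_ge4: list = field(default_factory=list)

    def p_values(self) -> dict:
        return {
            "p_total_le3": self.p_total_le3,
            "p_total_ge4": self.p_total_ge4,
            "p_ratio": self.p_ratio,
            "p_fc_contrast": self.p_fc_contrast,
        }


def saturation_tests(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    lipid_class: str,
    drop_subjects: Sequence[str] = (),
    cutoff_low: int = 3,
    cutoff_high: int = 4,
    welch: bool = True,
) -> SaturationSummary:
    """Stratified totals and the four saturation p-values for one class/group."""
    totals = class_db_totals(matrix, lipid_class, cutoff_low, cutoff_high)
    le3, ge4 = totals.attrs["species_le3"], totals.attrs["species_ge4"]

    meta = metadata.loc[(metadata["group"] == group) & (metadata["role"] == "study")]
    subjects = [s for s in pd.unique(meta["subject_id"]) if s not in set(drop_subjects)]
    pairs = {}
    for subj in subjects:
        sub = meta.loc[meta["subject_id"] == subj].set_index("timepoint")["sample_id"]
        pairs[subj] = (sub["before"], sub["after"])

    rows = []
    for subj, (sb, sa) in pairs.items():
        for tp, sample in (("before", sb), ("after", sa)):
            t = totals.loc[sample]
            ratio = t["total_ge4"] / t["total_le3"] if t["total_le3"] > 0 else np.nan
            rows.append(
                {
                    "subject_id": subj,
                    "timepoint": tp,
                    "total_le3": t["total_le3"],
                    "total_ge4": t["total_ge4"],
                    "ratio_ge4_over_le3": ratio,
                }
            )
    tot = pd.DataFrame(rows)

    def _paired_p(column: str) -> float:
        wide = tot.pivot(index="subject_id", columns="timepoint", values=column)
        b, a = wide["before"].to_numpy(), wide["after"].to_numpy()
        if (b <= 0).any() or (a <= 0).any() or np.isnan(b).any() or np.isnan(a).any():
            return float("nan")
        return paired_t_log2(b, a)[2]

    p_le3 = _paired_p("total_le3") if le3 else float("nan")
    p_ge4 = _paired_p("total_ge4") if ge4 else float("nan")
    p_ratio = _paired_p("ratio_ge4_over_le3") if le3 and ge4 else float("nan")

    # stratum contrast on species-level mean log2FC (unpaired across strata)
    if le3 and ge4:
        d = log2fc_matrix(matrix, metadata, group, drop_subjects)
        mean_fc = d.mean(axis=0)
        res = stats.ttest_ind(mean_fc[le3], mean_fc[ge4], equal_var=not welch)
        p_contrast = float(res.pvalue)
    else:
        p_contrast = float("nan")

    return SaturationSummary(
        lipid_class=lipid_class,
        group=group,
        totals=tot,
        p_total_le3=p_le3,
        p_total_ge4=p_ge4,
        p_ratio=p_ratio,
        p_fc_contrast=p_contrast,
        species_le3=le3,
        species_ge4=ge4,
    )


def saturation_analysis(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    classes: Sequence[str] = DEFAULT_CLASSES,
    **kwargs,
) -> Dict[str, SaturationSummary]:
    """Run :func:`saturation_tests` for each requested class."""
    return {c: saturation_tests(matrix, metadata, group, c, **kwargs) for c in classes}
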