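"""Paired before/after differential statistics.

Each subject contributes one before and one after sample; the unit of
analysis is the per-subject log2 fold change log2(after/before).  Species
are tested with a paired two-tailed t-test on log2-transformed
concentrations and corrected per treatment group with the
Benjamini-Hochberg FDR procedure.  Fold changes are displayed with the
signed convention common in lipidomics figures: a halving is shown as
-2.0, not 0.5.

The clinical-chemistry panel (cortisol, lipase, TG, ...) is summarised per
analyte with the median signed fold change across subjects and an
*unadjusted* paired-t p-value — these are single-analyte tests, not a
family.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nomenclature import parse_lipid_name

__all__ = [
    "per_subject_log2fc",
    "signed_fold_change",
    "paired_t_log2",
    "bh_fdr",
    "differential_table",
    "log2fc_matrix",
    "paired_panel_summary",
]


class StatsError(ValueError):
    pass


def per_subject_log2fc(before: float, after: float, label: str = "") -> float:
    """log2(after/before) for a single subject and analyte."""
    if before <= 0 or after <= 0:
        raise StatsError(f"non-positive paired value{f' for {label}' if label else ''}: "
                         f"before={before}, after={after}")
    return math.log2(after / before)


def signed_fold_change(mean_log2fc: float) -> float:
    """Back-transform a mean log2FC to the signed fold-change display scale.

    Increases map to 2**x (>= 1), decreases to -2**(-x) (<= -1); no change
    maps to +1.  This is the negative-reciprocal convention: -2 means the
    level halved.
    """
    if mean_log2fc >= 0:
        return 2.0 ** mean_log2fc
    return -(2.0 ** (-mean_log2fc))


def paired_t_log2(
    before: Sequence[float], after: Sequence[float]
) -> tuple[float, int, float]:
    """Paired two-tailed t-test on log2-transformed values.

    Returns ``(t, df, p)`` with ``df = n - 1``.  When the per-subject
    differences have zero variance the test statistic is undefined and
    ``(nan, df, nan)`` is returned (flagged degenerate downstream, never
    "significant").
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise StatsError("before/after must be subject-aligned and equal length")
    if b.size < 2:
        raise StatsError(f"need n >= 2 paired observations, got {b.size}")
    if (b <= 0).any() or (a <= 0).any():
        raise StatsError("paired t on log2 values requires positive data")
    d = np.log2(a) - np.log2(b)
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return float("nan"), n - 1, float("nan")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-preserving and NaN-aware.

    NaN entries (degenerate tests) are excluded from the family size m and
    returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    if defined.any():
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def _paired_matrices(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    drop_subjects: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Subject-aligned before/after concentration matrices for one group."""
    meta = metadata.loc[
        (metadata["group"] == group) & (metadata["role"] == "study")
    ]
    subjects = [s for s in pd.unique(meta["subject_id"]) if s not in set(drop_subjects)]
    rows_b, rows_a = [], []
    for subj in subjects:
        sub = meta.loc[meta["subject_id"] == subj].set_index("timepoint")["sample_id"]
        if "before" not in sub.index or "after" not in sub.index or len(sub) != 2:
            raise StatsError(f"subject {subj!r} lacks exactly one before and one after sample")
        rows_b.append(sub["before"])
        rows_a.append(sub["after"])
    before = matrix.reindex(rows_b)
    after = matrix.reindex(rows_a)
    before.index = after.index = pd.Index(subjects, name="subject_id")
    return before, after, subjects


def log2fc_matrix(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    drop_subjects: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-subject log2 fold changes (subjects x species) for one group."""
    before, after, _ = _paired_matrices(matrix, metadata, group, drop_subjects)
    if (before <= 0).any().any() or (after <= 0).any().any():
        raise StatsError("non-positive concentrations in paired data")
    return np.log2(after / before)


def differential_table(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    alpha: float = 0.05,
    fdr_scope: str = "group",
    drop_subjects: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-species paired differential results for one treatment group.

    Parameters
    ----------
    matrix
        QC-filtered concentration matrix (samples x species, all positive).
    fdr_scope
        ``"group"`` corrects across all species of the group's reporting
        set in one BH family (default); ``"class"`` runs BH within each
        lipid class separately.

    Returns a frame indexed by species with columns ``lipid_class``,
    ``mean_log2fc``, ``fold_change`` (signed), ``p_raw``, ``p_fdr``,
    ``significant`` (p_fdr <= alpha), ``sig_tier`` ("**" for p_fdr <= 0.01,
    "*" for <= 0.05) and one ``log2fc_<subject>`` column per subject.
    """
    if not 0 < alpha < 1:
        raise StatsError(f"alpha must lie in (0, 1), got {alpha}")
    if fdr_scope not in ("group", "class"):
        raise StatsError(f"unknown fdr_scope {fdr_scope!r}")

    d = log2fc_matrix(matrix, metadata, group, drop_subjects)
    n = d.shape[0]
    if n < 2:
        raise StatsError("need >= 2 subjects for the paired test")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = t.where(sd > 0)
    p_raw = pd.Series(2.0 * stats.t.sf(np.abs(t), n - 1), index=d.columns).where(sd > 0)

    classes = pd.Series(
        {s: parse_lipid_name(s).lipid_class for s in d.columns}, name="lipid_class"
    )
    if fdr_scope == "group":
        p_fdr = pd.Series(bh_fdr(p_raw.to_numpy()), index=p_raw.index)
    else:
        p_fdr = pd.Series(np.nan, index=p_raw.index)
        for _, idx in classes.groupby(classes).groups.items():
            p_fdr.loc[idx] = bh_fdr(p_raw.loc[idx].to_numpy())

    out = pd.DataFrame(
        {
            "lipid_class": classes,
            "mean_log2fc": mean,
            "fold_change": mean.map(signed_fold_change),
            "t": t,
            "p_raw": p_raw,
            "p_fdr": p_fdr,
            "significant": (p_fdr <= alpha).fillna(False),
            "sig_tier": np.select(
                [p_fdr <= 0.01, p_fdr <= alpha], ["**", "*"], default=""
            ),
        }
    )
    for subj in d.index:
        out[f"log2fc_{subj}"] = d.loc[subj]
    out.index.name = "species"
    out.attrs["group"] = group
    out.attrs["n_subjects"] = n
    return out


def paired_panel_summary(
    before: pd.DataFrame, after: pd.DataFrame
) -> pd.DataFrame:
    """Clinical-chemistry style per-analyte summary.

    ``before``/``after`` are subject-aligned frames (subjects x analytes,
    positive values).  Per analyte the per-subject fold change
    after/before is mapped to the signed display scale and the median
    across subjects is reported alongside the raw (unadjusted) paired-t
    p-value on log2 values.
    """
    if not before.index.equals(after.index) or not before.columns.equals(after.columns):
        raise StatsError("before/after frames must be aligned")
    if (before <= 0).any().any() or (after <= 0).any().any():
        raise StatsError("paired panel values must be positive")
    fc = after / before
    signed = fc.where(fc >= 1, -1.0 / fc)
    rows = {}
    for analyte in before.columns:
        _, _, p = paired_t_log2(before[analyte], after[analyte])
        rows[analyte] = {
            "median_fc_signed": float(signed[analyte].median()),
            "p_raw": p,
            "n": int(before.shape[0]),
        }
    return pd.DataFrame(rows).T.rename_axis("analyte")
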