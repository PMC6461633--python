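"""Internal-standard quantification of raw MRM peak areas.

Each analyte species is assigned one internal standard (ISTD), a spiked
non-endogenous lipid of known molar concentration measured in the same
panel and sample.  Normalised peak area = analyte area / ISTD area;
relative molar concentration = normalised area x ISTD concentration
(single-point calibration, response factor 1 — the resulting values are
relative abundances, not absolute concentrations).

The module also implements the isotope cross-talk correction needed for
sphingosine-1-phosphate: the M+2 isotopologue of S1P d18:1 co-elutes with
S1P d18:0 (two mass units heavier) and its contribution is subtracted from
the S1P d18:0 peak area before quantification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PANELS",
    "QuantificationError",
    "Quantification",
    "normalize_area",
    "to_concentration",
    "isotope_m2_fraction",
    "correct_s1p_interference",
    "quantify_table",
]

PANELS = ("PL_CE_DG", "SPHINGO", "S1P", "TG")

#: Natural abundance of 13C.
P13C_DEFAULT = 0.0107


class QuantificationError(ValueError):
    pass


def normalize_area(area: float, istd_area: float) -> float:
    """Peak area divided by the ISTD peak area of the same sample."""
    if istd_area <= 0:
        raise QuantificationError(f"non-positive ISTD area: {istd_area}")
    return area / istd_area


def to_concentration(normalized_area: float, istd_conc: float) -> float:
    """Relative molar concentration (µmol/L) from a normalised area."""
    if istd_conc <= 0:
        raise QuantificationError(f"non-positive ISTD concentration: {istd_conc}")
    return normalized_area * istd_conc


def isotope_m2_fraction(carbon_count: int, p13c: float = P13C_DEFAULT) -> float:
    """M+2/M+0 abundance ratio under a carbon-only binomial isotope model.

    The probability that exactly two of ``carbon_count`` carbons are 13C,
    relative to the all-12C probability, is C(n, 2) * (p / (1 - p))^2.
    Contributions of 2H/15N/18O are neglected; for an 18-carbon backbone the
    ratio is ~0.018.
    """
    if carbon_count < 2:
        raise QuantificationError(f"carbon_count must be >= 2, got {carbon_count}")
    if not 0.0 < p13c < 1.0:
        raise QuantificationError(f"p13c must lie in (0, 1), got {p13c}")
    odds = p13c / (1.0 - p13c)
    return math.comb(carbon_count, 2) * odds * odds


def correct_s1p_interference(
    table: pd.DataFrame,
    interferer: str = "S1P d18:1",
    target: str = "S1P d18:0",
    fraction: float | None = None,
) -> pd.DataFrame:
    """Subtract isotope cross-talk of ``interferer`` from ``target`` areas.

    Per sample: ``target_area' = max(0, target_area - fraction *
    interferer_area)``.  Negative corrected areas are clamped to zero with a
    warning (blank samples legitimately fall below the interference level).

    Parameters
    ----------
    table
        Long-format peak-area table with columns ``sample_id``, ``species``,
        ``area`` (others are carried through unchanged).
    fraction
        M+2 cross-talk fraction; ``None`` selects the carbon-only binomial
        default for the interferer's 18-carbon base.

    Returns
    -------
    A new table with corrected ``target`` areas; a per-sample correction log
    is attached under ``result.attrs["isotope_correction"]``.
    """
    if fraction is None:
        fraction = isotope_m2_fraction(18)
    if fraction < 0:
        raise QuantificationError(f"negative interference fraction: {fraction}")

    out = table.copy()
    tgt = out["species"] == target
    if fraction == 0 or not tgt.any():
        out.attrs["isotope_correction"] = pd.DataFrame(
            columns=["sample_id", "target_area", "interferer_area", "corrected_area", "clamped"]
        )
        return out

    inter = out.loc[out["species"] == interferer].set_index("sample_id")["area"]
    tgt_rows = out.loc[tgt]
    missing = set(tgt_rows["sample_id"]) - set(inter.index)
    if missing:
        raise QuantificationError(
            f"interferer {interferer!r} missing in samples containing {target!r}: "
            f"{sorted(missing)}"
        )
    inter_areas = inter.reindex(tgt_rows["sample_id"]).to_numpy()
    corrected = tgt_rows["area"].to_numpy() - fraction * inter_areas
    clamped = corrected < 0
    if clamped.any():
        logger.warning(
            "%s: corrected area clamped to 0 in %d sample(s)", target, int(clamped.sum())
        )
    log = pd.DataFrame(
        {
            "sample_id": tgt_rows["sample_id"].to_numpy(),
            "target_area": tgt_rows["area"].to_numpy(),
            "interferer_area": inter_areas,
            "corrected_area": np.maximum(corrected, 0.0),
            "clamped": clamped,
        }
    )
    out.loc[tgt, "area"] = np.maximum(corrected, 0.0)
    out.attrs["isotope_correction"] = log
    return out


@dataclass
class Quantification:
    """Wide-format quantification result (samples in rows, species in columns).

    ``normalized`` holds ISTD-normalised areas, ``concentration`` relative
    molar concentrations in µmol/L; ``panels`` maps species to their
    analytical panel.
    """

    normalized: pd.DataFrame
    concentration: pd.DataFrame
    panels: pd.Series

    def __post_init__(self) -> None:
        if not self.normalized.columns.equals(self.concentration.columns):
            raise QuantificationError("normalized/concentration column mismatch")


def quantify_table(table: pd.DataFrame, istd_map: pd.DataFrame) -> Quantification:
    """Quantify every sample (study, PQC and blank alike) against its ISTDs.

    Parameters
    ----------
    table
        Long-format areas with columns ``sample_id``, ``species``, ``panel``,
        ``area`` and ``is_istd``.  ISTD rows carry the ISTD id in the
        ``species`` column.
    istd_map
        Indexed by analyte species, columns ``istd_id`` and
        ``istd_conc_umol_per_l``.

    Notes
    -----
    Blanks are quantified with their own ISTD areas — the ISTD is spiked
    into blanks during extraction, so normalisation is well defined there.
    """
    required = {"sample_id", "species", "panel", "area"}
    if not required.issubset(table.columns):
        raise QuantificationError(f"table missing columns {required - set(table.columns)}")
    if (table["area"] < 0).any():
        bad = table.loc[table["area"] < 0]
        raise QuantificationError(f"negative peak areas for {bad['species'].unique()[:5]}")
    if table.duplicated(["sample_id", "species"]).any():
        raise QuantificationError("duplicate (sample_id, species) records")

    if "is_istd" in table.columns:
        is_istd = table["is_istd"].astype(bool)
    else:
        is_istd = table["species"].isin(set(istd_map["istd_id"]))

    analytes = table.loc[~is_istd]
    istds = table.loc[is_istd]

    unmapped = sorted(set(analytes["species"]) - set(istd_map.index))
    if unmapped:
        raise QuantificationError(f"species without ISTD mapping: {unmapped}")

    istd_areas = istds.pivot(index="sample_id", columns="species", values="area")
    if (istd_areas <= 0).any().any() or istd_areas.isna().any().any():
        bad = istd_areas.stack(future_stack=True)
        bad = bad[(bad <= 0) | bad.isna()]
        raise QuantificationError(
            "missing or non-positive ISTD areas: "
            + ", ".join(f"{s}/{i}" for s, i in bad.index[:10])
        )

    merged = analytes.merge(
        istd_map[["istd_id", "istd_conc_umol_per_l"]],
        left_on="species",
        right_index=True,
        how="left",
    )
    istd_area_per_row = istd_areas.to_numpy()[
        istd_areas.index.get_indexer(merged["sample_id"]),
        istd_areas.columns.get_indexer(merged["istd_id"]),
    ]
    merged["normalized"] = merged["area"].to_numpy() / istd_area_per_row
    merged["concentration"] = merged["normalized"] * merged["istd_conc_umol_per_l"]

    # preserve first-seen sample/species order for deterministic output
    sample_order = pd.unique(analytes["sample_id"])
    species_order = pd.unique(analytes["species"])
    normalized = (
        merged.pivot(index="sample_id", columns="species", values="normalized")
        .reindex(index=sample_order, columns=species_order)
    )
    concentration = (
        merged.pivot(index="sample_id", columns="species", values="concentration")
        .reindex(index=sample_order, columns=species_order)
    )
    panels = (
        analytes.drop_duplicates("species").set_index("species")["panel"].reindex(species_order)
    )
    return Quantification(normalized=normalized, concentration=concentration, panels=panels)
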