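"""Plain-text tabular I/O for the pipeline.

All tables are UTF-8 TSV with '.' decimal separators.  Clinical tables
exported from spreadsheets occasionally contain typographic Unicode minus
signs; these are normalised to ASCII hyphen-minus on read so numeric
parsing never silently produces NaN.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_peak_areas",
    "write_peak_areas",
    "read_metadata",
    "write_metadata",
    "read_istd_map",
    "write_istd_map",
    "write_matrix",
    "read_matrix",
    "normalize_minus_signs",
    "write_json",
    "load_yaml_config",
]

_MINUS_CHARS = {"−": "-", "‒": "-", "–": "-"}


def normalize_minus_signs(df: pd.DataFrame) -> pd.DataFrame:
    """Replace Unicode minus/figure-dash/en-dash with ASCII '-' in object columns."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object:
            s = out[col].astype(str)
            for ch, repl in _MINUS_CHARS.items():
                s = s.str.replace(ch, repl, regex=False)
            out[col] = s
    return out


def read_peak_areas(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "species", "panel", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: peak-area table missing columns {sorted(missing)}")
    if "is_istd" not in df.columns:
        df["is_istd"] = False
    df["is_istd"] = df["is_istd"].astype(bool)
    df["area"] = pd.to_numeric(df["area"])
    return df


def write_peak_areas(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"sample_id", "subject_id", "group", "timepoint", "role", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_istd_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "istd_id", "istd_conc_umol_per_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ISTD map missing columns {sorted(missing)}")
    df = df.set_index("species")
    if (df["istd_conc_umol_per_l"] <= 0).any():
        raise ValueError(f"{path}: ISTD concentrations must be positive")
    return df


def write_istd_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="species")


def write_matrix(matrix: pd.DataFrame, panels: pd.Series, path) -> None:
    """Wide matrix with a two-line header: species names, then panels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.columns) + "\n")
        fh.write("panel\t" + "\t".join(str(panels.get(s, "")) for s in matrix.columns) + "\n")
        for sample, row in matrix.iterrows():
            fh.write(
                str(sample) + "\t"
                + "\t".join(format(float(v), ".17g") for v in row.to_numpy()) + "\n"
            )


def read_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        panels = fh.readline().rstrip("\n").split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    df.columns = pd.Index(header, name="species")
    df.index.name = "sample_id"
    return df, pd.Series(panels, index=header, name="panel")


class _Encoder(json.JSONEncoder):
    def default(self, o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
        fh.write("\n")


def load_yaml_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
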