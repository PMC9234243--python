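"""Delimited-text input/output for the pipeline's tables.

All formats are plain CSV.  Annotation tables carry columns
``lipid,mode,adduct,rt_min,abundance``; abundance tables are written as a
values CSV (lipids x samples) plus a sample-metadata CSV
(``sample,mouse_id,tissue,temperature,amount``); the internal-standard
map is one CSV with ``lipid_class,spiked_pmol`` followed by per-sample IS
area columns.  Floats are written with repr-round-trip precision so a
write/read cycle is lossless and deterministic.
"""

from __future__ import annotations

import os

import pandas as pd

from .curation import FeatureAnnotation
from .nomenclature import parse_lipid_name
from .quantify import AbundanceTable, InternalStandardMap

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_abundance",
    "write_abundance",
    "read_is_map",
    "write_tables",
]

def read_annotations(path: str) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"lipid", "mode", "rt_min", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        adduct = getattr(row, "adduct", None)
        if pd.isna(adduct):
            adduct = None
        out.append(
            FeatureAnnotation(
                lipid=parse_lipid_name(row.lipid),
                mode=row.mode,
                retention_time=float(row.rt_min),
                abundance=float(row.abundance),
                adduct=adduct,
            )
        )
    return out


def write_annotations(annotations: list[FeatureAnnotation], path: str) -> None:
    df = pd.DataFrame(
        {
            "lipid": [a.lipid.render() for a in annotations],
            "mode": [a.mode for a in annotations],
            "adduct": [a.adduct for a in annotations],
            "rt_min": [a.retention_time for a in annotations],
            "abundance": [a.abundance for a in annotations],
        }
    )
    df.to_csv(path, index=False)


def read_abundance(values_path: str, meta_path: str) -> AbundanceTable:
    data = pd.read_csv(values_path, index_col=0, float_precision="round_trip")
    meta = pd.read_csv(meta_path, index_col=0, float_precision="round_trip")
    return AbundanceTable(data, meta)


def write_abundance(table: AbundanceTable, values_path: str, meta_path: str) -> None:
    table.data.to_csv(values_path)
    table.meta.loc[list(table.data.columns)].to_csv(meta_path)


def read_is_map(path: str) -> InternalStandardMap:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if "spiked_pmol" not in df.columns:
        raise ValueError(f"{path}: missing spiked_pmol column")
    spiked = df["spiked_pmol"].astype(float).to_dict()
    identities = {}
    if "is_identity" in df.columns:
        identities = df["is_identity"].dropna().to_dict()
    areas = df.drop(columns=[c for c in ("spiked_pmol", "is_identity") if c in df.columns])
    return InternalStandardMap(spiked_pmol=spiked, areas=areas.astype(float), identities=identities)


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str, prefix: str = "") -> list[str]:
    """Write a dict of tidy DataFrames as CSVs; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = os.path.join(out_dir, f"{prefix}{name}.csv")
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
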