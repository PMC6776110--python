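"""Readers and writers for the pipeline's on-disk formats.

Grain maps are CSV (id, x_mm, y_mm, radius_mm); metric and OTU tables are
TSV; configuration is YAML; image stacks and masks are multi-page TIFF
(see :mod:`porebiofilm.imgcore`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .synthgen import DeviceGeometry

__all__ = [
    "read_grain_map", "write_grain_map",
    "read_otu_table", "write_otu_table",
    "read_table", "write_table",
    "read_config", "write_config",
]


def write_grain_map(geometry: DeviceGeometry, path) -> None:
    geometry.to_dataframe().to_csv(path, index=False)


def read_grain_map(path, domain_mm: tuple[float, float], pixel_size_um: float) -> DeviceGeometry:
    df = pd.read_csv(path)
    return DeviceGeometry.from_dataframe(df, domain_mm, pixel_size_um)


def write_otu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="otu_id")


def read_otu_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="otu_id")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
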