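"""File formats and run configuration.

Feature tables travel as comma-separated UTF-8 CSV with '.' decimals and
a mandatory header (``id, diameter_um, te_count, te_density,
te_size_variance, icm_area_um2, ploidy``); a column-mapping block in the
config absorbs alternative header names from externally produced tables.
Ploidy strings are normalized case-insensitively to euploid / mosaic /
aneuploid, and the binary outcome is euploid = 1, non-euploid
(mosaic or aneuploid pooled) = 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthgen import TABLE_HEADER

PLOIDY_CATEGORIES = ("euploid", "mosaic", "aneuploid")


class TableValidationError(ValueError):
    pass


def normalize_ploidy(values: pd.Series) -> pd.Series:
    """Lower-case/strip ploidy strings; reject anything off the alphabet."""
    norm = values.astype(str).str.strip().str.lower()
    bad = sorted(set(norm) - set(PLOIDY_CATEGORIES))
    if bad:
        raise TableValidationError(f"unknown ploidy values: {bad}")
    return norm


def read_feature_table(
    path, column_mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a morphological feature table.

    ``column_mapping`` maps file column names to the canonical ones.
    Adds the binary ``euploid`` column (1 iff ploidy == euploid).
    """
    table = pd.read_csv(path)
    if column_mapping:
        table = table.rename(columns=column_mapping)
    missing = [c for c in TABLE_HEADER if c not in table.columns]
    if missing:
        raise TableValidationError(f"missing columns: {missing}")
    table = table[TABLE_HEADER].copy()
    feature_cols = [c for c in TABLE_HEADER if c not in ("id", "ploidy")]
    if table[feature_cols].isna().any().any():
        raise TableValidationError("missing values in feature columns")
    if (table["te_count"] < 0).any() or not np.allclose(
        table["te_count"], np.rint(table["te_count"])
    ):
        raise TableValidationError("te_count must be a non-negative integer")
    table["te_count"] = table["te_count"].astype(int)
    table["ploidy"] = normalize_ploidy(table["ploidy"])
    table["euploid"] = (table["ploidy"] == "euploid").astype(int)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table[TABLE_HEADER].to_csv(path, index=False)


def save_rotations(rotations: list[np.ndarray], path, diagnostics=None) -> None:
    """Serialize rotations as quaternions (x, y, z, w) with diagnostics."""
    from scipy.spatial.transform import Rotation

    payload = {
        "quaternions_xyzw": [
            Rotation.from_matrix(np.asarray(R)).as_quat().tolist() for R in rotations
        ],
        "diagnostics": diagnostics or [],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rotations(path) -> list[np.ndarray]:
    from scipy.spatial.transform import Rotation

    payload = json.loads(Path(path).read_text())
    return [
        Rotation.from_quat(q).as_matrix() for q in payload["quaternions_xyzw"]
    ]


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with documented defaults."""

    pixel_scale: float = 0.5
    map_shape: tuple[int, int] = (256, 512)
    supersample: int = 2
    sift_max_ratio: float = 0.75
    ransac_threshold_deg: float = 2.0
    ransac_max_iter: int = 500
    ransac_min_inliers: int = 6
    ransac_seed: int = 0
    smoothing_sigma: float = 1.0
    ridge_scale: float = 1.5
    icm_min_area_frac: float = 0.02
    min_cell_area_um2: float = 10.0
    sd_ddof: int = 1
    welch: bool = True
    k_folds: int = 5
    rule_te_count: float = 94.0
    rule_variance: float = 478.0
    rule_icm: float = 8007.0
    column_mapping: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["map_shape"] = list(self.map_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "map_shape" in data:
            data["map_shape"] = tuple(data["map_shape"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def manifest(self, seeds: dict | None = None) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest(),
            "config": self.to_dict(),
            "seeds": seeds or {},
        }
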