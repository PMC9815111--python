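"""Core tabular containers: glycan peak tables and twin metadata.

A glycan peak table is a samples × peaks matrix of chromatogram peak
areas (``raw``), percentages of total area (``percent``) or natural-log
percentages (``log_percent``).  Twin metadata is a plain pandas DataFrame
with one row per sample; :func:`validate_metadata` enforces the schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCALES = ("raw", "percent", "log_percent")
ZYGOSITIES = ("MZ", "DZ")

#: Required columns of a twin metadata table.
METADATA_COLUMNS = ("sample_id", "pair_id", "zygosity", "age", "batch")


class ValidationError(ValueError):
    """Raised when an input table violates its schema."""


@dataclass
class GlycanPeakTable:
    """Samples × peaks matrix of glycan chromatogram peak values.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per peak (GP1…GPn).
    scale
        One of ``raw`` (areas), ``percent`` (rows sum to 100) or
        ``log_percent`` (natural log of percentages).
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(
                f"scale must be one of {SCALES}, got {self.scale!r}"
            )
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()][:5]
            raise ValidationError(f"duplicate sample ids: {list(dupes)}")
        # negative areas/percentages are invalid; strict positivity is
        # enforced at the steps that need it (normalization, log)
        if self.scale in ("raw", "percent"):
            arr = self.values.to_numpy(dtype=float)
            if not np.all(arr >= 0):
                i, j = np.argwhere(~(arr >= 0))[0]
                raise ValidationError(
                    f"negative value at sample {self.values.index[i]!r}, "
                    f"peak {self.values.columns[j]!r} on {self.scale} scale"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peak_names(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_csv(self, path, sep: str = ",") -> None:
        self.values.to_csv(path, sep=sep, index_label="sample_id",
                           float_format="%.12g")

    @classmethod
    def from_csv(cls, path, scale: str = "raw", sep: str = ",") -> "GlycanPeakTable":
        df = pd.read_csv(path, sep=sep, index_col="sample_id")
        return cls(df, scale=scale)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a twin metadata table and return it unchanged.

    Requires the columns in :data:`METADATA_COLUMNS`; ``time_point`` and
    ``cohort`` are optional.  Checks unique sample ids, zygosity codes,
    pair sizes (1 or 2 per time point) and zygosity agreement within pairs.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"]
        raise ValidationError(f"duplicate sample ids: {list(dupes[:5])}")
    bad = set(metadata["zygosity"]) - set(ZYGOSITIES)
    if bad:
        raise ValidationError(f"unknown zygosity codes: {sorted(bad)}")
    group_cols = ["pair_id"]
    if "time_point" in metadata.columns:
        group_cols.append("time_point")
    sizes = metadata.groupby(group_cols, sort=False).size()
    if (sizes > 2).any():
        bad_pairs = sizes[sizes > 2].index[:5].tolist()
        raise ValidationError(f"pairs with more than two members: {bad_pairs}")
    zyg_counts = metadata.groupby("pair_id")["zygosity"].nunique()
    if (zyg_counts > 1).any():
        bad_pairs = zyg_counts[zyg_counts > 1].index[:5].tolist()
        raise ValidationError(f"pairs with mixed zygosity: {bad_pairs}")
    return metadata


def read_metadata(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a twin metadata CSV/TSV."""
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "pair_id": str,
                                           "batch": str})
    return validate_metadata(df)


def write_metadata(metadata: pd.DataFrame, path, sep: str = ",") -> None:
    metadata.to_csv(path, sep=sep, index=False)
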