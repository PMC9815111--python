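"""The glycan clock: a polynomial predictor of age from IgG glycan peaks.

The clock is quadratic in one primary peak and linear in two secondary
peaks, all expressed as percent of total chromatogram area:

    glycan_age = b0 + b1·GPp + b2·GPp² + s1·GPs1 + s2·GPs2

Two published coefficient sets are shipped as frozen constants, one per
cohort (the two cohorts were integrated into 24 vs 22 chromatogram peaks,
hence the different peak names).  :func:`fit_clock` re-estimates the
coefficients by OLS from one twin per pair, and :func:`predict_glycan_age`
scores any percent-scale peak table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from glycanclock.datasets import GlycanPeakTable, ValidationError


@dataclass(frozen=True)
class ClockModel:
    """Coefficients of the glycan-age polynomial.

    Units: ``intercept`` in years; ``beta_linear`` years per percent;
    ``beta_quadratic`` years per percent²; ``beta_secondary`` years per
    percent for each secondary peak.
    """

    intercept: float
    primary_peak: str
    beta_linear: float
    beta_quadratic: float
    secondary_peaks: tuple[str, str]
    beta_secondary: tuple[float, float]
    cohort_tag: str = ""

    def __post_init__(self) -> None:
        names = (self.primary_peak, *self.secondary_peaks)
        if len(set(names)) != 3:
            raise ValidationError(f"clock peak names must be distinct: {names}")

    @property
    def required_peaks(self) -> tuple[str, str, str]:
        return (self.primary_peak, *self.secondary_peaks)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClockModel":
        with open(path) as fh:
            d = json.load(fh)
        d["secondary_peaks"] = tuple(d["secondary_peaks"])
        d["beta_secondary"] = tuple(d["beta_secondary"])
        return cls(**d)


#: Published cross-sectional cohort clock (24-peak integration).
CROSS_SECTIONAL_CLOCK = ClockModel(
    intercept=53.83,
    primary_peak="GP6",
    beta_linear=5.24,
    beta_quadratic=-0.29,
    secondary_peaks=("GP14", "GP15"),
    beta_secondary=(-1.57, 1.76),
    cohort_tag="cross_sectional",
)

#: Published longitudinal cohort clock (22-peak integration).
LONGITUDINAL_CLOCK = ClockModel(
    intercept=50.29,
    primary_peak="GP4",
    beta_linear=5.11,
    beta_quadratic=-0.32,
    secondary_peaks=("GP12", "GP13"),
    beta_secondary=(-1.24, 1.49),
    cohort_tag="longitudinal",
)

PRINTED_CLOCKS = {
    "cross_sectional": CROSS_SECTIONAL_CLOCK,
    "longitudinal": LONGITUDINAL_CLOCK,
}


def predict_glycan_age(clock: ClockModel, table: GlycanPeakTable) -> pd.Series:
    """Score a percent-scale peak table with a clock model.

    Returns glycan age in years, indexed by sample id.
    """
    if table.scale != "percent":
        raise ValidationError(
            f"clock scoring requires a percent-scale table, got {table.scale!r}"
        )
    for peak in clock.required_peaks:
        if peak not in table.values.columns:
            raise ValidationError(f"required peak {peak!r} missing from table")
    p = table.values[clock.primary_peak].to_numpy(dtype=float)
    s1 = table.values[clock.secondary_peaks[0]].to_numpy(dtype=float)
    s2 = table.values[clock.secondary_peaks[1]].to_numpy(dtype=float)
    age = (
        clock.intercept
        + clock.beta_linear * p
        + clock.beta_quadratic * p**2
        + clock.beta_secondary[0] * s1
        + clock.beta_secondary[1] * s2
    )
    return pd.Series(age, index=table.values.index, name="glycan_age")


def fit_clock(
    table: GlycanPeakTable,
    ages: pd.Series,
    primary_peak: str,
    secondary_peaks: tuple[str, str],
    cohort_tag: str = "refit",
) -> ClockModel:
    """Estimate clock coefficients by OLS of age on [1, GPp, GPp², GPs1, GPs2].

    ``ages`` must be indexed by sample id and cover every sample in the
    table.  Requires at least 10 samples and a full-rank design.
    """
    if table.scale != "percent":
        raise ValidationError("clock fitting requires a percent-scale table")
    for peak in (primary_peak, *secondary_peaks):
        if peak not in table.values.columns:
            raise ValidationError(f"required peak {peak!r} missing from table")
    y = ages.reindex(table.values.index)
    if y.isna().any():
        missing = list(y.index[y.isna()][:5])
        raise ValidationError(f"ages missing for samples: {missing}")
    n = len(y)
    if n < 10:
        raise ValidationError(f"clock fitting requires ≥ 10 samples, got {n}")
    p = table.values[primary_peak].to_numpy(dtype=float)
    s1 = table.values[secondary_peaks[0]].to_numpy(dtype=float)
    s2 = table.values[secondary_peaks[1]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), p, p**2, s1, s2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "rank-deficient clock design (constant or collinear peaks)"
        )
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    return ClockModel(
        intercept=float(beta[0]),
        primary_peak=primary_peak,
        beta_linear=float(beta[1]),
        beta_quadratic=float(beta[2]),
        secondary_peaks=tuple(secondary_peaks),
        beta_secondary=(float(beta[3]), float(beta[4])),
        cohort_tag=cohort_tag,
    )


def select_one_per_pair(
    metadata: pd.DataFrame,
    seed: int,
    rule: str = "random",
) -> list[str]:
    """Pick one sample id per twin pair for clock fitting.

    With ``rule="random"`` the kept member is drawn uniformly per pair with
    the given seed; ``rule="first"`` keeps the lexicographically first
    sample id (a deterministic audit rule).  Singletons pass through.
    Repeated time points of the same individual are not collapsed; callers
    fitting per time point should pass one time point's metadata.
    """
    if rule not in ("random", "first"):
        raise ValidationError(f"unknown selection rule {rule!r}")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for _, group in metadata.sort_values("sample_id").groupby("pair_id", sort=True):
        ids = list(group["sample_id"])
        if rule == "first" or len(ids) == 1:
            selected.append(ids[0])
        else:
            selected.append(ids[rng.integers(len(ids))])
    return sorted(selected)
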