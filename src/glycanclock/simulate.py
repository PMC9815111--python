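"""Synthetic twin glycome generator.

Produces twin cohorts with a planted A/C/E variance structure in the
glycan-age phenotype, full compositional glycan-peak tables that carry
that phenotype through the clock polynomial, and per-batch technical
location/scale effects plus a random total chromatogram area — i.e.
everything the preprocessing, clock and heritability stages must undo or
estimate.  All generators are pure functions of (config, seed).

Construction of the ACE phenotype: with path coefficients a = √a², etc.,

    y = mean + a·A + c·C + e·E,

where MZ co-twins share the same standard-normal A draw, DZ co-twins'
A draws correlate 0.5 (A_i = √½·A_common + √½·A_unique_i), C is shared
within a pair regardless of zygosity, and E is independent per
individual.  Hence Cov(MZ) = a²+c² and Cov(DZ) = ½a²+c².

Peak embedding inverts the clock polynomial: the two secondary predictor
peaks are drawn from truncated normals, the primary (quadratic) peak is
solved from the polynomial on its ascending branch (below the vertex,
keeping the peak in a realistic 0–10 percent range), and the remaining
peaks are a symmetric-Dirichlet composition rescaled so each sample sums
to exactly 100 percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from glycanclock.datasets import GlycanPeakTable, ValidationError
from glycanclock.clock import ClockModel, CROSS_SECTIONAL_CLOCK
from glycanclock.twin import TwinPairDataset


@dataclass
class SimulationConfig:
    """Study-design parameters for a simulated twin cohort.

    Defaults mirror the cross-sectional study design: 479 MZ + 1193 DZ
    pairs (3344 samples), a 39/45/16 percent A/C/E split of the
    glycan-age variance, and a 24-peak chromatogram scored by the
    cross-sectional clock.  Variances are in years²; the total phenotype
    SD defaults to 4 years around a mean glycan age of 55.  ``age_beta``
    (years of glycan age per year of chronological age, through the
    means model; co-twins share their age) defaults to 0 so the planted
    variance components are exactly the phenotype's — age confounding is
    an explicit scenario, not the default.
    """

    n_mz_pairs: int = 479
    n_dz_pairs: int = 1193
    a2: float = 0.39 * 16.0
    c2: float = 0.45 * 16.0
    e2: float = 0.16 * 16.0
    phenotype_mean: float = 55.0
    age_range: tuple[float, float] = (30.0, 70.0)
    age_beta: float = 0.0
    n_peaks: int = 24
    clock_model: ClockModel = field(default_factory=lambda: CROSS_SECTIONAL_CLOCK)
    batch_count: int = 4
    batch_shift_sd: float = 0.1
    batch_scale_sd: float = 0.05
    total_area_range: tuple[float, float] = (8e4, 1.2e5)
    secondary_means: tuple[float, float] = (8.0, 2.0)
    secondary_sds: tuple[float, float] = (1.5, 0.5)
    background_concentration: float = 20.0
    longitudinal: bool = False
    time_spacing_means: tuple[float, float] = (7.5, 6.0)
    time_spacing_sds: tuple[float, float] = (3.27, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a2, self.c2, self.e2) < 0:
            raise ValidationError("variance components must be non-negative")
        if self.a2 + self.c2 + self.e2 == 0:
            raise ValidationError("total phenotype variance must be positive")
        if self.n_mz_pairs < 1 or self.n_dz_pairs < 1:
            raise ValidationError("need at least one pair per zygosity")
        if not self.age_range[0] < self.age_range[1]:
            raise ValidationError("age_range must satisfy min < max")
        if self.n_peaks < 4:
            raise ValidationError("need at least 4 peaks (3 predictors + rest)")
        if self.batch_count < 1:
            raise ValidationError("batch_count must be ≥ 1")


def simulate_ace_phenotype(n_mz: int, n_dz: int, a2: float, c2: float,
                           e2: float, mean: float, seed: int) -> TwinPairDataset:
    """Simulate twin-pair phenotypes with the classical ACE covariance."""
    for name, val in (("a2", a2), ("c2", c2), ("e2", e2)):
        if val < 0:
            raise ValidationError(f"{name} must be non-negative, got {val}")
    if a2 + c2 + e2 == 0:
        raise ValidationError("at least one variance component must be positive")
    if n_mz < 1 or n_dz < 1:
        raise ValidationError("need at least one pair per zygosity")
    rng = np.random.default_rng(seed)
    a, c, e = np.sqrt(a2), np.sqrt(c2), np.sqrt(e2)
    n = n_mz + n_dz
    zyg = np.array(["MZ"] * n_mz + ["DZ"] * n_dz, dtype=object)

    A_common = rng.normal(size=n)
    A_unique = rng.normal(size=(n, 2))
    A1 = np.where(zyg == "MZ", A_common,
                  np.sqrt(0.5) * A_common + np.sqrt(0.5) * A_unique[:, 0])
    A2 = np.where(zyg == "MZ", A_common,
                  np.sqrt(0.5) * A_common + np.sqrt(0.5) * A_unique[:, 1])
    C = rng.normal(size=n)
    E = rng.normal(size=(n, 2))
    y1 = mean + a * A1 + c * C + e * E[:, 0]
    y2 = mean + a * A2 + c * C + e * E[:, 1]
    return TwinPairDataset(y1, y2, zyg)


def _truncated_normal(rng, mean, sd, size):
    """Normal truncated at 0 by resampling (positivity for percent peaks)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= 0
    return out


def embed_clock_signal(
    target_ages: pd.Series,
    clock: ClockModel = CROSS_SECTIONAL_CLOCK,
    n_peaks: int = 24,
    secondary_means: tuple[float, float] = (8.0, 2.0),
    secondary_sds: tuple[float, float] = (1.5, 0.5),
    background_concentration: float = 20.0,
    seed: int = 0,
    max_retries: int = 50,
) -> GlycanPeakTable:
    """Build a percent-scale peak table whose clock score equals the target.

    For each sample the secondary peaks are drawn from truncated normals
    and the primary peak is solved from the clock polynomial on its
    ascending branch; secondaries are resampled (up to ``max_retries``)
    until the target is attainable, then completed deterministically by
    drawing the secondary-peak contribution uniformly from the exactly
    attainable interval.  Targets above the polynomial's global maximum
    (given a zero first secondary peak) are an error.
    """
    b0, b1, b2 = clock.intercept, clock.beta_linear, clock.beta_quadratic
    s_coef = clock.beta_secondary
    if b2 >= 0:
        raise ValidationError("clock inversion assumes a negative quadratic "
                              "coefficient (age rises then falls in the peak)")
    if not (s_coef[0] < 0 < s_coef[1]):
        raise ValidationError("clock inversion assumes one negative and one "
                              "positive secondary coefficient")
    peak_names = [f"GP{i}" for i in range(1, n_peaks + 1)]
    missing = [p for p in clock.required_peaks if p not in peak_names]
    if missing:
        raise ValidationError(
            f"n_peaks={n_peaks} does not cover clock peaks {missing}"
        )
    t = np.asarray(target_ages, dtype=float)
    n = len(t)
    rng = np.random.default_rng(seed)
    height = b1**2 / (4.0 * abs(b2))  # vertex height above the p=0 value

    s1 = _truncated_normal(rng, secondary_means[0], secondary_sds[0], n)
    s2 = _truncated_normal(rng, secondary_means[1], secondary_sds[1], n)
    u = s_coef[0] * s1 + s_coef[1] * s2          # secondary contribution
    # attainable iff the polynomial at p=0 sits within [t - height, t]
    bad = ~((t - b0 - height <= u) & (u <= t - b0))
    for _ in range(max_retries):
        if not bad.any():
            break
        k = int(bad.sum())
        s1[bad] = _truncated_normal(rng, secondary_means[0], secondary_sds[0], k)
        s2[bad] = _truncated_normal(rng, secondary_means[1], secondary_sds[1], k)
        u = s_coef[0] * s1 + s_coef[1] * s2
        bad = ~((t - b0 - height <= u) & (u <= t - b0))
    if bad.any():
        # deterministic completion: pick the secondary contribution
        # uniformly inside the attainable interval, honouring s1 ≥ 0
        idx = np.nonzero(bad)[0]
        d_hi = np.full(len(idx), height)
        d_lo = np.maximum(0.0, t[idx] - b0 - s_coef[1] * s2[idx])
        infeasible = d_lo > d_hi
        if infeasible.any():
            j = idx[np.nonzero(infeasible)[0][0]]
            raise ValidationError(
                f"target glycan age {t[j]:.2f} (sample "
                f"{target_ages.index[j]!r}) exceeds the clock polynomial's "
                "attainable range"
            )
        d = d_lo + rng.uniform(size=len(idx)) * (d_hi - d_lo)
        u[idx] = t[idx] - b0 - d
        s1[idx] = (u[idx] - s_coef[1] * s2[idx]) / s_coef[0]

    # ascending-branch root of b2·p² + b1·p − d = 0, d = t − (b0 + u) ∈ [0, h]
    d_quad = t - b0 - u
    disc = np.maximum(b1**2 + 4.0 * b2 * d_quad, 0.0)
    p = (b1 - np.sqrt(disc)) / (2.0 * abs(b2))

    predictor_total = p + s1 + s2
    remainder = 100.0 - predictor_total
    if not np.all(remainder > 0):
        j = int(np.nonzero(~(remainder > 0))[0][0])
        raise ValidationError(
            f"predictor peaks exceed 100 percent for sample "
            f"{target_ages.index[j]!r}"
        )
    n_bg = n_peaks - 3
    bg = rng.dirichlet(np.full(n_bg, background_concentration), size=n)
    bg *= remainder[:, None]

    values = pd.DataFrame(0.0, index=target_ages.index, columns=peak_names)
    values[clock.primary_peak] = p
    values[clock.secondary_peaks[0]] = s1
    values[clock.secondary_peaks[1]] = s2
    bg_names = [c for c in peak_names if c not in clock.required_peaks]
    values[bg_names] = bg
    return GlycanPeakTable(values, scale="percent")


@dataclass
class BatchEffectRecord:
    """Bookkeeping of drawn technical effects (for recovery tests)."""

    batch_labels: list
    gamma: np.ndarray       # batch × peak, additive on the log scale
    delta: np.ndarray       # batch × peak, multiplicative on the log scale
    total_area: np.ndarray  # per sample


def apply_batch_effects(
    table: GlycanPeakTable,
    batches: pd.Series,
    shift_sd: float,
    scale_sd: float,
    total_area_range: tuple[float, float],
    seed: int = 0,
) -> tuple[GlycanPeakTable, BatchEffectRecord]:
    """Inject per-batch location/scale effects and a random total area.

    On the log scale each peak value x becomes
    μ_g + γ_bg + δ_bg·(log x − μ_g), with γ ~ Normal(0, shift_sd²) and
    δ log-normal with log-SD ``scale_sd`` (so δ > 0); μ_g is the peak's
    grand mean of log values.  Each sample is then rescaled from percent
    to raw areas by a uniform total-area draw.
    """
    if table.scale != "percent":
        raise ValidationError("batch effects are applied to a percent table")
    lo, hi = total_area_range
    if not (0 < lo <= hi):
        raise ValidationError("total_area_range must be positive with lo <= hi")
    b = batches.reindex(table.values.index)
    if b.isna().any():
        raise ValidationError("batch labels missing for some samples")
    rng = np.random.default_rng(seed)
    labels = sorted(pd.unique(b))
    L = np.log(table.to_numpy())
    mu = L.mean(axis=0)
    gamma = rng.normal(0.0, shift_sd, size=(len(labels), L.shape[1]))
    delta = np.exp(rng.normal(0.0, scale_sd, size=(len(labels), L.shape[1])))
    out = np.empty_like(L)
    for i, lab in enumerate(labels):
        idx = np.nonzero((b == lab).to_numpy())[0]
        out[idx] = mu + gamma[i] + delta[i] * (L[idx] - mu)
    total = rng.uniform(lo, hi, size=L.shape[0])
    raw = np.exp(out) * (total[:, None] / 100.0)
    record = BatchEffectRecord(batch_labels=labels, gamma=gamma, delta=delta,
                               total_area=total)
    return (
        GlycanPeakTable(
            pd.DataFrame(raw, index=table.values.index,
                         columns=table.values.columns),
            scale="raw",
        ),
        record,
    )


def simulate_twin_cohort(
    config: SimulationConfig,
) -> tuple[GlycanPeakTable, pd.DataFrame, dict]:
    """End-to-end cohort generator: metadata, raw peak table, truth record.

    Cross-sectional mode emits one sample per individual; longitudinal
    mode emits three time points with configurable mean spacings (the A
    and C draws persist across time points, E is redrawn, and the age
    trend moves the mean through ``age_beta``).  The truth record stores
    every planted parameter plus the per-sample true glycan age.
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_mz_pairs + config.n_dz_pairs
    zyg = np.array(["MZ"] * config.n_mz_pairs + ["DZ"] * config.n_dz_pairs,
                   dtype=object)
    pair_ids = [f"pair{str(i + 1).zfill(4)}" for i in range(n_pairs)]
    base_age = rng.uniform(*config.age_range, size=n_pairs)  # shared by co-twins
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    a, c, e = np.sqrt([config.a2, config.c2, config.e2])
    A_common = rng.normal(size=n_pairs)
    A_unique = rng.normal(size=(n_pairs, 2))
    A = np.empty((n_pairs, 2))
    for m in range(2):
        A[:, m] = np.where(
            zyg == "MZ", A_common,
            np.sqrt(0.5) * A_common + np.sqrt(0.5) * A_unique[:, m],
        )
    C = rng.normal(size=n_pairs)

    if config.longitudinal:
        gap12 = rng.normal(*np.array([config.time_spacing_means[0],
                                      config.time_spacing_sds[0]]), size=n_pairs)
        gap23 = rng.normal(*np.array([config.time_spacing_means[1],
                                      config.time_spacing_sds[1]]), size=n_pairs)
        gap12 = np.maximum(gap12, 0.5)
        gap23 = np.maximum(gap23, 0.5)
        offsets = [np.zeros(n_pairs), gap12, gap12 + gap23]
    else:
        offsets = [np.zeros(n_pairs)]

    rows = []
    phen = {}
    for tp, off in enumerate(offsets, start=1):
        E = rng.normal(size=(n_pairs, 2))
        age_tp = base_age + off
        for m in range(2):
            y = (config.phenotype_mean
                 + config.age_beta * (age_tp - age_mid)
                 + a * A[:, m] + c * C + e * E[:, m])
            for i in range(n_pairs):
                sid = f"{pair_ids[i]}-{m + 1}-t{tp}"
                rows.append({
                    "sample_id": sid,
                    "pair_id": pair_ids[i],
                    "zygosity": zyg[i],
                    "age": float(age_tp[i]),
                    "time_point": tp,
                    "cohort": ("longitudinal" if config.longitudinal
                               else "cross_sectional"),
                })
                phen[sid] = float(y[i])
    metadata = pd.DataFrame(rows)
    metadata["batch"] = [
        f"batch{rng.integers(config.batch_count) + 1}"
        for _ in range(len(metadata))
    ]

    target = pd.Series(phen).loc[metadata["sample_id"]]
    percent = embed_clock_signal(
        target,
        clock=config.clock_model,
        n_peaks=config.n_peaks,
        secondary_means=config.secondary_means,
        secondary_sds=config.secondary_sds,
        background_concentration=config.background_concentration,
        seed=int(rng.integers(2**31)),
    )
    raw, batch_record = apply_batch_effects(
        percent,
        metadata.set_index("sample_id")["batch"],
        config.batch_shift_sd,
        config.batch_scale_sd,
        config.total_area_range,
        seed=int(rng.integers(2**31)),
    )

    total = config.a2 + config.c2 + config.e2
    truth = {
        "config": {k: v for k, v in asdict(config).items()
                   if k != "clock_model"},
        "clock_cohort_tag": config.clock_model.cohort_tag,
        "a2": config.a2, "c2": config.c2, "e2": config.e2,
        "h2": config.a2 / total,
        "c2_std": config.c2 / total,
        "e2_std": config.e2 / total,
        "glycan_age": phen,
        "batch_gamma": batch_record.gamma.tolist(),
        "batch_delta": batch_record.delta.tolist(),
    }
    return raw, metadata, truth
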