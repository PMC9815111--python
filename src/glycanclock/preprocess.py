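"""Glycan peak-table preprocessing.

The chain mirrors standard UHPLC glycomics practice: total-area
normalization of chromatogram peaks to percentages, natural-log transform,
parametric empirical-Bayes batch correction (the ComBat location/scale
model of Johnson, Li & Rabinovic 2007), and back-transformation to the
percent scale before clock scoring.

ComBat details.  Each peak is standardized against its grand mean and
pooled variance; per-batch location effects γ and scale effects δ² are
shrunk toward a batch-level normal prior and an inverse-gamma prior whose
hyperparameters come from the method of moments across peaks; the
posterior (γ*, δ²*) pair is solved by fixed-point iteration.  The
corrected value is grand_mean + pooled_sd · (z − γ*)/√δ²*.  No covariates
enter the batch-correction design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycanclock.datasets import GlycanPeakTable, ValidationError

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Fixed-point iteration for the batch posteriors did not converge."""


@dataclass
class BatchCorrectionModel:
    """Fitted empirical-Bayes batch-correction parameters.

    Arrays are batch × peak: ``gamma_hat``/``delta2_hat`` are the raw
    per-batch estimates on the standardized scale and ``gamma_star``/
    ``delta2_star`` their empirical-Bayes posteriors.  ``grand_mean`` and
    ``var_pooled`` are per-peak standardization parameters;
    ``gamma_bar``/``t2`` and ``a_prior``/``b_prior`` are the per-batch
    prior hyperparameters.
    """

    batch_labels: list
    peak_names: list
    grand_mean: np.ndarray
    var_pooled: np.ndarray
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    gamma_bar: np.ndarray
    t2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray


def total_area_normalize(table: GlycanPeakTable) -> GlycanPeakTable:
    """Express each peak as percent of the sample's total peak area."""
    if table.scale == "percent":
        return GlycanPeakTable(table.values.copy(), scale="percent")
    if table.scale != "raw":
        raise ValidationError(
            f"total-area normalization expects a raw table, got {table.scale!r}"
        )
    arr = table.to_numpy()
    if not np.all(arr > 0):
        i, j = np.argwhere(~(arr > 0))[0]
        raise ValidationError(
            f"non-positive area at sample {table.values.index[i]!r}, "
            f"peak {table.values.columns[j]!r}"
        )
    totals = arr.sum(axis=1)
    bad = np.nonzero(~(totals > 0))[0]
    if bad.size:
        raise ValidationError(
            f"non-positive total area for sample {table.values.index[bad[0]]!r}"
        )
    out = arr / totals[:, None] * 100.0
    return GlycanPeakTable(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        scale="percent",
    )


def log_transform(table: GlycanPeakTable) -> GlycanPeakTable:
    """Natural log, elementwise, percent → log_percent."""
    if table.scale != "percent":
        raise ValidationError(
            f"log transform expects a percent table, got {table.scale!r}"
        )
    arr = table.to_numpy()
    if not np.all(arr > 0):
        i, j = np.argwhere(~(arr > 0))[0]
        raise ValidationError(
            f"non-positive value at sample {table.values.index[i]!r}, "
            f"peak {table.values.columns[j]!r}: cannot log-transform"
        )
    return GlycanPeakTable(
        pd.DataFrame(np.log(arr), index=table.values.index,
                     columns=table.values.columns),
        scale="log_percent",
    )


def back_transform(table: GlycanPeakTable) -> GlycanPeakTable:
    """Elementwise exp, log_percent → percent-scale values.

    After batch correction rows need not sum exactly to 100 any more; the
    values are used as-is downstream (no re-normalization).
    """
    if table.scale != "log_percent":
        raise ValidationError(
            f"back transform expects a log_percent table, got {table.scale!r}"
        )
    return GlycanPeakTable(
        pd.DataFrame(np.exp(table.to_numpy()), index=table.values.index,
                     columns=table.values.columns),
        scale="percent",
    )


def combat_correct(
    table: GlycanPeakTable,
    batches: pd.Series,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[GlycanPeakTable, BatchCorrectionModel | None]:
    """Parametric empirical-Bayes batch correction of a log-percent table.

    ``batches`` maps sample id to batch label.  Each peak is a feature.
    A single batch overall is returned unchanged (nothing to correct,
    with a logged warning); a batch with a single sample is an error
    because its scale effect is not estimable.
    """
    if table.scale != "log_percent":
        raise ValidationError(
            f"batch correction expects a log_percent table, got {table.scale!r}"
        )
    b = batches.reindex(table.values.index)
    if b.isna().any():
        missing = list(b.index[b.isna()][:5])
        raise ValidationError(f"batch labels missing for samples: {missing}")

    labels = sorted(pd.unique(b))
    if len(labels) == 1:
        logger.warning("single batch %r: batch correction is a no-op", labels[0])
        return GlycanPeakTable(table.values.copy(), scale="log_percent"), None

    Y = table.to_numpy()                       # n samples × G peaks
    n, G = Y.shape
    groups = [np.nonzero((b == lab).to_numpy())[0] for lab in labels]
    n_b = np.array([len(g) for g in groups])
    for lab, nb in zip(labels, n_b):
        if nb < 2:
            raise ValidationError(
                f"batch {lab!r} has a single sample: scale effect not estimable"
            )

    # standardization: grand mean weighted by batch size, variance pooled
    # around the per-batch means (ML divisor n)
    batch_means = np.stack([Y[g].mean(axis=0) for g in groups])   # B × G
    grand_mean = (n_b[:, None] * batch_means).sum(axis=0) / n
    fitted = np.empty_like(Y)
    for g, m in zip(groups, batch_means):
        fitted[g] = m
    var_pooled = ((Y - fitted) ** 2).mean(axis=0)
    if not np.all(var_pooled > 0):
        j = int(np.nonzero(~(var_pooled > 0))[0][0])
        raise ValidationError(
            f"peak {table.values.columns[j]!r} is constant within batches"
        )
    Z = (Y - grand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.stack([Z[g].mean(axis=0) for g in groups])       # B × G
    delta2_hat = np.stack([Z[g].var(axis=0, ddof=1) for g in groups])

    # hyperpriors by method of moments across peaks
    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2.0 * s2 + m**2) / s2
    b_prior = (m * s2 + m**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i, g in enumerate(groups):
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        nb = n_b[i]
        for _ in range(max_iter):
            g_new = (t2[i] * nb * gamma_hat[i] + d_old * gamma_bar[i]) / (
                t2[i] * nb + d_old
            )
            sum2 = ((Z[g] - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior[i]) / (nb / 2.0 + a_prior[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        else:
            raise ConvergenceError(
                f"batch {labels[i]!r}: posterior iteration did not converge "
                f"in {max_iter} steps (last change {change:.3g})"
            )
        gamma_star[i] = g_old
        delta2_star[i] = d_old

    Z_corr = Z.copy()
    for i, g in enumerate(groups):
        Z_corr[g] = (Z[g] - gamma_star[i]) / np.sqrt(delta2_star[i])
    corrected = Z_corr * np.sqrt(var_pooled) + grand_mean

    model = BatchCorrectionModel(
        batch_labels=labels,
        peak_names=list(table.values.columns),
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
    )
    out = GlycanPeakTable(
        pd.DataFrame(corrected, index=table.values.index,
                     columns=table.values.columns),
        scale="log_percent",
    )
    return out, model


def preprocess(
    table: GlycanPeakTable,
    batches: pd.Series,
) -> tuple[GlycanPeakTable, BatchCorrectionModel | None]:
    """Full chain: normalize → log → batch-correct → back-transform.

    Returns a percent-scale, clock-ready table (strictly positive; rows
    may deviate from a 100 sum after correction) plus the fitted batch
    model (None when only one batch is present).
    """
    percent = total_area_normalize(table)
    logged = log_transform(percent)
    corrected, model = combat_correct(logged, batches)
    return back_transform(corrected), model
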