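"""End-to-end study orchestration at desk scale.

simulate → preprocess → clock → glycan age → singleton exclusion →
twin variance decomposition, per cohort / time point, fully reproducible
from (config, seed), with a machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from glycanclock.datasets import GlycanPeakTable, ValidationError
from glycanclock.clock import (
    ClockModel, PRINTED_CLOCKS, fit_clock, predict_glycan_age,
    select_one_per_pair,
)
from glycanclock.preprocess import preprocess
from glycanclock.simulate import SimulationConfig, simulate_twin_cohort
from glycanclock.twin import (
    TwinPairDataset, intrapair_correlations, select_model,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class StudyConfig:
    """Configuration of a full simulated twin study.

    ``clock_source`` chooses between the two published coefficient sets
    and a cohort-internal refit (OLS on one twin per pair, requiring
    ages).  ``adjust_for_age`` adds chronological age to the means model
    of the variance decomposition.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cohort_mode: str = "cross_sectional"
    clock_source: str = "printed_cross_sectional"
    adjust_for_age: bool = False
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_mode not in ("cross_sectional", "longitudinal"):
            raise ValidationError(f"unknown cohort_mode {self.cohort_mode!r}")
        if self.clock_source not in ("printed_cross_sectional",
                                     "printed_longitudinal", "refit"):
            raise ValidationError(f"unknown clock_source {self.clock_source!r}")
        self.simulation.longitudinal = self.cohort_mode == "longitudinal"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"].pop("clock_model", None)
        d["simulation"]["clock_cohort_tag"] = self.simulation.clock_model.cohort_tag
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        tag = sim.pop("clock_cohort_tag", None)
        for key in ("age_range", "total_area_range", "secondary_means",
                    "secondary_sds", "time_spacing_means", "time_spacing_sds"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if tag:
            sim["clock_model"] = PRINTED_CLOCKS[tag]
        return cls(simulation=SimulationConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class HeritabilityReport:
    """Machine-readable study outcome, one entry per cohort/time point."""

    estimates: list[dict]
    truth: dict
    config_hash: str
    seed: int
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> str:
        lines = []
        for est in self.estimates:
            lines.append(
                f"time point {est['time_point']}: "
                f"{est['n_mz_pairs']} MZ + {est['n_dz_pairs']} DZ pairs, "
                f"rMZ={est['rMZ']:.3f} rDZ={est['rDZ']:.3f}, "
                f"best model {est['best_model']}: "
                f"h²={est['h2']:.3f} C={est['c2_std']:.3f} E={est['e2_std']:.3f}"
            )
        return "\n".join(lines)


def exclude_singletons(metadata: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop every participant without a co-twin; return kept rows + log.

    Pairing is checked per time point when a ``time_point`` column is
    present (a co-twin must be measured at the same visit).
    """
    group_cols = ["pair_id"]
    if "time_point" in metadata.columns:
        group_cols.append("time_point")
    sizes = metadata.groupby(group_cols, sort=False)["sample_id"].transform("size")
    kept = metadata[sizes == 2].copy()
    removed = sorted(metadata.loc[sizes != 2, "sample_id"])
    if removed:
        logger.info("excluded %d singleton(s): %s", len(removed), removed)
    return kept, removed


def _resolve_clock(config: StudyConfig, percent: GlycanPeakTable,
                   metadata: pd.DataFrame) -> ClockModel:
    if config.clock_source == "printed_cross_sectional":
        return PRINTED_CLOCKS["cross_sectional"]
    if config.clock_source == "printed_longitudinal":
        return PRINTED_CLOCKS["longitudinal"]
    # refit on one twin per pair, first time point only
    meta = metadata
    if "time_point" in meta.columns:
        meta = meta[meta["time_point"] == meta["time_point"].min()]
    if meta["age"].isna().any():
        raise ValidationError("clock refit requires ages for every sample")
    chosen = select_one_per_pair(meta, seed=config.seed)
    sub = GlycanPeakTable(percent.values.loc[chosen], scale="percent")
    ages = meta.set_index("sample_id")["age"].loc[chosen]
    design = config.simulation.clock_model
    return fit_clock(sub, ages, design.primary_peak, design.secondary_peaks,
                     cohort_tag="refit")


def run_study(config: StudyConfig) -> HeritabilityReport:
    """Execute the full simulated study and return the report.

    Stages: cohort simulation, preprocessing (total-area normalization,
    log, batch correction, back-transform), clock resolution and glycan
    age prediction, singleton exclusion, and nested-model ACE selection
    per time point (optionally age-adjusted).  Any stage failure aborts
    with the stage name in the exception message.
    """
    stage = "simulate"
    try:
        config.simulation.seed = config.seed
        raw, metadata, truth = simulate_twin_cohort(config.simulation)
        logger.info("stage simulate: %d samples, %d peaks",
                    *raw.values.shape)

        stage = "preprocess"
        batches = metadata.set_index("sample_id")["batch"]
        percent, batch_model = preprocess(raw, batches)
        logger.info("stage preprocess: %d samples corrected across %d batches",
                    percent.values.shape[0],
                    len(batch_model.batch_labels) if batch_model else 1)

        stage = "clock"
        clock = _resolve_clock(config, percent, metadata)
        glycan_age = predict_glycan_age(clock, percent)
        logger.info("stage clock: scored %d samples with %s clock",
                    len(glycan_age), clock.cohort_tag or "refit")

        stage = "exclude_singletons"
        kept, removed = exclude_singletons(metadata)
        logger.info("stage exclude_singletons: %d kept, %d removed",
                    len(kept), len(removed))

        stage = "heritability"
        kept = kept.assign(glycan_age=glycan_age.loc[kept["sample_id"]].values)
        estimates = []
        time_points = (sorted(kept["time_point"].unique())
                       if "time_point" in kept.columns else [1])
        for tp in time_points:
            sub = (kept[kept["time_point"] == tp]
                   if "time_point" in kept.columns else kept)
            data = TwinPairDataset.from_dataframe(
                sub, phenotype="glycan_age", covariates=("age",),
            )
            covs = ("age",) if config.adjust_for_age else ()
            sel = select_model(data, covariates=covs, seed=config.seed)
            best = sel.best_fit
            corr = intrapair_correlations(data)
            counts = data.counts()
            ci = best.conf_int()
            estimates.append({
                "time_point": int(tp),
                "n_mz_pairs": counts["MZ"],
                "n_dz_pairs": counts["DZ"],
                "rMZ": corr["rMZ"],
                "rDZ": corr["rDZ"],
                "best_model": sel.best,
                "h2": best.h2,
                "c2_std": best.c2_std,
                "e2_std": best.e2_std,
                "ci": {k: list(v) for k, v in ci.items()},
                "aic": {lab: fit.aic for lab, fit in sel.fits.items()},
                "lrt": {lab: {"statistic": s, "df": d, "p": p}
                        for lab, (s, d, p) in sel.lrt.items()},
                "adjusted_for_age": config.adjust_for_age,
            })
            logger.info("stage heritability: time point %s best=%s h2=%.3f",
                        tp, sel.best, best.h2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = HeritabilityReport(
        estimates=estimates,
        truth={k: v for k, v in truth.items() if k != "glycan_age"},
        config_hash=cfg_hash,
        seed=config.seed,
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out / "peak_table_raw.csv")
        percent.to_csv(out / "peak_table_preprocessed.csv")
        metadata.to_csv(out / "metadata.csv", index=False)
        glycan_age.to_csv(out / "glycan_age.csv", header=True)
        clock.to_json(out / "clock_model.json")
        with open(out / "exclusions.json", "w") as fh:
            json.dump({"removed_sample_ids": removed}, fh, indent=2)
        with open(out / "config.json", "w") as fh:
            json.dump(cfg_dict, fh, indent=2, default=str)
        report.to_json(out / "report.json")
    return report
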