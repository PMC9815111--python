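"""Maximum-likelihood twin variance decomposition (classical twin design).

The phenotype of a twin pair is modelled as bivariate normal with a
per-individual means model x'β and a zygosity-structured covariance

    Cov = [[v, ρ_z], [ρ_z, v]],   v = a² + c² + e²,
    ρ_MZ = a² + c²,   ρ_DZ = ½·a² + c²,

where a², c², e² are the additive-genetic (A), shared-environment (C) and
unique-environment (E) variance components.  MZ co-twins share their
additive-genetic value fully; DZ co-twins correlate 0.5 genetically; the
shared environment is common to both members regardless of zygosity; the
unique environment (which absorbs measurement error) is independent per
individual.  Heritability is h² = a²/v.

The likelihood is maximized over path coefficients (a, c, e) — their
squares are the variances, which enforces non-negativity without
constrained optimization — plus the means-model β, with multi-start
quasi-Newton optimization seeded from Falconer-style moment estimates.
Model reduction (ACE → AE / CE / E) uses likelihood-ratio tests against a
plain chi-square reference, and the best model is picked by AIC among
reductions the LRT did not reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from glycanclock.datasets import ValidationError, ZYGOSITIES

LOG2PI = float(np.log(2.0 * np.pi))

#: Weight of a² in the within-pair phenotypic covariance, by zygosity.
GENETIC_WEIGHT = {"MZ": 1.0, "DZ": 0.5}

COMPONENT_ORDER = ("A", "C", "E")


@dataclass(frozen=True)
class VarianceModelSpec:
    """A candidate variance model: which components are free, which
    covariates enter the means model.  E is always present (the residual
    variance must exist)."""

    components: tuple[str, ...] = ("A", "C", "E")
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        unknown = set(comps) - set(COMPONENT_ORDER)
        if unknown:
            raise ValidationError(f"unknown variance components: {sorted(unknown)}")
        if "E" not in comps:
            raise ValidationError("every variance model must include E")

    @property
    def label(self) -> str:
        return "".join(c for c in COMPONENT_ORDER if c in self.components)


class TwinPairDataset:
    """Phenotype duos grouped by zygosity, with optional covariates.

    Parameters
    ----------
    y1, y2
        Phenotypes of the two pair members, shape (n_pairs,).
    zygosity
        "MZ" or "DZ" per pair.
    X1, X2
        Optional per-member covariate matrices, shape (n_pairs, k),
        without an intercept column.
    covariate_names
        Names of the k covariate columns.
    """

    def __init__(self, y1, y2, zygosity, X1=None, X2=None,
                 covariate_names=()):
        self.y1 = np.asarray(y1, dtype=float)
        self.y2 = np.asarray(y2, dtype=float)
        self.zygosity = np.asarray(zygosity, dtype=object)
        if not (self.y1.shape == self.y2.shape == self.zygosity.shape):
            raise ValidationError("y1, y2 and zygosity must have equal length")
        bad = set(self.zygosity) - set(ZYGOSITIES)
        if bad:
            raise ValidationError(f"unknown zygosity codes: {sorted(bad)}")
        if not (np.isfinite(self.y1).all() and np.isfinite(self.y2).all()):
            raise ValidationError("phenotypes must be finite (no missing values "
                                  "within retained pairs)")
        self.covariate_names = tuple(covariate_names)
        k = len(self.covariate_names)
        if k:
            self.X1 = np.asarray(X1, dtype=float).reshape(len(self.y1), k)
            self.X2 = np.asarray(X2, dtype=float).reshape(len(self.y2), k)
            if not (np.isfinite(self.X1).all() and np.isfinite(self.X2).all()):
                raise ValidationError("covariates must be finite for every "
                                      "individual")
        else:
            self.X1 = np.empty((len(self.y1), 0))
            self.X2 = np.empty((len(self.y2), 0))

    @property
    def n_pairs(self) -> int:
        return len(self.y1)

    def counts(self) -> dict[str, int]:
        return {z: int(np.sum(self.zygosity == z)) for z in ZYGOSITIES}

    def subset_covariates(self, names) -> "TwinPairDataset":
        idx = []
        for name in names:
            if name not in self.covariate_names:
                raise ValidationError(f"covariate {name!r} not present in dataset")
            idx.append(self.covariate_names.index(name))
        return TwinPairDataset(
            self.y1, self.y2, self.zygosity,
            self.X1[:, idx], self.X2[:, idx], tuple(names),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str,
                       pair_col: str = "pair_id", zygosity_col: str = "zygosity",
                       covariates=()) -> "TwinPairDataset":
        """Pivot a long-format twin table (one row per individual) to pairs.

        Every pair must be complete; remove singletons upstream
        (see :func:`glycanclock.pipeline.exclude_singletons`).
        """
        covariates = tuple(covariates)
        for col in (phenotype, pair_col, zygosity_col, *covariates):
            if col not in df.columns:
                raise ValidationError(f"column {col!r} missing from twin table")
        y1, y2, zyg, X1, X2 = [], [], [], [], []
        for pid, grp in df.groupby(pair_col, sort=True):
            if len(grp) != 2:
                raise ValidationError(
                    f"pair {pid!r} has {len(grp)} members; exclude singletons "
                    "before building a TwinPairDataset"
                )
            a, b = grp.iloc[0], grp.iloc[1]
            if a[zygosity_col] != b[zygosity_col]:
                raise ValidationError(f"pair {pid!r} has mixed zygosity")
            y1.append(a[phenotype]); y2.append(b[phenotype])
            zyg.append(a[zygosity_col])
            X1.append([a[c] for c in covariates])
            X2.append([b[c] for c in covariates])
        return cls(np.array(y1), np.array(y2), np.array(zyg, dtype=object),
                   np.array(X1), np.array(X2), covariates)


def intrapair_correlations(data: TwinPairDataset) -> dict[str, float]:
    """Double-entry Pearson intrapair correlations rMZ and rDZ.

    Each pair contributes both orderings, so the result is invariant to
    arbitrary within-pair labelling.  Requires ≥ 2 pairs per zygosity.
    """
    out = {}
    for z in ZYGOSITIES:
        mask = data.zygosity == z
        if mask.sum() < 2:
            raise ValidationError(
                f"intrapair correlation needs ≥ 2 {z} pairs, got {int(mask.sum())}"
            )
        y1, y2 = data.y1[mask], data.y2[mask]
        # symmetric sufficient statistics keep the value bit-identical
        # under arbitrary within-pair relabelling
        m = (y1.sum() + y2.sum()) / (2.0 * len(y1))
        d1, d2 = y1 - m, y2 - m
        denom = (d1 * d1 + d2 * d2).sum()
        out["r" + z] = float(2.0 * (d1 * d2).sum() / denom)
    return out


class TwinVarianceModel:
    """ML twin variance-component model (statsmodels-style).

    Parameters
    ----------
    data
        A :class:`TwinPairDataset` of complete pairs.
    components
        Free variance components, a subset of ("A", "C", "E") containing E.
    covariates
        Covariate names (from the dataset) for the means model; the means
        model always includes a single intercept shared across zygosity
        groups.  Default: none.
    """

    def __init__(self, data: TwinPairDataset, components=("A", "C", "E"),
                 covariates=None):
        self.spec = VarianceModelSpec(
            tuple(c for c in COMPONENT_ORDER if c in tuple(components)),
            tuple(covariates or ()),
        )
        if self.spec.covariates:
            data = data.subset_covariates(self.spec.covariates)
        elif data.covariate_names:
            data = TwinPairDataset(data.y1, data.y2, data.zygosity)
        self.data = data
        counts = data.counts()
        if ("A" in self.spec.components or "C" in self.spec.components):
            if min(counts.values()) == 0:
                raise ValidationError(
                    "A and C are not separately identifiable with a single "
                    f"zygosity group (counts: {counts})"
                )
        # design matrices with intercept, per member
        n = data.n_pairs
        self._D1 = np.column_stack([np.ones(n), data.X1])
        self._D2 = np.column_stack([np.ones(n), data.X2])
        self._groups = {z: np.nonzero(data.zygosity == z)[0] for z in ZYGOSITIES
                        if np.any(data.zygosity == z)}
        self.k_beta = self._D1.shape[1]
        self.k_paths = len(self.spec.components)
        self.nparams = self.k_paths + self.k_beta
        self.exog_names = ["intercept", *self.spec.covariates]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, phenotype: str,
                       pair_col: str = "pair_id", zygosity_col: str = "zygosity",
                       components=("A", "C", "E"), covariates=()):
        data = TwinPairDataset.from_dataframe(
            df, phenotype, pair_col, zygosity_col, covariates
        )
        return cls(data, components=components, covariates=covariates)

    # -- likelihood ----------------------------------------------------

    def _unpack(self, params):
        paths = {c: 0.0 for c in COMPONENT_ORDER}
        for i, c in enumerate(self.spec.components):
            paths[c] = params[i]
        beta = np.asarray(params[self.k_paths:], dtype=float)
        return paths, beta

    def loglike(self, params) -> float:
        """Sum over pairs of the bivariate-normal log density.

        Returns -inf for parameter values with a singular or invalid
        pair covariance (e.g. e = 0 with a or c free).
        """
        paths, beta = self._unpack(params)
        a2, c2, e2 = paths["A"] ** 2, paths["C"] ** 2, paths["E"] ** 2
        v = a2 + c2 + e2
        r1 = self.data.y1 - self._D1 @ beta
        r2 = self.data.y2 - self._D2 @ beta
        ll = 0.0
        for z, idx in self._groups.items():
            rho = GENETIC_WEIGHT[z] * a2 + c2
            det = v * v - rho * rho
            if not (det > 0.0 and v > 0.0):
                return -np.inf
            u1, u2 = r1[idx], r2[idx]
            # grouping keeps the value bit-identical under member swap
            quad = (v * (u1 * u1 + u2 * u2)
                    - 2.0 * rho * (u1 * u2)).sum() / det
            ll += -len(idx) * (LOG2PI + 0.5 * np.log(det)) - 0.5 * quad
        return float(ll)

    # -- starting values -----------------------------------------------

    def _moment_start(self):
        y = np.concatenate([self.data.y1, self.data.y2])
        D = np.vstack([self._D1, self._D2])
        beta0, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta0
        V = float(resid.var())
        counts = self.data.counts()
        if min(counts.values()) >= 2:
            # Falconer-style decomposition from double-entry correlations
            rdata = TwinPairDataset(
                self.data.y1 - self._D1 @ beta0,
                self.data.y2 - self._D2 @ beta0,
                self.data.zygosity,
            )
            r = intrapair_correlations(rdata)
            a2 = 2.0 * (r["rMZ"] - r["rDZ"]) * V
            c2 = (2.0 * r["rDZ"] - r["rMZ"]) * V
            e2 = (1.0 - r["rMZ"]) * V
        else:
            a2 = c2 = e2 = V / 3.0
        floor = 1e-3 * V
        comp = {"A": max(a2, floor), "C": max(c2, floor), "E": max(e2, floor)}
        active = {c: comp[c] for c in self.spec.components}
        scale = V / sum(active.values())
        paths = [np.sqrt(active[c] * scale) for c in self.spec.components]
        return np.concatenate([paths, beta0])

    def fit(self, start=None, n_starts: int = 5, seed: int = 0,
            maxiter: int = 500) -> "TwinVarianceResults":
        """Maximize the likelihood; best of ``n_starts`` perturbed starts."""
        base = np.asarray(start, dtype=float) if start is not None \
            else self._moment_start()
        if base.shape != (self.nparams,):
            raise ValidationError(
                f"start must have {self.nparams} entries "
                f"({self.k_paths} paths + {self.k_beta} means coefficients)"
            )
        rng = np.random.default_rng(seed)
        starts = [base]
        for _ in range(n_starts - 1):
            pert = base.copy()
            pert[: self.k_paths] *= np.exp(rng.normal(0.0, 0.4, self.k_paths))
            pert[self.k_paths:] += rng.normal(
                0.0, 0.1 * (1.0 + np.abs(base[self.k_paths:]))
            )
            starts.append(pert)

        def nll(p):
            val = self.loglike(p)
            return 1e12 if not np.isfinite(val) else -val

        best = None
        for s in starts:
            res = optimize.minimize(
                nll, s, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        params = best.x.copy()
        params[: self.k_paths] = np.abs(params[: self.k_paths])  # sign ambiguity
        return TwinVarianceResults(self, params, float(-best.fun),
                                   converged=bool(best.success))


def _numerical_hessian(f, x, rel_step=1e-4):
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


class TwinVarianceResults:
    """Fitted twin variance model: estimates, proportions, CIs, AIC.

    Attributes
    ----------
    a2, c2, e2 : float
        Variance components in phenotype units² (0 when absent from the
        model).
    h2, c2_std, e2_std : float
        Standardized proportions (sum to 1); h² is the heritability.
    beta : ndarray
        Means-model coefficients (intercept first).
    llf, aic : float
        Maximized log-likelihood and Akaike information criterion
        2k − 2·logL, k = free path coefficients + means coefficients.
    """

    def __init__(self, model: TwinVarianceModel, params: np.ndarray,
                 llf: float, converged: bool = True):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        paths, beta = model._unpack(self.params)
        self.a2 = paths["A"] ** 2
        self.c2 = paths["C"] ** 2
        self.e2 = paths["E"] ** 2
        self.beta = beta
        self.total_variance = self.a2 + self.c2 + self.e2
        self.h2 = self.a2 / self.total_variance
        self.c2_std = self.c2 / self.total_variance
        self.e2_std = self.e2 / self.total_variance
        self.nobs = model.data.n_pairs
        self.n_params = model.nparams
        self._prop_cov = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def proportions(self) -> dict[str, float]:
        return {"A": self.h2, "C": self.c2_std, "E": self.e2_std}

    # -- uncertainty ----------------------------------------------------

    def _proportion_se(self) -> dict[str, float]:
        """Delta-method standard errors of the standardized proportions.

        Uses a numerical Hessian of the log-likelihood at the optimum;
        near a boundary (a path coefficient at 0) the curvature can be
        singular and the pseudo-inverse makes these approximate.
        """
        if self._prop_cov is None:
            H = _numerical_hessian(lambda p: -self.model.loglike(p), self.params)
            cov = np.linalg.pinv(H)
            self._prop_cov = cov
        cov = self._prop_cov
        comps = self.model.spec.components
        paths = self.params[: self.model.k_paths]
        v = self.total_variance
        ses = {}
        for comp in ("A", "C", "E"):
            grad = np.zeros(self.model.nparams)
            if comp in comps and v > 0:
                x2 = {"A": self.a2, "C": self.c2, "E": self.e2}[comp]
                for j, cj in enumerate(comps):
                    pj = paths[j]
                    # d(x²/v)/d p_j = (2p_j·[j==comp]·v − x²·2p_j)/v²
                    grad[j] = (2.0 * pj * (cj == comp) * v - x2 * 2.0 * pj) / v**2
            var = float(grad @ cov @ grad)
            ses[comp] = float(np.sqrt(max(var, 0.0)))
        return ses

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """Delta-method CIs for the standardized proportions, clipped to
        [0, 1].  The source study reports none; these are an additive
        diagnostic."""
        zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
        ses = self._proportion_se()
        out = {}
        for comp, p in self.proportions.items():
            lo = max(0.0, p - zcrit * ses[comp])
            hi = min(1.0, p + zcrit * ses[comp])
            out[comp] = (lo, hi)
        return out

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "model": self.model.spec.label,
            "covariates": list(self.model.spec.covariates),
            "a2": self.a2, "c2": self.c2, "e2": self.e2,
            "h2": self.h2, "c2_std": self.c2_std, "e2_std": self.e2_std,
            "beta": {n: float(b) for n, b in
                     zip(self.model.exog_names, self.beta)},
            "loglik": self.llf, "n_params": self.n_params, "aic": self.aic,
            "n_pairs": self.nobs, "ci": {k: list(v) for k, v in ci.items()},
            "converged": self.converged,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        counts = self.model.data.counts()
        lines = [
            f"Twin variance model: {self.model.spec.label}",
            f"  pairs: {self.nobs} (MZ {counts['MZ']}, DZ {counts['DZ']})",
            f"  log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}   "
            f"params: {self.n_params}",
            f"  total variance: {self.total_variance:.4f}",
            "  component  variance  proportion     95% CI",
        ]
        for comp, var in (("A", self.a2), ("C", self.c2), ("E", self.e2)):
            p = self.proportions[comp]
            lo, hi = ci[comp]
            lines.append(
                f"      {comp}     {var:9.4f}   {p:8.4f}   [{lo:.3f}, {hi:.3f}]"
            )
        lines.append("  means model: " + ", ".join(
            f"{n}={b:.4f}" for n, b in zip(self.model.exog_names, self.beta)))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of standardized variance proportions with CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        ci = self.conf_int()
        comps = list(self.proportions)
        vals = [self.proportions[c] for c in comps]
        err = np.array([[vals[i] - ci[c][0], ci[c][1] - vals[i]]
                        for i, c in enumerate(comps)]).T
        ax.bar(comps, vals, yerr=err, capsize=4,
               color=["#4C72B0", "#DD8452", "#55A868"])
        ax.set_ylabel("proportion of variance")
        ax.set_ylim(0, 1)
        ax.set_title(f"{self.model.spec.label} decomposition")
        return ax


# -- functional interface ------------------------------------------------


def pair_loglik(params: dict, data: TwinPairDataset,
                spec: VarianceModelSpec | None = None) -> float:
    """Log-likelihood at explicit path coefficients and means-model beta.

    ``params`` maps component letters to path coefficients (e.g.
    ``{"a": 0.6, "e": 0.4}``) and "beta" to the means coefficients
    (intercept first).  ``e`` must be nonzero: with e = 0 the pair
    covariance is singular.
    """
    spec = spec or VarianceModelSpec(
        tuple(c for c in COMPONENT_ORDER if params.get(c.lower()) is not None),
        (),
    )
    e = params.get("e", 0.0)
    if e == 0.0:
        raise ValidationError("e = 0 gives a singular pair covariance")
    model = TwinVarianceModel(data, components=spec.components,
                              covariates=spec.covariates)
    theta = [params.get(c.lower(), 0.0) for c in spec.components]
    beta = np.atleast_1d(np.asarray(params.get("beta", [0.0]), dtype=float))
    return model.loglike(np.concatenate([theta, beta]))


def fit_model(data: TwinPairDataset, spec: VarianceModelSpec | tuple = ("A", "C", "E"),
              start=None, seed: int = 0) -> TwinVarianceResults:
    """Fit one variance model specification by maximum likelihood."""
    if not isinstance(spec, VarianceModelSpec):
        spec = VarianceModelSpec(tuple(spec), ())
    model = TwinVarianceModel(data, components=spec.components,
                              covariates=spec.covariates)
    return model.fit(start=start, seed=seed)


@dataclass
class ModelSelectionResult:
    """Trace of nested-model selection.

    ``fits`` holds the fitted candidates by label; ``lrt`` the reduction
    tests against the full ACE model as (statistic, df, p); ``best`` is
    the chosen label.
    """

    fits: dict[str, TwinVarianceResults]
    lrt: dict[str, tuple[float, int, float]]
    best: str
    alpha: float = 0.05

    @property
    def best_fit(self) -> TwinVarianceResults:
        return self.fits[self.best]

    def to_dict(self) -> dict:
        return {
            "best": self.best,
            "alpha": self.alpha,
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
            "lrt": {k: {"statistic": s, "df": d, "p": p}
                    for k, (s, d, p) in self.lrt.items()},
        }

    def summary(self) -> str:
        lines = [f"Model selection (alpha = {self.alpha}):",
                 "  model  k   logL        AIC       LRT vs ACE (stat, df, p)"]
        for label, fit in self.fits.items():
            if label in self.lrt:
                s, d, p = self.lrt[label]
                tail = f"{s:8.3f}  {d}  {p:.4f}"
            else:
                tail = "       —"
            lines.append(f"  {label:<5} {fit.n_params}  {fit.llf:10.3f} "
                         f"{fit.aic:10.3f}   {tail}")
        lines.append(f"  best model: {self.best}")
        lines.append(self.fits[self.best].summary())
        return "\n".join(lines)


def select_model(data: TwinPairDataset, covariates=(), alpha: float = 0.05,
                 seed: int = 0) -> ModelSelectionResult:
    """Sequential reduction of the full ACE model with LRT + AIC choice.

    Fits ACE, AE, CE and E; tests each reduction against ACE with a
    likelihood-ratio statistic 2·(logL_ACE − logL_reduced) on df = number
    of dropped components (plain chi-square reference; conservative at
    the a²=0 / c²=0 boundary).  The best model is the minimum-AIC
    candidate among ACE and the reductions whose LRT did not reject at
    ``alpha``; AIC ties (within 1e-9) go to the model with fewer
    parameters.
    """
    covariates = tuple(covariates)
    specs = {
        "ACE": ("A", "C", "E"),
        "AE": ("A", "E"),
        "CE": ("C", "E"),
        "E": ("E",),
    }
    fits: dict[str, TwinVarianceResults] = {}
    for label, comps in specs.items():
        model = TwinVarianceModel(data, components=comps, covariates=covariates)
        fits[label] = model.fit(seed=seed)
    full = fits["ACE"]
    lrt: dict[str, tuple[float, int, float]] = {}
    for label in ("AE", "CE", "E"):
        df = full.model.k_paths - fits[label].model.k_paths
        statistic = max(0.0, 2.0 * (full.llf - fits[label].llf))
        p = float(stats.chi2.sf(statistic, df))
        lrt[label] = (statistic, df, p)
    candidates = ["ACE"] + [lab for lab in ("AE", "CE", "E")
                            if lrt[lab][2] > alpha]
    min_aic = min(fits[lab].aic for lab in candidates)
    tied = [lab for lab in candidates if fits[lab].aic <= min_aic + 1e-9]
    best = min(tied, key=lambda lab: (fits[lab].n_params, lab))
    return ModelSelectionResult(fits=fits, lrt=lrt, best=best, alpha=alpha)


def heritability_with_covariate(data: TwinPairDataset, covariate: str = "age",
                                alpha: float = 0.05,
                                seed: int = 0) -> ModelSelectionResult:
    """Model selection with a per-individual covariate in the means model.

    The variance components then describe residual variation around the
    covariate-adjusted mean; with twins sharing their covariate (age),
    this typically moves variance out of C.
    """
    if covariate not in data.covariate_names:
        raise ValidationError(f"covariate {covariate!r} missing from dataset")
    return select_model(data, covariates=(covariate,), alpha=alpha, seed=seed)
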