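"""Quadratic-time linear mixed-effect trajectories of taxon abundance.

For one taxon, abundance is modelled over days since RT start as

    y ~ 1 + days + days^2 + group + days:group + days^2:group
        + antihormone + age [+ the other clinical factor]
        + (1 | patient)

fitted by REML. ``group`` is the analysis factor (toxicity or RT field) and
always interacts with the linear and quadratic day terms. Predictive
margins evaluate the fixed-effect predictor per group on a day grid,
averaging over the cohort's observed covariate distribution (identical to
at-means for a linear predictor); the group contrast at each day is tested
with a delta-method chi-squared statistic (df 1).

Model construction, margins, contrasts and inference are own code; the REML
optimization itself is delegated to statsmodels' MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .containers import AbundanceTable, CohortMetadata

__all__ = ["LmeSpec", "MarginsResult", "QuadraticLME", "fit_lme", "predictive_margins"]

_FACTOR_ENCODING = {"field": {"local": 0, "large": 1}}


@dataclass
class LmeSpec:
    """Which taxon to model and with which factor/covariates."""

    response: str
    group: str = "toxicity"  # 'toxicity' or 'field'
    covariates: tuple = ("antihormone", "age")
    include_other_factor: bool = True
    log_response: bool = False
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if self.group not in ("toxicity", "field"):
            raise ValueError("group must be 'toxicity' or 'field'")
        self.covariates = tuple(self.covariates)


@dataclass
class MarginsResult:
    """Per-day group margins, their contrast, and chi-squared inference."""

    frame: pd.DataFrame  # day, margin_0, se_0, margin_1, se_1, contrast, ...
    group: str
    extrapolated_days: tuple = field(default_factory=tuple)


def _encode(col: pd.Series, name: str) -> np.ndarray:
    mapping = _FACTOR_ENCODING.get(name)
    if mapping is not None and col.dtype == object:
        unknown = set(col) - set(mapping)
        if unknown:
            raise ValueError(f"unknown {name} level(s) {sorted(unknown)}")
        return col.map(mapping).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


class QuadraticLME(BaseEstimator):
    """Random-intercept LME with a quadratic day-by-group interaction.

    Parameters
    ----------
    group : str
        Analysis factor, ``'toxicity'`` or ``'field'``; interacts with days
        and days^2.
    covariates : tuple of str
        Additional fixed effects taken from the data as-is.
    include_other_factor : bool
        Also adjust for the non-analysis factor (field when group=toxicity,
        toxicity when group=field).
    include_group_terms : bool
        If False, fit a group-free trajectory (no group main effect or
        interactions); margins then coincide between levels and every
        contrast is exactly 0 with p = 1.

    Fitted attributes: ``params_``, ``cov_params_``, ``feature_names_``,
    ``random_intercept_var_``, ``residual_var_``, ``converged_``.
    """

    def __init__(
        self,
        group: str = "toxicity",
        covariates: tuple = ("antihormone", "age"),
        include_other_factor: bool = True,
        include_group_terms: bool = True,
    ):
        self.group = group
        self.covariates = covariates
        self.include_other_factor = include_other_factor
        self.include_group_terms = include_group_terms

    # -- design construction ------------------------------------------------
    def _design(self, data: pd.DataFrame) -> pd.DataFrame:
        g = _encode(data[self.group], self.group)
        days = data["days"].to_numpy(dtype=float)
        cols = {
            "Intercept": np.ones(len(data)),
            "days": days,
            "days2": days**2,
        }
        if self.include_group_terms:
            cols[self.group] = g
            cols[f"days:{self.group}"] = days * g
            cols[f"days2:{self.group}"] = days**2 * g
        for c in self.covariates:
            cols[c] = _encode(data[c], c)
        if self.include_other_factor:
            other = "field" if self.group == "toxicity" else "toxicity"
            if other in data.columns:
                cols[other] = _encode(data[other], other)
        return pd.DataFrame(cols, index=data.index)

    def fit(self, data: pd.DataFrame, response_col: str = "response"):
        """Fit by REML. ``data`` needs response, days, patient_id, the group
        factor and the covariate columns."""
        y = data[response_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        X = self._design(data)
        arr = X.to_numpy()
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            _, _, piv = qr(arr, pivoting=True)
            collinear = [X.columns[i] for i in piv[rank:]]
            raise ValueError(f"singular design; collinear term(s): {collinear}")
        groups = data["patient_id"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, arr, groups=groups)
            res = model.fit(reml=True)
        k = arr.shape[1]
        self.feature_names_ = list(X.columns)
        self.params_ = pd.Series(res.fe_params, index=self.feature_names_)
        cov = np.asarray(res.cov_params())[:k, :k]
        self.cov_params_ = pd.DataFrame(
            cov, index=self.feature_names_, columns=self.feature_names_
        )
        self.random_intercept_var_ = float(np.asarray(res.cov_re).ravel()[0])
        self.residual_var_ = float(res.scale)
        self.converged_ = bool(res.converged)
        self.train_data_ = data.reset_index(drop=True)
        self.observed_day_range_ = (float(data["days"].min()), float(data["days"].max()))
        if not self.converged_:
            warnings.warn("mixed-model REML did not report convergence", stacklevel=2)
        return self

    # -- margins ------------------------------------------------------------
    def _margin_row(self, day: float, level: float) -> np.ndarray:
        """Fixed-effect design row at (day, group level), covariates averaged
        over the training observations. For a linear predictor this equals
        evaluation at covariate means."""
        d = self.train_data_.copy()
        d["days"] = day
        d[self.group] = level if self.group != "field" else (
            "large" if level == 1 else "local"
        ) if d[self.group].dtype == object else level
        X = self._design(d)
        return X.to_numpy().mean(axis=0)

    def margins(self, grid_days, levels=(0, 1)) -> MarginsResult:
        """Predictive margins per group over a day grid, with contrasts."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit must be called before margins")
        if not self.converged_:
            warnings.warn(
                "margins computed from a fit that did not report convergence",
                stacklevel=2,
            )
        beta = self.params_.to_numpy()
        cov = self.cov_params_.to_numpy()
        lo, hi = self.observed_day_range_
        span = hi - lo
        extrapolated = []
        rows = []
        for day in grid_days:
            day = float(day)
            if day < lo - 0.1 * span or day > hi + 0.1 * span:
                extrapolated.append(day)
            x0 = self._margin_row(day, levels[0])
            x1 = self._margin_row(day, levels[1])
            m0, m1 = float(x0 @ beta), float(x1 @ beta)
            se0 = float(np.sqrt(max(x0 @ cov @ x0, 0.0)))
            se1 = float(np.sqrt(max(x1 @ cov @ x1, 0.0)))
            dx = x1 - x0
            contrast = float(dx @ beta)
            c_se = float(np.sqrt(max(dx @ cov @ dx, 0.0)))
            if c_se > 0:
                chi2 = (contrast / c_se) ** 2
                p = float(chi2_dist.sf(chi2, 1))
            else:
                chi2, p = 0.0, 1.0
            rows.append(
                {
                    "day": day,
                    "margin_0": m0,
                    "se_0": se0,
                    "margin_1": m1,
                    "se_1": se1,
                    "contrast": contrast,
                    "contrast_se": c_se,
                    "chi2": chi2,
                    "p_value": p,
                }
            )
        if extrapolated:
            warnings.warn(
                f"margin grid extrapolates beyond observed days: {extrapolated}",
                stacklevel=2,
            )
        return MarginsResult(pd.DataFrame(rows), self.group, tuple(extrapolated))


def _response_frame(
    table: AbundanceTable, metadata: CohortMetadata, spec: LmeSpec
) -> pd.DataFrame:
    rel = table if table.unit == "proportions" else table.relative_abundance()
    if spec.response not in rel.values.index:
        raise KeyError(f"taxon {spec.response!r} not in the table")
    meta = metadata.align(rel).frame.copy()
    y = rel.values.loc[spec.response].to_numpy()
    meta["response"] = (
        np.log10(y + spec.pseudocount) if spec.log_response else y
    )
    return meta


def fit_lme(
    table: AbundanceTable, metadata: CohortMetadata, spec: LmeSpec
) -> QuadraticLME:
    """Fit the quadratic-day random-intercept LME for one taxon."""
    data = _response_frame(table, metadata, spec)
    est = QuadraticLME(
        group=spec.group,
        covariates=spec.covariates,
        include_other_factor=spec.include_other_factor,
    )
    return est.fit(data)


def predictive_margins(model: QuadraticLME, grid_days, levels=(0, 1)) -> MarginsResult:
    """Margins and group contrasts of a fitted model (thin wrapper)."""
    return model.margins(grid_days, levels=levels)
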