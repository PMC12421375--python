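"""Mixed-model inference for drought-induced growth responses.

Two model families, both linear mixed models on log growth-response ratios:

* :class:`SingleYearDroughtModel` -- the cross-site model of responses to
  the first (severe) drought year. Fixed effects are the three-way
  interaction of a neighborhood diversity moderator (nSR or normalized
  FD_HSM), the focal species' hydraulic safety margin, and a site-level
  drought covariate (REWmin, SPEI, or drought days), plus controls for
  standardized tree size, competition, age, and the preceding year's
  drought conditions. Random intercepts: plot nested within site.

* :class:`ConsecutiveDroughtModel` -- the site-specific model of responses
  across consecutive drought years. The response year enters as a
  categorical effect with the global intercept suppressed, so each year
  level measures mean log response relative to pre-drought growth; the
  diversity moderator and the safety margin interact with the year, and a
  tree-level random intercept absorbs repeated measures. Drought covariates
  are excluded by construction (they would be confounded with the year).

Both are thin, opinionated fronts over statsmodels' MixedLM: ``fit()``
(REML by default) returns a :class:`DroughtModelResults` carrying estimates,
Wald-t inference, variance components, Nakagawa marginal/conditional R2, and
AIC from a maximum-likelihood refit (REML likelihoods are not comparable
across fixed-effect sets, so model comparison always uses ML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ModelSpec",
    "SingleYearDroughtModel",
    "ConsecutiveDroughtModel",
    "DroughtModelResults",
    "compare_models",
    "marginal_effects",
    "r2_nakagawa",
    "DegenerateFitError",
    "RankDeficientError",
]

DIVERSITY_MODERATORS = ("nSR", "FD_HSM_norm")
DROUGHT_COVARIATES = ("SPEI12", "SPEI6_AprSep", "REWmin", "DrDays_12m", "DrDays_AprSep")


class DegenerateFitError(ValueError):
    """Response has (near-)zero variance; a mixed model cannot be fitted."""


class RankDeficientError(ValueError):
    """Fixed-effect design matrix is rank deficient; names the culprit terms."""


@dataclass
class ModelSpec:
    """Declarative description of one growth-response model.

    kind: 'single_year' (cross-site, m1-style) or 'consecutive'
    (site-specific, m2-style). ``drought_cov`` must be None for consecutive
    models. ``preceding_cov`` names the preceding-year drought control,
    matched in kind to ``drought_cov`` by default.
    """

    kind: str = "single_year"
    response_metric: str = "BIOMinc"
    diversity: str = "FD_HSM_norm"
    drought_cov: str | None = "auto"
    interaction_order: int = 3
    include_age: bool = True
    preceding_cov: str | None = None
    hegyi_group: str = "site"
    center_hsm: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("single_year", "consecutive"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.diversity not in DIVERSITY_MODERATORS:
            raise ValueError(f"diversity moderator must be one of {DIVERSITY_MODERATORS}")
        if self.drought_cov == "auto":
            self.drought_cov = "REWmin" if self.kind == "single_year" else None
        if self.kind == "consecutive" and self.drought_cov is not None:
            raise ValueError(
                "consecutive-year models exclude drought covariates: they would "
                "confound the categorical response-year effect"
            )
        if self.drought_cov is not None and self.drought_cov not in DROUGHT_COVARIATES:
            raise ValueError(f"drought covariate must be one of {DROUGHT_COVARIATES}")
        if self.preceding_cov is None and self.drought_cov is not None:
            self.preceding_cov = f"prev_{self.drought_cov}"
        if not self.name:
            tag = "m1" if self.kind == "single_year" else "m2"
            sub = "a" if self.diversity == "nSR" else "b"
            self.name = f"{tag}{sub}"


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, scanning left to right
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(names[j])
            else:
                cols.append(j)
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} columns; inestimable terms: {bad}"
        )


class _BaseModel:
    """Shared construction and fitting for the two model families."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.data = data.reset_index(drop=True)
        if "log_response" not in self.data:
            raise ValueError("data must contain a log_response column")
        resp = self.data["log_response"].to_numpy(dtype=float)
        if not np.all(np.isfinite(resp)):
            raise ValueError("log_response contains non-finite values")
        if np.var(resp) < 1e-12:
            raise DegenerateFitError("log_response has zero variance")
        self.formula = self._build_formula()
        y, X = patsy.dmatrices(self.formula, self.data, return_type="dataframe")
        _check_design(X.to_numpy(), list(X.columns))
        self._y = y
        self._X = X

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **spec_kwargs) -> "_BaseModel":
        return cls(data, ModelSpec(kind=cls.KIND, **spec_kwargs))

    def _build_formula(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError

    def _make_mixedlm(self) -> MixedLM:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, reml: bool = True, ml_refit: bool = True, **fit_kwargs) -> "DroughtModelResults":
        """Fit by REML (default) and attach an ML refit for AIC comparison.

        ``ml_refit=False`` skips the extra maximum-likelihood pass (halving
        the cost) at the price of making AIC unavailable.
        """
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = self._make_mixedlm().fit(reml=reml, **fit_kwargs)
            if reml and ml_refit:
                res_ml = self._make_mixedlm().fit(reml=False, **fit_kwargs)
            else:
                res_ml = None if reml else res
        messages = sorted({str(w.message) for w in caught})
        return DroughtModelResults(self, res, res_ml, reml=reml, warnings=messages)


class SingleYearDroughtModel(_BaseModel):
    """Cross-site model of log growth response in the first drought year.

    One record per focal tree. Expected columns: log_response, the diversity
    moderator, HSM_TLP, BA_z, Hegyi_z, site_id, plot_id, and (for 3-way
    specs) the site-level drought covariate plus its preceding-year control
    and age_z.
    """

    KIND = "single_year"

    def _build_formula(self) -> str:
        s = self.spec
        hsm = "center(HSM_TLP)" if s.center_hsm else "HSM_TLP"
        if s.drought_cov and s.interaction_order == 3:
            core = f"{s.diversity} * {hsm} * center({s.drought_cov})"
        else:
            core = f"{s.diversity} * {hsm}"
        terms = [core, "BA_z", "Hegyi_z"]
        if s.include_age and "age_z" in self.data:
            terms.append("age_z")
        if s.preceding_cov and s.preceding_cov in self.data:
            terms.append(s.preceding_cov)
        return "log_response ~ " + " + ".join(terms)

    def _make_mixedlm(self) -> MixedLM:
        return MixedLM.from_formula(
            self.formula,
            self.data,
            groups="site_id",
            re_formula="1",
            vc_formula={"plot": "0 + C(plot_id)"},
        )


class ConsecutiveDroughtModel(_BaseModel):
    """Site-specific model of log responses across consecutive drought years.

    Long format: one record per focal tree per labeled response year.
    Expected columns: log_response, resp_yr (1..4), the diversity moderator,
    HSM_TLP, BA_z, Hegyi_z, tree_id. The intercept is suppressed so each
    response-year level estimates the mean log response relative to
    pre-drought growth; missing year levels for a tree raise an error.
    """

    KIND = "consecutive"

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        levels = sorted(data["resp_yr"].unique())
        counts = data.groupby("tree_id")["resp_yr"].nunique()
        missing = counts[counts < len(levels)]
        if len(missing):
            raise ValueError(
                f"{len(missing)} tree(s) missing response-year levels: "
                f"{list(missing.index[:5])}"
            )
        super().__init__(data, spec)

    def _build_formula(self) -> str:
        s = self.spec
        hsm = "center(HSM_TLP)" if s.center_hsm else "HSM_TLP"
        return (
            "log_response ~ 0 + C(resp_yr)"
            f" + C(resp_yr):{s.diversity}"
            f" + C(resp_yr):{hsm}"
            f" + {s.diversity}:{hsm}"
            " + BA_z + Hegyi_z"
        )

    def _make_mixedlm(self) -> MixedLM:
        return MixedLM.from_formula(self.formula, self.data, groups="tree_id", re_formula="1")


@dataclass
class DroughtModelResults:
    """Estimates, uncertainty, and diagnostics of a fitted response model.

    Fixed effects come from the (default REML) fit; AIC always from the ML
    refit. Wald t inference uses residual-based denominator degrees of
    freedom (n_obs - fixed-effect rank - n_groups), recorded in
    ``metadata['df_method']``.
    """

    model: _BaseModel
    _res: object
    _res_ml: object
    reml: bool = True
    warnings: list[str] = field(default_factory=list)

    # -- basic accessors ----------------------------------------------------
    @property
    def converged(self) -> bool:
        return bool(getattr(self._res, "converged", False))

    @property
    def fe_names(self) -> list[str]:
        return list(self._res.fe_params.index)

    @property
    def params(self) -> pd.Series:
        return self._res.fe_params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse_fe

    @property
    def df_resid(self) -> float:
        n = self._res.model.exog.shape[0]
        k = self._res.model.exog.shape[1]
        ngroups = len(self._res.model.group_labels)
        return float(max(n - k - ngroups, 1))

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues.to_numpy()), self.df_resid),
            index=self.fe_names,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- variance components ------------------------------------------------
    @property
    def sigma2_resid(self) -> float:
        return float(self._res.scale)

    @property
    def variance_components(self) -> dict[str, float]:
        out = {}
        cov_re = np.atleast_2d(self._res.cov_re)
        if cov_re.size:
            out["group"] = float(cov_re[0, 0])
        vc = getattr(self._res, "vcomp", None)
        if vc is not None and len(np.atleast_1d(vc)):
            names = getattr(self._res.model, "exog_vc", None)
            vc_names = (
                list(self._res.model.exog_vc.names)
                if names is not None and hasattr(self._res.model.exog_vc, "names")
                else [f"vc{i}" for i in range(len(np.atleast_1d(vc)))]
            )
            for nm, v in zip(vc_names, np.atleast_1d(vc)):
                out[str(nm)] = float(v)
        out["residual"] = self.sigma2_resid
        return out

    @property
    def singular(self) -> bool:
        vcs = self.variance_components
        total = sum(vcs.values())
        return any(v / total < 1e-6 for k, v in vcs.items() if k != "residual")

    # -- fit statistics ------------------------------------------------------
    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def aic(self) -> float:
        """AIC from the ML refit: -2 llf + 2 (k_fixed + k_variance)."""
        if self._res_ml is None:
            raise ValueError("AIC unavailable: model was fitted with ml_refit=False")
        k = len(self._res_ml.fe_params) + len(self._params_var(self._res_ml))
        return float(-2.0 * self._res_ml.llf + 2.0 * k)

    @staticmethod
    def _params_var(res) -> list[float]:
        out = [float(res.scale)]
        cov_re = np.atleast_2d(res.cov_re)
        if cov_re.size:
            out.append(float(cov_re[0, 0]))
        vc = getattr(res, "vcomp", None)
        if vc is not None:
            out.extend(float(v) for v in np.atleast_1d(vc))
        return out

    def r2(self) -> tuple[float, float]:
        return r2_nakagawa(self)

    @property
    def nobs(self) -> int:
        return int(self._res.model.exog.shape[0])

    @property
    def metadata(self) -> dict:
        return {
            "kind": self.model.spec.kind,
            "name": self.model.spec.name,
            "formula": self.model.formula,
            "estimation": "REML" if self.reml else "ML",
            "df_method": "residual (n_obs - rank - n_groups)",
            "aic_basis": "ML refit",
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.nobs,
            "warnings": self.warnings,
        }

    def coefficient_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_lower": ci["lower"],
                "ci_upper": ci["upper"],
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary (coefficients, variances, fit stats)."""
        r2m, r2c = self.r2()
        lines = [
            f"{self.model.spec.name}: {self.model.formula}",
            f"  estimation: {'REML' if self.reml else 'ML'}   n_obs: {self.nobs}"
            f"   converged: {self.converged}" + ("   SINGULAR" if self.singular else ""),
            f"  logLik: {self.llf:.2f}   AIC (ML): {self.aic:.2f}"
            f"   R2 marginal: {r2m:.3f}   conditional: {r2c:.3f}",
            "",
            self.coefficient_table().to_string(float_format=lambda v: f"{v: .4f}"),
            "",
            "  variance components: "
            + ", ".join(f"{k}={v:.4g}" for k, v in self.variance_components.items()),
        ]
        return "\n".join(lines)

    # -- predictions ----------------------------------------------------------
    def predict_fixed(self, new_data: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
        """Fixed-effect predictions with Wald confidence bands."""
        design_info = self._res.model.data.design_info
        (X,) = patsy.build_design_matrices([design_info], new_data, return_type="dataframe")
        beta = self.params.to_numpy()
        cov = np.asarray(self._res.cov_params())[: len(beta), : len(beta)]
        pred = X.to_numpy() @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X.to_numpy(), cov, X.to_numpy()))
        q = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        out = new_data.copy()
        out["predicted"] = pred
        out["se"] = se
        out["ci_lower"] = pred - q * se
        out["ci_upper"] = pred + q * se
        return out


def compare_models(fits: list[DroughtModelResults]) -> pd.DataFrame:
    """Rank fitted models by AIC (always from maximum-likelihood refits).

    All fits must be on identical response vectors; REML likelihoods are not
    comparable across fixed-effect sets, hence the ML basis.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = np.sort(fits[0].model.data["log_response"].to_numpy())
    for f in fits[1:]:
        other = np.sort(f.model.data["log_response"].to_numpy())
        if ref.shape != other.shape or not np.allclose(ref, other):
            raise ValueError("models fitted to different response vectors")
    rows = [
        {"name": f.model.spec.name, "formula": f.model.formula, "AIC": f.aic, "llf_ml": float(f._res_ml.llf)}
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def marginal_effects(
    fit: DroughtModelResults,
    focus: dict[str, list],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fixed-effect predictions over a grid of the focus predictors.

    ``focus`` maps predictor names to grid values (e.g. diversity at
    {0, 0.3, 0.6}, HSM at {0.8, 1.5}, a drought covariate at its observed
    quartiles). All other numeric covariates are held at 0 (their
    standardized center); categoricals at their reference level. Grid points
    outside the observed range of a predictor are flagged ``extrapolated``
    with a warning.
    """
    if not fit.converged:
        raise ValueError("marginal effects require a converged fit")
    data = fit.model.data
    grids = [list(v) for v in focus.values()]
    names = list(focus.keys())
    combos = list(__import__("itertools").product(*grids))
    base: dict[str, object] = {}
    for col in data.columns:
        if col in names or col == "log_response":
            continue
        if pd.api.types.is_numeric_dtype(data[col]):
            base[col] = 0.0
        else:
            base[col] = data[col].iloc[0]
    rows = []
    for combo in combos:
        row = dict(base)
        row.update(dict(zip(names, combo)))
        rows.append(row)
    grid_df = pd.DataFrame(rows)
    out = fit.predict_fixed(grid_df, alpha=alpha)
    extrap = np.zeros(len(out), dtype=bool)
    for nm in names:
        if pd.api.types.is_numeric_dtype(data[nm]):
            lo, hi = data[nm].min(), data[nm].max()
            extrap |= (out[nm] < lo) | (out[nm] > hi)
    if extrap.any():
        warnings.warn(
            f"{int(extrap.sum())} grid point(s) outside the observed predictor range",
            RuntimeWarning,
            stacklevel=2,
        )
    out["extrapolated"] = extrap
    keep = names + ["predicted", "se", "ci_lower", "ci_upper", "extrapolated"]
    return out[keep]


def r2_nakagawa(fit: DroughtModelResults) -> tuple[float, float]:
    """Marginal and conditional R2 for a mixed model.

    marginal = var(fixed predictions) / (var(fixed) + sum(random variances)
    + residual variance); conditional adds the random variances to the
    numerator. Conditional >= marginal always.
    """
    res = fit._res
    X = np.asarray(res.model.exog)
    beta = res.fe_params.to_numpy()
    var_f = float(np.var(X @ beta))
    vcs = fit.variance_components
    var_r = sum(v for k, v in vcs.items() if k != "residual")
    var_e = vcs["residual"]
    total = var_f + var_r + var_e
    return var_f / total, (var_f + var_r) / total
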