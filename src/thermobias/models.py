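"""Nested mixed-effects models linking thermal bias to occupancy responses.

Three model families, each a Model class whose ``fit()`` returns a Results
object with estimates, uncertainties, diagnostics, and a ``summary()``:

* :class:`SpeciesResponseModel` — ordered occupancy response (treated as
  continuous) regressed on species thermal bias, optionally regional
  temperature change, clade (reference Bivalvia), and their interactions;
  random intercepts for species nested in regions nested in time zones,
  fitted by REML.
* :class:`SlopeWarmingModel` — inverse-variance-weighted least squares of
  per-context bias-per-level slopes on regional warming magnitude
  (meta-regression across regions and times).
* :class:`AssemblageResponseModel` — assemblage change measures (percent
  extirpated, percent immigrating, turnover, ...) regressed on one predictor
  with regions nested in time zones as random intercepts, optionally
  weighted by the inverse SD of member species' biases.

Mixed models report marginal R² (variance explained by fixed effects alone)
and conditional R² (fixed plus random), following the variance-partition
convention: R²m = var(Xβ) / (var(Xβ) + Σ var(random) + var(residual)).
p-values for fixed effects use t statistics with a residual
degrees-of-freedom approximation (df = n_obs − n_fixed by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM


# --------------------------------------------------------------------------
# shared machinery
# --------------------------------------------------------------------------

def _pvalues_t(params: np.ndarray, bse: np.ndarray, df: float) -> np.ndarray:
    t = params / bse
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class MixedFitInternals:
    """Raw pieces of a fitted (possibly reduced) mixed model."""

    result: object
    fe_names: list[str]
    random_structure: str
    singular: bool
    converged: bool


def _fit_mixed(
    endog: np.ndarray,
    exog: pd.DataFrame,
    groups: np.ndarray,
    vc_levels: dict[str, np.ndarray],
    reml: bool = True,
) -> MixedFitInternals:
    """Fit a nested random-intercept model, reducing the random structure on
    singular/non-converged fits (drop the innermost level first, then fall
    back to OLS-equivalent with near-zero variance)."""
    level_names = list(vc_levels)
    attempts = [level_names[: len(level_names) - k] for k in range(len(level_names) + 1)]
    last_exc: Exception | None = None
    for kept in attempts:
        data = exog.copy()
        data["_groups"] = groups
        vcf = {}
        for name in kept:
            data[f"_vc_{name}"] = vc_levels[name]
            vcf[name] = f"0 + C(_vc_{name})"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM.from_formula(
                    "_y ~ 0 + " + " + ".join(f"Q('{c}')" for c in exog.columns),
                    data=data.assign(_y=endog),
                    groups="_groups",
                    vc_formula=vcf or None,
                    re_formula="1",
                )
                res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)
            bad = (
                not np.all(np.isfinite(res.bse_fe.values))
                or np.any(res.bse_fe.values <= 0)
            )
            if bad and kept:
                continue
            singular = len(kept) < len(level_names)
            return MixedFitInternals(
                res, list(exog.columns), "+".join(["zone"] + kept), singular, bool(res.converged)
            )
        except Exception as exc:  # pragma: no cover - depends on optimizer
            last_exc = exc
            continue
    raise RuntimeError(f"mixed model could not be fitted: {last_exc}")


def _r2_nakagawa(res, exog: np.ndarray) -> tuple[float, float]:
    """Marginal and conditional R² by variance partition."""
    beta = res.fe_params.values if hasattr(res.fe_params, "values") else np.asarray(res.fe_params)
    fitted_fixed = exog @ beta
    var_f = float(np.var(fitted_fixed))
    var_resid = float(res.scale)
    var_re = 0.0
    if res.cov_re.size:
        var_re += float(np.trace(np.atleast_2d(res.cov_re)))
    if getattr(res, "vcomp", None) is not None:
        var_re += float(np.sum(res.vcomp))
    total = var_f + var_re + var_resid
    if total <= 0:
        return float("nan"), float("nan")
    return var_f / total, (var_f + var_re) / total


class _CoefTableMixin:
    """Shared tidy-output and text-summary behaviour for Results objects."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    tvalues: pd.Series
    n_obs: int

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {0: self.params - q * self.bse, 1: self.params + q * self.bse}
        )

    def summary(self) -> str:
        lines = [self._title(), "=" * 72]
        lines.append(f"n_obs: {self.n_obs}")
        lines.extend(self._extra_header_lines())
        lines.append("-" * 72)
        lines.append(f"{'term':<38}{'coef':>9}{'se':>8}{'t':>8}{'p':>9}")
        for name in self.params.index:
            lines.append(
                f"{name:<38}{self.params[name]:>9.3f}{self.bse[name]:>8.3f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.2g}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)

    def _title(self) -> str:
        return type(self).__name__

    def _extra_header_lines(self) -> list[str]:
        return []


# --------------------------------------------------------------------------
# species-level response model
# --------------------------------------------------------------------------

class SpeciesResponseResults(_CoefTableMixin):
    """Fitted species-level occupancy-response regression."""

    def __init__(
        self,
        model: "SpeciesResponseModel",
        internals: MixedFitInternals,
        exog: pd.DataFrame,
        endog: np.ndarray,
        df_rule: str,
    ):
        self.model = model
        res = internals.result
        self.params = pd.Series(np.asarray(res.fe_params), index=internals.fe_names)
        self.bse = pd.Series(np.asarray(res.bse_fe), index=internals.fe_names)
        self.n_obs = len(endog)
        self.df_resid = (
            self.n_obs - len(self.params) if df_rule == "residual" else res.df_resid
        )
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            _pvalues_t(self.params.values, self.bse.values, self.df_resid),
            index=self.params.index,
        )
        self.r2_marginal, self.r2_conditional = _r2_nakagawa(res, exog.values)
        self.variance_components = {
            "zone_intercept": float(np.trace(np.atleast_2d(res.cov_re)))
            if res.cov_re.size
            else 0.0,
            "residual": float(res.scale),
        }
        vcomp = np.atleast_1d(getattr(res, "vcomp", np.array([])))
        vc_names = getattr(getattr(res.model, "exog_vc", None), "names", None) or [
            f"vc_{i}" for i in range(vcomp.size)
        ]
        self.variance_components.update(
            {n: float(v) for n, v in zip(vc_names, vcomp)}
        )
        self.random_structure = internals.random_structure
        self.singular = internals.singular
        self.converged = internals.converged
        self._statsmodels_result = res

    def _title(self) -> str:
        return "Species occupancy response ~ thermal bias (nested mixed LM, REML)"

    def _extra_header_lines(self) -> list[str]:
        return [
            f"R2 marginal: {self.r2_marginal:.3f}   R2 conditional: {self.r2_conditional:.3f}",
            f"random intercepts: {self.random_structure}"
            + ("   [reduced: singular fit]" if self.singular else ""),
        ]


class _ZeroVarianceResults(_CoefTableMixin):
    """Mixed-model results in the zero-random-variance limit."""

    def __init__(self, params, bse, df_resid, n_obs, r2):
        self.params = params
        self.bse = bse
        self.df_resid = df_resid
        self.n_obs = n_obs
        self.tvalues = params / bse
        self.pvalues = pd.Series(
            _pvalues_t(params.values, bse.values, df_resid), index=params.index
        )
        self.r2_marginal = self.r2_conditional = r2
        self.variance_components = {"residual": None}
        self.random_structure = "none (variances pinned at zero)"
        self.singular = False
        self.converged = True


def _fit_zero_variance(endog: np.ndarray, exog: pd.DataFrame) -> _ZeroVarianceResults:
    X = exog.values
    beta, *_ = np.linalg.lstsq(X, endog, rcond=None)
    resid = endog - X @ beta
    df_resid = len(endog) - X.shape[1]
    scale = float(resid @ resid) / df_resid
    cov = scale * np.linalg.inv(X.T @ X)
    var_f = float(np.var(X @ beta))
    r2 = var_f / (var_f + scale) if var_f + scale > 0 else float("nan")
    res = _ZeroVarianceResults(
        pd.Series(beta, index=exog.columns),
        pd.Series(np.sqrt(np.diag(cov)), index=exog.columns),
        df_resid,
        len(endog),
        r2,
    )
    res.variance_components = {"residual": scale}
    return res


class SpeciesResponseModel:
    """Ordered occupancy response regressed on thermal bias and covariates.

    The response level (1–5, optionally pooled) is treated as a continuous
    dependent variable. Fixed effects are chosen from ``thermal_bias``,
    ``delta_T``, ``clade`` (treatment-coded against Bivalvia) and the
    ``thermal_bias:clade`` / ``delta_T:clade`` interactions. Random
    intercepts nest species within regions within time zones; the structure
    reduces automatically on singular fits (flagged on the results).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        fixed: tuple[str, ...] = ("thermal_bias",),
        random: str = "species_region_zone",
        reference_clade: str = "Bivalvia",
        min_clade_n: int = 20,
        region_col: str = "region_id",
    ):
        self.records = records
        self.fixed = tuple(fixed)
        self.random = random
        self.reference_clade = reference_clade
        self.min_clade_n = min_clade_n
        self.region_col = region_col

    @classmethod
    def from_records(cls, records: pd.DataFrame, **kwargs) -> "SpeciesResponseModel":
        return cls(records, **kwargs)

    def _design(self) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
        df = self.records.copy()
        if df["response"].nunique() < 2:
            raise ValueError("need at least two response levels to fit")
        use_clade = any("clade" in t for t in self.fixed)
        if use_clade:
            counts = df.groupby("clade")["species"].count()
            keep = counts[counts >= self.min_clade_n].index
            df = df[df["clade"].isin(keep)].copy()
            clades = sorted(df["clade"].unique())
            if self.reference_clade in clades:
                clades.remove(self.reference_clade)
                clades.insert(0, self.reference_clade)
        exog = pd.DataFrame(index=df.index)
        exog["Intercept"] = 1.0
        for term in self.fixed:
            if term == "thermal_bias":
                exog["thermal_bias"] = df["thermal_bias"].values
            elif term == "delta_T":
                exog["delta_T"] = df["delta_T"].values
            elif term == "clade":
                for c in clades[1:]:
                    exog[f"clade[{c}]"] = (df["clade"] == c).astype(float)
            elif term in ("thermal_bias:clade", "delta_T:clade"):
                base = term.split(":")[0]
                for c in clades[1:]:
                    exog[f"{base}:clade[{c}]"] = (
                        df[base] * (df["clade"] == c)
                    ).astype(float)
            else:
                raise ValueError(f"unknown fixed term {term!r}")
        return df["response"].values.astype(float), exog, df

    def fit(
        self,
        reml: bool = True,
        df_rule: str = "residual",
        force_zero_variance: bool = False,
    ) -> SpeciesResponseResults:
        endog, exog, df = self._design()
        if force_zero_variance:
            # The mixed GLS solve with all random variances pinned at zero:
            # V = sigma^2 I, so the fixed effects satisfy the OLS normal
            # equations exactly.
            return _fit_zero_variance(endog, exog)
        zone = df["boundary"].astype(str).values
        region = df[self.region_col].astype(str).values
        vc_levels: dict[str, np.ndarray] = {}
        if self.random in ("species_region_zone", "region_zone"):
            vc_levels["region"] = region
        if self.random == "species_region_zone":
            vc_levels["species"] = (
                df[self.region_col].astype(str) + "/" + df["species"].astype(str)
            ).values
        internals = _fit_mixed(endog, exog, zone, vc_levels, reml=reml)
        return SpeciesResponseResults(self, internals, exog, endog, df_rule)


# --------------------------------------------------------------------------
# per-context slopes and warming meta-regression
# --------------------------------------------------------------------------

def per_context_slopes(
    records: pd.DataFrame,
    region_col: str = "region_id",
    pooling_applied: bool = True,
) -> pd.DataFrame:
    """Per-(region, boundary) linear regression of thermal bias on response
    level — the mean °C difference in bias between adjacent response levels.

    Contexts with a single represented level are excluded (slope not
    estimable). Returns slope, its SE, n_species, and the context delta_T.
    """
    rows = []
    for (region, boundary), grp in records.groupby([region_col, "boundary"]):
        levels = grp["response"].values.astype(float)
        bias = grp["thermal_bias"].values.astype(float)
        if np.unique(levels).size < 2:
            continue
        X = sm.add_constant(levels)
        res = sm.OLS(bias, X).fit()
        se = float(res.bse[1])
        if not np.isfinite(se) or se == 0:
            # Perfect fit: fall back to a tiny SE so weighting stays finite.
            se = 1e-9
        rows.append(
            {
                region_col: region,
                "boundary": boundary,
                "slope": float(res.params[1]),
                "se": se,
                "n_species": int(len(grp)),
                "delta_T": float(grp["delta_T"].iloc[0]),
                "phase": grp["phase"].iloc[0] if "phase" in grp.columns else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[region_col, "boundary", "slope", "se", "n_species", "delta_T", "phase"],
    )


class SlopeWarmingResults(_CoefTableMixin):
    """Weighted meta-regression of bias-per-level slopes on warming."""

    def __init__(self, model: "SlopeWarmingModel", res, data: pd.DataFrame):
        self.model = model
        self.params = pd.Series(res.params, index=["Intercept", "delta_T"])
        self.bse = pd.Series(res.bse, index=self.params.index)
        self.n_obs = int(res.nobs)
        self.df_resid = res.df_resid
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            _pvalues_t(self.params.values, self.bse.values, self.df_resid),
            index=self.params.index,
        )
        self.data = data
        w = 1.0 / data["se"] ** 2
        self.weighted_r = _weighted_corr(data["delta_T"].values, data["slope"].values, w.values)
        sx = _weighted_std(data["delta_T"].values, w.values)
        sy = _weighted_std(data["slope"].values, w.values)
        self.standardized_slope = float(self.params["delta_T"] * sx / sy) if sy > 0 else float("nan")
        self._statsmodels_result = res

    def _title(self) -> str:
        return "Bias-per-level slope ~ regional warming (inverse-variance WLS)"

    def _extra_header_lines(self) -> list[str]:
        return [
            f"weighted correlation R: {self.weighted_r:.3f}"
            f"   standardized slope: {self.standardized_slope:.3f}"
        ]


def _weighted_corr(x, y, w) -> float:
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def _weighted_std(x, w) -> float:
    w = w / w.sum()
    m = np.sum(w * x)
    return float(np.sqrt(np.sum(w * (x - m) ** 2)))


class SlopeWarmingModel:
    """WLS of per-context slopes on regional warming magnitude.

    Weights are 1/SE²; contexts with fewer than ``min_species`` species are
    excluded (default 20). Needs at least 3 contexts after filtering.
    """

    def __init__(self, slopes: pd.DataFrame, min_species: int = 20):
        self.slopes = slopes
        self.min_species = min_species

    def fit(self) -> SlopeWarmingResults:
        data = self.slopes[self.slopes["n_species"] >= self.min_species].copy()
        data = data[np.isfinite(data["slope"]) & np.isfinite(data["delta_T"])]
        if len(data) < 3:
            raise ValueError(
                f"need >= 3 contexts with n_species >= {self.min_species}, have {len(data)}"
            )
        X = sm.add_constant(data["delta_T"].values)
        res = sm.WLS(data["slope"].values, X, weights=1.0 / data["se"].values ** 2).fit()
        return SlopeWarmingResults(self, res, data)


# --------------------------------------------------------------------------
# assemblage-level models
# --------------------------------------------------------------------------

class AssemblageModelResults(_CoefTableMixin):
    """One fitted (response, predictor) assemblage regression."""

    def __init__(
        self,
        model: "AssemblageResponseModel",
        internals: MixedFitInternals,
        exog: pd.DataFrame,
        endog: np.ndarray,
    ):
        self.model = model
        res = internals.result
        self.params = pd.Series(np.asarray(res.fe_params), index=internals.fe_names)
        self.bse = pd.Series(np.asarray(res.bse_fe), index=internals.fe_names)
        self.n_obs = len(endog)
        self.df_resid = max(self.n_obs - len(self.params), 1)
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            _pvalues_t(self.params.values, self.bse.values, self.df_resid),
            index=self.params.index,
        )
        self.r2_marginal, self.r2_conditional = _r2_nakagawa(res, exog.values)
        self.singular = internals.singular
        self.converged = internals.converged
        self.response_name = model.response
        self.predictor_name = model.predictor
        # Fixed-effect covariance for prediction intervals.
        k = len(self.params)
        self._cov_fe = np.asarray(res.cov_params())[:k, :k]
        self._statsmodels_result = res

    def predict(self, predictor_value: float, alpha: float = 0.05) -> dict:
        """Point prediction at a predictor value with a CI propagated from
        the fixed-effect covariance. At predictor 0 this is the intercept."""
        x = np.array([1.0, float(predictor_value)])
        point = float(x @ self.params.values)
        var = float(x @ self._cov_fe @ x)
        # Degenerate fits (e.g. a constant response) can carry a numerically
        # invalid covariance; report a zero-width interval rather than NaN.
        se = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else 0.0
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return {
            "prediction": point,
            "se": se,
            "ci_low": point - q * se,
            "ci_high": point + q * se,
        }

    def _title(self) -> str:
        return f"{self.response_name} ~ {self.predictor_name} (nested random effects LM)"

    def _extra_header_lines(self) -> list[str]:
        return [f"R2 marginal: {self.r2_marginal:.3f}   R2 conditional: {self.r2_conditional:.3f}"]


class AssemblageResponseModel:
    """One assemblage change measure regressed on one predictor.

    Regions nested in time zones enter as random intercepts. For models with
    assemblage thermal bias as the predictor, observations can be weighted by
    the inverse SD of member species' biases (``weights='inv_bias_sd'``),
    implemented by scaling both sides (WLS transform) before the mixed fit.
    A ``subset='warming'`` restriction keeps only warming-associated
    boundaries (unidirectional hypotheses).
    """

    def __init__(
        self,
        summaries: pd.DataFrame,
        response: str,
        predictor: str,
        weights: str | None = None,
        subset: str | None = None,
        region_col: str = "region_id",
    ):
        self.summaries = summaries
        self.response = response
        self.predictor = predictor
        self.weights = weights
        self.subset = subset
        self.region_col = region_col

    def fit(self, reml: bool = True) -> AssemblageModelResults:
        df = self.summaries.copy()
        if self.subset == "warming":
            from .metrics import WARMING_ASSOCIATED_PHASES

            df = df[df["phase"].isin(WARMING_ASSOCIATED_PHASES)]
        df = df[np.isfinite(df[self.response]) & np.isfinite(df[self.predictor])]
        if len(df) < 6:
            raise ValueError(f"need >= 6 assemblage rows, have {len(df)}")
        y = df[self.response].values.astype(float)
        exog = pd.DataFrame(
            {"Intercept": 1.0, self.predictor: df[self.predictor].values}, index=df.index
        )
        if self.weights == "inv_bias_sd":
            sd = df["bias_sd"].values.astype(float)
            sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.nanmedian(sd))
            w = np.sqrt(1.0 / sd)
            y = y * w
            exog = exog.mul(w, axis=0)
        zone = df["boundary"].astype(str).values
        vc_levels = {"region": df[self.region_col].astype(str).values}
        internals = _fit_mixed(y, exog, zone, vc_levels, reml=reml)
        return AssemblageModelResults(self, internals, exog, y)


def predict_at_warming(result: AssemblageModelResults, delta_T: float = 3.0) -> dict:
    """Predicted assemblage response (percent) at a stated regional warming,
    with CI from the fixed-effect covariance. The model must have been fitted
    with ``delta_T`` as its predictor."""
    if result.predictor_name != "delta_T":
        raise ValueError("model was not fitted with delta_T as predictor")
    return result.predict(delta_T)


def standardized_correlation(
    summaries: pd.DataFrame,
    var_a: str,
    var_b: str,
    region_col: str = "region_id",
) -> tuple[float, float]:
    """Correlation-scale association between two assemblage measures via a
    mixed model of standardised variables (slope of z(b) on z(a)), returning
    (R, p)."""
    df = summaries[np.isfinite(summaries[var_a]) & np.isfinite(summaries[var_b])].copy()
    za = (df[var_a] - df[var_a].mean()) / df[var_a].std(ddof=1)
    zb = (df[var_b] - df[var_b].mean()) / df[var_b].std(ddof=1)
    exog = pd.DataFrame({"Intercept": 1.0, "z": za.values}, index=df.index)
    internals = _fit_mixed(
        zb.values,
        exog,
        df["boundary"].astype(str).values,
        {"region": df[region_col].astype(str).values},
    )
    res = internals.result
    params = np.asarray(res.fe_params)
    bse = np.asarray(res.bse_fe)
    p = float(_pvalues_t(params, bse, max(len(df) - 2, 1))[1])
    return float(params[1]), p
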