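"""Mixed-effects and weighted regression models: oracles and recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from thermobias import (
    AssemblageResponseModel,
    SlopeWarmingModel,
    SpeciesResponseModel,
    per_context_slopes,
)
from thermobias.models import predict_at_warming, standardized_correlation


def _records_frame(bias, response, region=None, boundary=None, species=None, delta_T=None):
    n = len(bias)
    return pd.DataFrame(
        {
            "thermal_bias": bias,
            "response": response,
            "region_id": region if region is not None else np.zeros(n, dtype=int),
            "boundary": boundary if boundary is not None else ["b0"] * n,
            "species": species if species is not None else [f"s{i}" for i in range(n)],
            "delta_T": delta_T if delta_T is not None else np.zeros(n),
            "clade": ["Bivalvia"] * n,
            "phase": ["warming_1"] * n,
        }
    )


# ---------------------------------------------------------------------------
# species model
# ---------------------------------------------------------------------------

def test_species_model_matches_ols_without_group_structure():
    """With random variances pinned at zero the fixed effects equal OLS to
    1e-6; with merely ungrouped data the free REML fit lands close by."""
    rng = np.random.default_rng(0)
    n = 400
    bias = rng.normal(0, 3, n)
    response = 3.0 - 0.12 * bias + rng.normal(0, 0.7, n)
    regions = rng.integers(0, 4, n)
    zones = np.array(["z1", "z2", "z3", "z4"])[rng.integers(0, 4, n)]
    rec = _records_frame(bias, response, region=regions, boundary=zones)
    ols = sm.OLS(response, sm.add_constant(bias)).fit()

    pinned = SpeciesResponseModel(rec, random="region_zone").fit(force_zero_variance=True)
    assert pinned.params["Intercept"] == pytest.approx(ols.params[0], abs=1e-6)
    assert pinned.params["thermal_bias"] == pytest.approx(ols.params[1], abs=1e-6)
    assert pinned.bse["thermal_bias"] == pytest.approx(ols.bse[1], abs=1e-6)

    res = SpeciesResponseModel(rec, random="region_zone").fit()
    assert res.params["thermal_bias"] == pytest.approx(ols.params[1], abs=5e-3)
    assert res.r2_marginal <= res.r2_conditional <= 1
    assert (res.bse > 0).all()


def test_species_model_recovers_group_intercepts():
    rng = np.random.default_rng(1)
    n_per, k = 80, 6
    zone_eff = rng.normal(0, 1.5, k)
    rows = []
    for z in range(k):
        bias = rng.normal(0, 3, n_per)
        resp = 3.0 + zone_eff[z] - 0.1 * bias + rng.normal(0, 0.5, n_per)
        rows.append(
            _records_frame(bias, resp, boundary=[f"z{z}"] * n_per, region=np.full(n_per, z % 3))
        )
    rec = pd.concat(rows, ignore_index=True)
    res = SpeciesResponseModel(rec, random="region_zone").fit()
    assert res.params["thermal_bias"] == pytest.approx(-0.1, abs=0.02)
    assert res.variance_components["zone_intercept"] > 0.5
    assert res.r2_conditional > res.r2_marginal


def test_species_model_needs_two_levels():
    rec = _records_frame(np.random.default_rng(2).normal(size=20), np.full(20, 3))
    with pytest.raises(ValueError):
        SpeciesResponseModel(rec).fit()


def test_species_model_clade_terms_and_reference():
    rng = np.random.default_rng(3)
    n = 600
    bias = rng.normal(0, 3, n)
    clade = np.where(rng.random(n) < 0.5, "Bivalvia", "Rhynchonelliformea")
    slope = np.where(clade == "Bivalvia", -0.05, -0.20)
    resp = 3.0 + slope * bias + rng.normal(0, 0.4, n)
    rec = _records_frame(bias, resp, boundary=np.array(["z1", "z2"])[rng.integers(0, 2, n)])
    rec["clade"] = clade
    res = SpeciesResponseModel(
        rec, fixed=("thermal_bias", "clade", "thermal_bias:clade"), random="region_zone"
    ).fit()
    # Treatment coding against Bivalvia: interaction term estimates the
    # brachiopod-vs-bivalve slope difference.
    assert "thermal_bias:clade[Rhynchonelliformea]" in res.params.index
    assert res.params["thermal_bias"] == pytest.approx(-0.05, abs=0.03)
    assert res.params["thermal_bias:clade[Rhynchonelliformea]"] == pytest.approx(-0.15, abs=0.05)
    assert "t" in res.summary() and "coef" in res.summary()


# ---------------------------------------------------------------------------
# per-context slopes
# ---------------------------------------------------------------------------

def test_per_context_slope_exact_line():
    rec = _records_frame(
        bias=[2, 2, 0, 0, -2, -2],
        response=[2, 2, 3, 3, 4, 4],
        delta_T=np.full(6, 4.0),
    )
    slopes = per_context_slopes(rec)
    assert len(slopes) == 1
    assert slopes["slope"].iat[0] == pytest.approx(-2.0)
    assert slopes["n_species"].iat[0] == 6


def test_per_context_single_level_excluded():
    rec = _records_frame(bias=[1, 2], response=[3, 3])
    assert len(per_context_slopes(rec)) == 0


def test_per_context_matches_closed_form():
    rng = np.random.default_rng(4)
    bias = rng.normal(0, 2, 40)
    level = rng.integers(2, 5, 40).astype(float)
    rec = _records_frame(bias, level)
    rec["response"] = level
    slopes = per_context_slopes(rec)
    x, y = level, bias
    beta = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    assert slopes["slope"].iat[0] == pytest.approx(beta, rel=1e-8)


def test_pooled_slopes_equal_five_level_when_extremes_empty():
    rng = np.random.default_rng(5)
    bias = rng.normal(0, 2, 60)
    level = rng.integers(2, 5, 60)
    rec = _records_frame(bias, level)
    from thermobias.classify import pool_levels

    s_merged = per_context_slopes(pool_levels(rec, "merged"))
    s_five = per_context_slopes(pool_levels(rec, "five_level"))
    assert s_merged["slope"].iat[0] == pytest.approx(s_five["slope"].iat[0])


# ---------------------------------------------------------------------------
# slope-vs-warming meta-regression
# ---------------------------------------------------------------------------

def _slopes_frame(delta_T, slope, se, n_species=30):
    return pd.DataFrame(
        {
            "region_id": np.arange(len(slope)) % 5,
            "boundary": [f"b{i}" for i in range(len(slope))],
            "slope": slope,
            "se": se,
            "n_species": n_species,
            "delta_T": delta_T,
        }
    )


def test_wls_recovers_exact_line():
    dT = np.linspace(0, 8, 10)
    slopes = _slopes_frame(dT, -0.2 - 0.1 * dT, np.full(10, 0.3))
    res = SlopeWarmingModel(slopes, min_species=20).fit()
    assert res.params["Intercept"] == pytest.approx(-0.2, abs=1e-10)
    assert res.params["delta_T"] == pytest.approx(-0.1, abs=1e-10)


def test_wls_weight_expansion_oracle():
    """Halving one SE quadruples its weight: the fit equals OLS on data with
    that point replicated four times."""
    rng = np.random.default_rng(6)
    dT = rng.uniform(0, 8, 8)
    slope = -0.1 * dT + rng.normal(0, 0.2, 8)
    se = np.full(8, 1.0)
    se[3] = 0.5
    res = SlopeWarmingModel(_slopes_frame(dT, slope, se), min_species=20).fit()
    dT_x = np.concatenate([dT, [dT[3]] * 3])
    slope_x = np.concatenate([slope, [slope[3]] * 3])
    ols = sm.OLS(slope_x, sm.add_constant(dT_x)).fit()
    assert res.params["Intercept"] == pytest.approx(ols.params[0], rel=1e-8)
    assert res.params["delta_T"] == pytest.approx(ols.params[1], rel=1e-8)


def test_wls_min_species_filter_and_minimum_contexts():
    slopes = _slopes_frame(np.arange(5.0), np.zeros(5), np.ones(5), n_species=10)
    with pytest.raises(ValueError):
        SlopeWarmingModel(slopes, min_species=20).fit()


def test_wls_detects_negative_trend_in_simulation():
    """Contexts whose bias effect strengthens with warming yield a negative
    slope-on-warming trend at 25 contexts."""
    rng = np.random.default_rng(7)
    detected = 0
    for _ in range(20):
        dT = rng.uniform(-1, 9, 25)
        true = -0.05 - 0.08 * dT
        se = rng.uniform(0.1, 0.4, 25)
        slope = true + rng.normal(0, se)
        res = SlopeWarmingModel(_slopes_frame(dT, slope, se), min_species=20).fit()
        if res.params["delta_T"] < 0 and res.pvalues["delta_T"] < 0.05:
            detected += 1
    assert detected >= 16


def test_weighted_r_bounds(tracking_run):
    if tracking_run.slope_result is not None:
        assert -1 <= tracking_run.slope_result.weighted_r <= 1


# ---------------------------------------------------------------------------
# assemblage models
# ---------------------------------------------------------------------------

def _summaries_frame(rng, n=25, b=0.0, response_name="pct_immigrating"):
    dT = rng.uniform(-1, 9, n)
    resp = 10 + b * dT + rng.normal(0, 3, n)
    return pd.DataFrame(
        {
            response_name: resp,
            "delta_T": dT,
            "assemblage_bias": rng.normal(-1, 2, n),
            "bias_sd": rng.uniform(1, 3, n),
            "region_id": np.arange(n) % 5,
            "boundary": [f"b{i // 5}" for i in range(n)],
            "phase": ["warming_1"] * n,
        }
    )


def test_assemblage_constant_response_zero_slope():
    rng = np.random.default_rng(8)
    df = _summaries_frame(rng)
    df["pct_immigrating"] = 15.0
    res = AssemblageResponseModel(df, "pct_immigrating", "delta_T").fit()
    assert res.params["delta_T"] == pytest.approx(0.0, abs=1e-8)
    assert res.predict(3.0)["prediction"] == pytest.approx(15.0, abs=1e-6)


def test_assemblage_recovers_known_slope_and_prediction():
    rng = np.random.default_rng(9)
    df = _summaries_frame(rng, b=2.5)
    res = AssemblageResponseModel(df, "pct_immigrating", "delta_T").fit()
    ci = res.conf_int()
    assert ci.loc["delta_T", 0] < 2.5 < ci.loc["delta_T", 1]
    pred = predict_at_warming(res, 3.0)
    expect = res.params["Intercept"] + 3.0 * res.params["delta_T"]
    assert pred["prediction"] == pytest.approx(expect)
    pred0 = res.predict(0.0)
    assert pred0["prediction"] == pytest.approx(res.params["Intercept"])


def test_assemblage_equal_weights_match_unweighted():
    rng = np.random.default_rng(10)
    df = _summaries_frame(rng, b=1.0)
    df["bias_sd"] = 2.0
    res_w = AssemblageResponseModel(df, "pct_immigrating", "assemblage_bias", weights="inv_bias_sd").fit()
    res_u = AssemblageResponseModel(df, "pct_immigrating", "assemblage_bias").fit()
    # Identical up to REML optimizer tolerance (a constant weight rescales
    # the whole problem).
    assert res_w.params["assemblage_bias"] == pytest.approx(
        res_u.params["assemblage_bias"], abs=1e-3
    )


def test_assemblage_needs_six_rows():
    rng = np.random.default_rng(11)
    df = _summaries_frame(rng, n=5)
    with pytest.raises(ValueError):
        AssemblageResponseModel(df, "pct_immigrating", "delta_T").fit()


def test_predict_requires_delta_T_model():
    rng = np.random.default_rng(12)
    res = AssemblageResponseModel(_summaries_frame(rng), "pct_immigrating", "assemblage_bias").fit()
    with pytest.raises(ValueError):
        predict_at_warming(res, 3.0)


def test_standardized_correlation_symmetric_and_bounded():
    rng = np.random.default_rng(13)
    df = _summaries_frame(rng, b=2.0)
    df["pct_extirpated"] = 0.6 * df["pct_immigrating"] + rng.normal(0, 2, len(df))
    r_ab, _ = standardized_correlation(df, "pct_immigrating", "pct_extirpated")
    r_ba, _ = standardized_correlation(df, "pct_extirpated", "pct_immigrating")
    assert -1.05 <= r_ab <= 1.05
    assert r_ab == pytest.approx(r_ba, abs=0.15)
    assert r_ab > 0
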