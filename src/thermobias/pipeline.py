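"""End-to-end orchestration: ingest -> climate -> regions -> metrics ->
classification -> inference, with config validation and a reconciled report.

A run consumes either file inputs (occurrence CSV, per-bin temperature
fields, FAD/LAD CSV) or a named synthetic preset, and produces the full
chain of stage outputs plus fitted models. Runs are deterministic given
(config, seed).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import attach_bias, classify_responses, pool_levels, summarize_assemblages
from .climate import TemperatureField, sample_temperatures
from .metrics import (
    WARMING_ASSOCIATED_PHASES,
    assemblage_bias,
    regional_climate,
    sti_table,
)
from .models import (
    AssemblageResponseModel,
    SlopeWarmingModel,
    SpeciesResponseModel,
    per_context_slopes,
    predict_at_warming,
)
from .occurrences import RangeTable, read_occurrences
from .regions import assign_regions, flag_analyzable
from .simulate import SyntheticWorld, WorldConfig, generate_world, scenario_presets
from .timebins import TimeBinSequence

_version = "0.1.0"

__all__ = [
    "RunConfig",
    "RunReport",
    "RunResult",
    "ConfigError",
    "run_pipeline",
    "run_species_analysis",
    "sensitivity_matrix",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``preset``/``world`` (synthetic) or the three input paths must be
    given. Defaults mirror the study configuration: ten spatial clusters for
    file-based data, n > 25 occurrences per bin for an analyzable region,
    two-timer classification with extinctions pooled into extirpations,
    contexts with at least 20 species in the warming meta-regression, and a
    +3 °C prediction point.
    """

    preset: str | None = None
    world: WorldConfig | None = None
    occurrences_path: str | None = None
    fields_paths: dict[str, str] | None = None       # time_bin -> NetCDF/CSV path
    range_table_path: str | None = None
    synonyms_path: str | None = None

    geography: str = "180Ma"                          # 180Ma primary, 185Ma secondary
    scenario: str = "main"                            # main or secondary pCO2
    scheme: str = "two_timer"
    pooling: str = "merged"
    k_regions: int | None = None
    min_occ_per_bin: int = 25
    region_whitelist: tuple[int, ...] = ()
    min_species: int = 20
    sti_method: str = "median"
    fixed_terms: tuple[str, ...] = ("thermal_bias",)
    random_structure: str = "region_zone"
    subset: str = "warming"
    prediction_delta_T: float = 3.0
    bin_sequence: TimeBinSequence = field(default_factory=TimeBinSequence)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> list[str]:
        """Machine-readable list of configuration errors (empty = valid)."""
        errors = []
        synthetic = self.preset is not None or self.world is not None
        if synthetic:
            if self.preset is not None and self.preset not in scenario_presets():
                errors.append(f"unknown preset: {self.preset}")
        else:
            for name in ("occurrences_path", "range_table_path"):
                p = getattr(self, name)
                if p is None:
                    errors.append(f"{name} is required for file-based runs")
                elif not Path(p).exists():
                    errors.append(f"{name} does not exist: {p}")
            if not self.fields_paths:
                errors.append("fields_paths is required for file-based runs")
            else:
                for b, p in self.fields_paths.items():
                    if not Path(p).exists():
                        errors.append(f"temperature field for {b} does not exist: {p}")
        if self.scheme not in ("two_timer", "three_timer"):
            errors.append(f"unknown scheme: {self.scheme}")
        if self.pooling not in ("merged", "five_level", "three_level"):
            errors.append(f"unknown pooling: {self.pooling}")
        if self.geography not in ("180Ma", "185Ma"):
            errors.append(f"unknown geography: {self.geography}")
        if self.scenario not in ("main", "secondary"):
            errors.append(f"unknown scenario: {self.scenario}")
        return errors


@dataclass
class RunReport:
    """Per-stage accounting; counts reconcile across stages."""

    config_echo: dict = field(default_factory=dict)
    version: str = _version
    wall_time_s: float = 0.0
    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "wall_time_s": self.wall_time_s,
            "config": self.config_echo,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
        }


@dataclass
class RunResult:
    """All stage outputs of one pipeline run."""

    occurrences: pd.DataFrame
    sti: pd.DataFrame
    climate: pd.DataFrame
    records: pd.DataFrame
    slopes: pd.DataFrame
    summaries: pd.DataFrame
    species_result: object | None
    slope_result: object | None
    assemblage_results: dict
    predictions: dict
    report: RunReport
    world: SyntheticWorld | None = None


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


def _load_inputs(config: RunConfig):
    """Resolve occurrences, fields, and range table from config."""
    seq = config.bin_sequence
    if config.preset is not None or config.world is not None:
        wc = config.world or scenario_presets()[config.preset]
        wc = replace(wc, seed=config.seed, bins=seq)
        world = generate_world(wc)
        fields = {
            b: world.field_for(b, config.geography, config.scenario)
            for b in seq.all_bins
        }
        return world.occurrences, fields, world.range_table, world

    synonyms = None
    if config.synonyms_path:
        syn = pd.read_csv(config.synonyms_path)
        synonyms = dict(zip(syn["bad_name"], syn["accepted_name"]))
    occ, _ = read_occurrences(
        config.occurrences_path, bin_sequence=seq, synonyms=synonyms
    )
    fields = {}
    for b, p in config.fields_paths.items():
        p = Path(p)
        fields[b] = (
            TemperatureField.from_csv(p)
            if p.suffix == ".csv"
            else TemperatureField.from_netcdf(p)
        )
    rt = RangeTable.from_frame(pd.read_csv(config.range_table_path), seq)
    return occ, fields, rt, None


def _assemblage_table(
    occ: pd.DataFrame,
    sti: pd.DataFrame,
    climate: pd.DataFrame,
    summaries: pd.DataFrame,
    seq: TimeBinSequence,
) -> pd.DataFrame:
    """Join assemblage summaries with their predictors: assemblage thermal
    bias (current assemblage vs ambient at time i), its member-bias SD, the
    warming step, the bias change across the boundary, and habitat-share
    changes."""
    sti_of = sti.set_index("species")["sti"]
    clim = climate.set_index(["region_id", "boundary"])
    rows = []
    for _, srow in summaries.iterrows():
        region, boundary, i = srow["region_id"], srow["boundary"], int(srow["boundary_index"])
        b0, b1 = seq.bins[i], seq.bins[i + 1]
        in_region = occ[occ["region_id"] == region]
        sp_i = in_region.loc[in_region["time_bin"] == b0, "species"].unique()
        sp_i1 = in_region.loc[in_region["time_bin"] == b1, "species"].unique()
        stis_i = sti_of.reindex(sp_i).dropna().values
        stis_i1 = sti_of.reindex(sp_i1).dropna().values
        t_i = clim["median_T_i"].get((region, boundary), np.nan)
        t_i1 = clim["median_T_i1"].get((region, boundary), np.nan)
        entry = dict(srow)
        entry["phase"] = clim["phase"].get((region, boundary), "")
        entry["delta_T"] = clim["delta_T"].get((region, boundary), np.nan)
        if stis_i.size >= 1 and np.isfinite(t_i):
            cti, bias, bias_sd = assemblage_bias(stis_i, t_i)
            entry.update(cti=cti, assemblage_bias=bias, bias_sd=bias_sd)
        else:
            entry.update(cti=np.nan, assemblage_bias=np.nan, bias_sd=np.nan)
        if stis_i1.size >= 1 and np.isfinite(t_i1) and np.isfinite(entry["assemblage_bias"]):
            _, bias1, _ = assemblage_bias(stis_i1, t_i1)
            entry["bias_change"] = bias1 - entry["assemblage_bias"]
        else:
            entry["bias_change"] = np.nan
        for colcat, colname in (
            ("lith_category", "carbonate"),
            ("bath_category", "deep"),
        ):
            def share(bin_label):
                sub = in_region[in_region["time_bin"] == bin_label]
                known = sub[sub[colcat] != "unknown"]
                if len(known) == 0:
                    return np.nan
                return 100.0 * (known[colcat] == colname).mean()

            entry[f"d_pct_{colname}"] = share(b1) - share(b0)
        rows.append(entry)
    return pd.DataFrame(rows)


#: (response, predictor, weighting, subset) combinations fitted by default.
ASSEMBLAGE_MODEL_GRID = [
    ("pct_originating", "assemblage_bias", "inv_bias_sd", "warming"),
    ("pct_immigrating", "assemblage_bias", "inv_bias_sd", "warming"),
    ("pct_extirpated", "assemblage_bias", "inv_bias_sd", "warming"),
    ("pct_extinct", "assemblage_bias", "inv_bias_sd", "warming"),
    ("pct_immigrating", "delta_T", None, None),
    ("pct_extirpated", "delta_T", None, None),
    ("jaccard_turnover", "delta_T", None, None),
    ("bias_change", "delta_T", None, None),
]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis chain for one configuration."""
    t0 = time.time()
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    seq = config.bin_sequence
    report = RunReport(config_echo=_config_echo(config))

    occ, fields, range_table, world = _load_inputs(config)
    report.stage_counts["ingested"] = len(occ)

    # --- temperature sampling -------------------------------------------
    lon_col = "paleo_lon_primary" if config.geography == "180Ma" else "paleo_lon_secondary"
    lat_col = "paleo_lat_primary" if config.geography == "180Ma" else "paleo_lat_secondary"
    occ = occ.copy()
    temps = np.full(len(occ), np.nan)
    for b, fld in fields.items():
        m = (occ["time_bin"] == b).values
        if m.any():
            temps[m] = sample_temperatures(
                fld, occ.loc[m, lon_col].values, occ.loc[m, lat_col].values
            )
    occ["temperature"] = temps
    report.stage_counts["no_temperature"] = int(np.isnan(temps).sum())

    # --- regions ---------------------------------------------------------
    k = config.k_regions
    if k is None:
        k = world.config.n_regions if world is not None else 10
    assignment = assign_regions(
        occ, k=k, bin_sequence=seq, lon_col=lon_col, lat_col=lat_col
    )
    assignment = flag_analyzable(
        assignment,
        config.min_occ_per_bin,
        seq,
        whitelist=set(config.region_whitelist),
    )
    occ["region_id"] = assignment.occurrence_region.reindex(occ["occurrence_id"]).values
    analyzable = {r for r, ok in assignment.analyzable.items() if ok}
    occ_ok = occ[occ["region_id"].isin(analyzable)].copy()
    report.stage_counts["regions_total"] = len(assignment.region_ids)
    report.stage_counts["regions_analyzable"] = len(analyzable)
    report.stage_counts["occ_in_analyzable_regions"] = len(occ_ok)
    report.stage_counts["occ_outside"] = len(occ) - len(occ_ok)

    # --- thermal metrics -------------------------------------------------
    sti = sti_table(occ, method=config.sti_method, bin_sequence=seq)
    climate = regional_climate(occ_ok, bin_sequence=seq)
    report.stage_counts["species_with_sti"] = len(sti)

    # --- classification --------------------------------------------------
    records, cls_report = classify_responses(
        occ_ok, range_table, scheme=config.scheme, bin_sequence=seq
    )
    report.stage_counts["response_candidates"] = cls_report.n_candidates
    report.stage_counts["responses_classified"] = cls_report.n_classified
    report.stage_counts["responses_unclassifiable"] = cls_report.n_unclassifiable
    records, n_dropped_bias = attach_bias(records, sti, climate)
    report.stage_counts["responses_without_bias"] = n_dropped_bias
    records = pool_levels(records, config.pooling)
    report.stage_counts["responses_modelled"] = len(records)

    # --- species-level inference ----------------------------------------
    model_records = records
    if config.subset == "warming":
        model_records = records[records["phase"].isin(WARMING_ASSOCIATED_PHASES)]
    species_result = None
    if len(model_records) and model_records["response"].nunique() >= 2:
        try:
            species_result = SpeciesResponseModel(
                model_records,
                fixed=config.fixed_terms,
                random=config.random_structure,
            ).fit()
        except (ValueError, RuntimeError) as exc:
            report.warnings.append(f"species model not fitted: {exc}")

    three_level = pool_levels(records, "merged")
    slopes = per_context_slopes(three_level)
    slope_result = None
    if len(slopes) >= 3:
        try:
            slope_result = SlopeWarmingModel(slopes, config.min_species).fit()
        except ValueError as exc:
            report.warnings.append(f"slope-vs-warming model not fitted: {exc}")

    # --- assemblage-level inference --------------------------------------
    summaries = summarize_assemblages(records, occ_ok, seq)
    summaries = (
        _assemblage_table(occ_ok, sti, climate, summaries, seq)
        if len(summaries)
        else summaries
    )
    assemblage_results = {}
    predictions = {}
    for response, predictor, weights, subset in ASSEMBLAGE_MODEL_GRID:
        if response not in summaries.columns or predictor not in summaries.columns:
            continue
        try:
            res = AssemblageResponseModel(
                summaries, response, predictor, weights=weights, subset=subset
            ).fit()
            assemblage_results[(response, predictor)] = res
            if predictor == "delta_T":
                predictions[response] = predict_at_warming(res, config.prediction_delta_T)
        except (ValueError, RuntimeError) as exc:
            report.warnings.append(f"assemblage model {response}~{predictor}: {exc}")

    report.wall_time_s = time.time() - t0
    result = RunResult(
        occ_ok,
        sti,
        climate,
        records,
        slopes,
        summaries,
        species_result,
        slope_result,
        assemblage_results,
        predictions,
        report,
        world,
    )
    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _config_echo(config: RunConfig) -> dict:
    echo = {}
    for k, v in vars(config).items():
        if isinstance(v, (str, int, float, bool, type(None))):
            echo[k] = v
        elif isinstance(v, tuple):
            echo[k] = list(v)
        elif isinstance(v, TimeBinSequence):
            echo[k] = list(v.bins)
        elif isinstance(v, WorldConfig):
            echo[k] = "WorldConfig"
        elif isinstance(v, dict):
            echo[k] = {str(kk): str(vv) for kk, vv in v.items()}
    return echo


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.sti.to_csv(outdir / "sti.csv", index=False)
    result.climate.to_csv(outdir / "regional_climate.csv", index=False)
    result.records.to_csv(outdir / "responses.csv", index=False)
    result.slopes.to_csv(outdir / "context_slopes.csv", index=False)
    result.summaries.to_csv(outdir / "assemblage_summaries.csv", index=False)
    coef_rows = []
    if result.species_result is not None:
        tab = result.species_result.coef_table().reset_index(names="term")
        tab.insert(0, "model", "species_response")
        coef_rows.append(tab)
    if result.slope_result is not None:
        tab = result.slope_result.coef_table().reset_index(names="term")
        tab.insert(0, "model", "slope_vs_warming")
        coef_rows.append(tab)
    for (response, predictor), res in result.assemblage_results.items():
        tab = res.coef_table().reset_index(names="term")
        tab.insert(0, "model", f"{response}~{predictor}")
        coef_rows.append(tab)
    if coef_rows:
        pd.concat(coef_rows, ignore_index=True).to_csv(
            outdir / "coefficients.csv", index=False
        )
    payload = result.report.to_dict()
    payload["predictions"] = {
        k: {kk: float(vv) for kk, vv in v.items()} for k, v in result.predictions.items()
    }
    (outdir / "run_report.json").write_text(json.dumps(payload, indent=2))


def run_species_analysis(
    preset: str | WorldConfig,
    seed: int = 0,
    scheme: str = "two_timer",
    pooling: str = "merged",
    subset: str = "warming",
    random_structure: str = "region_zone",
    bin_sequence: TimeBinSequence | None = None,
):
    """Generate a synthetic world and fit the species-level response model.

    A lean path through the chain (world -> sampling -> regions -> metrics ->
    classification -> species model) for simulation studies that do not need
    the assemblage-level stages. Returns ``(records, result, world)``; the
    result is None when fewer than two response levels survive the subset.
    """
    seq = bin_sequence or TimeBinSequence()
    wc = preset if isinstance(preset, WorldConfig) else scenario_presets()[preset]
    wc = replace(wc, seed=seed, bins=seq)
    world = generate_world(wc)
    occ = world.occurrences.copy()

    temps = np.full(len(occ), np.nan)
    for b in seq.all_bins:
        fld = world.field_for(b)
        m = (occ["time_bin"] == b).values
        if m.any():
            temps[m] = sample_temperatures(
                fld, occ.loc[m, "paleo_lon_primary"].values, occ.loc[m, "paleo_lat_primary"].values
            )
    occ["temperature"] = temps

    assignment = assign_regions(occ, k=wc.n_regions, bin_sequence=seq)
    occ["region_id"] = assignment.occurrence_region.reindex(occ["occurrence_id"]).values

    sti = sti_table(occ, bin_sequence=seq)
    climate = regional_climate(occ, bin_sequence=seq)
    records, _ = classify_responses(occ, world.range_table, scheme=scheme, bin_sequence=seq)
    records, _ = attach_bias(records, sti, climate)
    records = pool_levels(records, pooling)
    # Map clustering labels back to the generator's latent regions (majority
    # vote) so simulation studies can address regions by their true identity.
    majority = occ.groupby("region_id")["true_region"].agg(lambda s: s.mode().iat[0])
    records["true_region"] = records["region_id"].map(majority)

    model_records = records
    if subset == "warming":
        model_records = records[records["phase"].isin(WARMING_ASSOCIATED_PHASES)]
    result = None
    if len(model_records) and model_records["response"].nunique() >= 2:
        try:
            result = SpeciesResponseModel(model_records, random=random_structure).fit()
        except (ValueError, RuntimeError):
            result = None
    return records, result, world


def sensitivity_matrix(
    config: RunConfig,
    axes: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline over a cross-product of configuration axes and
    collate the species-level thermal-bias coefficient per cell.

    ``axes`` maps axis names (scenario, geography, scheme, pooling) to value
    lists; empty/None yields a single-run table.
    """
    axes = {k: list(v) for k, v in (axes or {}).items()}
    valid = {"scenario", "geography", "scheme", "pooling"}
    unknown = set(axes) - valid
    if unknown:
        raise ValueError(f"unknown sensitivity axes: {sorted(unknown)}")
    names = sorted(axes)
    combos = [()]
    for name in names:
        combos = [c + (v,) for c in combos for v in axes[name]]

    rows = []
    for combo in combos:
        cfg = replace(config, outdir=None, **dict(zip(names, combo)))
        res = run_pipeline(cfg)
        row = dict(zip(names, combo))
        if res.species_result is not None:
            ci = res.species_result.conf_int()
            row.update(
                bias_coefficient=float(res.species_result.params["thermal_bias"]),
                se=float(res.species_result.bse["thermal_bias"]),
                ci_low=float(ci.loc["thermal_bias", 0]),
                ci_high=float(ci.loc["thermal_bias", 1]),
                p_value=float(res.species_result.pvalues["thermal_bias"]),
                n_obs=res.species_result.n_obs,
            )
        rows.append(row)
    return pd.DataFrame(rows)
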