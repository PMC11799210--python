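"""Synthetic occurrence/temperature worlds with known ground truth.

The generator emulates the structure the analysis assumes: species with
conserved Gaussian thermal niches (an optimum and a breadth, narrower for
the brachiopod-analog clade), a handful of latitudinally-ordered regions
whose summer SST follows an ordered trajectory of stasis -> warming ->
transition -> stasis phases, regional occupancy governed by thermal
suitability, imperfect per-region-bin detection, and an optional anoxia mask
that zeroes detection in chosen region-bins regardless of suitability.

Everything the pipeline consumes is emitted in the same shapes it reads from
real data — an occurrence table, per-bin temperature fields, and a global
FAD/LAD table — together with a :class:`GroundTruth` carrying the latent
state, so that estimator recovery can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate import TemperatureField
from .occurrences import RangeTable
from .timebins import TimeBinSequence


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    Temperature trajectory defaults produce five boundary steps of roughly
    (+0.2, +3.4, +3.4, +0.8, -0.4) °C at the reference latitude — a cold
    stasis, two warming pulses, a warm transitional step, and warm stasis —
    amplified toward higher latitudes, over a steep latitudinal SST gradient
    (regions ~4 °C apart), mirroring a mid-latitude epicontinental-sea
    transect.
    """

    n_species: int = 500
    clade_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Bivalvia": 0.55,
            "Rhynchonelliformea": 0.35,
            "Gastropoda": 0.10,
        }
    )
    clade_breadth: dict[str, float] = field(
        default_factory=lambda: {
            "Bivalvia": 2.0,
            "Rhynchonelliformea": 1.4,
            "Gastropoda": 1.8,
        }
    )
    optimum_mean: float = 29.0
    optimum_sd: float = 7.0
    persistence_breadth_factor: float = 2.0
    colonization_rate: float = 0.6
    kernel: str = "warm_edge"            # or "gaussian"
    cool_side_factor: float = 1.5        # cool-tail widening of the niche
    establishment_margin: float = 2.5    # °C of thermal headroom colonization demands
    n_regions: int = 5
    region_lat_centers: tuple[float, ...] = (42.0, 36.0, 30.0, 24.0, 18.0)
    region_lon_centers: tuple[float, ...] = (-2.0, 3.0, -4.0, 2.0, -1.0)
    spatial_spread: float = 1.2          # SD of locality jitter, degrees
    bins: TimeBinSequence = field(default_factory=TimeBinSequence)
    trajectory: tuple[float, ...] = (0.0, 0.2, 3.4, 6.8, 7.6, 7.2)
    warming_amplification: float = 0.03  # per degree latitude from the mean
    equator_T: float = 46.0
    lat_gradient: float = 0.7            # °C lost per degree latitude
    suitability_sigma_scale: float = 1.0
    base_occupancy: float = 0.9
    temperature_dependent: bool = True
    flat_presence_prob: float = 0.5      # colonization suitability when temperature_dependent=False
    flat_persistence_prob: float = 0.75  # persistence suitability when temperature_dependent=False
    detection: float = 0.9
    n_localities: int = 30
    locality_occ_rate: float = 0.25
    anoxia_mask: tuple[tuple[int, str], ...] = ()   # (region index, bin label)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.detection <= 1:
            raise ValueError("detection must be in [0, 1]")
        if any(b <= 0 for b in self.clade_breadth.values()):
            raise ValueError("niche breadths must be positive")
        if len(self.region_lat_centers) < self.n_regions:
            raise ValueError("need a latitude center per region")
        if len(self.trajectory) != self.bins.n:
            raise ValueError("trajectory must give one offset per bin")


@dataclass
class GroundTruth:
    """Latent state of a generated world."""

    species: pd.DataFrame          # species, clade, optimum, breadth
    region_bins: pd.DataFrame      # region_id, time_bin, ambient_T, detection, anoxia
    presence: np.ndarray           # species x region x all_bins (pre-detection)
    bin_sequence: TimeBinSequence

    def ambient(self, region: int, time_bin: str) -> float:
        rb = self.region_bins
        row = rb[(rb["region_id"] == region) & (rb["time_bin"] == time_bin)]
        return float(row["ambient_T"].iloc[0])


@dataclass
class SyntheticWorld:
    """Everything a pipeline run needs, plus the ground truth."""

    occurrences: pd.DataFrame
    fields: dict[tuple[str, str, str], TemperatureField]  # (geography, scenario, bin)
    range_table: RangeTable
    truth: GroundTruth
    config: WorldConfig

    def field_for(self, time_bin: str, geography: str = "180Ma", scenario: str = "main") -> TemperatureField:
        return self.fields[(geography, scenario, time_bin)]


# Fixed offset between the primary and secondary paleorotation.
_SECONDARY_ROTATION = (-3.0, 2.0)   # dlon, dlat
_SECONDARY_SCENARIO_SCALE = 1.3     # more extreme pCO2 -> amplified trajectory


def suitability(
    dev: np.ndarray,
    sigma: np.ndarray,
    kernel: str = "warm_edge",
    cool_side_factor: float = 2.5,
    margin: float = 0.0,
) -> np.ndarray:
    """Thermal suitability as a function of ``dev = optimum - ambient``.

    ``gaussian``: symmetric bell around the optimum. ``warm_edge``: peak
    performance sits ``margin`` °C below the optimum (establishment needs
    thermal headroom against summer extremes), with the warm side of the
    niche keeping the stated breadth and the cool side ``cool_side_factor``
    times wider — the sharp upper and soft lower thermal limits typical of
    marine ectotherms.
    """
    if kernel == "gaussian":
        return np.exp(-(dev**2) / (2.0 * sigma**2))
    if kernel != "warm_edge":
        raise ValueError("kernel must be 'gaussian' or 'warm_edge'")
    d = dev - margin
    sig = np.where(d > 0, sigma * cool_side_factor, sigma)
    return np.exp(-(d**2) / (2.0 * sig**2))


def _field_values(cfg: WorldConfig, lon: np.ndarray, lat: np.ndarray, offset: float, scale: float,
                  shift: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Analytic SST surface: latitudinal gradient + amplified trajectory offset."""
    LON, LAT = np.meshgrid(lon, lat)
    lat_eff = LAT - shift[1]
    mean_lat = float(np.mean(cfg.region_lat_centers[: cfg.n_regions]))
    amp = 1.0 + cfg.warming_amplification * (np.abs(lat_eff) - mean_lat)
    return cfg.equator_T - cfg.lat_gradient * np.abs(lat_eff) + offset * scale * amp


def _ambient_matrix(cfg: WorldConfig, scale: float = 1.0) -> np.ndarray:
    """region x all_bins ambient °C at region centers (flanks mirror the ends)."""
    lats = np.asarray(cfg.region_lat_centers[: cfg.n_regions])
    mean_lat = float(lats.mean())
    amp = 1.0 + cfg.warming_amplification * (np.abs(lats) - mean_lat)
    base = cfg.equator_T - cfg.lat_gradient * np.abs(lats)
    traj = np.array([cfg.trajectory[0], *cfg.trajectory, cfg.trajectory[-1]])
    return base[:, None] + traj[None, :] * scale * amp[:, None]


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a synthetic world from its configuration, reproducibly.

    Random streams are split per component (niches, presence, detection,
    localities) so toggling one leaves the others untouched.
    """
    cfg = config
    seq = cfg.bins
    root = np.random.SeedSequence(cfg.seed)
    rng_niche, rng_presence, rng_detect, rng_local = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    # --- species niches --------------------------------------------------
    clades = list(cfg.clade_mix)
    probs = np.array([cfg.clade_mix[c] for c in clades], dtype=float)
    probs /= probs.sum()
    clade_idx = rng_niche.choice(len(clades), size=cfg.n_species, p=probs)
    optima = rng_niche.normal(cfg.optimum_mean, cfg.optimum_sd, size=cfg.n_species)
    breadths = np.array(
        [cfg.clade_breadth[clades[c]] * cfg.suitability_sigma_scale for c in clade_idx]
    )
    species_names = [f"Genus{i // 10} species{i}" for i in range(cfg.n_species)]
    species_df = pd.DataFrame(
        {
            "species": species_names,
            "clade": [clades[c] for c in clade_idx],
            "optimum": optima,
            "breadth": breadths,
        }
    )

    # --- regional climate and presence ----------------------------------
    all_bins = seq.all_bins
    ambient = _ambient_matrix(cfg)          # regions x all_bins
    anoxic = np.zeros((cfg.n_regions, len(all_bins)), dtype=bool)
    for region, bin_label in cfg.anoxia_mask:
        anoxic[region, all_bins.index(bin_label)] = True

    # Occupancy follows a colonization/persistence Markov process: getting
    # established demands a close thermal match (narrow colonization kernel,
    # rate-limited), while established populations tolerate a wider window
    # (persistence kernel broader by `persistence_breadth_factor`). This
    # establishment-persistence asymmetry makes assemblages lag the climate:
    # cool-adapted legacy members persist while only warm-adapted species
    # newly arrive — the structure thermal-bias analysis presumes.
    shape = (cfg.n_species, cfg.n_regions, len(all_bins))
    if cfg.temperature_dependent:
        dev = optima[:, None, None] - ambient[None, :, :]
        suit_col = suitability(
            dev,
            breadths[:, None, None],
            cfg.kernel,
            cfg.cool_side_factor,
            cfg.establishment_margin,
        )
        sig_per = (breadths * cfg.persistence_breadth_factor)[:, None, None]
        # Established populations have no establishment margin: they persist
        # until conditions leave the (wider) adult tolerance window.
        suit_per = suitability(dev, sig_per, cfg.kernel, cfg.cool_side_factor, 0.0)
    else:
        suit_col = np.full(shape, cfg.flat_presence_prob)
        suit_per = np.full(shape, cfg.flat_persistence_prob)

    presence = np.zeros(shape, dtype=bool)
    presence[:, :, 0] = (
        rng_presence.random(shape[:2]) < cfg.base_occupancy * suit_col[:, :, 0]
    )
    presence[:, :, 0] &= ~anoxic[None, :, 0]
    for b in range(1, len(all_bins)):
        p = np.where(
            presence[:, :, b - 1],
            suit_per[:, :, b],
            cfg.colonization_rate * suit_col[:, :, b],
        )
        presence[:, :, b] = rng_presence.random(shape[:2]) < p
        presence[:, :, b] &= ~anoxic[None, :, b]

    # --- detection and occurrence emission ------------------------------
    detected = presence & (
        rng_detect.random(presence.shape) < (cfg.detection if cfg.detection < 1 else 1.0)
    )
    if cfg.detection >= 1:
        detected = presence.copy()
    detected &= ~anoxic[None, :, :]

    # Detected species emit 1 + Binomial(n_localities - 1, occ_rate)
    # occurrences, so the expected count scales linearly with detection.
    n_extra = rng_local.binomial(
        max(cfg.n_localities - 1, 0), cfg.locality_occ_rate, size=detected.shape
    )
    n_occ = np.where(detected, 1 + n_extra, 0)

    # Fixed locality set per region-bin (shared collection sites): keeps the
    # unique-coordinate pool realistic for the spatial clustering step.
    loc_lon = (
        np.asarray(cfg.region_lon_centers[: cfg.n_regions])[:, None, None]
        + rng_local.normal(0, cfg.spatial_spread, (cfg.n_regions, len(all_bins), cfg.n_localities))
    )
    loc_lat = (
        np.asarray(cfg.region_lat_centers[: cfg.n_regions])[:, None, None]
        + rng_local.normal(0, cfg.spatial_spread, (cfg.n_regions, len(all_bins), cfg.n_localities))
    )

    sp_i, rg_i, bn_i = np.nonzero(n_occ)
    counts = n_occ[sp_i, rg_i, bn_i]
    sp_rep = np.repeat(sp_i, counts)
    rg_rep = np.repeat(rg_i, counts)
    bn_rep = np.repeat(bn_i, counts)
    total = sp_rep.size

    # Each detected species occupies `count` distinct localities of its
    # region-bin.
    loc_rep = np.empty(total, dtype=int)
    pos = 0
    for k in counts:
        loc_rep[pos : pos + k] = rng_local.choice(cfg.n_localities, size=k, replace=False)
        pos += k
    lons = loc_lon[rg_rep, bn_rep, loc_rep]
    lats = loc_lat[rg_rep, bn_rep, loc_rep]

    occ = pd.DataFrame(
        {
            "occurrence_id": [f"syn{i}" for i in range(total)],
            "species": [species_names[i] for i in sp_rep],
            "genus": [species_names[i].split(" ")[0] for i in sp_rep],
            "clade": [clades[clade_idx[i]] for i in sp_rep],
            "collection_id": [
                f"loc{r}_{b}_{l}" for r, b, l in zip(rg_rep, bn_rep, loc_rep)
            ],
            "modern_lon": lons,
            "modern_lat": lats,
            "paleo_lon_primary": lons,
            "paleo_lat_primary": lats,
            "paleo_lon_secondary": lons + _SECONDARY_ROTATION[0],
            "paleo_lat_secondary": lats + _SECONDARY_ROTATION[1],
            "time_bin": [all_bins[b] for b in bn_rep],
            "lith_category": "unknown",
            "bath_category": "unknown",
            "true_region": rg_rep,
        }
    )

    # --- temperature fields ----------------------------------------------
    lon_axis = np.arange(-12.0, 12.01, 1.0)
    lat_axis = np.arange(10.0, 55.01, 1.0)
    fields: dict[tuple[str, str, str], TemperatureField] = {}
    for gi, (geog, shift) in enumerate(
        [("180Ma", (0.0, 0.0)), ("185Ma", _SECONDARY_ROTATION)]
    ):
        glon = lon_axis + shift[0]
        glat = lat_axis + shift[1]
        for scen, scale in [("main", 1.0), ("secondary", _SECONDARY_SCENARIO_SCALE)]:
            for bi, b in enumerate(seq.bins):
                vals = _field_values(cfg, glon, glat, cfg.trajectory[bi], scale, shift)
                fields[(geog, scen, b)] = TemperatureField(
                    glon, glat, vals, geography_tag=geog, scenario_tag=scen
                )
            # Flank-bin fields mirror the adjacent end bins.
            for b, bi in ((seq.flank_before, 0), (seq.flank_after, seq.n - 1)):
                vals = _field_values(cfg, glon, glat, cfg.trajectory[bi], scale, shift)
                fields[(geog, scen, b)] = TemperatureField(
                    glon, glat, vals, geography_tag=geog, scenario_tag=scen
                )

    # --- global FAD/LAD from realized presence ---------------------------
    global_presence = presence.any(axis=1)  # species x all_bins
    rows = []
    for i, sp in enumerate(species_names):
        occupied = np.nonzero(global_presence[i])[0]
        if occupied.size == 0:
            continue
        rows.append(
            {
                "species": sp,
                "fad_index": int(occupied.min()) - 1,   # all_bins offset -> bin index
                "lad_index": int(occupied.max()) - 1,
            }
        )
    range_table = RangeTable(pd.DataFrame(rows), seq)

    rb_rows = []
    for r in range(cfg.n_regions):
        for bi, b in enumerate(all_bins):
            rb_rows.append(
                {
                    "region_id": r,
                    "time_bin": b,
                    "ambient_T": float(ambient[r, bi]),
                    "detection": 0.0 if anoxic[r, bi] else cfg.detection,
                    "anoxia": bool(anoxic[r, bi]),
                }
            )
    truth = GroundTruth(species_df, pd.DataFrame(rb_rows), presence, seq)
    if total == 0:
        import warnings

        warnings.warn("degenerate configuration produced an empty occurrence table")
    return SyntheticWorld(occ, fields, range_table, truth, cfg)


def scenario_presets() -> dict[str, WorldConfig]:
    """Named study-condition configurations.

    * ``tracking`` — occupancy follows thermal suitability exactly (the
      default world): species-level bias effect should be recovered.
    * ``null`` — presence probability is independent of temperature: the
      bias coefficient should cover zero.
    * ``anoxia`` — as tracking, but the two high-latitude regions lose all
      benthic habitat (detection and presence to zero) during the peak-warming
      and transitional bins, collapsing the bias-response link there.
    * ``clade-contrast`` — brachiopod-analog breadths much narrower than
      bivalve-analog ones, so the clade interaction is recoverable.
    """
    tracking = WorldConfig()
    # The null holds climate flat as well as making occupancy
    # temperature-blind: with ambient change present, the context-bin
    # convention alone (immigrants measured against the later, warmer bin)
    # would couple response level to bias mechanically.
    null = replace(
        tracking, temperature_dependent=False, trajectory=(0.0,) * len(tracking.trajectory)
    )
    anoxia_bins = [
        (r, b) for r in (0, 1) for b in ("Tenuicostatum", "Exaratum", "Falciferum")
    ]
    anoxia = replace(tracking, anoxia_mask=tuple(anoxia_bins))
    clade_contrast = replace(
        tracking,
        clade_breadth={"Bivalvia": 3.0, "Rhynchonelliformea": 1.0, "Gastropoda": 1.8},
    )
    return {
        "tracking": tracking,
        "null": null,
        "anoxia": anoxia,
        "clade-contrast": clade_contrast,
    }
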