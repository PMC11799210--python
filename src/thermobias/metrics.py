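"""Thermal metrics: STI, regional ambient temperatures, thermal bias, CTI.

A species temperature index (STI) is the long-term central tendency (median
by default) of the ambient temperatures sampled at all of a species'
occurrences across the full study interval. Thermal bias is the species' (or
assemblage's) preference minus the ambient regional temperature, so a
positive bias means a preference for warmer water than locally available —
the signature of an immigrating, warm-adapted species under warming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timebins import TimeBinSequence

#: Default boundary -> climate phase mapping for the standard bin sequence.
DEFAULT_PHASE_MAP: dict[str, str] = {
    "Margaritatus-Spinatum": "cold_stasis",
    "Spinatum-Tenuicostatum": "warming_1",
    "Tenuicostatum-Exaratum": "warming_2",
    "Exaratum-Falciferum": "transitional",
    "Falciferum-Bifrons": "warm_stasis",
}

#: Phases treated as warming-associated in the response analysis.
WARMING_ASSOCIATED_PHASES = frozenset({"warming_1", "warming_2", "transitional"})


@dataclass(frozen=True)
class SpeciesNiche:
    """A species' estimated thermal niche centre and spread."""

    species: str
    sti: float
    n_temps: int
    temp_spread: float


def species_sti(occ_temps, method: str = "median", species: str = "") -> SpeciesNiche:
    """Species temperature index from per-occurrence sampled temperatures.

    Temperatures are pooled over all zone-level occurrences of the species
    across the full interval and all regions; the central tendency is the
    median (the operative definition) or the mean as a sensitivity option.
    """
    temps = np.asarray(occ_temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise ValueError(f"no non-missing temperatures for species {species!r}")
    if method == "median":
        sti = float(np.median(temps))
    elif method == "mean":
        sti = float(np.mean(temps))
    else:
        raise ValueError("method must be 'median' or 'mean'")
    spread = float(np.std(temps, ddof=1)) if temps.size > 1 else 0.0
    return SpeciesNiche(species, sti, int(temps.size), spread)


def sti_table(
    occurrences: pd.DataFrame,
    method: str = "median",
    bin_sequence: TimeBinSequence | None = None,
    temp_col: str = "temperature",
) -> pd.DataFrame:
    """STI for every species with >= 1 non-missing sampled temperature.

    Temperatures are pooled over the bins of the analysis sequence only
    (flanking bins are excluded from niche estimation).
    """
    seq = bin_sequence or TimeBinSequence()
    pool = occurrences[
        occurrences["time_bin"].isin(seq.bins) & np.isfinite(occurrences[temp_col])
    ]
    rows = []
    for sp, grp in pool.groupby("species"):
        niche = species_sti(grp[temp_col].values, method=method, species=sp)
        rows.append(
            {
                "species": sp,
                "sti": niche.sti,
                "n_temps": niche.n_temps,
                "temp_spread": niche.temp_spread,
            }
        )
    return pd.DataFrame(rows, columns=["species", "sti", "n_temps", "temp_spread"])


def regional_median_T(sampled_temps) -> float:
    """Regional ambient for one region-bin: the median of temperatures
    sampled at its occurrence paleocoordinates (each occurrence counted once).
    """
    temps = np.asarray(sampled_temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if temps.size == 0:
        raise ValueError("no non-missing temperatures in region-bin")
    return float(np.median(temps))


def regional_climate(
    occurrences: pd.DataFrame,
    bin_sequence: TimeBinSequence | None = None,
    phase_map: dict[str, str] | None = None,
    temp_col: str = "temperature",
    region_col: str = "region_id",
    locality_unique: bool = False,
) -> pd.DataFrame:
    """Regional median temperature per (region, bin), warming steps, phases.

    Returns a frame with one row per (region, boundary): the medians at both
    ends, ``delta_T`` (median at i+1 minus median at i), and the boundary's
    climate-phase label. ``locality_unique=True`` collapses each collection
    to one temperature before taking the median.
    """
    seq = bin_sequence or TimeBinSequence()
    phases = phase_map if phase_map is not None else label_phases(seq)

    pool = occurrences[np.isfinite(occurrences[temp_col])]
    if locality_unique and "collection_id" in pool.columns:
        pool = (
            pool.groupby([region_col, "time_bin", "collection_id"], as_index=False)[temp_col]
            .median()
        )
    medians = (
        pool[pool["time_bin"].isin(seq.bins)]
        .groupby([region_col, "time_bin"])[temp_col]
        .median()
    )

    rows = []
    for region in medians.index.get_level_values(0).unique():
        for i, (b0, b1) in enumerate(seq.boundaries()):
            t0 = medians.get((region, b0), np.nan)
            t1 = medians.get((region, b1), np.nan)
            boundary = seq.boundary_label(i)
            rows.append(
                {
                    region_col: region,
                    "boundary": boundary,
                    "boundary_index": i,
                    "bin_i": b0,
                    "bin_i1": b1,
                    "median_T_i": t0,
                    "median_T_i1": t1,
                    "delta_T": t1 - t0,
                    "phase": phases.get(boundary, ""),
                }
            )
    return pd.DataFrame(rows)


def thermal_bias(preference: float, ambient: float) -> float:
    """Thermal bias = preference - ambient (°C).

    Positive: the species/assemblage prefers warmer water than the local
    ambient (immigrant-type); negative: cooler preference (extirpation-prone
    under warming).
    """
    if not (np.isfinite(preference) and np.isfinite(ambient)):
        raise ValueError("preference and ambient must be finite")
    return float(preference - ambient)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cutoff = 0.5 * w.sum()
    return float(v[np.searchsorted(cw, cutoff)])


def assemblage_bias(
    member_stis,
    ambient: float,
    weighting: str = "none",
    exponent: float = 1.0,
) -> tuple[float, float, float]:
    """Community temperature index, assemblage thermal bias, and bias SD.

    CTI is the median of member species' STIs (optionally a weighted median
    emphasising cool- or warm-adapted members, with weights proportional to
    the distance from the warm or cool end raised to ``exponent``). The
    assemblage bias is CTI - ambient; ``bias_sd`` is the SD of member-level
    biases, used downstream for inverse-variance weighting. With a common
    ambient, median(STI) - T equals median(STI - T), so the assemblage bias
    is also the median of member biases.
    """
    stis = np.asarray(member_stis, dtype=float)
    stis = stis[np.isfinite(stis)]
    if stis.size == 0:
        raise ValueError("need at least one member STI")
    if weighting == "none":
        cti = float(np.median(stis))
    elif weighting in ("cool", "warm"):
        span = stis.max() - stis.min()
        if span == 0:
            cti = float(stis[0])
        else:
            anchor = stis.max() if weighting == "cool" else stis.min()
            w = (np.abs(anchor - stis) / span + 1e-9) ** exponent
            cti = _weighted_median(stis, w)
    else:
        raise ValueError("weighting must be 'none', 'cool', or 'warm'")
    bias = thermal_bias(cti, ambient)
    biases = stis - ambient
    bias_sd = float(np.std(biases, ddof=1)) if stis.size > 1 else float("nan")
    return cti, bias, bias_sd


def label_phases(
    bin_sequence: TimeBinSequence | None = None,
    mapping: dict[str, str] | None = None,
) -> dict[str, str]:
    """Climate-phase label for every boundary of the bin sequence.

    For the default sequence the mapping runs cold stasis -> warming 1 ->
    warming 2 -> transitional -> warm stasis. A custom sequence requires an
    explicit mapping covering all of its boundaries.
    """
    seq = bin_sequence or TimeBinSequence()
    boundaries = [seq.boundary_label(i) for i in range(seq.n - 1)]
    if mapping is None:
        if all(b in DEFAULT_PHASE_MAP for b in boundaries):
            return {b: DEFAULT_PHASE_MAP[b] for b in boundaries}
        raise ValueError(
            "non-default bin sequence requires an explicit boundary->phase mapping"
        )
    missing = [b for b in boundaries if b not in mapping]
    if missing:
        raise ValueError(f"phase mapping missing boundaries: {missing}")
    return {b: mapping[b] for b in boundaries}
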