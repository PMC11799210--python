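"""Region-level species occupancy responses across time-bin boundaries.

For each (species, region, boundary i -> i+1) the two-timer scheme assigns
an ordered response level from the regional presence record around the
boundary and the dataset-wide FAD/LAD:

* persisting (3): present in the region in i AND i+1;
* immigrating (2): absent in i, present in i+1 AND i+2;
* originating (1): immigrating, with dataset-wide FAD = i+1;
* extirpated (4): present in i-1 AND i, absent in i+1;
* extinct (5): extirpated, with dataset-wide LAD = i.

Requiring two consecutive regional presences suppresses single-bin sampling
artifacts. At the first and last boundaries the i-1 / i+2 requirement may be
satisfied by a presence anywhere in the dataset in the flanking bin, but a
regional occurrence in i or i+1 is still required, so edge relaxation never
creates responses, it only lets well-sampled species pass the threshold.

The three-timer variant centres the response on bin i instead: immigrating =
present i and i+1, absent i-1 (originating adds FAD = i); extirpated =
present i-1 and i, absent i+1 (extinct adds LAD = i); persisting = present in
all of i-1, i, i+1.

Species matching no rule are unclassifiable and excluded (with counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrences import RangeTable
from .timebins import TimeBinSequence

#: Ordered response encoding.
RESPONSE_LEVELS: dict[str, int] = {
    "originating": 1,
    "immigrating": 2,
    "persisting": 3,
    "extirpated": 4,
    "extinct": 5,
}
LEVEL_NAMES = {v: k for k, v in RESPONSE_LEVELS.items()}


def _presence_at(presence, idx: int) -> bool:
    """Presence lookup supporting dict (bin index -> bool) or sequence
    indexed from the pre-flank bin (offset +1)."""
    if isinstance(presence, dict):
        return bool(presence.get(idx, False))
    pos = idx + 1
    if 0 <= pos < len(presence):
        return bool(presence[pos])
    return False


def classify_two_timer(
    presence,
    boundary: int,
    n_bins: int = 6,
    fad: int | None = None,
    lad: int | None = None,
    global_flank_before: bool = False,
    global_flank_after: bool = False,
) -> int | None:
    """Two-timer response level for one species at boundary ``i -> i+1``.

    Parameters
    ----------
    presence
        Regional presence record: a dict mapping bin index (-1 .. n_bins) to
        bool, or a boolean sequence of length ``n_bins + 2`` starting at the
        pre-flank bin.
    boundary
        Index i of the bin before the focal boundary (0 .. n_bins - 2).
    fad, lad
        Dataset-wide first/last appearance bin indices; None means the
        species is missing from the range table, in which case the
        non-extreme level is assigned.
    global_flank_before, global_flank_after
        Dataset-wide presence in the flanking bins, used to satisfy the
        i-1 / i+2 requirement at the first/last boundary only.

    Returns the integer level, or None if unclassifiable.
    """
    i = boundary
    if not (0 <= i <= n_bins - 2):
        raise ValueError(f"boundary {i} outside 0..{n_bins - 2}")
    p_i = _presence_at(presence, i)
    p_i1 = _presence_at(presence, i + 1)
    p_im1 = _presence_at(presence, i - 1)
    p_i2 = _presence_at(presence, i + 2)
    if i == 0:
        p_im1 = p_im1 or global_flank_before
    if i == n_bins - 2:
        p_i2 = p_i2 or global_flank_after

    if p_i and p_i1:
        return RESPONSE_LEVELS["persisting"]
    if (not p_i) and p_i1 and p_i2:
        if fad is None:
            warnings.warn("species missing from range table; assigning immigrating")
            return RESPONSE_LEVELS["immigrating"]
        return RESPONSE_LEVELS["originating"] if fad == i + 1 else RESPONSE_LEVELS["immigrating"]
    if p_im1 and p_i and not p_i1:
        if lad is None:
            warnings.warn("species missing from range table; assigning extirpated")
            return RESPONSE_LEVELS["extirpated"]
        return RESPONSE_LEVELS["extinct"] if lad == i else RESPONSE_LEVELS["extirpated"]
    return None


def classify_three_timer(
    presence,
    boundary: int,
    n_bins: int = 6,
    fad: int | None = None,
    lad: int | None = None,
    global_flank_before: bool = False,
    global_flank_after: bool = False,
) -> int | None:
    """Three-timer response level for one species at boundary ``i -> i+1``.

    Presence in a flanking bin required by a rule may be satisfied
    dataset-wide at the edge boundaries; required absences are always tested
    on the regional record.
    """
    i = boundary
    if not (0 <= i <= n_bins - 2):
        raise ValueError(f"boundary {i} outside 0..{n_bins - 2}")
    p_i = _presence_at(presence, i)
    p_i1 = _presence_at(presence, i + 1)
    p_im1 = _presence_at(presence, i - 1)
    p_im1_required = p_im1 or (i == 0 and global_flank_before)

    if p_im1_required and p_i and p_i1:
        return RESPONSE_LEVELS["persisting"]
    if p_i and p_i1 and not p_im1:
        if fad is None:
            warnings.warn("species missing from range table; assigning immigrating")
            return RESPONSE_LEVELS["immigrating"]
        return RESPONSE_LEVELS["originating"] if fad == i else RESPONSE_LEVELS["immigrating"]
    if p_im1_required and p_i and not p_i1:
        if lad is None:
            warnings.warn("species missing from range table; assigning extirpated")
            return RESPONSE_LEVELS["extirpated"]
        return RESPONSE_LEVELS["extinct"] if lad == i else RESPONSE_LEVELS["extirpated"]
    return None


@dataclass
class ClassificationReport:
    n_candidates: int = 0
    n_classified: int = 0
    n_unclassifiable: int = 0
    n_missing_range: int = 0


def classify_responses(
    occurrences: pd.DataFrame,
    range_table: RangeTable,
    scheme: str = "two_timer",
    bin_sequence: TimeBinSequence | None = None,
    region_col: str = "region_id",
) -> tuple[pd.DataFrame, ClassificationReport]:
    """Classify every (species, region, boundary) in an occurrence table.

    Builds regional presence matrices over all bins (flanks included) and the
    dataset-wide flanking presences, applies the chosen scheme at every
    boundary, and returns one record per classified combination with columns
    species, region, boundary, boundary_index, scheme, response, response_name,
    clade.
    """
    if scheme not in ("two_timer", "three_timer"):
        raise ValueError("scheme must be 'two_timer' or 'three_timer'")
    seq = bin_sequence or TimeBinSequence()
    classify = classify_two_timer if scheme == "two_timer" else classify_three_timer

    occ = occurrences[occurrences[region_col] >= 0]
    species = sorted(occ["species"].unique())
    regions = sorted(occ[region_col].unique())
    sp_idx = {s: i for i, s in enumerate(species)}
    rg_idx = {r: i for i, r in enumerate(regions)}
    all_bins = seq.all_bins
    bin_idx = {b: i for i, b in enumerate(all_bins)}

    P = np.zeros((len(species), len(regions), len(all_bins)), dtype=bool)
    for s, r, b in zip(occ["species"], occ[region_col], occ["time_bin"]):
        P[sp_idx[s], rg_idx[r], bin_idx[b]] = True

    global_bin = P.any(axis=1)  # species x all_bins
    flank_before = global_bin[:, 0]
    flank_after = global_bin[:, -1]

    clade_of = (
        occ.groupby("species")["clade"].agg(lambda s: s.mode().iat[0])
        if "clade" in occ.columns
        else pd.Series(dtype=object)
    )

    report = ClassificationReport()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for si, sp in enumerate(species):
            fad = range_table.fad(sp) if sp in range_table else None
            lad = range_table.lad(sp) if sp in range_table else None
            for ri, rg in enumerate(regions):
                vec = P[si, ri]
                if not vec.any():
                    continue
                for i in range(seq.n - 1):
                    report.n_candidates += 1
                    level = classify(
                        vec,
                        i,
                        n_bins=seq.n,
                        fad=fad,
                        lad=lad,
                        global_flank_before=bool(flank_before[si]),
                        global_flank_after=bool(flank_after[si]),
                    )
                    if level is None:
                        report.n_unclassifiable += 1
                        continue
                    if fad is None and level in (2, 4):
                        report.n_missing_range += 1
                    report.n_classified += 1
                    rows.append(
                        {
                            "species": sp,
                            region_col: rg,
                            "boundary": seq.boundary_label(i),
                            "boundary_index": i,
                            "scheme": scheme,
                            "response": level,
                            "response_name": LEVEL_NAMES[level],
                            "clade": clade_of.get(sp, ""),
                        }
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "species",
            region_col,
            "boundary",
            "boundary_index",
            "scheme",
            "response",
            "response_name",
            "clade",
        ],
    )
    return records, report


def pool_levels(records: pd.DataFrame, pooling: str = "merged") -> pd.DataFrame:
    """Apply the response-pooling rule used by the regressions.

    ``merged`` (default): extinctions counted conservatively as extirpations
    (5 -> 4) and originations as immigrations (1 -> 2); ``five_level`` keeps
    all levels; ``three_level`` drops levels 1 and 5 entirely.
    """
    out = records.copy()
    if pooling == "merged":
        out["response"] = out["response"].replace({1: 2, 5: 4})
    elif pooling == "three_level":
        out = out[~out["response"].isin([1, 5])].copy()
    elif pooling != "five_level":
        raise ValueError("pooling must be 'merged', 'five_level', or 'three_level'")
    return out


def attach_bias(
    records: pd.DataFrame,
    niches: pd.DataFrame,
    climate: pd.DataFrame,
    region_col: str = "region_id",
    context: str = "arrival",
) -> tuple[pd.DataFrame, int]:
    """Attach each record's thermal bias (STI minus regional ambient).

    The ambient context bin is time i for persisting/extirpated/extinct and
    time i+1 for immigrating/originating (their arrival context) under the
    default ``context='arrival'``; ``context='pre'`` uses time i for all
    levels. Records lacking an STI or a context-bin ambient are dropped and
    counted.
    """
    sti_of = niches.set_index("species")["sti"]
    clim = climate.set_index([region_col, "boundary"])

    out = records.copy()
    out["sti"] = out["species"].map(sti_of)

    key = list(zip(out[region_col], out["boundary"]))
    t_i = np.array([clim["median_T_i"].get(k, np.nan) for k in key])
    t_i1 = np.array([clim["median_T_i1"].get(k, np.nan) for k in key])
    d_t = np.array([clim["delta_T"].get(k, np.nan) for k in key])
    phase = [clim["phase"].get(k, "") if k in clim.index else "" for k in key]

    if context == "arrival":
        ambient = np.where(out["response"].isin([1, 2]), t_i1, t_i)
    elif context == "pre":
        ambient = t_i
    else:
        raise ValueError("context must be 'arrival' or 'pre'")

    out["ambient_T"] = ambient
    out["delta_T"] = d_t
    out["phase"] = phase
    out["thermal_bias"] = out["sti"] - out["ambient_T"]
    ok = np.isfinite(out["thermal_bias"])
    n_dropped = int((~ok).sum())
    return out[ok].reset_index(drop=True), n_dropped


def jaccard_turnover(set_a, set_b) -> float:
    """Jaccard distance between two species sets: 1 - |A∩B| / |A∪B|."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def summarize_assemblage(
    records: pd.DataFrame,
    current_set,
    new_set,
) -> dict:
    """Assemblage change summary for one (region, boundary).

    Percentages of the *current* (time-i) assemblage classified persisting /
    extirpated / extinct, percentages of the *new* (time-i+1) assemblage
    classified immigrating / originating, per-level species counts, and the
    Jaccard turnover between the two regional species sets. Percentages are
    computed over classified species, so persisting + extirpated + extinct
    sums to 100 whenever any current-assemblage member was classified.
    """
    counts = {name: 0 for name in RESPONSE_LEVELS}
    if len(records):
        for name, lvl in RESPONSE_LEVELS.items():
            counts[name] = int((records["response"] == lvl).sum())
    n_current = counts["persisting"] + counts["extirpated"] + counts["extinct"]
    n_new = counts["immigrating"] + counts["originating"]

    def pct(x: int, denom: int) -> float:
        return 100.0 * x / denom if denom else float("nan")

    return {
        "pct_persisting": pct(counts["persisting"], n_current),
        "pct_extirpated": pct(counts["extirpated"], n_current),
        "pct_extinct": pct(counts["extinct"], n_current),
        "pct_immigrating": pct(counts["immigrating"], n_new + counts["persisting"]),
        "pct_originating": pct(counts["originating"], n_new + counts["persisting"]),
        "jaccard_turnover": jaccard_turnover(current_set, new_set),
        "n_current_classified": n_current,
        "n_new_classified": n_new + counts["persisting"],
        **{f"n_{name}": c for name, c in counts.items()},
    }


def summarize_assemblages(
    records: pd.DataFrame,
    occurrences: pd.DataFrame,
    bin_sequence: TimeBinSequence | None = None,
    region_col: str = "region_id",
) -> pd.DataFrame:
    """Per-(region, boundary) assemblage summaries over a response table.

    The new-assemblage denominators for immigration/origination percentages
    include persisting species (members of the new assemblage too).
    """
    seq = bin_sequence or TimeBinSequence()
    occ = occurrences[occurrences[region_col] >= 0]
    rows = []
    for (region, boundary), grp in records.groupby([region_col, "boundary"]):
        i = int(grp["boundary_index"].iat[0])
        b0, b1 = seq.bins[i], seq.bins[i + 1]
        in_region = occ[occ[region_col] == region]
        set_i = set(in_region.loc[in_region["time_bin"] == b0, "species"])
        set_i1 = set(in_region.loc[in_region["time_bin"] == b1, "species"])
        summary = summarize_assemblage(grp, set_i, set_i1)
        rows.append(
            {region_col: region, "boundary": boundary, "boundary_index": i, **summary}
        )
    return pd.DataFrame(rows)
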