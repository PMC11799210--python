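"""Occurrence ingest, habitat categorisation, ranges, and environmental affinity.

Occurrence tables are handled as pandas DataFrames with one row per vetted
species occurrence. Ingest normalises species names, resolves time bins
against a :class:`~thermobias.timebins.TimeBinSequence`, categorises
depositional lithology and environment into coarse habitat classes, and
reports every dropped row with a reason, so that output + drops always
reconcile with the input row count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .timebins import TimeBinSequence

# Coarse habitat keys: depositional lithologies and environments mapped to
# carbonate/siliciclastic substrate and shallow/deep bathymetry classes.
CARBONATE_LITHOLOGIES = frozenset(
    {
        "carbonate",
        "limestone",
        "reef rocks",
        "bafflestone",
        "bindstone",
        "dolomite",
        "framestone",
        "grainstone",
        "lime mudstone",
        "packstone",
        "rudstone",
        "floatstone",
        "wackestone",
    }
)

SILICICLASTIC_LITHOLOGIES = frozenset(
    {
        "shale",
        "siliciclastic",
        "volcaniclastic",
        "claystone",
        "conglomerate",
        "mudstone",
        "phyllite",
        "quartzite",
        "sandstone",
        "siltstone",
        "slate",
        "schist",
    }
)

SHALLOW_ENVIRONMENTS = frozenset(
    {
        "coastal indet.",
        "delta front",
        "delta plain",
        "deltaic indet.",
        "estuary/bay",
        "foreshore",
        "interdistributary bay",
        "lagoonal",
        "lagoonal/restricted shallow subtidal",
        "marginal marine indet.",
        "open shallow subtidal",
        "fluvial-deltaic indet.",
        "paralic indet.",
        "peritidal",
        "prodelta",
        "sand shoal",
        "shallow subtidal indet.",
        "shoreface",
        "transition zone/lower shoreface",
        "intrashelf/intraplatform reef",
        "reef, buildup or bioherm",
        "perireef or subreef",
        "platform/shelf-margin reef",
    }
)

DEEP_ENVIRONMENTS = frozenset(
    {
        "basinal (carbonate)",
        "basinal (siliceous)",
        "basinal (siliciclastic)",
        "deep-water indet.",
        "deep subtidal indet.",
        "deep subtidal ramp",
        "deep subtidal shelf",
        "offshore",
        "offshore indet.",
        "offshore shelf",
        "slope",
        "submarine fan",
        "offshore ramp",
        "basin reef",
        "slope/ramp reef",
    }
)

#: Default mapping from logical field names to PBDB-download column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "occurrence_id": "occurrence_no",
    "species": "accepted_name",
    "genus": "genus",
    "clade": "class",
    "modern_lon": "lng",
    "modern_lat": "lat",
    "paleo_lon_primary": "paleolng_180",
    "paleo_lat_primary": "paleolat_180",
    "paleo_lon_secondary": "paleolng_185",
    "paleo_lat_secondary": "paleolat_185",
    "time_bin": "zone",
    "lithology": "lithology1",
    "environment": "environment",
    "collection_id": "collection_no",
}

MANDATORY_FIELDS = ("species", "modern_lon", "modern_lat", "time_bin")

_WS = re.compile(r"\s+")


def _clean_token(value: object) -> str:
    """Lowercase, trim, strip quotes, and collapse whitespace."""
    s = str(value).strip().strip('"“”').strip()
    return _WS.sub(" ", s).lower()


def normalize_species_name(name: object, synonyms: dict[str, str] | None = None) -> str:
    """Conservative binomial normalisation: trim/collapse whitespace, genus
    capitalised and epithet lowercased, then an optional synonym lookup
    (matched case-insensitively). No fuzzy matching.
    """
    s = _WS.sub(" ", str(name).strip())
    parts = s.split(" ")
    if parts and parts[0]:
        parts[0] = parts[0][0].upper() + parts[0][1:].lower()
    normalized = " ".join(p.lower() if i else p for i, p in enumerate(parts))
    if synonyms:
        key = normalized.lower()
        lowered = {k.lower(): v for k, v in synonyms.items()}
        if key in lowered:
            return normalize_species_name(lowered[key])
    return normalized


def categorize_habitat(lithology: object, environment: object) -> tuple[str, str]:
    """Map a depositional lithology and environment to (substrate, bathymetry).

    Membership is exact (after case/whitespace normalisation) in the four
    category keys; any string outside them maps to ``"unknown"``.
    """
    lith = _clean_token(lithology)
    env = _clean_token(environment)
    if lith in CARBONATE_LITHOLOGIES:
        lith_cat = "carbonate"
    elif lith in SILICICLASTIC_LITHOLOGIES:
        lith_cat = "siliciclastic"
    else:
        lith_cat = "unknown"
    if env in SHALLOW_ENVIRONMENTS:
        bath_cat = "shallow"
    elif env in DEEP_ENVIRONMENTS:
        bath_cat = "deep"
    else:
        bath_cat = "unknown"
    return lith_cat, bath_cat


@dataclass
class IngestReport:
    """Accounting of an ingest run; counts always reconcile with input rows."""

    n_input: int = 0
    n_kept: int = 0
    dropped_no_coords: int = 0
    dropped_bad_bin: int = 0
    dropped_unresolved_subzone: int = 0
    dropped_no_species: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.dropped_no_coords
            + self.dropped_bad_bin
            + self.dropped_unresolved_subzone
            + self.dropped_no_species
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "dropped_no_coords": self.dropped_no_coords,
            "dropped_bad_bin": self.dropped_bad_bin,
            "dropped_unresolved_subzone": self.dropped_unresolved_subzone,
            "dropped_no_species": self.dropped_no_species,
            "warnings": list(self.warnings),
        }


# Zone labels that cannot be resolved to the analysis (sub)zone level.
UNRESOLVED_ZONE_LABELS = frozenset({"serpentinum"})


def read_occurrences(
    path: str | Path | pd.DataFrame,
    column_map: dict[str, str] | None = None,
    bin_sequence: TimeBinSequence | None = None,
    synonyms: dict[str, str] | None = None,
    sep: str | None = None,
    duplicate_unresolved_subzone: bool = False,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read a delimited occurrence table into the normalised occurrence frame.

    Parameters
    ----------
    path
        CSV/TSV file, or an already-loaded raw DataFrame.
    column_map
        Mapping from logical field names to the file's column names;
        defaults to the PBDB-download dialect in :data:`DEFAULT_COLUMN_MAP`.
    bin_sequence
        Ordered bin list used to validate ``time_bin`` labels; rows whose
        label is not a member (including flanking bins) are dropped.
    synonyms
        Optional ``bad_name -> accepted_name`` table applied after the
        conservative normalisation.
    duplicate_unresolved_subzone
        If True, rows binned only to an unresolvable parent zone (e.g. an
        undivided "Serpentinum") are duplicated into both subzones instead of
        dropped — a sensitivity configuration.

    Returns
    -------
    (occurrences, report)
        A DataFrame with normalised columns plus ``lith_category`` and
        ``bath_category``, and an :class:`IngestReport`.
    """
    column_map = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    bin_sequence = bin_sequence or TimeBinSequence()

    if isinstance(path, pd.DataFrame):
        raw = path.copy()
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    report = IngestReport(n_input=len(raw))
    if len(raw) == 0:
        report.warnings.append("empty input file")
        return _empty_frame(), report

    missing = [
        col
        for f, col in column_map.items()
        if f in MANDATORY_FIELDS and col not in raw.columns
    ]
    if missing:
        raise KeyError(f"mandatory column(s) missing from input: {missing}")

    def col(fieldname: str) -> pd.Series:
        name = column_map.get(fieldname)
        if name is not None and name in raw.columns:
            return raw[name]
        return pd.Series([""] * len(raw), index=raw.index, dtype=object)

    out = pd.DataFrame(index=raw.index)
    out["occurrence_id"] = col("occurrence_id").astype(str)
    if (out["occurrence_id"] == "").all():
        out["occurrence_id"] = [f"occ{i}" for i in range(len(raw))]
    out["species"] = [
        normalize_species_name(s, synonyms) if str(s).strip() else ""
        for s in col("species")
    ]
    out["genus"] = col("genus").astype(str).str.strip()
    out["clade"] = col("clade").astype(str).str.strip()
    out["collection_id"] = col("collection_id").astype(str)

    for f in (
        "modern_lon",
        "modern_lat",
        "paleo_lon_primary",
        "paleo_lat_primary",
        "paleo_lon_secondary",
        "paleo_lat_secondary",
    ):
        out[f] = pd.to_numeric(col(f), errors="coerce")

    out["time_bin"] = col("time_bin").astype(str).str.strip()
    liths = col("lithology")
    envs = col("environment")
    cats = [categorize_habitat(l, e) for l, e in zip(liths, envs)]
    out["lith_category"] = [c[0] for c in cats]
    out["bath_category"] = [c[1] for c in cats]

    # Drop rules, applied in order; each row is counted once.
    no_species = out["species"] == ""
    bad_lon = out["modern_lon"].isna() | ~out["modern_lon"].between(-180, 180)
    bad_lat = out["modern_lat"].isna() | ~out["modern_lat"].between(-90, 90)
    no_coords = (bad_lon | bad_lat) & ~no_species

    labels_lower = out["time_bin"].str.lower()
    unresolved = labels_lower.isin(UNRESOLVED_ZONE_LABELS) & ~no_species & ~no_coords
    known = out["time_bin"].map(lambda b: b in bin_sequence)
    bad_bin = ~known & ~unresolved & ~no_species & ~no_coords

    report.dropped_no_species = int(no_species.sum())
    report.dropped_no_coords = int(no_coords.sum())
    report.dropped_bad_bin = int(bad_bin.sum())

    keep = ~(no_species | no_coords | bad_bin | unresolved)
    kept = out[keep].copy()

    if duplicate_unresolved_subzone and unresolved.any():
        # Sensitivity mode: an undivided parent label becomes one row in each
        # of the two subzones it spans.
        dup_rows = []
        for _, row in out[unresolved].iterrows():
            for sub in ("Exaratum", "Falciferum"):
                r = row.copy()
                r["time_bin"] = sub
                dup_rows.append(r)
        kept = pd.concat([kept, pd.DataFrame(dup_rows)], ignore_index=True)
        report.warnings.append(
            f"duplicated {int(unresolved.sum())} undivided-zone rows into both subzones"
        )
    else:
        report.dropped_unresolved_subzone = int(unresolved.sum())

    kept = kept.reset_index(drop=True)
    report.n_kept = len(kept)
    return kept, report


def _empty_frame() -> pd.DataFrame:
    cols = [
        "occurrence_id",
        "species",
        "genus",
        "clade",
        "collection_id",
        "modern_lon",
        "modern_lat",
        "paleo_lon_primary",
        "paleo_lat_primary",
        "paleo_lon_secondary",
        "paleo_lat_secondary",
        "time_bin",
        "lith_category",
        "bath_category",
    ]
    return pd.DataFrame(columns=cols)


class RangeTable:
    """Dataset-wide first/last appearance bins (FAD/LAD) per species.

    Built from a *global* occurrence set; FAD/LAD are expressed as bin labels
    of the configured sequence (flanking bins allowed) with FAD <= LAD in bin
    order.
    """

    def __init__(self, table: pd.DataFrame, bin_sequence: TimeBinSequence):
        self.bin_sequence = bin_sequence
        self._table = table.set_index("species") if "species" in table.columns else table
        self.fad_index = self._table["fad_index"].to_dict()
        self.lad_index = self._table["lad_index"].to_dict()

    def __contains__(self, species: str) -> bool:
        return species in self.fad_index

    def __len__(self) -> int:
        return len(self.fad_index)

    def fad(self, species: str) -> int:
        """FAD as a numeric bin index."""
        return self.fad_index[species]

    def lad(self, species: str) -> int:
        """LAD as a numeric bin index."""
        return self.lad_index[species]

    def to_frame(self) -> pd.DataFrame:
        seq = self.bin_sequence
        df = self._table.reset_index()
        df["fad_bin"] = [seq.label(i) for i in df["fad_index"]]
        df["lad_bin"] = [seq.label(i) for i in df["lad_index"]]
        return df[["species", "fad_bin", "lad_bin", "fad_index", "lad_index"]]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_sequence: TimeBinSequence | None = None) -> "RangeTable":
        """Load from a CSV-style frame with species, fad_bin, lad_bin columns."""
        seq = bin_sequence or TimeBinSequence()
        out = pd.DataFrame(
            {
                "species": df["species"],
                "fad_index": [seq.index(b) for b in df["fad_bin"]],
                "lad_index": [seq.index(b) for b in df["lad_bin"]],
            }
        )
        return cls(out, seq)


def compute_range_table(
    occurrences: pd.DataFrame, bin_sequence: TimeBinSequence | None = None
) -> RangeTable:
    """FAD/LAD per species: the earliest and latest occupied bin in the
    (global) occurrence set. Every record must carry a resolvable bin.
    """
    seq = bin_sequence or TimeBinSequence()
    idx = occurrences["time_bin"].map(seq.index)
    grouped = (
        pd.DataFrame({"species": occurrences["species"], "bin_index": idx})
        .groupby("species")["bin_index"]
        .agg(fad_index="min", lad_index="max")
        .reset_index()
    )
    return RangeTable(grouped, seq)


@dataclass(frozen=True)
class AffinityResult:
    """Outcome of a binomial environmental-affinity test for one species."""

    species: str
    category_axis: str          # "substrate" or "bathymetry"
    affinity: str               # focal/complement category name, or "none"
    p_value: float
    n_in: int
    n_total: int
    background_prop: float


def affinity_test(
    n_in: int,
    n_total: int,
    background_prop: float,
    alpha: float = 0.1,
    *,
    species: str = "",
    category_axis: str = "substrate",
    focal: str = "carbonate",
    complement: str = "siliciclastic",
    two_tailed: bool = False,
) -> AffinityResult:
    """Exact binomial test for habitat affinity.

    Tests whether ``n_in`` occurrences of a species in the focal category out
    of ``n_total`` classifiable occurrences deviates from the dataset-wide
    ``background_prop``. One-tailed in the direction of the observed
    deviation by default; an affinity is assigned only when p < alpha.
    Observations exactly at expectation yield ``affinity="none"`` with p = 1.
    """
    if n_total == 0:
        return AffinityResult(species, category_axis, "none", 1.0, 0, 0, background_prop)
    if not (0 <= n_in <= n_total):
        raise ValueError("require 0 <= n_in <= n_total")
    if not (0 < background_prop < 1):
        raise ValueError("background_prop must be in (0, 1)")

    expected = n_total * background_prop
    if n_in > expected:
        direction = focal
        p = float(stats.binom.sf(n_in - 1, n_total, background_prop))
    elif n_in < expected:
        direction = complement
        p = float(stats.binom.cdf(n_in, n_total, background_prop))
    else:
        return AffinityResult(
            species, category_axis, "none", 1.0, n_in, n_total, background_prop
        )
    if two_tailed:
        p = min(1.0, 2.0 * p)
    affinity = direction if p < alpha else "none"
    return AffinityResult(species, category_axis, affinity, p, n_in, n_total, background_prop)


def species_affinities(
    occurrences: pd.DataFrame,
    axis: str = "substrate",
    alpha: float = 0.1,
    two_tailed: bool = False,
) -> pd.DataFrame:
    """Run :func:`affinity_test` for every species along one habitat axis.

    The background proportion is the dataset-wide share of classifiable
    occurrences in the focal category, computed excluding "unknown".
    """
    if axis == "substrate":
        column, focal, complement = "lith_category", "carbonate", "siliciclastic"
    elif axis == "bathymetry":
        column, focal, complement = "bath_category", "shallow", "deep"
    else:
        raise ValueError("axis must be 'substrate' or 'bathymetry'")

    classifiable = occurrences[occurrences[column] != "unknown"]
    if len(classifiable) == 0:
        return pd.DataFrame(
            columns=["species", "category_axis", "affinity", "p_value", "n_in", "n_total", "background_prop"]
        )
    background = (classifiable[column] == focal).mean()
    background = min(max(background, 1e-12), 1 - 1e-12)

    rows = []
    for sp, grp in classifiable.groupby("species"):
        res = affinity_test(
            int((grp[column] == focal).sum()),
            len(grp),
            background,
            alpha,
            species=sp,
            category_axis=axis,
            focal=focal,
            complement=complement,
            two_tailed=two_tailed,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
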