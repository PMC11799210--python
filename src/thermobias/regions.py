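"""Bioregionalisation: spatial and ecological clustering of occurrences.

Discrete analysis regions are built by agglomerative clustering of unique
occurrence paleocoordinates (Euclidean distance on degrees, Ward linkage by
default). An independent ecological clustering of localities by Jaccard
distance on species incidence validates the spatial partition; a
pair-counting (Rand) agreement index compares the two. Regions are flagged
analyzable when they are consistently sampled above an occurrence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .timebins import TimeBinSequence


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_spatial(
    points: np.ndarray | pd.DataFrame,
    k: int = 10,
    linkage: str = "ward",
    great_circle: bool = False,
) -> np.ndarray:
    """Partition unique coordinate points into ``k`` agglomerative clusters.

    Euclidean distance on raw degree coordinates by default (a great-circle
    option is available). The input is sorted lexicographically before
    clustering so the partition is invariant to row order; labels are
    returned in the original row order, numbered by first appearance in
    lexicographic point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of lon, lat")
    if k < 2:
        raise ValueError("k must be >= 2")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < k:
        raise ValueError(f"need at least k={k} distinct points, have {uniq.shape[0]}")

    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    sorted_pts = uniq[order]
    if great_circle:
        from .climate import _great_circle_km

        n = sorted_pts.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            d[i] = _great_circle_km(
                sorted_pts[i, 0], sorted_pts[i, 1], sorted_pts[:, 0], sorted_pts[:, 1]
            )
        condensed = d[np.triu_indices(n, k=1)]
    else:
        condensed = pdist(sorted_pts, metric="euclidean")
    Z = scipy_linkage(condensed, method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    canon = _canonical_labels(raw)

    # Map unique-point labels back to the input rows.
    label_of_sorted = {tuple(p): int(l) for p, l in zip(sorted_pts, canon)}
    return np.array([label_of_sorted[tuple(p)] for p in pts], dtype=int)


def cluster_ecological(
    presence_matrix: pd.DataFrame,
    k: int = 10,
    min_species: int = 14,
    linkage: str = "average",
) -> pd.Series:
    """Cluster localities by Jaccard distance on species incidence.

    ``presence_matrix`` has localities as rows and species as columns
    (boolean/0-1). Clusters whose pooled species richness falls below
    ``min_species`` (default 14) are removed — small samples tend to drive
    dissimilarity through absences — and their localities labelled -1.

    Returns a Series of cluster labels indexed by locality.
    """
    if presence_matrix.empty:
        raise ValueError("presence matrix is empty")
    mat = presence_matrix.astype(bool)
    k = min(k, len(mat))
    d = pdist(mat.values, metric="jaccard")
    Z = scipy_linkage(d, method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(_canonical_labels(raw), index=mat.index, name="cluster")

    for lab in labels.unique():
        members = mat.loc[labels[labels == lab].index]
        richness = int(members.any(axis=0).sum())
        if richness < min_species:
            labels[labels == lab] = -1
    return labels


def agreement(partition_a, partition_b) -> float:
    """Pair-counting (Rand) agreement between two partitions of one item set.

    The fraction of item pairs on whose co-assignment the two partitions
    agree; 1 iff the partitions are identical up to relabelling.
    """
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same items")
    n = a.size
    if n < 2:
        return 1.0
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float((same_a[iu] == same_b[iu]).mean())


@dataclass
class RegionAssignment:
    """Occurrence-to-region mapping with per-region validity bookkeeping."""

    occurrence_region: pd.Series            # occurrence_id -> region_id
    bin_counts: pd.DataFrame                # region_id x time_bin occurrence counts
    analyzable: dict[int, bool] = field(default_factory=dict)
    labels: dict[int, str] = field(default_factory=dict)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self.bin_counts.index)

    def member_count(self, region_id: int) -> int:
        return int(self.bin_counts.loc[region_id].sum())

    def to_frame(self) -> pd.DataFrame:
        return self.occurrence_region.rename("region_id").rename_axis("occurrence_id").reset_index()

    def report(self) -> dict:
        return {
            "regions": {
                int(r): {
                    "label": self.labels.get(r, str(r)),
                    "n_occurrences": self.member_count(r),
                    "per_bin": {str(b): int(c) for b, c in self.bin_counts.loc[r].items()},
                    "analyzable": bool(self.analyzable.get(r, False)),
                }
                for r in self.region_ids
            }
        }


def assign_regions(
    occurrences: pd.DataFrame,
    k: int = 10,
    linkage: str = "ward",
    bin_sequence: TimeBinSequence | None = None,
    lon_col: str = "paleo_lon_primary",
    lat_col: str = "paleo_lat_primary",
) -> RegionAssignment:
    """Cluster occurrence paleocoordinates into regions and tabulate counts.

    Collections are pooled into unique coordinates before clustering; every
    occurrence inherits its coordinate's cluster.
    """
    seq = bin_sequence or TimeBinSequence()
    pts = occurrences[[lon_col, lat_col]].to_numpy(dtype=float)
    ok = np.isfinite(pts).all(axis=1)
    labels = np.full(len(occurrences), -1, dtype=int)
    labels[ok] = cluster_spatial(pts[ok], k=k, linkage=linkage)

    occ_region = pd.Series(labels, index=occurrences["occurrence_id"].values)
    df = pd.DataFrame(
        {"region_id": labels, "time_bin": occurrences["time_bin"].values}
    )
    df = df[df["region_id"] >= 0]
    counts = (
        df.groupby(["region_id", "time_bin"]).size().unstack(fill_value=0)
    )
    bin_order = [b for b in seq.all_bins if b in counts.columns]
    counts = counts.reindex(columns=bin_order, fill_value=0)
    return RegionAssignment(occ_region, counts)


def flag_analyzable(
    assignment: RegionAssignment,
    min_occ_per_bin: int = 25,
    bin_sequence: TimeBinSequence | None = None,
    whitelist: set[int] | None = None,
) -> RegionAssignment:
    """Mark regions analyzable: sampled above ``min_occ_per_bin`` (strict >)
    in at least two consecutive bins of the analysis sequence. Whitelisted
    regions are analyzable regardless (mirroring expert inclusion of a region
    whose gaps are ecologically, not sampling-, driven).
    """
    seq = bin_sequence or TimeBinSequence()
    whitelist = whitelist or set()
    flags: dict[int, bool] = {}
    for r in assignment.region_ids:
        if r in whitelist:
            flags[r] = True
            continue
        row = assignment.bin_counts.loc[r]
        ok = [
            (row.get(b, 0) > min_occ_per_bin) and (row.get(nb, 0) > min_occ_per_bin)
            for b, nb in seq.boundaries()
        ]
        flags[r] = any(ok)
    assignment.analyzable = flags
    return assignment
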