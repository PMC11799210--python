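"""Ordered time-bin sequences (ammonite zones) with flanking bins.

The analysis resolves time to ammonite (sub)zones, ~1 Myr bins that can be
correlated across regions. The default sequence spans the late Pliensbachian
to middle Toarcian; the bins immediately before and after the sequence
(Davoei, Variabilis) are tracked as *flanking* bins because edge-boundary
occupancy classification may draw on dataset-wide presences there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_BINS: tuple[str, ...] = (
    "Margaritatus",
    "Spinatum",
    "Tenuicostatum",
    "Exaratum",
    "Falciferum",
    "Bifrons",
)

DEFAULT_FLANKS: tuple[str, str] = ("Davoei", "Variabilis")


@dataclass(frozen=True)
class TimeBinSequence:
    """An ordered sequence of time-bin labels plus flanking bins.

    Bin *i* in ``bins`` has numeric index ``i``; the flanking bin before the
    first has index ``-1`` and the one after the last has index ``len(bins)``.
    """

    bins: tuple[str, ...] = DEFAULT_BINS
    flank_before: str = DEFAULT_FLANKS[0]
    flank_after: str = DEFAULT_FLANKS[1]

    def __post_init__(self) -> None:
        labels = self.all_bins
        if len(set(labels)) != len(labels):
            raise ValueError("time bin labels must be unique")
        if len(self.bins) < 2:
            raise ValueError("need at least two bins to form a boundary")

    @property
    def n(self) -> int:
        return len(self.bins)

    @property
    def all_bins(self) -> tuple[str, ...]:
        """All labels in time order, flanking bins included."""
        return (self.flank_before, *self.bins, self.flank_after)

    def index(self, label: str) -> int:
        """Numeric index of *label*; flanks map to -1 and ``n``."""
        if label == self.flank_before:
            return -1
        if label == self.flank_after:
            return self.n
        try:
            return self.bins.index(label)
        except ValueError:
            raise KeyError(f"unknown time bin {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self.all_bins

    def label(self, index: int) -> str:
        """Inverse of :meth:`index`."""
        if index == -1:
            return self.flank_before
        if index == self.n:
            return self.flank_after
        if 0 <= index < self.n:
            return self.bins[index]
        raise IndexError(f"bin index {index} out of range")

    def boundaries(self) -> list[tuple[str, str]]:
        """The ``n - 1`` ordered boundaries (bin_i, bin_i+1) within the sequence."""
        return list(zip(self.bins[:-1], self.bins[1:]))

    def boundary_label(self, i: int) -> str:
        """Human-readable label for the boundary after bin index *i*."""
        return f"{self.bins[i]}-{self.bins[i + 1]}"
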