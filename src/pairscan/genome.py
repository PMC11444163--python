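"""Genomic coordinate conventions, interval algebra, and bin grids.

All internal coordinates are 0-based, half-open ``[start, end)``. Conversions
to and from 1-based formats (VCF) happen only at parse/serialize boundaries
in :mod:`pairscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeDef",
    "Region",
    "BinGrid",
    "GenomicTrack",
    "make_bins",
    "overlap_bp",
    "merge_regions",
]

_VALID_STRANDS = {None, "+", "-", "."}


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome name ("chr"-prefixed canonical).
    start, end : int
        0-based half-open coordinates; ``0 <= start < end``.
    strand : str, optional
        One of ``+``, ``-``, ``.`` or None.
    """

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"coordinate inversion or empty interval: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return overlap_bp(self, other) > 0

    def contains(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # chrX:100-200 display form
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: Region, b: Region) -> int:
    """Number of base pairs shared by two regions (0 if different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class GenomeDef:
    """An ordered set of chromosomes with lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        names = tuple(self.chrom_names)
        object.__setattr__(self, "chrom_names", names)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if set(names) != set(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths disagree")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")

    @classmethod
    def from_lengths(cls, lengths: dict[str, int]) -> "GenomeDef":
        return cls(tuple(lengths), dict(lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def contains_region(self, region: Region) -> bool:
        return (
            region.chrom in self.chrom_lengths
            and region.end <= self.chrom_lengths[region.chrom]
        )

    def validate_region(self, region: Region) -> None:
        if region.chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {region.chrom!r}")
        if region.end > self.chrom_lengths[region.chrom]:
            raise ValueError(
                f"region {region} exceeds {region.chrom} length "
                f"{self.chrom_lengths[region.chrom]}"
            )


class BinGrid:
    """Consecutive fixed-width bins tiling every chromosome of a genome.

    Every bin has width ``bin_size`` except possibly the last bin of each
    chromosome, which is retained (flagged short via its actual width), so
    the tiling covers every base exactly once.
    """

    def __init__(self, genome: GenomeDef, bin_size: int) -> None:
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        self.genome = genome
        self.bin_size = int(bin_size)

        offsets: dict[str, int] = {}
        n_per_chrom: dict[str, int] = {}
        starts: list[np.ndarray] = []
        ends: list[np.ndarray] = []
        chrom_idx: list[np.ndarray] = []
        off = 0
        for ci, chrom in enumerate(genome.chrom_names):
            L = genome.length_of(chrom)
            n = -(-L // bin_size)  # ceil
            offsets[chrom] = off
            n_per_chrom[chrom] = n
            s = np.arange(n, dtype=np.int64) * bin_size
            e = np.minimum(s + bin_size, L)
            starts.append(s)
            ends.append(e)
            chrom_idx.append(np.full(n, ci, dtype=np.int32))
            off += n
        self.offsets = offsets
        self.n_per_chrom = n_per_chrom
        self.starts = np.concatenate(starts)
        self.ends = np.concatenate(ends)
        self.chrom_index = np.concatenate(chrom_idx)
        self.n_bins = off

    def __len__(self) -> int:
        return self.n_bins

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def chroms(self) -> np.ndarray:
        """Chromosome name per bin."""
        return np.asarray(self.genome.chrom_names, dtype=object)[self.chrom_index]

    def region(self, i: int) -> Region:
        chrom = self.genome.chrom_names[self.chrom_index[i]]
        return Region(chrom, int(self.starts[i]), int(self.ends[i]))

    def __iter__(self) -> Iterator[Region]:
        for i in range(self.n_bins):
            yield self.region(i)

    def bin_span(self, region: Region) -> tuple[int, int]:
        """Global [first, last) bin index range overlapping ``region``."""
        self.genome.validate_region(region)
        off = self.offsets[region.chrom]
        first = off + region.start // self.bin_size
        last = off + (region.end - 1) // self.bin_size + 1
        return first, last

    def bin_indices(self, region: Region) -> np.ndarray:
        first, last = self.bin_span(region)
        return np.arange(first, last)

    def region_of_bins(self, first: int, last: int) -> Region:
        """Region covered by the global bin index range [first, last)."""
        if not (0 <= first < last <= self.n_bins):
            raise ValueError("bin range out of bounds")
        if self.chrom_index[first] != self.chrom_index[last - 1]:
            raise ValueError("bin range crosses a chromosome boundary")
        chrom = self.genome.chrom_names[self.chrom_index[first]]
        return Region(chrom, int(self.starts[first]), int(self.ends[last - 1]))


def make_bins(genome: GenomeDef, bin_size: int = 1000) -> BinGrid:
    """Partition a genome into consecutive fixed-width bins (default 1 kb)."""
    return BinGrid(genome, bin_size)


@dataclass
class GenomicTrack:
    """Scored intervals (recurrence counts, CN sums, peak intensities...).

    Regions are kept sorted by (chromosome, start); scores must be finite.
    """

    regions: list[Region]
    scores: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.regions) != len(self.scores):
            raise ValueError("regions and scores length mismatch")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError(f"non-finite score in track {self.name!r}")
        order = sorted(
            range(len(self.regions)),
            key=lambda i: (self.regions[i].chrom, self.regions[i].start),
        )
        self.regions = [self.regions[i] for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.regions)

    def to_bins(self, grid: BinGrid, missing: float = 0.0,
                min_fraction: float = 0.0) -> np.ndarray:
        """Maximum score over intervals overlapping each bin (``missing``
        elsewhere). ``min_fraction`` requires an interval to cover at least
        that fraction of a bin to contribute (e.g. 0.5 keeps interval
        boundaries from bleeding into barely-touched edge bins)."""
        out = np.full(grid.n_bins, missing, dtype=float)
        for region, score in zip(self.regions, self.scores):
            if region.chrom not in grid.genome.chrom_lengths:
                continue
            clipped = Region(
                region.chrom,
                region.start,
                min(region.end, grid.genome.length_of(region.chrom)),
            )
            first, last = grid.bin_span(clipped)
            idx = np.arange(first, last)
            ov = (np.minimum(grid.ends[idx], clipped.end)
                  - np.maximum(grid.starts[idx], clipped.start))
            idx = idx[ov >= min_fraction * grid.widths[idx]]
            np.maximum.at(out, idx, score)
        return out


def merge_regions(regions: Sequence[Region], gap: int = 0) -> list[Region]:
    """Merge regions whose gaps are <= ``gap`` bp; input need not be sorted."""
    if not regions:
        return []
    out: list[Region] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if out and r.chrom == out[-1].chrom and r.start - out[-1].end <= gap:
            last = out[-1]
            out[-1] = Region(last.chrom, last.start, max(last.end, r.end))
        else:
            out.append(Region(r.chrom, r.start, r.end))
    return out
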