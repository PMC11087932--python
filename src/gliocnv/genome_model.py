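"""Reference-genome geometry: builds, bin grids, marker regions, exclusion masks.

Everything downstream of read counting is indexed by a :class:`BinGrid` — the
genome tiled into fixed-width windows (500 kb by default). This module owns
that coordinate backbone: chromosome lengths and centromere tables for hg19
and hg38 (shipped as packaged data, overridable), the glioma marker catalog
(CDKN2A/B, EGFR, 1p, 19q, chr7, chr10), and the centromere exclusion mask.

All coordinates are 0-based half-open internally; 1-based conventions (WIG)
are converted at the I/O boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidBuildError, InvalidParameterError, MarkerLookupError

DEFAULT_BIN_SIZE = 500_000
MIN_BIN_SIZE = 10_000

#: canonical chromosome order for human builds
HUMAN_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

MARKER_IDS = ("CDKN2AB", "EGFR", "ARM_1P", "ARM_19Q", "CHR7", "CHR10")
FOCAL_MARKERS = ("CDKN2AB", "EGFR")


def _read_packaged(name: str) -> str:
    return resources.files("gliocnv.data").joinpath(name).read_text()


@dataclass(frozen=True)
class GenomeBuild:
    """A reference build: chromosome lengths, arm boundaries, gap regions.

    ``arm_boundaries`` maps each chromosome to its centromere midpoint; the p
    arm is ``[0, boundary)`` and the q arm ``[boundary, length)``.
    ``gap_regions`` are (chrom, start, end) intervals (centromeres and
    adjacent gaps) excluded from analysis.
    """

    name: str
    chrom_lengths: Mapping[str, int]
    arm_boundaries: Mapping[str, int]
    gap_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        if not self.chrom_lengths:
            raise InvalidBuildError("build has no chromosomes")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise InvalidBuildError(f"{chrom}: non-positive length {length}")
        for chrom, boundary in self.arm_boundaries.items():
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise InvalidBuildError(f"arm boundary for unknown chromosome {chrom}")
            if not 0 < boundary < length:
                raise InvalidBuildError(
                    f"{chrom}: arm boundary {boundary} not inside (0, {length})"
                )
        for chrom, start, end in self.gap_regions:
            length = self.chrom_lengths.get(chrom)
            if length is None:
                raise InvalidBuildError(f"gap on unknown chromosome {chrom}")
            if not (0 <= start <= end <= length):
                raise InvalidBuildError(
                    f"gap {chrom}:{start}-{end} outside chromosome bounds"
                )

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    @classmethod
    def load(cls, name: str) -> "GenomeBuild":
        """Load a shipped human build (``hg19`` or ``hg38``)."""
        if name not in ("hg19", "hg38"):
            raise InvalidBuildError(f"unknown shipped build {name!r} (hg19/hg38)")
        lengths: dict[str, int] = {}
        for line in _read_packaged(f"{name}.chrom.sizes").splitlines():
            if not line.strip():
                continue
            chrom, size = line.split("\t")
            lengths[chrom] = int(size)
        lengths = {c: lengths[c] for c in HUMAN_CHROMS}
        gaps: list[tuple[str, int, int]] = []
        boundaries: dict[str, int] = {}
        for line in _read_packaged(f"{name}.gaps.bed").splitlines():
            if not line.strip():
                continue
            chrom, start, end, label = line.split("\t")
            gaps.append((chrom, int(start), int(end)))
            if label == "centromere":
                boundaries[chrom] = (int(start) + int(end)) // 2
        return cls(name=name, chrom_lengths=lengths,
                   arm_boundaries=boundaries, gap_regions=tuple(gaps))


@dataclass(frozen=True)
class BinGrid:
    """The genome tiled into fixed-width bins, in genomic order.

    Bins tile each chromosome ``[0, length)`` without gap or overlap; the last
    bin of a chromosome may be short. ``index[(chrom, start)]`` gives the
    ordinal position of a bin.
    """

    build: GenomeBuild
    bin_size: int
    chrom: np.ndarray        # str per bin
    start: np.ndarray        # int64 per bin
    end: np.ndarray          # int64 per bin
    index: dict = field(repr=False)
    chrom_slices: dict = field(repr=False)  # chrom -> slice into the bin arrays

    @property
    def n_bins(self) -> int:
        return self.start.size

    def autosomal_mask(self) -> np.ndarray:
        """True for bins on chr1–chr22 (toy builds: any non chrX/chrY name)."""
        return np.array([c not in ("chrX", "chrY") for c in self.chrom])

    def chrom_of(self, ordinal: int) -> str:
        return str(self.chrom[ordinal])


def build_bin_grid(build: GenomeBuild, bin_size: int = DEFAULT_BIN_SIZE) -> BinGrid:
    """Tile every chromosome of ``build`` into ``bin_size`` windows.

    The number of bins per chromosome is ``ceil(length / bin_size)``;
    deterministic for fixed inputs.
    """
    if bin_size is None or bin_size <= 0:
        raise InvalidParameterError(f"bin_size must be positive, got {bin_size}")
    if bin_size < MIN_BIN_SIZE:
        raise InvalidParameterError(
            f"bin_size {bin_size} below the minimum of {MIN_BIN_SIZE} bp"
        )
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    slices: dict[str, slice] = {}
    for chrom, length in build.chrom_lengths.items():
        n = math.ceil(length / bin_size)
        first = len(starts)
        for i in range(n):
            chroms.append(chrom)
            starts.append(i * bin_size)
            ends.append(min((i + 1) * bin_size, length))
        slices[chrom] = slice(first, len(starts))
    start_arr = np.asarray(starts, dtype=np.int64)
    return BinGrid(
        build=build,
        bin_size=int(bin_size),
        chrom=np.asarray(chroms, dtype=object),
        start=start_arr,
        end=np.asarray(ends, dtype=np.int64),
        index={(c, s): i for i, (c, s) in enumerate(zip(chroms, starts))},
        chrom_slices=slices,
    )


@dataclass(frozen=True)
class MarkerRegion:
    marker_id: str
    kind: str  # focal | arm | whole_chromosome
    regions: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class MarkerCatalog:
    """The glioma CNV marker regions for one build."""

    build_name: str
    entries: tuple[MarkerRegion, ...]

    def get(self, marker_id: str) -> MarkerRegion:
        for entry in self.entries:
            if entry.marker_id == marker_id:
                return entry
        raise MarkerLookupError(f"unknown marker {marker_id!r}")

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(e.marker_id for e in self.entries)

    @classmethod
    def default(cls, build: GenomeBuild) -> "MarkerCatalog":
        """Shipped catalog: focal genes from packaged BED, arms/chromosomes
        derived from the build's arm boundaries."""
        focal: dict[str, list[tuple[str, int, int]]] = {}
        for line in _read_packaged(f"{build.name}.markers.bed").splitlines():
            if not line.strip():
                continue
            chrom, start, end, name = line.split("\t")
            focal.setdefault(name, []).append((chrom, int(start), int(end)))
        entries = [
            MarkerRegion("CDKN2AB", "focal", tuple(focal["CDKN2AB"])),
            MarkerRegion("EGFR", "focal", tuple(focal["EGFR"])),
            MarkerRegion("ARM_1P", "arm",
                         (("chr1", 0, build.arm_boundaries["chr1"]),)),
            MarkerRegion("ARM_19Q", "arm",
                         (("chr19", build.arm_boundaries["chr19"],
                           build.chrom_lengths["chr19"]),)),
            MarkerRegion("CHR7", "whole_chromosome",
                         (("chr7", 0, build.chrom_lengths["chr7"]),)),
            MarkerRegion("CHR10", "whole_chromosome",
                         (("chr10", 0, build.chrom_lengths["chr10"]),)),
        ]
        return cls(build_name=build.name, entries=tuple(entries))

    @classmethod
    def from_regions(cls, build_name: str,
                     regions: Mapping[str, tuple[str, Sequence[tuple[str, int, int]]]]
                     ) -> "MarkerCatalog":
        """Build a catalog from ``{marker_id: (kind, [(chrom,start,end),...])}``
        — used for toy builds in tests and for user overrides."""
        entries = tuple(
            MarkerRegion(mid, kind, tuple(regs)) for mid, (kind, regs) in regions.items()
        )
        return cls(build_name=build_name, entries=entries)


def locate_marker_bins(catalog: MarkerCatalog, grid: BinGrid, marker_id: str
                       ) -> np.ndarray:
    """Ordinals of every grid bin overlapping the marker's region(s).

    Overlap is half-open ([start, end) vs [bin_start, bin_end)). The result is
    sorted, unique, and non-empty.
    """
    entry = catalog.get(marker_id)
    if catalog.build_name != grid.build.name:
        raise MarkerLookupError(
            f"catalog is for build {catalog.build_name!r}, grid for {grid.build.name!r}"
        )
    hits: set[int] = set()
    for chrom, start, end in entry.regions:
        sl = grid.chrom_slices.get(chrom)
        if sl is None:
            raise MarkerLookupError(
                f"marker {marker_id} on {chrom}, absent from grid build"
            )
        bin_starts = grid.start[sl]
        bin_ends = grid.end[sl]
        overlap = (bin_starts < end) & (bin_ends > start)
        hits.update(int(i) for i in np.nonzero(overlap)[0] + sl.start)
    if not hits:
        raise MarkerLookupError(f"marker {marker_id} overlaps no bin on this grid")
    return np.asarray(sorted(hits), dtype=np.int64)


def exclusion_mask(grid: BinGrid, padding_bins: int = 1) -> np.ndarray:
    """Boolean mask (True = excluded) over bins hitting a gap region, padded
    by ``padding_bins`` neighbours on each side within the same chromosome."""
    if padding_bins < 0:
        raise InvalidParameterError("padding_bins must be >= 0")
    mask = np.zeros(grid.n_bins, dtype=bool)
    for chrom, gstart, gend in grid.build.gap_regions:
        sl = grid.chrom_slices.get(chrom)
        if sl is None:
            continue
        bin_starts = grid.start[sl]
        bin_ends = grid.end[sl]
        hit = np.nonzero((bin_starts < gend) & (bin_ends > gstart))[0]
        if hit.size == 0:
            continue
        lo = max(hit.min() - padding_bins, 0)
        hi = min(hit.max() + padding_bins, bin_ends.size - 1)
        mask[sl.start + lo: sl.start + hi + 1] = True
    return mask
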