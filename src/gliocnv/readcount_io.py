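"""Per-bin read counting from alignments and fixed-step WIG round-tripping.

Counting convention: a retained read increments exactly the bin containing
its leftmost aligned position. Reads are dropped when unmapped, below the
mapping-quality threshold (default 20), or secondary/supplementary —
long-read aligners routinely emit supplementary records that would otherwise
double-count a molecule. Every dropped read is accounted for in
``filter_stats`` so that counted + filtered == records scanned.

WIG files are fixedStep with ``step == span == bin_size``, one declaration
line per chromosome, 1-based starts (converted to the grid's 0-based
coordinates on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pysam

from .errors import GridConsistencyError, InputFormatError
from .genome_model import BinGrid

DEFAULT_MIN_MAPQ = 20


@dataclass
class BinCounts:
    """Raw per-bin read counts with optional GC / mappability annotations.

    ``counts`` is float-valued so that missing bins can be NaN and noiseless
    simulations can carry exact expectations; real counting always produces
    non-negative integers. ``gc`` and ``mappability`` are fractions in [0, 1]
    with NaN where unknown.
    """

    grid: BinGrid
    counts: np.ndarray
    gc: np.ndarray = None
    mappability: np.ndarray = None
    total_reads: int = 0
    sample_id: str = "sample"
    filter_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.grid.n_bins:
            raise GridConsistencyError(
                f"counts length {self.counts.size} != grid bins {self.grid.n_bins}"
            )
        if self.gc is None:
            self.gc = np.full(self.grid.n_bins, np.nan)
        if self.mappability is None:
            self.mappability = np.full(self.grid.n_bins, np.nan)
        for name in ("gc", "mappability"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != self.grid.n_bins:
                raise GridConsistencyError(f"{name} track length mismatch")
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise GridConsistencyError(f"{name} values outside [0, 1]")
            setattr(self, name, arr)


def _reconcile_contig(name: str, grid: BinGrid) -> Optional[str]:
    """Match an alignment contig name to a grid chromosome, tolerating the
    presence/absence of the ``chr`` prefix."""
    if name in grid.chrom_slices:
        return name
    alt = name[3:] if name.startswith("chr") else f"chr{name}"
    if alt in grid.chrom_slices:
        return alt
    return None


def count_reads_in_bins(alignment_path: str, grid: BinGrid,
                        min_mapq: int = DEFAULT_MIN_MAPQ,
                        drop_secondary: bool = True,
                        sample_id: str | None = None) -> BinCounts:
    """Count reads per grid bin from a coordinate-sorted SAM/BAM file.

    Records are streamed sequentially (no index needed); the header must
    declare ``SO:coordinate``. Contigs absent from the grid are skipped and
    counted in ``filter_stats['skipped_contig']``.
    """
    with pysam.AlignmentFile(alignment_path, check_sq=False) as af:
        so = (af.header.get("HD") or {}).get("SO")
        if so != "coordinate":
            raise InputFormatError(
                f"{alignment_path}: alignment must be coordinate-sorted "
                f"(header SO={so!r})"
            )
        counts = np.zeros(grid.n_bins, dtype=np.int64)
        stats = {"scanned": 0, "counted": 0, "unmapped": 0, "low_mapq": 0,
                 "secondary_or_supplementary": 0, "skipped_contig": 0}
        contig_map: dict[str, Optional[str]] = {}
        for read in af.fetch(until_eof=True):
            stats["scanned"] += 1
            if read.is_unmapped:
                stats["unmapped"] += 1
                continue
            if drop_secondary and (read.is_secondary or read.is_supplementary):
                stats["secondary_or_supplementary"] += 1
                continue
            if read.mapping_quality < min_mapq:
                stats["low_mapq"] += 1
                continue
            ref = read.reference_name
            if ref not in contig_map:
                contig_map[ref] = _reconcile_contig(ref, grid)
            chrom = contig_map[ref]
            if chrom is None:
                stats["skipped_contig"] += 1
                continue
            sl = grid.chrom_slices[chrom]
            ordinal = sl.start + read.reference_start // grid.bin_size
            if ordinal >= sl.stop:  # past chromosome end (malformed record)
                stats["skipped_contig"] += 1
                continue
            counts[ordinal] += 1
            stats["counted"] += 1
    return BinCounts(grid=grid, counts=counts.astype(float),
                     total_reads=stats["scanned"],
                     sample_id=sample_id or alignment_path,
                     filter_stats=stats)


# ---------------------------------------------------------------------------
# fixedStep WIG
# ---------------------------------------------------------------------------

def _parse_fixedstep_header(line: str, lineno: int) -> dict:
    fields = {}
    for token in line.split()[1:]:
        if "=" not in token:
            raise InputFormatError(f"line {lineno}: malformed fixedStep token {token!r}")
        key, value = token.split("=", 1)
        fields[key] = value
    if "chrom" not in fields:
        raise InputFormatError(f"line {lineno}: fixedStep header missing chrom")
    try:
        fields["start"] = int(fields.get("start", 1))
        fields["step"] = int(fields["step"])
        fields["span"] = int(fields.get("span", fields["step"]))
    except (KeyError, ValueError) as exc:
        raise InputFormatError(f"line {lineno}: bad fixedStep header ({exc})") from exc
    return fields


def read_wig_values(path: str, grid: BinGrid) -> np.ndarray:
    """Read a fixedStep WIG into a per-bin float array (NaN where absent).

    ``step`` and ``span`` must equal the grid bin size; WIG 1-based starts are
    converted to the grid's 0-based bins.
    """
    values = np.full(grid.n_bins, np.nan)
    seen_header = False
    skip_chrom = False
    chrom = None
    ordinal = stop = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                seen_header = True
                fields = _parse_fixedstep_header(line, lineno)
                if fields["step"] != grid.bin_size or fields["span"] != grid.bin_size:
                    raise InputFormatError(
                        f"line {lineno}: step/span {fields['step']}/{fields['span']} "
                        f"does not match grid bin size {grid.bin_size}"
                    )
                chrom = _reconcile_contig(fields["chrom"], grid)
                skip_chrom = chrom is None  # unknown chromosome: ignore its values
                if skip_chrom:
                    continue
                sl = grid.chrom_slices[chrom]
                start0 = fields["start"] - 1
                if start0 % grid.bin_size != 0:
                    raise InputFormatError(
                        f"line {lineno}: start {fields['start']} not on the bin grid"
                    )
                ordinal = sl.start + start0 // grid.bin_size
                stop = sl.stop
            elif line.startswith("variableStep"):
                raise InputFormatError(f"line {lineno}: variableStep WIG not supported")
            else:
                if not seen_header:
                    raise InputFormatError(f"line {lineno}: value before fixedStep header")
                if skip_chrom:
                    continue
                if ordinal >= stop:
                    raise InputFormatError(
                        f"line {lineno}: more values than bins on {chrom}"
                    )
                try:
                    values[ordinal] = float(line)
                except ValueError as exc:
                    raise InputFormatError(f"line {lineno}: bad value {line!r}") from exc
                ordinal += 1
    return values


def read_wig(path: str, grid: BinGrid, sample_id: str | None = None) -> BinCounts:
    """Read a bin-count WIG profile onto ``grid``."""
    values = read_wig_values(path, grid)
    total = int(np.nansum(values)) if np.isfinite(values).any() else 0
    return BinCounts(grid=grid, counts=values, total_reads=total,
                     sample_id=sample_id or path)


def _format_value(v: float) -> str:
    if np.isfinite(v) and float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def write_wig(counts: BinCounts, path: str) -> None:
    """Write a BinCounts profile as fixedStep WIG (1-based starts).

    ``read_wig(write_wig(x)) == x`` bit-exactly for integer counts; NaN bins
    are written as ``nan`` and round-trip to NaN.
    """
    grid = counts.grid
    with open(path, "w") as fh:
        for chrom, sl in grid.chrom_slices.items():
            fh.write(
                f"fixedStep chrom={chrom} start=1 "
                f"step={grid.bin_size} span={grid.bin_size}\n"
            )
            for v in counts.counts[sl]:
                fh.write(_format_value(v) + "\n")


def read_track(path: str, grid: BinGrid) -> np.ndarray:
    """Read a per-bin value track: fixedStep WIG or 4-column TSV
    (chrom, start, end, value; 0-based half-open)."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(("fixedStep", "track")):
        return read_wig_values(path, grid)
    values = np.full(grid.n_bins, np.nan)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputFormatError(f"line {lineno}: expected 4 columns")
            chrom = _reconcile_contig(parts[0], grid)
            if chrom is None:
                continue
            key = (chrom, int(parts[1]))
            ordinal = grid.index.get(key)
            if ordinal is None:
                raise GridConsistencyError(
                    f"line {lineno}: interval {parts[0]}:{parts[1]} not on the grid"
                )
            values[ordinal] = float(parts[3])
    return values


def annotate_gc_mappability(counts: BinCounts,
                            gc_track: str | np.ndarray | None = None,
                            map_track: str | np.ndarray | None = None
                            ) -> BinCounts:
    """Return a copy of ``counts`` with GC / mappability fields populated
    from per-bin tracks (paths or arrays aligned to the grid)."""
    def resolve(track):
        if track is None:
            return None
        if isinstance(track, (str, bytes)):
            return read_track(track, counts.grid)
        arr = np.asarray(track, dtype=float)
        if arr.size != counts.grid.n_bins:
            raise GridConsistencyError("track length does not match the grid")
        return arr

    gc = resolve(gc_track)
    mp = resolve(map_track)
    return replace(
        counts,
        counts=counts.counts.copy(),
        gc=gc if gc is not None else counts.gc.copy(),
        mappability=mp if mp is not None else counts.mappability.copy(),
    )


def gc_fraction_from_fasta(fasta_path: str, grid: BinGrid) -> np.ndarray:
    """Per-bin GC fraction computed from a reference FASTA (N bases ignored;
    bins that are all-N get NaN)."""
    from pyfaidx import Fasta

    values = np.full(grid.n_bins, np.nan)
    with Fasta(fasta_path) as fa:
        for chrom, sl in grid.chrom_slices.items():
            name = chrom if chrom in fa else (
                chrom[3:] if chrom.startswith("chr") and chrom[3:] in fa else None
            )
            if name is None:
                continue
            for i in range(sl.start, sl.stop):
                seq = str(fa[name][grid.start[i]:grid.end[i]]).upper()
                acgt = sum(seq.count(b) for b in "ACGT")
                if acgt:
                    values[i] = (seq.count("G") + seq.count("C")) / acgt
    return values
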