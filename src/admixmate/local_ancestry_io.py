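"""Reading and writing local-ancestry calls.

Two plain-text interchange formats are defined here.

Ancestry-grid TSV (one row per sample/haplotype/chromosome)::

    sample  hap  chrom  sex  window_cm  calls
    NA001   0    chr1   F    0.1        1 1 1 3 3 2 ...

where ``calls`` is a space-separated list of per-window ancestry codes
(1, 2 or 3) on a fixed-width genetic grid (default 0.1 cM). Adapters for
RFMix-/Gnomix-style per-window matrices (windows in rows, haplotypes in
columns) are configured through a column map rather than hardcoded,
because native layouts vary between versions.

Segments BED dialect (half-open cM intervals)::

    sample  hap  chrom  start_cm  end_cm  ancestry

Per-haplotype records must tile the chromosome without gaps or overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AncestryGrid",
    "GridSample",
    "SegmentRecord",
    "ParseError",
    "read_ancestry_grid",
    "write_ancestry_grid",
    "grid_to_tracts",
    "read_segments_bed",
    "write_segments_bed",
    "validate_segments",
]

_VALID_CODES = frozenset((1, 2, 3))

_GRID_COLUMNS = ("sample", "hap", "chrom", "sex", "window_cm", "calls")
_BED_COLUMNS = ("sample", "hap", "chrom", "start_cm", "end_cm", "ancestry")


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class GridSample:
    """Calls of one haplotype on one chromosome's window grid."""

    sample: str
    hap: int
    chrom: str
    sex: str
    window_cm: float
    calls: np.ndarray

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.ndim != 1 or calls.size == 0:
            raise ValueError("calls must be a non-empty 1-D array")
        bad = set(np.unique(calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"unknown ancestry codes: {sorted(bad)}")
        object.__setattr__(self, "calls", calls)

    @property
    def length_cm(self) -> float:
        return self.calls.size * self.window_cm


@dataclass
class AncestryGrid:
    """A collection of per-haplotype window-call vectors."""

    entries: list[GridSample] = field(default_factory=list)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.sample, None)
        return list(seen)


@dataclass(frozen=True, order=True)
class SegmentRecord:
    """One maximal ancestry segment of a haplotype (cM, half-open)."""

    sample: str
    hap: int
    chrom: str
    start_cm: float
    end_cm: float
    ancestry: int

    def __post_init__(self):
        if not self.start_cm < self.end_cm:
            raise ValueError("segment must have start < end")
        if self.ancestry not in _VALID_CODES:
            raise ValueError(f"unknown ancestry code {self.ancestry}")

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


def read_ancestry_grid(path, dialect: str = "generic", column_map: Optional[dict] = None):
    """Parse an ancestry-grid file.

    ``dialect='generic'`` reads the TSV documented above.
    ``dialect='window_matrix'`` reads an RFMix-viterbi-like layout: one
    row per window, one whitespace-separated column per haplotype, with
    haplotype metadata supplied via ``column_map`` as
    ``{column_index: (sample, hap)}`` plus optional keys ``chrom``,
    ``sex_of`` (mapping sample -> sex) and ``window_cm``.
    """
    if dialect == "generic":
        return _read_generic_grid(path)
    if dialect == "window_matrix":
        if column_map is None:
            raise ValueError("window_matrix dialect requires a column_map")
        return _read_window_matrix(path, column_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_generic_grid(path) -> AncestryGrid:
    grid = AncestryGrid()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != _GRID_COLUMNS:
            raise ParseError(path, 1, f"expected header {' '.join(_GRID_COLUMNS)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_GRID_COLUMNS):
                raise ParseError(path, lineno, f"expected {len(_GRID_COLUMNS)} columns")
            sample, hap, chrom, sex, window_cm, calls = parts
            try:
                call_arr = np.array(calls.split(), dtype=int)
                entry = GridSample(
                    sample, int(hap), chrom, sex, float(window_cm), call_arr
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            grid.entries.append(entry)
    return grid


def _read_window_matrix(path, column_map: dict) -> AncestryGrid:
    chrom = column_map.get("chrom", "chr1")
    window_cm = float(column_map.get("window_cm", 0.1))
    sex_of = column_map.get("sex_of", {})
    hap_cols = {k: v for k, v in column_map.items() if isinstance(k, int)}
    columns: dict[int, list[int]] = {k: [] for k in hap_cols}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            for col in hap_cols:
                if col >= len(parts):
                    raise ParseError(path, lineno, f"missing column {col}")
                try:
                    columns[col].append(int(parts[col]))
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
    grid = AncestryGrid()
    for col, (sample, hap) in hap_cols.items():
        try:
            entry = GridSample(
                sample,
                hap,
                chrom,
                sex_of.get(sample, "F"),
                window_cm,
                np.array(columns[col], dtype=int),
            )
        except ValueError as exc:
            raise ParseError(path, 0, f"column {col}: {exc}") from exc
        grid.entries.append(entry)
    return grid


def write_ancestry_grid(grid: AncestryGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GRID_COLUMNS) + "\n")
        for e in grid.entries:
            calls = " ".join(str(int(c)) for c in e.calls)
            fh.write(
                f"{e.sample}\t{e.hap}\t{e.chrom}\t{e.sex}\t{e.window_cm:g}\t{calls}\n"
            )


def grid_to_tracts(grid: AncestryGrid) -> list[SegmentRecord]:
    """Run-length encode window calls into maximal ancestry segments."""
    out: list[SegmentRecord] = []
    for e in grid:
        calls = e.calls
        change = np.flatnonzero(np.diff(calls)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [calls.size]])
        for s, t in zip(starts, ends):
            out.append(
                SegmentRecord(
                    e.sample,
                    e.hap,
                    e.chrom,
                    s * e.window_cm,
                    t * e.window_cm,
                    int(calls[s]),
                )
            )
    return out


def validate_segments(segments: Sequence[SegmentRecord]) -> None:
    """Require per-haplotype records to tile their chromosome contiguously."""
    by_hap: dict[tuple, list[SegmentRecord]] = {}
    for seg in segments:
        by_hap.setdefault((seg.sample, seg.hap, seg.chrom), []).append(seg)
    for key, segs in by_hap.items():
        segs = sorted(segs, key=lambda s: s.start_cm)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start_cm < prev.end_cm - 1e-9:
                raise ValueError(f"{key}: overlapping segments at {cur.start_cm} cM")
            if cur.start_cm > prev.end_cm + 1e-9:
                raise ValueError(f"{key}: gap before {cur.start_cm} cM")


def write_segments_bed(segments: Iterable[SegmentRecord], path) -> None:
    segs = sorted(segments, key=lambda s: (s.sample, s.hap, s.chrom, s.start_cm))
    with open(path, "w") as fh:
        fh.write("\t".join(_BED_COLUMNS) + "\n")
        for s in segs:
            fh.write(
                f"{s.sample}\t{s.hap}\t{s.chrom}\t{s.start_cm:.6g}\t{s.end_cm:.6g}\t{s.ancestry}\n"
            )


def read_segments_bed(path, validate: bool = True) -> list[SegmentRecord]:
    out: list[SegmentRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != _BED_COLUMNS:
            raise ParseError(path, 1, f"expected header {' '.join(_BED_COLUMNS)}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_BED_COLUMNS):
                raise ParseError(path, lineno, f"expected {len(_BED_COLUMNS)} columns")
            try:
                out.append(
                    SegmentRecord(
                        parts[0],
                        int(parts[1]),
                        parts[2],
                        float(parts[3]),
                        float(parts[4]),
                        int(parts[5]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    if validate:
        validate_segments(out)
    return sorted(out, key=lambda s: (s.sample, s.hap, s.chrom, s.start_cm))
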