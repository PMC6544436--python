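"""Genomic interval model, BED/RepeatMasker readers and overlap primitives.

All coordinates are 0-based, half-open throughout the package. BED input is
taken as-is; RepeatMasker ``.out`` tables use 1-based inclusive starts and
are converted on read. Overlap means at least one shared base unless an
operation states a larger minimum, and all overlap logic ignores strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple


class FormatError(ValueError):
    """Raised for malformed or unrecognised annotation files."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bases(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TECopy:
    """One RepeatMasker-style transposable-element copy.

    ``length_fraction`` is the element length over the maximum length seen in
    its family; it is None until filled by family statistics.
    """

    interval: GenomicInterval
    subfamily: str
    copy_id: str
    family: str = ""
    length_fraction: Optional[float] = None

    def __post_init__(self):
        if not self.family:
            self.family = self.subfamily
        if self.length_fraction is not None and not (0 < self.length_fraction <= 1):
            raise ValueError("length_fraction must lie in (0, 1]")


#: assay labels understood throughout: ATAC, H3K27ac, H3K4me1, H3K4me3,
#: DNase, or TF:<name> for transcription-factor ChIP.
@dataclass
class Peak:
    interval: GenomicInterval
    assay: str
    signal: float = 0.0
    sample: str = ""

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError("peak signal must be non-negative")


class PeakSet:
    """Per-assay peak collections for one sample."""

    def __init__(self, sample: str, peaks: Iterable[Peak] = ()):
        self.sample = sample
        self.by_assay: Dict[str, List[Peak]] = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak) -> None:
        if peak.sample and peak.sample != self.sample:
            raise ValueError(
                f"peak sample {peak.sample!r} does not match set sample {self.sample!r}"
            )
        peak.sample = self.sample
        self.by_assay.setdefault(peak.assay, []).append(peak)

    def assays(self) -> List[str]:
        return sorted(self.by_assay)

    def intervals(self, assay: str) -> List[GenomicInterval]:
        return [p.interval for p in self.by_assay.get(assay, [])]

    def require(self, assays: Sequence[str]) -> None:
        missing = [a for a in assays if a not in self.by_assay]
        if missing:
            raise KeyError(
                f"peak set {self.sample!r} is missing required assays: {missing}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def read_bed(path, min_fields: int = 3) -> List[Tuple[GenomicInterval, List[str]]]:
    """Read a BED file; returns (interval, extra columns) per record."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < min_fields:
                raise FormatError(f"{path}: line {lineno}: expected >= {min_fields} fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            out.append((iv, fields[3:]))
    return out


def _parse_rm_out(path) -> List[TECopy]:
    copies = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            # header block: "SW perc perc..." / "score div. del..." lines
            if stripped.startswith(("SW", "score", "bit")):
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise FormatError(f"{path}: line {lineno}: too few columns for .out row")
            try:
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from None
            strand = "+" if fields[8] == "+" else "-"  # RM uses 'C' for reverse
            subfam = fields[9]
            iv = GenomicInterval(chrom, begin - 1, end, strand)  # 1-based -> 0-based
            copies.append(
                TECopy(interval=iv, subfamily=subfam, copy_id=f"{subfam}|{chrom}:{begin - 1}-{end}")
            )
    return copies


def _parse_te_bed(path) -> List[TECopy]:
    copies = []
    for iv, extra in read_bed(path, min_fields=4):
        subfam = extra[0]
        copies.append(
            TECopy(
                interval=iv,
                subfamily=subfam,
                copy_id=f"{subfam}|{iv.chrom}:{iv.start}-{iv.end}",
            )
        )
    return copies


def read_repeatmasker(path) -> List[TECopy]:
    """Read a TE annotation as RepeatMasker ``.out`` or 6-column BED.

    The dialect is sniffed from the first data line: a line whose second and
    third whitespace-separated fields are integers is taken as BED; a line
    with a numeric Smith-Waterman score and >= 11 columns as ``.out``.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            s = line.strip()
            if s and not s.startswith(("#", "track", "SW", "score", "bit")):
                first = s
                break
    if not first:
        return []
    fields = first.split()
    is_bed = False
    if len(fields) >= 4:
        try:
            int(fields[1]), int(fields[2])
            is_bed = True
        except ValueError:
            is_bed = False
    if is_bed:
        return _parse_te_bed(path)
    if len(fields) >= 11:
        return _parse_rm_out(path)
    raise FormatError(f"{path}: unrecognised TE annotation dialect")


def write_te_bed(copies: Iterable[TECopy], path) -> None:
    """Write TE copies as 6-column BED (name = subfamily, score = 0)."""
    with open(path, "w") as fh:
        for c in copies:
            iv = c.interval
            strand = iv.strand if iv.strand != "." else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.subfamily}\t0\t{strand}\n")


def read_tss_bed(path) -> List[Tuple[GenomicInterval, str]]:
    """Gene/TSS annotation: BED with the gene name in column 4."""
    return [(iv, extra[0] if extra else "") for iv, extra in read_bed(path, min_fields=4)]


# ---------------------------------------------------------------------------
# overlap primitives


def overlap(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> List[Tuple[int, int]]:
    """All index pairs (i, j) where a[i] and b[j] share >= min_overlap bases.

    Strand-blind. Uses a per-chromosome sweep over sorted endpoints; the
    result is sorted by (i, j).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    pairs: List[Tuple[int, int]] = []
    import bisect

    for i, iv in enumerate(a):
        cand = by_chrom.get(iv.chrom)
        if not cand:
            continue
        starts = [c[0] for c in cand]
        # any b interval with start < iv.end could overlap; scan and filter
        hi = bisect.bisect_left(starts, iv.end)
        for start, end, j in cand[:hi]:
            if min(iv.end, end) - max(iv.start, start) >= min_overlap:
                pairs.append((i, j))
    pairs.sort()
    return pairs


def overlaps_any(
    queries: Sequence[GenomicInterval],
    references: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> List[bool]:
    """Per-query flag: does it overlap any reference by >= min_overlap bases."""
    flags = [False] * len(queries)
    for i, _ in overlap(queries, references, min_overlap):
        flags[i] = True
    return flags


def distance_to_nearest(
    queries: Sequence[GenomicInterval],
    references: Sequence[GenomicInterval],
) -> List[int]:
    """Distance in bases from each query to its nearest reference.

    0 when overlapping; otherwise the gap between closest edges; ties go to
    the reference with the smaller start. Queries on chromosomes with no
    reference get a very large sentinel (2**63 - 1).
    """
    if not references:
        raise ValueError("reference interval set is empty")
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in references:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    sentinel = 2**63 - 1
    out = []
    for q in queries:
        refs = by_chrom.get(q.chrom)
        if not refs:
            out.append(sentinel)
            continue
        best = sentinel
        for start, end in refs:
            if min(q.end, end) > max(q.start, start):
                best = 0
                break
            # half-open coordinates: abutting intervals have gap 0
            gap = max(start - q.end, q.start - end)
            if gap < best:
                best = gap
        out.append(best)
    return out
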