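"""Family-level TE statistics, solo-LTR vs provirus calling, and mappability.

The mappability score of an element is the fraction of its length covered by
in-silico reads whose sequence occurs exactly once in the genome across both
strands — the desk-scale analogue of mapping simulated reads with an aligner
and keeping unique alignments. Reads tile every start position within the
element (stride 1), uniqueness is exact-match (no mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from ._sequtils import canonical, kmer_counts
from .intervals import TECopy


@dataclass
class FamilyStats:
    family: str
    n_copies: int
    max_length: int
    quartiles: tuple  # (q25, median, q75) of member lengths


@dataclass
class MappabilityScore:
    copy_id: str
    score: float
    read_length: int

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("mappability score must lie in [0, 1]")


def family_length_stats(copies: Sequence[TECopy]) -> Dict[str, FamilyStats]:
    """Per-family copy counts and length summaries; fills length_fraction.

    length_fraction = element length / maximum member length of its family,
    so the longest copy in each family scores exactly 1.0.
    """
    by_family: Dict[str, List[TECopy]] = {}
    for c in copies:
        by_family.setdefault(c.family, []).append(c)
    stats = {}
    for fam, members in by_family.items():
        lengths = np.array([len(m.interval) for m in members])
        max_len = int(lengths.max())
        q25, q50, q75 = np.percentile(lengths, [25, 50, 75])
        stats[fam] = FamilyStats(fam, len(members), max_len, (q25, q50, q75))
        for m in members:
            m.length_fraction = len(m.interval) / max_len
    return stats


def long_elements(copies: Iterable[TECopy], min_fraction: float = 0.60) -> List[TECopy]:
    """Copies longer than ``min_fraction`` of their family maximum (strict >)."""
    return [c for c in copies if c.length_fraction is not None and c.length_fraction > min_fraction]


def classify_solo_vs_provirus(
    copies: Sequence[TECopy],
    max_internal_gap: int = 15_000,
    min_internal_gap: int = 1_000,
) -> Dict[str, str]:
    """Label each copy solo / proviral_pair / ambiguous.

    Two consecutive same-subfamily copies whose inter-LTR gap falls inside
    [min_internal_gap, max_internal_gap] look like the paired LTRs of a
    provirus: same strand -> both proviral_pair; discordant strands ->
    ambiguous. Everything else is a solo LTR. Input must be sorted by
    (chrom, start).
    """
    coords = [(c.interval.chrom, c.interval.start) for c in copies]
    if coords != sorted(coords):
        raise ValueError("copies must be sorted by (chrom, start)")
    labels = {c.copy_id: "solo" for c in copies}
    for prev, cur in zip(copies, copies[1:]):
        if prev.interval.chrom != cur.interval.chrom:
            continue
        if prev.subfamily != cur.subfamily:
            continue
        gap = cur.interval.start - prev.interval.end
        if not (min_internal_gap <= gap <= max_internal_gap):
            continue
        if prev.interval.strand == cur.interval.strand and prev.interval.strand != ".":
            label = "proviral_pair"
        else:
            label = "ambiguous"
        # do not downgrade an existing proviral_pair label
        for c in (prev, cur):
            if labels[c.copy_id] != "proviral_pair":
                labels[c.copy_id] = label
    return labels


def build_kmer_index(genome: Mapping[str, str], read_length: int) -> Dict[str, int]:
    """Canonical k-mer multiplicity table for a genome (k = read_length)."""
    return kmer_counts(genome, read_length)


def mappability_score(
    copy: TECopy,
    genome: Mapping[str, str],
    read_length: int = 40,
    index: Optional[Dict[str, int]] = None,
) -> MappabilityScore:
    """Fraction of the element covered by >=1 globally unique read.

    Every read of ``read_length`` starting inside the element is classified
    unique iff its sequence (equivalently its reverse complement) occurs
    exactly once in the genome; covered bases are the union of unique-read
    spans clipped to the element.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    iv = copy.interval
    if len(iv) < read_length:
        raise ValueError(
            f"element {copy.copy_id} ({len(iv)} bp) shorter than read_length {read_length}"
        )
    if index is None:
        index = build_kmer_index(genome, read_length)
    seq = genome[iv.chrom]
    covered = np.zeros(len(iv), dtype=bool)
    last_start = min(iv.end, len(seq) - read_length + 1)
    for pos in range(iv.start, last_start):
        kmer = seq[pos : pos + read_length]
        if "N" in kmer:
            continue
        if index.get(canonical(kmer), 0) == 1:
            lo = max(pos, iv.start) - iv.start
            hi = min(pos + read_length, iv.end) - iv.start
            covered[lo:hi] = True
    return MappabilityScore(copy.copy_id, float(covered.mean()), read_length)


def mappable_filter(
    scores: Iterable[MappabilityScore], threshold: float = 0.5
) -> List[str]:
    """copy_ids with score strictly above ``threshold`` (default 0.5)."""
    return [s.copy_id for s in scores if s.score > threshold]


def write_scores_tsv(scores: Iterable[MappabilityScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("copy_id\tscore\tread_length\n")
        for s in scores:
            fh.write(f"{s.copy_id}\t{s.score:.6g}\t{s.read_length}\n")
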