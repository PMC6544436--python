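"""ChIP-seq read simulation at TE-centred peaks and peak recoverability.

The simulator plants an idealised immunoprecipitation peak on each element:
fragments of length ``fragment_length`` +/- a uniform jitter are centred on
the element midpoint and sequenced from a uniformly chosen end, plus uniform
background ("control") reads over a window of ``control_span`` around the
element. Mapping is replaced by an exact-uniqueness contract: a read counts
iff its sequence occurs exactly once in the genome across both strands. A
simplified Poisson caller stands in for MACS2: maximal runs of bases whose
count clears a Bonferroni-corrected upper-tail Poisson test, at least
``min_width`` wide, become peaks.

Recoverability then asks, per element, whether a peak called from the
post-mapping (unique-read) coverage still overlaps it; calling on the
pre-mapping coverage (all reads kept) recovers every element by construction
and serves as the control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._sequtils import canonical, revcomp
from .intervals import GenomicInterval, Peak
from .annotation import build_kmer_index


@dataclass
class SimulatedRead:
    chrom: str
    start: int
    length: int
    strand: str
    origin: str  # element_id or "background"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("read length must be positive")

    @property
    def end(self) -> int:
        return self.start + self.length

    def sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom][self.start : self.end]
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class RecoverabilityReport:
    recovered: Dict[str, bool]  # element_id -> post-mapping recovery flag
    premap_recovered: Dict[str, bool]
    per_family: Dict[str, Tuple[int, int]] = field(default_factory=dict)  # (recovered, failed)

    @property
    def n_recovered(self) -> int:
        return sum(self.recovered.values())

    @property
    def n_failed(self) -> int:
        return len(self.recovered) - self.n_recovered


def simulate_peak_reads(
    elements: Sequence[Tuple[str, GenomicInterval]],
    genome: Mapping[str, str],
    read_length: int = 40,
    fragment_length: int = 150,
    fragment_jitter: int = 40,
    depth: int = 200,
    background_depth: Optional[int] = None,
    control_span: int = 10_000,
    seed: int = 0,
) -> List[SimulatedRead]:
    """Simulate peak and control reads for each (element_id, interval).

    Per element: ``depth`` fragments centred on the element midpoint with
    length fragment_length + U{-jitter..jitter}; one read of ``read_length``
    is taken from a uniformly chosen fragment end (strand follows the end).
    ``background_depth`` (default = depth) uniform background reads are
    placed across element +/- control_span/2. Reads are clipped to contig
    bounds with a warning. Deterministic under ``seed``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if background_depth is None:
        background_depth = depth
    rng = np.random.default_rng(seed)
    reads: List[SimulatedRead] = []
    for element_id, iv in elements:
        contig_len = len(genome[iv.chrom])
        mid = (iv.start + iv.end) // 2
        # peak fragments
        if depth:
            jitters = rng.integers(-fragment_jitter, fragment_jitter + 1, size=depth)
            flens = np.maximum(fragment_length + jitters, read_length)
            frag_starts = mid - flens // 2
            frag_ends = frag_starts + flens
            from_five_prime = rng.integers(0, 2, size=depth).astype(bool)
            for fs, fe, five in zip(frag_starts, frag_ends, from_five_prime):
                if five:
                    start, strand = int(fs), "+"
                else:
                    start, strand = int(fe) - read_length, "-"
                start = _clip_start(start, read_length, contig_len, iv.chrom)
                reads.append(SimulatedRead(iv.chrom, start, read_length, strand, element_id))
        # background reads over the control window
        lo = mid - control_span // 2
        hi = mid + control_span // 2
        if lo < 0 or hi > contig_len:
            warnings.warn(
                f"control span around {element_id} clipped to contig bounds",
                stacklevel=2,
            )
            lo, hi = max(lo, 0), min(hi, contig_len)
        if background_depth:
            starts = rng.integers(lo, max(hi - read_length, lo + 1), size=background_depth)
            strands = rng.integers(0, 2, size=background_depth)
            for s, st in zip(starts, strands):
                reads.append(
                    SimulatedRead(iv.chrom, int(s), read_length, "+-"[st], "background")
                )
    return reads


def _clip_start(start: int, read_length: int, contig_len: int, chrom: str) -> int:
    if start < 0 or start + read_length > contig_len:
        warnings.warn(f"read clipped to bounds of {chrom}", stacklevel=3)
        start = min(max(start, 0), contig_len - read_length)
    return start


def coverage_all(
    reads: Sequence[SimulatedRead], genome: Mapping[str, str]
) -> Dict[str, np.ndarray]:
    """Per-base coverage counting every read (pre-mapping coverage)."""
    cov = {chrom: np.zeros(len(seq), dtype=np.int64) for chrom, seq in genome.items()}
    for r in reads:
        cov[r.chrom][r.start : r.end] += 1
    return cov


def place_reads_unique(
    reads: Sequence[SimulatedRead],
    genome: Mapping[str, str],
    index: Optional[Dict[str, int]] = None,
) -> Dict[str, np.ndarray]:
    """Per-base coverage keeping only reads whose sequence is genome-unique.

    A read contributes iff its sequence (either strand) occurs exactly once
    in the genome; multi-mapping reads are discarded, mirroring the
    uniquely-mapped-read filter of real pipelines.
    """
    if reads and index is None:
        k = reads[0].length
        index = build_kmer_index(genome, k)
    cov = {chrom: np.zeros(len(seq), dtype=np.int64) for chrom, seq in genome.items()}
    for r in reads:
        kmer = genome[r.chrom][r.start : r.end]
        if "N" in kmer:
            continue
        if index.get(canonical(kmer), 0) == 1:
            cov[r.chrom][r.start : r.end] += 1
    return cov


def call_peaks_poisson(
    coverage: Mapping[str, np.ndarray],
    background_lambda: float,
    min_width: int = 100,
    alpha: float = 0.05,
    merge_gap: int = 0,
) -> List[Peak]:
    """Poisson-test peak calling on per-base counts.

    A base is significant when its count has upper-tail Poisson probability
    (P[X >= count] under lambda = background_lambda) below alpha divided by
    the genome length (Bonferroni). Significant runs separated by fewer than
    ``merge_gap`` non-significant bases are joined (MACS2-style gap merging);
    runs at least ``min_width`` wide are reported, with signal = mean fold
    enrichment over background_lambda.
    """
    if background_lambda <= 0:
        raise ValueError("background_lambda must be positive")
    genome_length = int(sum(len(c) for c in coverage.values()))
    corrected = alpha / max(genome_length, 1)
    # minimal count whose upper tail beats the corrected threshold
    min_count = int(stats.poisson.isf(corrected, background_lambda)) + 1
    peaks: List[Peak] = []
    for chrom in sorted(coverage):
        sig = coverage[chrom] >= min_count
        if not sig.any():
            continue
        runs = _runs(sig)
        if merge_gap > 0:
            runs = _merge_runs(runs, merge_gap)
        for start, end in runs:
            if end - start < min_width:
                continue
            fold = float(coverage[chrom][start:end].mean() / background_lambda)
            peaks.append(
                Peak(GenomicInterval(chrom, int(start), int(end)), "simulated", fold)
            )
    return peaks


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: List[Tuple[int, int]], gap: int) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def poisson_upper_tail(count: int, lam: float) -> float:
    """P[X >= count] for X ~ Poisson(lam)."""
    return float(stats.poisson.sf(count - 1, lam))


def recoverability(
    elements: Sequence[Tuple[str, GenomicInterval]],
    genome: Mapping[str, str],
    families: Optional[Mapping[str, str]] = None,
    read_length: int = 40,
    fragment_length: int = 150,
    fragment_jitter: int = 40,
    depth: int = 200,
    control_span: int = 10_000,
    min_width: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    index: Optional[Dict[str, int]] = None,
) -> RecoverabilityReport:
    """Which elements still yield a called peak after unique-read filtering.

    Simulates reads, calls peaks on pre-mapping (all reads) and post-mapping
    (unique reads only) coverage, and flags each element recovered iff a
    called peak overlaps it. The background rate is estimated from the
    simulated control read density.
    """
    if not elements:
        raise ValueError("need at least one element")
    reads = simulate_peak_reads(
        elements,
        genome,
        read_length=read_length,
        fragment_length=fragment_length,
        fragment_jitter=fragment_jitter,
        depth=depth,
        control_span=control_span,
        seed=seed,
    )
    n_background = sum(1 for r in reads if r.origin == "background")
    # expected background coverage: reads spread over the control windows
    span_total = sum(
        min(control_span, len(genome[iv.chrom])) for _, iv in elements
    )
    background_lambda = max(n_background * read_length / max(span_total, 1), 1e-6)

    pre_cov = coverage_all(reads, genome)
    post_cov = place_reads_unique(reads, genome, index=index)
    merge_gap = 2 * read_length
    pre_peaks = call_peaks_poisson(pre_cov, background_lambda, min_width, alpha, merge_gap)
    post_peaks = call_peaks_poisson(post_cov, background_lambda, min_width, alpha, merge_gap)

    def hit_map(peaks: List[Peak]) -> Dict[str, bool]:
        from .intervals import overlaps_any

        ivs = [iv for _, iv in elements]
        flags = overlaps_any(ivs, [p.interval for p in peaks])
        return {eid: bool(f) for (eid, _), f in zip(elements, flags)}

    recovered = hit_map(post_peaks)
    premap = hit_map(pre_peaks)
    per_family: Dict[str, Tuple[int, int]] = {}
    if families:
        tally: Dict[str, List[int]] = {}
        for eid, _ in elements:
            fam = families.get(eid, "?")
            ok = recovered[eid]
            rec, fail = tally.get(fam, [0, 0])
            tally[fam] = [rec + ok, fail + (not ok)]
        per_family = {f: (v[0], v[1]) for f, v in tally.items()}
    return RecoverabilityReport(recovered, premap, per_family)


def reads_to_fastq(reads: Sequence[SimulatedRead], genome: Mapping[str, str], path) -> None:
    """Export simulated reads as FASTQ with fixed quality 'I'."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            seq = r.sequence(genome)
            fh.write(f"@read{i}|{r.origin}|{r.chrom}:{r.start}:{r.strand}\n")
            fh.write(seq + "\n+\n" + "I" * len(seq) + "\n")


def coverage_to_bedgraph(coverage: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            arr = coverage[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate([[0], change, [arr.size]])
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                val = int(arr[lo])
                if val:
                    fh.write(f"{chrom}\t{lo}\t{hi}\t{val}\n")
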