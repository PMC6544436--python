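"""Repeat-family sgRNA design for CRISPRi.

Candidate protospacers are every 20-mer immediately 5' of a PAM (default
NGG) on either strand of any target copy; identical protospacers found in
several copies merge into one guide with the union of hits. Two greedy panel
objectives mirror the two targeting strategies used for family-wide
interference: *breadth* maximises the number of copies hit by at least one
guide (classic greedy maximum coverage); *depth* maximises the number of
copies reached by at least ``min_depth`` of the selected guides, so a
smaller set of copies each receives several guides. Off-target scanning is
a Hamming-distance search under the PAM constraint (Cas-OFFinder style),
exact and brute-force-verifiable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._sequtils import IUPAC, revcomp

Hit = Tuple[str, int, str, int]  # (target_id, position, strand, mismatches)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class Guide:
    protospacer: str
    pam_pattern: str = "NGG"
    hits: List[Hit] = field(default_factory=list)

    def __post_init__(self):
        if len(self.protospacer) == 0 or any(
            b not in "ACGT" for b in self.protospacer
        ):
            raise ValueError("protospacer must be a non-empty ACGT string")

    @property
    def targets(self) -> frozenset:
        return frozenset(t for t, _, _, _ in self.hits)


@dataclass
class GuidePanel:
    guides: List[Guide]
    coverage: int
    depth_profile: Dict[str, int]  # target -> number of panel guides hitting

    @property
    def covered_targets(self) -> frozenset:
        return frozenset(t for t, d in self.depth_profile.items() if d >= 1)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_positions(seq: str, pam: str) -> np.ndarray:
    """Start positions of PAM matches in ``seq`` (forward orientation)."""
    n, m = len(seq), len(pam)
    if n < m:
        return np.array([], dtype=np.int64)
    arr = _encode(seq)
    ok = np.ones(n - m + 1, dtype=bool)
    for j, code in enumerate(pam):
        allowed = np.frombuffer(IUPAC.get(code, "").encode("ascii"), dtype=np.uint8)
        ok &= np.isin(arr[j : j + n - m + 1], allowed)
    return np.flatnonzero(ok)


def enumerate_guides(
    targets: Mapping[str, str],
    pam_pattern: str = "NGG",
    guide_length: int = 20,
) -> List[Guide]:
    """All candidate guides across target sequences, merged by protospacer.

    A hit is recorded as (target_id, protospacer start on the forward strand
    of the target, strand, 0). Windows containing non-ACGT characters are
    skipped; the count of skipped windows is attached to the returned list
    as the attribute ``skipped_windows``.
    """
    pam_len = len(pam_pattern)
    merged: Dict[str, Guide] = {}
    skipped = 0
    for tid in sorted(targets):
        seq = targets[tid].upper()
        if len(seq) < guide_length + pam_len:
            raise ValueError(
                f"target {tid!r} shorter than guide + PAM ({guide_length + pam_len})"
            )
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for pam_start in _pam_positions(s, pam_pattern):
                g_start = pam_start - guide_length
                if g_start < 0:
                    continue
                proto = s[g_start:pam_start]
                if any(b not in "ACGT" for b in proto):
                    skipped += 1
                    continue
                if strand == "+":
                    pos = int(g_start)
                else:
                    pos = len(seq) - (int(g_start) + guide_length)
                guide = merged.get(proto)
                if guide is None:
                    guide = Guide(proto, pam_pattern)
                    merged[proto] = guide
                guide.hits.append((tid, pos, strand, 0))
    class _GuideList(list):
        """List of guides carrying the count of skipped (non-ACGT) windows."""

        skipped_windows = 0

    result = _GuideList(merged[p] for p in sorted(merged))
    result.skipped_windows = skipped
    return result


def count_hits_with_mismatches(
    guide: Guide,
    sequences: Mapping[str, str],
    max_mismatch: int = 0,
) -> List[Hit]:
    """All PAM-adjacent sites within Hamming distance ``max_mismatch``.

    Scans both strands of every sequence; positions refer to the protospacer
    start on the forward strand of the scanned sequence. Sorted by
    (sequence id, position, strand).
    """
    if max_mismatch > 5:
        raise ValueError("max_mismatch must be <= 5")
    L = len(guide.protospacer)
    pam = guide.pam_pattern
    proto_arr = _encode(guide.protospacer)
    hits: List[Hit] = []
    for sid in sorted(sequences):
        seq = sequences[sid].upper()
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            if n < L + len(pam):
                continue
            arr = _encode(s)
            pams = _pam_positions(s, pam)
            pams = pams[pams >= L]
            if pams.size == 0:
                continue
            # vectorised Hamming distance at each candidate site
            window = np.lib.stride_tricks.sliding_window_view(arr, L)
            sites = window[pams - L]
            mism = (sites != proto_arr).sum(axis=1)
            # windows containing non-ACGT count as mismatching everywhere they differ;
            # exclude windows with non-ACGT entirely
            acgt = np.isin(sites, _encode("ACGT")).all(axis=1)
            keep = (mism <= max_mismatch) & acgt
            for pam_start, mm in zip(pams[keep], mism[keep]):
                g_start = int(pam_start) - L
                pos = g_start if strand == "+" else n - (g_start + L)
                hits.append((sid, pos, strand, int(mm)))
    hits.sort()
    return hits


def _panel_from(guides: List[Guide], all_targets: frozenset) -> GuidePanel:
    depth: Dict[str, int] = {}
    for g in guides:
        for t in g.targets:
            depth[t] = depth.get(t, 0) + 1
    coverage = sum(1 for d in depth.values() if d >= 1)
    return GuidePanel(guides, coverage, depth)


def select_panel_breadth(guides: Sequence[Guide], k: int = 4) -> GuidePanel:
    """Greedy maximum-coverage panel of up to ``k`` guides.

    Each step adds the guide covering the most yet-uncovered targets; ties
    break by larger total hit count, then lexicographic protospacer. Stops
    early at full coverage.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not guides:
        raise ValueError("no guides supplied")
    all_targets = frozenset().union(*(g.targets for g in guides))
    chosen: List[Guide] = []
    covered: set = set()
    pool = list(guides)
    while len(chosen) < k and covered != all_targets:
        best = max(
            pool,
            key=lambda g: (
                len(g.targets - covered),
                len(g.hits),
                _lex_key(g.protospacer),
            ),
        )
        if not (best.targets - covered):
            break
        chosen.append(best)
        covered |= best.targets
        pool.remove(best)
        if not pool:
            break
    return _panel_from(chosen, all_targets)


def _lex_key(proto: str):
    # max() picks the largest key; lexicographically *smallest* protospacer
    # must win ties, so invert the ordering
    return tuple(-ord(c) for c in proto)


def _depth_objective(depths: Dict[str, int], min_depth: int) -> Tuple[int, int]:
    return (
        sum(1 for d in depths.values() if d >= min_depth),
        sum(depths.values()),
    )


def select_panel_depth(
    guides: Sequence[Guide], k: int = 4, min_depth: Optional[int] = None
) -> GuidePanel:
    """Greedy panel maximising targets reached by >= ``min_depth`` guides.

    ``min_depth`` defaults to ``k``. Each step adds the guide that maximises
    (number of targets at depth >= min_depth, total depth); further ties
    break by total hit count then lexicographic protospacer.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not guides:
        raise ValueError("no guides supplied")
    if min_depth is None:
        min_depth = k
    all_targets = frozenset().union(*(g.targets for g in guides))
    chosen: List[Guide] = []
    depths: Dict[str, int] = {}
    pool = list(guides)
    while len(chosen) < k and pool:
        def gain(g: Guide):
            trial = dict(depths)
            for t in g.targets:
                trial[t] = trial.get(t, 0) + 1
            obj = _depth_objective(trial, min_depth)
            return (obj[0], obj[1], len(g.hits), _lex_key(g.protospacer))

        best = max(pool, key=gain)
        chosen.append(best)
        for t in best.targets:
            depths[t] = depths.get(t, 0) + 1
        pool.remove(best)
    return _panel_from(chosen, all_targets)


def exhaustive_best_panel(
    guides: Sequence[Guide],
    k: int,
    objective: str = "breadth",
    min_depth: Optional[int] = None,
) -> Tuple[Tuple[int, int], List[Guide]]:
    """Exhaustive optimum over all C(n, k) panels (test oracle, tiny n only).

    Returns ((primary objective, secondary objective), best panel).
    """
    if min_depth is None:
        min_depth = k
    best_obj = None
    best_panel: List[Guide] = []
    for combo in combinations(range(len(guides)), min(k, len(guides))):
        depths: Dict[str, int] = {}
        for i in combo:
            for t in guides[i].targets:
                depths[t] = depths.get(t, 0) + 1
        if objective == "breadth":
            obj = (sum(1 for d in depths.values() if d >= 1), sum(depths.values()))
        else:
            obj = _depth_objective(depths, min_depth)
        if best_obj is None or obj > best_obj:
            best_obj = obj
            best_panel = [guides[i] for i in combo]
    return best_obj, best_panel


def predicted_hit_counts(
    panel: GuidePanel,
    element_sequences: Mapping[str, str],
    element_families: Optional[Mapping[str, str]] = None,
    max_mismatch: int = 0,
) -> Tuple[Dict[str, int], Dict[str, Dict[int, int]]]:
    """Per-element count of panel guides with >= 1 site at <= max_mismatch.

    Returns (hit counts per element, per-family histogram of hit counts);
    the histogram separates off-family groups, the usual off-target summary
    for family-targeted panels.
    """
    counts: Dict[str, int] = {eid: 0 for eid in element_sequences}
    for g in panel.guides:
        hits = count_hits_with_mismatches(g, element_sequences, max_mismatch)
        for eid in {h[0] for h in hits}:
            counts[eid] += 1
    by_family: Dict[str, Dict[int, int]] = {}
    if element_families:
        for eid, n in counts.items():
            fam = element_families.get(eid, "?")
            hist = by_family.setdefault(fam, {})
            hist[n] = hist.get(n, 0) + 1
    return counts, by_family
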