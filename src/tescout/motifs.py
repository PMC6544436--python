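"""Log-odds PWM scanning and motif co-occurrence summaries.

Motifs are position weight matrices read from MEME minimal format and scored
as summed log-odds against a 0-order background (uniform 0.25 unless given).
The default hit threshold is the smallest score whose p-value under the
background model is below 1e-4, computed exactly for motifs up to 12 bp by
dynamic-programming convolution of the per-position score distributions and
by Monte-Carlo sampling for longer motifs. An element "contains" a motif iff
at least one hit falls anywhere on either strand of its sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._sequtils import revcomp
from .classify import EnhancerCall, NON_ENHANCER, TE_PLUS

_BASES = "ACGT"
_PSEUDO = 1e-3  # probability floor before taking log-odds


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # (width, 4) log-odds
    threshold: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1].copy(), self.threshold)


def pwm_from_probabilities(
    name: str,
    probs: np.ndarray,
    background: Optional[Sequence[float]] = None,
    p_value: float = 1e-4,
) -> PWM:
    """Build a log-odds PWM from base probabilities and set its threshold.

    The threshold is the smallest achievable score with upper-tail
    probability < ``p_value`` under the background model.
    """
    probs = np.asarray(probs, dtype=float)
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    bg = bg / bg.sum()
    lod = np.log2(np.maximum(probs, _PSEUDO) / bg)
    threshold = score_threshold(lod, bg, p_value)
    return PWM(name, lod, threshold)


def score_threshold(
    lod: np.ndarray,
    background: np.ndarray,
    p_value: float = 1e-4,
    resolution: float = 1e-3,
    n_samples: int = 200_000,
    max_exact_width: int = 12,
    seed: int = 0,
) -> float:
    """Score cutoff whose upper-tail probability under background < p_value.

    Exact for widths <= ``max_exact_width`` via DP convolution of discretized
    per-position score distributions; Monte-Carlo quantile otherwise.
    """
    width = lod.shape[0]
    if width <= max_exact_width:
        # distribution over integer-scaled scores
        scaled = np.round(lod / resolution).astype(np.int64)
        dist: Dict[int, float] = {0: 1.0}
        for j in range(width):
            new: Dict[int, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    key = s + scaled[j, b]
                    new[key] = new.get(key, 0.0) + p * background[b]
            dist = new
        items = sorted(dist.items())
        scores = np.array([k for k, _ in items], dtype=float) * resolution
        probs = np.array([p for _, p in items])
        tail = np.cumsum(probs[::-1])[::-1]  # P[S >= score]
        ok = tail < p_value
        if not ok.any():
            return float(scores[-1])  # only the max score (or nothing) passes
        return float(scores[np.argmax(ok)])
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n_samples, width), p=background)
    samples = lod[np.arange(width), draws].sum(axis=1)
    return float(np.quantile(samples, 1.0 - p_value))


def read_meme(path, background: Optional[Sequence[float]] = None, p_value: float = 1e-4) -> List[PWM]:
    """Read PWMs from MEME minimal format.

    Uses the file's own 'Background letter frequencies' when present and no
    explicit background is supplied.
    """
    with open(path) as fh:
        text = fh.read()
    file_bg = background
    m = re.search(
        r"Background letter frequencies.*?\nA\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
    )
    if file_bg is None and m:
        file_bg = [float(m.group(i)) for i in range(1, 5)]
    pwms = []
    for mm in re.finditer(
        r"MOTIF\s+(\S+)[^\n]*\nletter-probability matrix:[^\n]*\n((?:\s*[\d.eE+-]+[^\n]*\n)+)",
        text,
    ):
        name = mm.group(1)
        rows = [
            [float(x) for x in line.split()]
            for line in mm.group(2).strip().splitlines()
        ]
        pwms.append(pwm_from_probabilities(name, np.array(rows), file_bg, p_value))
    return pwms


def _scores_one_strand(seq_idx: np.ndarray, valid: np.ndarray, pwm: PWM) -> np.ndarray:
    n, w = seq_idx.size, pwm.width
    if n < w:
        return np.full(0, -np.inf)
    scores = np.zeros(n - w + 1)
    ok = np.ones(n - w + 1, dtype=bool)
    for j in range(w):
        scores += pwm.matrix[j, seq_idx[j : j + n - w + 1]]
        ok &= valid[j : j + n - w + 1]
    scores[~ok] = -np.inf
    return scores


def scan_pwm(sequence: str, pwm: PWM) -> List[Tuple[int, str, float]]:
    """Hits of a PWM on both strands of a sequence.

    Returns (position on the forward strand, strand, score) for every window
    scoring >= pwm.threshold; windows containing N are skipped.
    """
    seq = sequence.upper()
    idx = np.full(len(seq), 0, dtype=np.int8)
    valid = np.zeros(len(seq), dtype=bool)
    for i, b in enumerate(seq):
        j = _BASES.find(b)
        if j >= 0:
            idx[i] = j
            valid[i] = True
    hits: List[Tuple[int, str, float]] = []
    fwd = _scores_one_strand(idx, valid, pwm)
    for pos in np.flatnonzero(fwd >= pwm.threshold):
        hits.append((int(pos), "+", float(fwd[pos])))
    rc_pwm = pwm.reverse_complement()
    rev = _scores_one_strand(idx, valid, rc_pwm)
    for pos in np.flatnonzero(rev >= pwm.threshold):
        hits.append((int(pos), "-", float(rev[pos])))
    hits.sort()
    return hits


def motif_hit_table(
    sequences: Mapping[str, str], pwms: Sequence[PWM]
) -> pd.DataFrame:
    """element_id x motif presence/absence table."""
    data = {
        pwm.name: {
            eid: len(scan_pwm(seq, pwm)) > 0 for eid, seq in sequences.items()
        }
        for pwm in pwms
    }
    return pd.DataFrame(data).fillna(False)


def motif_cooccurrence(
    calls: Sequence[EnhancerCall],
    hits: pd.DataFrame,
    length_fractions: Mapping[str, float],
    motif_combos: Sequence[Sequence[str]],
    min_fraction: float = 0.60,
) -> pd.DataFrame:
    """Fraction of each class's (long) elements carrying each motif combo.

    Elements with length_fraction <= min_fraction are excluded (strict >).
    Rows: combos (joined by '+'); columns: TE+ enhancer and non-enhancer TE
    classes. A combo counts only when all its motifs are present.
    """
    for combo in motif_combos:
        unknown = [m for m in combo if m not in hits.columns]
        if unknown:
            raise KeyError(f"combo references unknown motifs: {unknown}")
    by_class: Dict[str, List[str]] = {TE_PLUS: [], NON_ENHANCER: []}
    for c in calls:
        if c.klass in by_class and c.element_id in hits.index:
            if length_fractions.get(c.element_id, 0.0) > min_fraction:
                by_class[c.klass].append(c.element_id)
    rows = {}
    for combo in motif_combos:
        label = "+".join(combo)
        rows[label] = {}
        for klass, ids in by_class.items():
            if not ids:
                rows[label][klass] = np.nan
                continue
            sub = hits.loc[ids, list(combo)]
            rows[label][klass] = float(sub.all(axis=1).mean())
    return pd.DataFrame.from_dict(rows, orient="index")


def reporter_overlap_summary(
    reporter_positive: Sequence,
    reporter_input: Sequence,
    te_annotation: Sequence,
    chromatin_calls: Sequence[EnhancerCall],
    hits: pd.DataFrame,
) -> Dict[str, float]:
    """Plasmid-reporter concordance summary.

    Intersects reporter-positive fragments with TE copies, then reports the
    fraction of reporter-positive TE copies carrying each motif and the
    fraction lacking an enhancer-like chromatin call (discordant fraction).
    """
    from .intervals import overlap

    te_ivs = [c.interval for c in te_annotation]
    pos_hit = {j for _, j in overlap(list(reporter_positive), te_ivs)}
    pos_copies = [te_annotation[j] for j in sorted(pos_hit)]
    call_by_id = {c.element_id: c.klass for c in chromatin_calls}
    out: Dict[str, float] = {"n_reporter_positive_tes": float(len(pos_copies))}
    if not pos_copies:
        return out
    for motif in hits.columns:
        carriers = [
            c for c in pos_copies if c.copy_id in hits.index and hits.loc[c.copy_id, motif]
        ]
        out[f"fraction_with_{motif}"] = len(carriers) / len(pos_copies)
    concordant = [
        c for c in pos_copies if call_by_id.get(c.copy_id) == TE_PLUS
    ]
    out["fraction_concordant"] = len(concordant) / len(pos_copies)
    out["fraction_no_enhancer_profile"] = 1.0 - out["fraction_concordant"]
    return out
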