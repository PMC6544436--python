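"""Three-way element classification: TE+ enhancer, TE- enhancer, non-enhancer TE.

A TE copy is a TE+ enhancer when it carries the full enhancer signature —
open chromatin (ATAC peak), H3K27ac, and binding of at least one key
transcription factor — while showing no promoter character (no H3K4me3 peak
overlap and more than 500 bp from any annotated TSS). TE- enhancers are
regions with the identical signature built from ATAC peaks that touch no
annotated repeat. Non-enhancer TEs are a matched control set: mappable
family members (score > 0.5) ranked by ascending ATAC signal, taken to twice
the TE+ count of the same family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import MappabilityScore
from .intervals import (
    GenomicInterval,
    Peak,
    PeakSet,
    TECopy,
    distance_to_nearest,
    overlaps_any,
)

TE_PLUS = "TE_plus_enhancer"
TE_MINUS = "TE_minus_enhancer"
NON_ENHANCER = "non_enhancer_TE"
UNCLASSIFIED = "unclassified"


@dataclass
class EnhancerCall:
    element_id: str
    interval: GenomicInterval
    klass: str
    evidence: Dict[str, bool] = field(default_factory=dict)
    family: str = ""
    warning: str = ""


def _enhancer_evidence(
    intervals: Sequence[GenomicInterval],
    peaks: PeakSet,
    tss: Sequence[GenomicInterval],
    tf_names: Sequence[str],
    tss_exclusion: int,
) -> List[Dict[str, bool]]:
    tf_assays = [f"TF:{name}" for name in tf_names]
    peaks.require(["H3K4me3", "H3K27ac", "ATAC"] + tf_assays)

    k4me3 = overlaps_any(intervals, peaks.intervals("H3K4me3"))
    k27ac = overlaps_any(intervals, peaks.intervals("H3K27ac"))
    atac = overlaps_any(intervals, peaks.intervals("ATAC"))
    tf_any = [False] * len(intervals)
    for assay in tf_assays:
        for i, hit in enumerate(overlaps_any(intervals, peaks.intervals(assay))):
            tf_any[i] = tf_any[i] or hit
    tss_dist = distance_to_nearest(intervals, list(tss))

    out = []
    for i in range(len(intervals)):
        out.append(
            {
                "no_H3K4me3": not k4me3[i],
                "tss_far": tss_dist[i] > tss_exclusion,
                "H3K27ac": k27ac[i],
                "ATAC": atac[i],
                "TF": tf_any[i],
            }
        )
    return out


def call_te_plus_enhancers(
    copies: Sequence[TECopy],
    peaks: PeakSet,
    tss: Sequence[GenomicInterval],
    tf_names: Sequence[str],
    tss_exclusion: int = 500,
) -> List[EnhancerCall]:
    """Call TE+ enhancers among TE copies; non-passing copies stay unclassified.

    The rule is conjunctive: no H3K4me3 overlap, TSS distance strictly greater
    than ``tss_exclusion``, and overlap with an H3K27ac peak AND an ATAC peak
    AND at least one of the named TF tracks.
    """
    evidence = _enhancer_evidence(
        [c.interval for c in copies], peaks, tss, tf_names, tss_exclusion
    )
    calls = []
    for c, ev in zip(copies, evidence):
        klass = TE_PLUS if all(ev.values()) else UNCLASSIFIED
        calls.append(EnhancerCall(c.copy_id, c.interval, klass, ev, family=c.family))
    return calls


def call_te_minus_enhancers(
    atac_peaks: Sequence[Peak],
    all_repeats: Sequence[GenomicInterval],
    peaks: PeakSet,
    tss: Sequence[GenomicInterval],
    tf_names: Sequence[str],
    tss_exclusion: int = 500,
) -> List[EnhancerCall]:
    """Call TE- enhancers from repeat-free ATAC peak regions.

    Any repeat overlap (>= 1 bp) disqualifies a peak region; surviving
    regions then pass exactly the TE+ filters.
    """
    regions = [p.interval for p in atac_peaks]
    repeat_hit = overlaps_any(regions, list(all_repeats))
    evidence = _enhancer_evidence(regions, peaks, tss, tf_names, tss_exclusion)
    calls = []
    for idx, (p, ev) in enumerate(zip(atac_peaks, evidence)):
        ev = dict(ev, repeat_free=not repeat_hit[idx])
        klass = TE_MINUS if all(ev.values()) else UNCLASSIFIED
        rid = f"region|{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
        calls.append(EnhancerCall(rid, p.interval, klass, ev))
    return calls


def select_non_enhancer_tes(
    copies: Sequence[TECopy],
    scores: Sequence[MappabilityScore],
    atac_signal: Mapping[str, float],
    calls: Sequence[EnhancerCall],
    mappability_threshold: float = 0.5,
    multiple: int = 2,
) -> List[EnhancerCall]:
    """Pick the matched non-enhancer TE control set.

    Eligible copies are mappable (score strictly > threshold) and not already
    TE+ enhancers. Per family, the ``multiple`` x (TE+ count of that family)
    copies with the lowest ATAC signal are selected; ties break by copy_id.
    Returns updated calls for every TE copy (TE+ calls pass through).
    """
    score_by_id = {s.copy_id: s.score for s in scores}
    missing = [c.copy_id for c in copies if c.copy_id not in atac_signal]
    if missing:
        raise KeyError(f"atac_signal missing for copies: {missing[:5]}...")
    call_by_id = {c.element_id: c for c in calls}

    te_plus_per_family: Dict[str, int] = {}
    for c in copies:
        call = call_by_id.get(c.copy_id)
        if call is not None and call.klass == TE_PLUS:
            te_plus_per_family[c.family] = te_plus_per_family.get(c.family, 0) + 1

    by_family: Dict[str, List[TECopy]] = {}
    for c in copies:
        by_family.setdefault(c.family, []).append(c)

    out: List[EnhancerCall] = []
    for fam, members in sorted(by_family.items()):
        n_wanted = multiple * te_plus_per_family.get(fam, 0)
        eligible = [
            m
            for m in members
            if score_by_id.get(m.copy_id, 0.0) > mappability_threshold
            and (
                call_by_id.get(m.copy_id) is None
                or call_by_id[m.copy_id].klass != TE_PLUS
            )
        ]
        eligible.sort(key=lambda m: (atac_signal[m.copy_id], m.copy_id))
        chosen = {m.copy_id for m in eligible[:n_wanted]}
        warn = ""
        if len(eligible) < n_wanted:
            warn = f"only {len(eligible)} eligible of {n_wanted} requested"
        for m in members:
            prior = call_by_id.get(m.copy_id)
            if prior is not None and prior.klass == TE_PLUS:
                out.append(prior)
            elif m.copy_id in chosen:
                out.append(
                    EnhancerCall(
                        m.copy_id,
                        m.interval,
                        NON_ENHANCER,
                        {"mappable": True, "low_atac": True},
                        family=m.family,
                        warning=warn,
                    )
                )
            else:
                ev = prior.evidence if prior is not None else {}
                out.append(
                    EnhancerCall(m.copy_id, m.interval, UNCLASSIFIED, ev, family=m.family)
                )
    return out


def overlap_fraction_matrix(
    element_sets: Mapping[str, Sequence[GenomicInterval]],
    per_sample_peaks: Mapping[str, Sequence[GenomicInterval]],
    replicate_grouping: Optional[Mapping[str, str]] = None,
    per_element: bool = False,
):
    """Open-chromatin overlap summaries across samples.

    Default mode: one row per element-set label, one column per sample, value
    = fraction of the set's elements overlapped by that sample's peaks.
    ``per_element=True`` gives per-element rows and per-tissue columns, value
    = fraction of that tissue's replicates whose peaks overlap the element
    (requires ``replicate_grouping`` sample -> tissue).
    """
    if not per_sample_peaks:
        raise ValueError("need at least one sample of peaks")
    if not per_element:
        data = {}
        for sample, peaks in per_sample_peaks.items():
            col = {}
            for label, elements in element_sets.items():
                hits = overlaps_any(list(elements), list(peaks))
                col[label] = float(np.mean(hits)) if len(hits) else np.nan
            data[sample] = col
        return pd.DataFrame(data)

    if replicate_grouping is None:
        raise ValueError("per_element mode requires replicate_grouping")
    tissues: Dict[str, List[str]] = {}
    for sample, tissue in replicate_grouping.items():
        tissues.setdefault(tissue, []).append(sample)
    rows = {}
    for label, elements in element_sets.items():
        elements = list(elements)
        hit_by_sample = {
            s: overlaps_any(elements, list(per_sample_peaks[s]))
            for s in replicate_grouping
        }
        for i, iv in enumerate(elements):
            key = f"{label}|{iv.chrom}:{iv.start}-{iv.end}"
            rows[key] = {
                tissue: float(np.mean([hit_by_sample[s][i] for s in samples]))
                for tissue, samples in tissues.items()
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def mean_methylation_per_element(
    elements: Sequence[GenomicInterval],
    cpg_calls: pd.DataFrame,
) -> pd.Series:
    """Weighted mean methylation per element.

    ``cpg_calls`` columns: chrom, pos, meth, total. Per element the value is
    sum(meth)/sum(total) over CpGs with position inside [start, end); elements
    covering no CpG get NaN, never zero.
    """
    if (cpg_calls["total"] < 1).any():
        raise ValueError("every CpG call must have total >= 1")
    by_chrom = {chrom: df.sort_values("pos") for chrom, df in cpg_calls.groupby("chrom")}
    values = []
    for iv in elements:
        df = by_chrom.get(iv.chrom)
        if df is None:
            values.append(np.nan)
            continue
        inside = df[(df["pos"] >= iv.start) & (df["pos"] < iv.end)]
        if inside.empty:
            values.append(np.nan)
        else:
            values.append(inside["meth"].sum() / inside["total"].sum())
    index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in elements]
    return pd.Series(values, index=index, name="mean_methylation")


def calls_to_frame(calls: Iterable[EnhancerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "element_id": c.element_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "class": c.klass,
                "family": c.family,
                "warning": c.warning,
            }
        )
    return pd.DataFrame(rows)
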