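"""PCHi-C gene linking, expression normalization, allelic and CRISPRi analyses.

Elements are coupled to genes through promoter capture Hi-C: an element is
assigned to the non-promoter restriction fragment(s) it overlaps, and
inherits the genes of every promoter fragment those fragments interact with.
Genes touched by both TE+ and TE- enhancers are removed before any
expression comparison (exclusive partition). Expression panels from
heterogeneous sources are made comparable by histogram matching onto a
reference sample. Allele-specific enhancers come from a hybrid-cross read
filter (>= 5 reads on one allele and an allelic ratio above 0.8 or below
0.2), and the CRISPRi readout is a per-element log2 control/treatment
H3K27ac ratio stratified by the number of predicted sgRNA hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, TECopy, distance_to_nearest, overlap


@dataclass
class RestrictionFragment:
    interval: GenomicInterval
    fragment_id: str
    is_promoter: bool = False
    genes: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.is_promoter and not self.genes:
            raise ValueError(f"promoter fragment {self.fragment_id} carries no genes")
        if not self.is_promoter and self.genes:
            raise ValueError(f"non-promoter fragment {self.fragment_id} carries genes")


@dataclass
class InteractionMap:
    """Links between promoter fragments and other-end fragments."""

    pairs: List[Tuple[str, str, float]]  # (promoter fragment, other end, score)

    def others_for_promoter(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for p, o, _ in self.pairs:
            out.setdefault(p, set()).add(o)
        return out

    def promoters_for_other(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for p, o, _ in self.pairs:
            out.setdefault(o, set()).add(p)
        return out


def validate_interactions(
    interactions: InteractionMap, fragments: Sequence[RestrictionFragment]
) -> None:
    frag = {f.fragment_id: f for f in fragments}
    for p, o, _ in interactions.pairs:
        if p in frag and not frag[p].is_promoter:
            raise ValueError(f"interaction promoter end {p} is not a promoter fragment")
        if o in frag and frag[o].is_promoter:
            raise ValueError(f"interaction other end {o} is a promoter fragment")


def link_elements_to_genes(
    elements: Mapping[str, GenomicInterval],
    fragments: Sequence[RestrictionFragment],
    interactions: InteractionMap,
) -> Dict[str, FrozenSet[str]]:
    """Element -> set of genes reachable through fragment interactions.

    An element overlapping only promoter fragments gets an empty set (and a
    warning); an element in fragments with no interactions gets an empty set.
    """
    validate_interactions(interactions, fragments)
    ids = list(elements)
    ivs = [elements[i] for i in ids]
    frag_ivs = [f.interval for f in fragments]
    promoters_by_other = interactions.promoters_for_other()
    genes_of = {f.fragment_id: set(f.genes) for f in fragments}

    links: Dict[str, FrozenSet[str]] = {}
    hit_fragments: Dict[str, List[RestrictionFragment]] = {i: [] for i in ids}
    for ei, fj in overlap(ivs, frag_ivs):
        hit_fragments[ids[ei]].append(fragments[fj])
    for eid in ids:
        frs = hit_fragments[eid]
        nonprom = [f for f in frs if not f.is_promoter]
        if frs and not nonprom:
            warnings.warn(
                f"element {eid} overlaps promoter fragments only; no link assigned",
                stacklevel=2,
            )
        genes: Set[str] = set()
        for f in nonprom:
            for p in promoters_by_other.get(f.fragment_id, ()):
                genes |= genes_of.get(p, set())
        links[eid] = frozenset(genes)
    return links


def exclusive_gene_partition(
    links_te_plus: Mapping[str, FrozenSet[str]],
    links_te_minus: Mapping[str, FrozenSet[str]],
) -> Dict[str, Set[str]]:
    """Partition linked genes into TE_plus_only / TE_minus_only / excluded_both."""
    plus = set().union(*links_te_plus.values()) if links_te_plus else set()
    minus = set().union(*links_te_minus.values()) if links_te_minus else set()
    return {
        "TE_plus_only": plus - minus,
        "TE_minus_only": minus - plus,
        "excluded_both": plus & minus,
    }


def histogram_match_normalize(
    table: pd.DataFrame, reference: str
) -> pd.DataFrame:
    """Map every sample's value distribution onto the reference sample's.

    Each column is rank-mapped onto the empirical distribution of the
    reference column via quantile interpolation, so sorted values of any
    normalized sample reproduce the reference's sorted values (up to
    interpolation when lengths differ after NaN removal). The reference
    column is returned unchanged. Idempotent.
    """
    if reference not in table.columns:
        raise KeyError(f"reference sample {reference!r} not in table")
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    ref_sorted = np.sort(table[reference].dropna().to_numpy(dtype=float))
    m = ref_sorted.size
    out = table.copy().astype(float)
    for col in table.columns:
        if col == reference:
            continue
        vals = table[col].to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        x = vals[mask]
        n = x.size
        if n == 0:
            continue
        if np.all(x == x[0]):
            warnings.warn(
                f"sample {col!r} is constant; mapped to reference median", stacklevel=2
            )
            out.loc[mask, col] = float(np.median(ref_sorted))
            continue
        ranks = sps.rankdata(x, method="average") - 1.0  # 0 .. n-1
        q = ranks / (n - 1) if n > 1 else np.zeros(1)
        mapped = np.interp(q * (m - 1), np.arange(m), ref_sorted)
        out.loc[mask, col] = mapped
    return out


def lineage_ratio(
    expr: pd.DataFrame,
    sample_tissue: Mapping[str, str],
    lineage_a: str = "ESC",
    lineage_b: str = "TSC",
    expressed_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 lineage ratio, restricted to genes expressed somewhere.

    Ratio = log2((mean_a + pc) / (mean_b + pc)); genes whose mean stays below
    ``expressed_threshold`` in both lineages are dropped.
    """
    cols_a = [s for s in expr.columns if sample_tissue.get(s) == lineage_a]
    cols_b = [s for s in expr.columns if sample_tissue.get(s) == lineage_b]
    if not cols_a or not cols_b:
        raise ValueError(f"need >=1 sample for each of {lineage_a!r} and {lineage_b!r}")
    mean_a = expr[cols_a].mean(axis=1)
    mean_b = expr[cols_b].mean(axis=1)
    expressed = (mean_a >= expressed_threshold) | (mean_b >= expressed_threshold)
    ratio = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return ratio[expressed].rename(f"log2_{lineage_a}_{lineage_b}")


def allele_specific_elements(
    allelic_peaks: pd.DataFrame,
    te_annotation: Sequence[TECopy],
    min_reads: int = 5,
    ratio_hi: float = 0.8,
    ratio_lo: float = 0.2,
) -> Tuple[pd.DataFrame, List[TECopy]]:
    """Allele-specific peaks and the TE copies they overlap.

    ``allelic_peaks`` columns: chrom, start, end, reads_129, reads_cast.
    A peak is selected iff max(reads_129, reads_cast) >= min_reads and the
    allelic ratio reads_129/total is strictly > ratio_hi or strictly <
    ratio_lo. Peaks with zero total reads are skipped.
    """
    df = allelic_peaks.copy()
    if (df[["reads_129", "reads_cast"]] < 0).any().any():
        raise ValueError("allelic read counts must be non-negative")
    total = df["reads_129"] + df["reads_cast"]
    df = df[total > 0].copy()
    df["ratio"] = df["reads_129"] / (df["reads_129"] + df["reads_cast"])
    floor_ok = df[["reads_129", "reads_cast"]].max(axis=1) >= min_reads
    skew_ok = (df["ratio"] > ratio_hi) | (df["ratio"] < ratio_lo)
    selected = df[floor_ok & skew_ok].copy()

    peak_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in selected.itertuples()
    ]
    te_ivs = [c.interval for c in te_annotation]
    hit = {j for _, j in overlap(peak_ivs, te_ivs)}
    as_tes = [te_annotation[j] for j in sorted(hit)]
    return selected, as_tes


def allelic_gene_effects(
    as_elements: Sequence[GenomicInterval],
    tss: Mapping[str, GenomicInterval],
    allelic_expr: pd.DataFrame,
    window: int = 100_000,
    fold: float = 1.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes near allele-specific enhancers, flagged when allelically skewed.

    Candidates are genes whose TSS lies within ``window`` of any
    allele-specific element (TSS to element edge); a candidate is flagged
    when (reads_129 + pc)/(reads_cast + pc) >= fold or <= 1/fold.
    ``allelic_expr`` is indexed by gene with columns reads_129, reads_cast.
    """
    if not as_elements:
        return pd.DataFrame(columns=["gene", "distance", "ratio", "affected"])
    gene_ids = list(tss)
    dists = distance_to_nearest([tss[g] for g in gene_ids], list(as_elements))
    rows = []
    for g, d in zip(gene_ids, dists):
        if d > window:
            continue
        if g not in allelic_expr.index:
            continue
        r129 = float(allelic_expr.loc[g, "reads_129"])
        rcast = float(allelic_expr.loc[g, "reads_cast"])
        ratio = (r129 + pseudocount) / (rcast + pseudocount)
        rows.append(
            {
                "gene": g,
                "distance": d,
                "ratio": ratio,
                "affected": bool(ratio >= fold or ratio <= 1 / fold),
            }
        )
    return pd.DataFrame(rows)


def crispri_h3k27ac_effect(
    elements: Sequence[TECopy],
    signal_control: Mapping[str, float],
    signal_crispri: Mapping[str, float],
    hit_counts: Mapping[str, int],
    peak_overlap: Mapping[str, bool],
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-element H3K27ac log2 effect and hit-count-stratified summary.

    Effect = log2((control + pc) / (CRISPRi + pc)); an element counts as a
    ">fold_threshold loss" only when it overlapped an H3K27ac peak in the
    control. Strata are hit counts 0, 1, and >=2; families whose members all
    have 0 hits form the untargeted control group and are summarised
    separately.
    """
    rows = []
    for c in elements:
        ctrl = float(signal_control[c.copy_id])
        trt = float(signal_crispri[c.copy_id])
        hits = int(hit_counts.get(c.copy_id, 0))
        eff = np.log2((ctrl + pseudocount) / (trt + pseudocount))
        rows.append(
            {
                "element_id": c.copy_id,
                "family": c.family,
                "hits": hits,
                "signal_control": ctrl,
                "signal_crispri": trt,
                "log2_effect": eff,
                "peak_overlap": bool(peak_overlap.get(c.copy_id, False)),
                "strong_loss": bool(
                    peak_overlap.get(c.copy_id, False)
                    and eff > np.log2(fold_threshold)
                ),
            }
        )
    table = pd.DataFrame(rows)
    fam_targeted = table.groupby("family")["hits"].max() > 0
    table["group"] = table["family"].map(
        lambda f: "targeted" if fam_targeted.get(f, False) else "untargeted_control"
    )

    def stratum(h: int) -> str:
        return "0" if h == 0 else ("1" if h == 1 else ">=2")

    table["stratum"] = table["hits"].map(stratum)
    summary = (
        table.groupby(["group", "stratum"])
        .agg(
            n=("element_id", "size"),
            mean_log2_effect=("log2_effect", "mean"),
            n_strong_loss=("strong_loss", "sum"),
        )
        .reset_index()
    )
    return table, summary


def differential_expression_simple(
    counts_control: pd.DataFrame,
    counts_treated: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Median-of-ratios normalization + per-gene t-test + BH correction.

    Both inputs are gene x replicate count matrices sharing a gene index.
    Genes with zero counts in every replicate of both conditions are dropped.
    Returns a frame with log2_fold_change (treated vs control on normalized
    log2 counts), p_value, q_value and a significance flag at ``alpha``.
    """
    if counts_control.shape[1] < 2 or counts_treated.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    genes = counts_control.index
    if not genes.equals(counts_treated.index):
        raise ValueError("gene indices must match")
    keep = (counts_control.sum(axis=1) + counts_treated.sum(axis=1)) > 0
    ctrl = counts_control.loc[keep].to_numpy(dtype=float)
    trt = counts_treated.loc[keep].to_numpy(dtype=float)
    both = np.hstack([ctrl, trt])

    # median-of-ratios size factors over genes positive in all samples
    positive = (both > 0).all(axis=1)
    if positive.sum() < 1:
        size = np.ones(both.shape[1])
    else:
        log_geo = np.log(both[positive]).mean(axis=1, keepdims=True)
        size = np.exp(np.median(np.log(both[positive]) - log_geo, axis=0))
    norm = both / size
    log_norm = np.log2(norm + 1.0)
    nc = ctrl.shape[1]
    lc, lt = log_norm[:, :nc], log_norm[:, nc:]

    lfc = lt.mean(axis=1) - lc.mean(axis=1)
    tstat, pval = sps.ttest_ind(lt, lc, axis=1)
    pval = np.where(np.isnan(pval), 1.0, pval)
    rej, qval, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": pval,
            "q_value": qval,
            "significant": rej,
        },
        index=genes[keep],
    )


# ---------------------------------------------------------------------------
# tabular IO for the external interfaces


def read_fragments_tsv(path) -> List[RestrictionFragment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        genes = tuple(str(r.genes).split(",")) if isinstance(r.genes, str) and r.genes else ()
        out.append(
            RestrictionFragment(
                GenomicInterval(r.chrom, int(r.start), int(r.end)),
                str(r.fragment_id),
                bool(r.is_promoter),
                genes,
            )
        )
    return out


def write_fragments_tsv(fragments: Sequence[RestrictionFragment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tfragment_id\tis_promoter\tgenes\n")
        for f in fragments:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.fragment_id}\t"
                f"{int(f.is_promoter)}\t{','.join(f.genes)}\n"
            )


def read_interactions_tsv(path) -> InteractionMap:
    df = pd.read_csv(path, sep="\t")
    pairs = [
        (str(r.frag_promoter), str(r.frag_other), float(getattr(r, "score", 1.0)))
        for r in df.itertuples()
    ]
    return InteractionMap(pairs)


def write_interactions_tsv(interactions: InteractionMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("frag_promoter\tfrag_other\tscore\n")
        for p, o, s in interactions.pairs:
            fh.write(f"{p}\t{o}\t{s}\n")
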