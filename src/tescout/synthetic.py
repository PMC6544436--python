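"""Fully-labelled synthetic worlds for end-to-end pipeline testing.

The generator emulates the study design at desk scale: a small random genome
carrying two LTR families (one with enhancer activity in embryonic stem
cells, one in trophoblast stem cells), with

* TE copies derived from a family consensus by per-base substitution and
  occasional 5' truncation;
* a planted subset of copies given the full enhancer signature (ATAC +
  H3K27ac + one key-TF peak, no H3K4me3, far from any TSS) in their lineage
  only, and repeat-free regions given the same signature (TE- enhancers);
* a fraction of copies duplicated verbatim (with 1 kb flanks) elsewhere in
  the genome, making them unmappable to unique reads;
* restriction fragments cut between items so every planted enhancer sits on
  its own non-promoter fragment, with interactions routing enhancer
  fragments to promoter fragments of planted target genes;
* expression matrices with a lineage fold-effect for TE+-linked genes,
  broadly expressed TE--linked genes, and a small set of genes linked to
  both enhancer types (which the exclusive partition must discard);
* allelic ATAC counts (binomial, a planted subset skewed to p = 0.9/0.1),
  CpG methylation lower at enhancers than elsewhere, and a CRISPRi H3K27ac
  pair with a planted per-sgRNA-hit knockdown.

All randomness flows from one master seed through named substreams, so the
same seed regenerates the identical world and individual layers are stable
against changes in other layers.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._sequtils import read_fasta, write_fasta
from .intervals import (
    GenomicInterval,
    Peak,
    PeakSet,
    TECopy,
    read_repeatmasker,
    write_te_bed,
)
from .linking import (
    InteractionMap,
    RestrictionFragment,
    read_fragments_tsv,
    read_interactions_tsv,
    write_fragments_tsv,
    write_interactions_tsv,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: consensus motif strings planted into enhancer copies (synthetic stand-ins
#: shaped like the canonical core motifs of each factor)
MOTIF_CONSENSUS = {
    "OCT4": "ATGCAAAT",
    "SOX2": "CATTGTTA",
    "NANOG": "CCATTAAC",
    "CDX2": "TTTATGGC",
    "ELF5": "AACCGGAA",
    "EOMES": "AGGTGTGA",
}

LINEAGE_TFS = {
    "ESC": ("OCT4", "SOX2", "NANOG"),
    "TSC": ("CDX2", "ELF5", "EOMES"),
}

_STREAMS = (
    "genome",
    "tes",
    "placement",
    "duplication",
    "peaks",
    "expression",
    "allelic",
    "methylation",
    "crispri",
)


@dataclass
class WorldParams:
    """Tunable knobs of the synthetic world; defaults are the study conditions."""

    n_contigs: int = 4
    copy_numbers: Dict[str, int] = field(
        default_factory=lambda: {"RLTR13D6": 150, "RLTR13D5": 150}
    )
    family_lineage: Dict[str, str] = field(
        default_factory=lambda: {"RLTR13D6": "ESC", "RLTR13D5": "TSC"}
    )
    consensus_length: int = 350
    mutation_rate: float = 0.12
    fraction_truncated: float = 0.3
    fraction_enhancers: float = 0.2  # of all copies -> 60 TE+ at defaults
    n_te_minus: int = 40
    n_promoter_like_per_family: int = 5
    fraction_duplicated: float = 0.1
    duplication_flank: int = 1000
    n_genes: int = 200
    n_shared_genes: int = 5
    spacer_range: Tuple[int, int] = (2000, 4000)
    te_minus_length: int = 400
    motif_carriage_enhancer: float = 0.8
    motif_carriage_other: float = 0.3
    lineage_fold: float = 8.0
    expression_noise_sd: float = 0.1  # multiplicative, log2 scale
    n_allelic_peaks: int = 1000
    allelic_mean_reads: float = 30.0
    allelic_skew_fraction: float = 0.1
    allelic_skew_p: float = 0.9
    n_allele_affected_genes: int = 4
    allelic_expr_base: float = 200.0
    crispri_effect_per_hit: float = 0.5
    crispri_noise_sd: float = 0.12  # log2 scale (~8% multiplicative noise)
    mappability_read_length: int = 40
    repair_mappability: bool = True
    seed: int = 0

    def validate(self) -> None:
        n_copies = sum(self.copy_numbers.values())
        n_enh = int(round(self.fraction_enhancers * n_copies))
        if n_enh > n_copies:
            raise ValueError("more enhancers requested than TE copies")
        for frac_name in (
            "mutation_rate",
            "fraction_truncated",
            "fraction_enhancers",
            "fraction_duplicated",
            "allelic_skew_fraction",
        ):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v}")
        for fam in self.copy_numbers:
            if fam not in self.family_lineage:
                raise ValueError(f"family {fam} has no lineage assignment")
            if self.family_lineage[fam] not in LINEAGE_TFS:
                raise ValueError(f"unknown lineage {self.family_lineage[fam]}")
        if min(self.copy_numbers.values()) < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticWorld:
    params: WorldParams
    genome: Dict[str, str]
    copies: List[TECopy]
    tss: Dict[str, GenomicInterval]
    peaksets: Dict[str, PeakSet]
    atac_signal: Dict[str, float]
    te_minus_regions: List[Tuple[str, GenomicInterval, str]]  # (id, interval, lineage)
    fragments: List[RestrictionFragment]
    interactions: InteractionMap
    expression: pd.DataFrame
    sample_tissue: Dict[str, str]
    methylation: pd.DataFrame
    allelic_peaks: pd.DataFrame
    allelic_expression: pd.DataFrame
    crispri: pd.DataFrame
    truth: pd.DataFrame
    duplicated_ids: Set[str]

    @property
    def te_plus_ids(self) -> Set[str]:
        return set(self.truth.loc[self.truth["label"] == "TE_plus_enhancer", "element_id"])

    @property
    def te_minus_ids(self) -> Set[str]:
        return set(self.truth.loc[self.truth["label"] == "TE_minus_enhancer", "element_id"])


def _rngs(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        shifts = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(idx + shifts) % 4]
    return out


def _plant_motif(rng: np.random.Generator, seq: np.ndarray, motif: str) -> None:
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    if seq.size <= m.size + 20:
        return
    pos = int(rng.integers(10, seq.size - m.size - 10))
    seq[pos : pos + m.size] = m


def make_world(params: Optional[WorldParams] = None, seed: Optional[int] = None, **overrides) -> SyntheticWorld:
    """Generate a complete labelled world; deterministic under the seed."""
    if params is None:
        params = WorldParams()
    if overrides:
        params = dataclasses.replace(params, **overrides)
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    params.validate()
    rngs = _rngs(params.seed)

    families = sorted(params.copy_numbers)
    n_copies_total = sum(params.copy_numbers.values())
    n_te_plus_total = int(round(params.fraction_enhancers * n_copies_total))

    # --- per-family consensus and copy sequences -------------------------
    rng_te = rngs["tes"]
    consensus = {f: _random_seq(rng_te, params.consensus_length) for f in families}

    copy_plan = []  # (family, lineage, role)
    for fam in families:
        lineage = params.family_lineage[fam]
        n = params.copy_numbers[fam]
        n_plus = int(round(n_te_plus_total * n / n_copies_total))
        n_promlike = min(params.n_promoter_like_per_family, n - n_plus)
        roles = (
            ["TE_plus_enhancer"] * n_plus
            + ["promoter_like_TE"] * n_promlike
            + ["background_TE"] * (n - n_plus - n_promlike)
        )
        for role in roles:
            copy_plan.append((fam, lineage, role))

    copy_seqs: List[np.ndarray] = []
    for fam, lineage, role in copy_plan:
        seq = _mutate(rng_te, consensus[fam], params.mutation_rate)
        if role != "TE_plus_enhancer" and rng_te.random() < params.fraction_truncated:
            cut = int(rng_te.integers(1, params.consensus_length // 2))
            seq = seq[cut:]  # 5' truncation
        carriage = (
            params.motif_carriage_enhancer
            if role == "TE_plus_enhancer"
            else params.motif_carriage_other
        )
        if rng_te.random() < carriage:
            for tf in LINEAGE_TFS[lineage]:
                _plant_motif(rng_te, seq, MOTIF_CONSENSUS[tf])
        copy_seqs.append(seq)

    # --- genome assembly: shuffled items separated by spacers ------------
    rng_place = rngs["placement"]
    rng_gen = rngs["genome"]
    items: List[Tuple[str, int]] = (
        [("te", i) for i in range(len(copy_plan))]
        + [("tss", g) for g in range(params.n_genes)]
        + [("teminus", r) for r in range(params.n_te_minus)]
    )
    order = rng_place.permutation(len(items))
    contig_names = [f"chr{i + 1}" for i in range(params.n_contigs)]
    per_contig = np.array_split(order, params.n_contigs)

    genome_arrays: Dict[str, np.ndarray] = {}
    cut_points: Dict[str, List[int]] = {c: [] for c in contig_names}
    copies: List[TECopy] = []
    copy_meta: List[Tuple[str, str, str]] = []  # aligned with copies
    tss: Dict[str, GenomicInterval] = {}
    te_minus_regions: List[Tuple[str, GenomicInterval, str]] = []
    lo_sp, hi_sp = params.spacer_range

    for cname, idxs in zip(contig_names, per_contig):
        parts: List[np.ndarray] = []
        cursor = 0
        for k in idxs:
            kind, j = items[int(k)]
            spacer_len = int(rng_place.integers(lo_sp, hi_sp))
            parts.append(_random_seq(rng_gen, spacer_len))
            cut_points[cname].append(cursor + spacer_len // 2)
            cursor += spacer_len
            if kind == "te":
                fam, lineage, role = copy_plan[j]
                seq = copy_seqs[j]
                iv = GenomicInterval(cname, cursor, cursor + seq.size, "+")
                cid = f"{fam}_{j:04d}"
                copies.append(TECopy(iv, subfamily=fam, copy_id=cid))
                copy_meta.append((cid, role, lineage))
                parts.append(seq)
                cursor += seq.size
            elif kind == "tss":
                gene = f"G{j:04d}"
                tss[gene] = GenomicInterval(cname, cursor, cursor + 1, "+")
                core = _random_seq(rng_gen, 200)
                parts.append(core)
                cursor += core.size
            else:
                region = _random_seq(rng_gen, params.te_minus_length)
                iv = GenomicInterval(cname, cursor, cursor + region.size)
                te_minus_regions.append((f"TEminus_{j:03d}", iv, ""))
                parts.append(region)
                cursor += region.size
        tail = _random_seq(rng_gen, int(rng_place.integers(lo_sp, hi_sp)))
        parts.append(tail)
        genome_arrays[cname] = (
            np.concatenate(parts) if parts else _random_seq(rng_gen, 1000)
        )

    # assign TE- lineages round-robin (balanced across ESC/TSC)
    lineage_cycle = sorted(LINEAGE_TFS)
    te_minus_regions = [
        (rid, iv, lineage_cycle[i % len(lineage_cycle)])
        for i, (rid, iv, _) in enumerate(te_minus_regions)
    ]

    # --- duplication of a fraction of non-enhancer copies ----------------
    rng_dup = rngs["duplication"]
    eligible = [
        i
        for i, (cid, role, lin) in enumerate(copy_meta)
        if role == "background_TE"
    ]
    n_dup = int(round(params.fraction_duplicated * len(copies)))
    dup_idx = sorted(rng_dup.choice(eligible, size=min(n_dup, len(eligible)), replace=False).tolist())
    duplicated_ids: Set[str] = set()
    for i in dup_idx:
        c = copies[i]
        iv = c.interval
        arr = genome_arrays[iv.chrom]
        lo = max(iv.start - params.duplication_flank, 0)
        hi = min(iv.end + params.duplication_flank, arr.size)
        block = arr[lo:hi].copy()
        dest = contig_names[int(rng_dup.integers(0, len(contig_names)))]
        spacer = _random_seq(rng_dup, 2000)
        cut_points[dest].append(genome_arrays[dest].size + 1000)
        genome_arrays[dest] = np.concatenate([genome_arrays[dest], spacer, block])
        duplicated_ids.add(c.copy_id)

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}
    if params.repair_mappability:
        _repair_unique_windows(
            genome_arrays,
            genome,
            copies,
            duplicated_ids,
            params.mappability_read_length,
            rng_dup,
        )
        genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arrays.items()}

    # --- peaks per lineage ------------------------------------------------
    rng_peaks = rngs["peaks"]
    peaksets = {lin: PeakSet(lin) for lin in LINEAGE_TFS}
    # promoter H3K4me3 + ATAC at every TSS in both lineages
    for gene, giv in tss.items():
        for lin in LINEAGE_TFS:
            s, e = max(giv.start - 300, 0), giv.start + 300
            peaksets[lin].add(Peak(GenomicInterval(giv.chrom, s, e), "H3K4me3", 10.0))
            peaksets[lin].add(Peak(GenomicInterval(giv.chrom, s, e), "ATAC", 5.0))
    atac_signal: Dict[str, float] = {}
    for c, (cid, role, lineage) in zip(copies, copy_meta):
        iv = c.interval
        if role in ("TE_plus_enhancer", "promoter_like_TE"):
            ps = peaksets[lineage]
            ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 50, iv.end + 50), "ATAC", float(rng_peaks.uniform(20, 60))))
            ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200), "H3K27ac", float(rng_peaks.uniform(10, 40))))
            tf = LINEAGE_TFS[lineage][int(rng_peaks.integers(0, 3))]
            ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 30, iv.end + 30), f"TF:{tf}", float(rng_peaks.uniform(5, 20))))
            if role == "promoter_like_TE":
                ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 100, iv.end + 100), "H3K4me3", 8.0))
            atac_signal[cid] = float(rng_peaks.uniform(20, 100))
        else:
            atac_signal[cid] = float(rng_peaks.uniform(0, 5))
    for rid, iv, lineage in te_minus_regions:
        ps = peaksets[lineage]
        ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 50, iv.end + 50), "ATAC", float(rng_peaks.uniform(20, 60))))
        ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 200, iv.end + 200), "H3K27ac", float(rng_peaks.uniform(10, 40))))
        tf = LINEAGE_TFS[lineage][int(rng_peaks.integers(0, 3))]
        ps.add(Peak(GenomicInterval(iv.chrom, iv.start - 30, iv.end + 30), f"TF:{tf}", float(rng_peaks.uniform(5, 20))))
    # every lineage needs all TF tracks present even if empty -> add sentinel
    for lin, ps in peaksets.items():
        for tf in LINEAGE_TFS[lin]:
            ps.by_assay.setdefault(f"TF:{tf}", [])
        ps.by_assay.setdefault("H3K27ac", [])

    # --- restriction fragments (cut at spacer midpoints) ------------------
    fragments: List[RestrictionFragment] = []
    tss_by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for gene, giv in tss.items():
        tss_by_chrom.setdefault(giv.chrom, []).append((giv.start, gene))
    frag_counter = 0
    frag_of_element: Dict[str, str] = {}
    element_intervals: Dict[str, GenomicInterval] = {
        c.copy_id: c.interval for c in copies
    }
    for rid, iv, _ in te_minus_regions:
        element_intervals[rid] = iv
    for cname in contig_names:
        cuts = sorted(set(cut_points[cname]))
        bounds = [0] + [c for c in cuts if 0 < c < len(genome[cname])] + [len(genome[cname])]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if hi <= lo:
                continue
            fid = f"frag_{frag_counter:05d}"
            frag_counter += 1
            genes_here = tuple(
                g for pos, g in tss_by_chrom.get(cname, []) if lo <= pos < hi
            )
            fragments.append(
                RestrictionFragment(
                    GenomicInterval(cname, lo, hi), fid, bool(genes_here), genes_here
                )
            )
    # fragment lookup for planted elements
    frag_by_chrom: Dict[str, List[RestrictionFragment]] = {}
    for f in fragments:
        frag_by_chrom.setdefault(f.interval.chrom, []).append(f)
    for eid, iv in element_intervals.items():
        for f in frag_by_chrom[iv.chrom]:
            if f.interval.start <= iv.start < f.interval.end:
                frag_of_element[eid] = f.fragment_id
                break
    frag_of_gene = {
        g: f.fragment_id for f in fragments if f.is_promoter for g in f.genes
    }

    # --- interactions and planted gene links ------------------------------
    te_plus_ids = [cid for cid, role, lin in copy_meta if role == "TE_plus_enhancer"]
    te_minus_ids = [rid for rid, _, _ in te_minus_regions]
    genes_sorted = sorted(tss)
    n_plus, n_minus = len(te_plus_ids), len(te_minus_ids)
    gene_iter = iter(genes_sorted)
    plus_targets = {eid: next(gene_iter) for eid in te_plus_ids}
    minus_targets = {rid: next(gene_iter) for rid in te_minus_ids}
    shared_genes = [next(gene_iter) for _ in range(params.n_shared_genes)]
    pairs: List[Tuple[str, str, float]] = []
    for eid, gene in {**plus_targets, **minus_targets}.items():
        pairs.append((frag_of_gene[gene], frag_of_element[eid], 1.0))
    for i, gene in enumerate(shared_genes):
        pairs.append((frag_of_gene[gene], frag_of_element[te_plus_ids[i % n_plus]], 1.0))
        pairs.append((frag_of_gene[gene], frag_of_element[te_minus_ids[i % n_minus]], 1.0))
    interactions = InteractionMap(pairs)

    # --- expression --------------------------------------------------------
    rng_expr = rngs["expression"]
    samples = [f"{lin}_rep{r}" for lin in sorted(LINEAGE_TFS) for r in (1, 2, 3)]
    sample_tissue = {s: s.split("_")[0] for s in samples}
    lineage_of_plus = dict(zip(te_plus_ids, [lin for cid, role, lin in copy_meta if role == "TE_plus_enhancer"]))
    base = {}
    for gene in genes_sorted:
        base[gene] = float(rng_expr.lognormal(np.log(2.0), 1.0))
    expr = pd.DataFrame(index=genes_sorted, columns=samples, dtype=float)
    plus_gene_lineage = {g: lineage_of_plus[eid] for eid, g in plus_targets.items()}
    minus_genes = set(minus_targets.values())
    for gene in genes_sorted:
        for s in samples:
            lin = sample_tissue[s]
            if gene in plus_gene_lineage:
                mean = 5.0 * (params.lineage_fold if lin == plus_gene_lineage[gene] else 1.0)
            elif gene in minus_genes or gene in shared_genes:
                mean = 20.0
            else:
                mean = base[gene]
            noise = 2.0 ** rng_expr.normal(0.0, params.expression_noise_sd)
            expr.loc[gene, s] = mean * noise

    # --- methylation -------------------------------------------------------
    rng_meth = rngs["methylation"]
    meth_rows = []
    te_plus_set = set(te_plus_ids)
    for c in copies:
        iv = c.interval
        n_cpg = max(len(iv) // 50, 2)
        positions = sorted(
            rng_meth.choice(np.arange(iv.start, iv.end), size=n_cpg, replace=False).tolist()
        )
        lo_meth = c.copy_id in te_plus_set
        for pos in positions:
            frac = rng_meth.beta(2, 8) if lo_meth else rng_meth.beta(8, 2)
            total = 10
            meth = int(rng_meth.binomial(total, frac))
            meth_rows.append((iv.chrom, int(pos), meth, total))
    methylation = pd.DataFrame(meth_rows, columns=["chrom", "pos", "meth", "total"])

    # --- allelic ATAC peaks ------------------------------------------------
    rng_al = rngs["allelic"]
    n_peaks = params.n_allelic_peaks
    n_on_te = min(len(copies), n_peaks // 5)
    te_pick = rng_al.choice(len(copies), size=n_on_te, replace=False)
    peak_rows = []
    for i in range(n_peaks):
        if i < n_on_te:
            iv = copies[int(te_pick[i])].interval
            chrom, start, end = iv.chrom, iv.start, iv.end
        else:
            chrom = contig_names[int(rng_al.integers(0, len(contig_names)))]
            start = int(rng_al.integers(0, max(len(genome[chrom]) - 300, 1)))
            end = start + 300
        total = int(rng_al.poisson(params.allelic_mean_reads)) + 1
        skewed = rng_al.random() < params.allelic_skew_fraction
        if skewed:
            p = params.allelic_skew_p if rng_al.random() < 0.5 else 1 - params.allelic_skew_p
        else:
            p = 0.5
        r129 = int(rng_al.binomial(total, p))
        peak_rows.append((chrom, start, end, r129, total - r129, skewed))
    allelic_peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "reads_129", "reads_cast", "planted_skew"],
    )

    # allele-specific TEs implied by the generating rule, used to plant
    # allelically-affected genes nearby
    sel = allelic_peaks[
        (allelic_peaks[["reads_129", "reads_cast"]].max(axis=1) >= 5)
        & (
            (allelic_peaks["reads_129"] / (allelic_peaks["reads_129"] + allelic_peaks["reads_cast"]) > 0.8)
            | (allelic_peaks["reads_129"] / (allelic_peaks["reads_129"] + allelic_peaks["reads_cast"]) < 0.2)
        )
    ]
    as_te_ivs = []
    for r in sel.itertuples():
        for c in copies:
            if c.interval.chrom == r.chrom and c.interval.start == r.start and c.interval.end == r.end:
                as_te_ivs.append(c.interval)
                break
    candidate_genes = []
    for gene in genes_sorted:
        giv = tss[gene]
        for iv in as_te_ivs:
            if iv.chrom == giv.chrom and max(iv.start - giv.end, giv.start - iv.end) <= 100_000:
                candidate_genes.append(gene)
                break
    n_aff = min(params.n_allele_affected_genes, len(candidate_genes))
    affected = list(rng_al.choice(candidate_genes, size=n_aff, replace=False)) if n_aff else []
    al_expr_rows = []
    for gene in genes_sorted:
        if gene in affected:
            r129 = int(rng_al.poisson(params.allelic_expr_base * 1.5))
            rcast = int(rng_al.poisson(params.allelic_expr_base / 1.5))
        else:
            r129 = int(rng_al.poisson(params.allelic_expr_base))
            rcast = int(rng_al.poisson(params.allelic_expr_base))
        al_expr_rows.append((gene, r129, rcast, gene in affected))
    allelic_expression = pd.DataFrame(
        al_expr_rows, columns=["gene", "reads_129", "reads_cast", "planted_affected"]
    ).set_index("gene")

    # --- CRISPRi H3K27ac pair ---------------------------------------------
    target_family = next(
        f for f in families if params.family_lineage[f] == "ESC"
    )
    crispri = make_crispri_table(
        [(c.copy_id, c.family) for c in copies],
        te_plus_ids=te_plus_set,
        target_family=target_family,
        effect_per_hit=params.crispri_effect_per_hit,
        noise_sd=params.crispri_noise_sd,
        rng=rngs["crispri"],
    )

    # --- truth labels ------------------------------------------------------
    truth_rows = []
    for c, (cid, role, lineage) in zip(copies, copy_meta):
        label = role
        if cid in duplicated_ids:
            label = "duplicated_TE"
        truth_rows.append(
            {
                "element_id": cid,
                "label": label,
                "family": c.family,
                "lineage": lineage,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "linked_gene": plus_targets.get(cid, ""),
            }
        )
    for rid, iv, lineage in te_minus_regions:
        truth_rows.append(
            {
                "element_id": rid,
                "label": "TE_minus_enhancer",
                "family": "",
                "lineage": lineage,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "linked_gene": minus_targets.get(rid, ""),
            }
        )
    truth = pd.DataFrame(truth_rows)

    return SyntheticWorld(
        params=params,
        genome=genome,
        copies=copies,
        tss=tss,
        peaksets=peaksets,
        atac_signal=atac_signal,
        te_minus_regions=te_minus_regions,
        fragments=fragments,
        interactions=interactions,
        expression=expr,
        sample_tissue=sample_tissue,
        methylation=methylation,
        allelic_peaks=allelic_peaks,
        allelic_expression=allelic_expression,
        crispri=crispri,
        truth=truth,
        duplicated_ids=duplicated_ids,
    )


def make_guide_toy_instance(seed: int, objective: str = "breadth"):
    """Tiny sgRNA panel-selection instance with a greedily reachable optimum.

    Breadth instances: 4-6 "primary" guides with pairwise-disjoint target
    sets plus 2-4 guides whose targets are a subset of one primary's — the
    optimum is the k largest primaries and greedy selection provably attains
    it. Depth instances: two groups of 4 guides, each group sharing one
    target set (sets may overlap) — stacking the larger group is provably
    optimal for the depth objective. These instances exercise counting and
    tie-breaking against the exhaustive oracle; the greedy approximation
    bound on unstructured instances is a separate property.
    """
    from .guides import Guide

    rng = np.random.default_rng(seed)

    def proto() -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))

    guides = []
    if objective == "breadth":
        n_primary = int(rng.integers(4, 7))
        targets = [f"t{j}" for j in range(10)]
        perm = list(rng.permutation(targets))
        sets = []
        pos = 0
        for i in range(n_primary):
            left_for_rest = n_primary - i - 1
            size = min(int(rng.integers(1, 3)), len(perm) - pos - left_for_rest)
            sets.append(perm[pos : pos + size])
            pos += size
        for s in sets:
            guides.append(Guide(proto(), hits=[(t, 0, "+", 0) for t in s]))
        for _ in range(int(rng.integers(2, 5))):
            parent = sets[int(rng.integers(0, len(sets)))]
            keep = [t for t in parent if rng.random() < 0.7] or parent[:1]
            guides.append(Guide(proto(), hits=[(t, 0, "+", 0) for t in keep]))
    else:
        # two stacked groups with strictly different set sizes: greedy piles
        # onto the larger group, which is the exhaustive optimum
        all_targets = [f"t{j}" for j in range(10)]
        while True:
            group_sets = [
                [t for t in all_targets if rng.random() < 0.5] or all_targets[:1]
                for _ in range(2)
            ]
            if len(group_sets[0]) != len(group_sets[1]):
                break
        for members in group_sets:
            for _ in range(4):
                guides.append(Guide(proto(), hits=[(t, 0, "+", 0) for t in members]))
    return guides


def _repair_unique_windows(
    genome_arrays: Dict[str, np.ndarray],
    genome: Mapping[str, str],
    copies: Sequence[TECopy],
    duplicated_ids: Set[str],
    k: int,
    rng: np.random.Generator,
) -> None:
    """Guarantee that unmappability arises only from planted duplication.

    Family copies occasionally share an identical k-bp stretch by chance
    (divergence is random); a substitution is injected into each such run so
    every window of every non-duplicated element is genome-unique, making
    planted mappability labels exact by construction.
    """
    from ._sequtils import kmer_counts, canonical

    counts = kmer_counts(genome, k)
    for c in copies:
        if c.copy_id in duplicated_ids:
            continue
        iv = c.interval
        seq = genome[iv.chrom]
        bad = [
            pos
            for pos in range(iv.start, min(iv.end, len(seq) - k + 1))
            if counts.get(canonical(seq[pos : pos + k]), 0) > 1
        ]
        if not bad:
            continue
        arr = genome_arrays[iv.chrom]
        # one substitution every k bases kills every window of a run
        runs: List[Tuple[int, int]] = []
        for pos in bad:
            if runs and pos <= runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], pos)
            else:
                runs.append((pos, pos))
        for a, b in runs:
            m = a + k - 1
            while m <= b + k - 1:
                site = min(m, iv.end - 1)
                idx = int(np.searchsorted(_BASES, arr[site]))
                arr[site] = _BASES[(idx + int(rng.integers(1, 4))) % 4]
                m += k
    # note: the multiplicity table is intentionally not rebuilt; a collision
    # repaired in one copy also frees its partner copy, where the stale table
    # may trigger one extra (harmless) substitution


def make_crispri_table(
    elements: Sequence[Tuple[str, str]],
    te_plus_ids: Set[str],
    target_family: str,
    effect_per_hit: float = 0.5,
    noise_sd: float = 0.12,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Control/CRISPRi H3K27ac signal pair with planted per-hit knockdown.

    Elements of ``target_family`` receive 0-4 predicted sgRNA hits; all other
    families stay at 0 (untargeted control). CRISPRi signal = control x
    2^(-effect_per_hit * hits) with multiplicative log2-normal noise.
    ``peak_overlap`` flags elements carrying control H3K27ac (the planted
    TE+ enhancers).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for eid, family in elements:
        if family == target_family:
            hits = int(rng.choice([0, 1, 2, 3, 4], p=[0.3, 0.25, 0.2, 0.15, 0.1]))
        else:
            hits = 0
        control = float(2.0 ** rng.normal(np.log2(100.0), 0.5))
        knock = 2.0 ** (-effect_per_hit * hits + rng.normal(0.0, noise_sd))
        rows.append(
            {
                "element_id": eid,
                "family": family,
                "hits": hits,
                "signal_control": control,
                "signal_crispri": control * knock,
                "peak_overlap": eid in te_plus_ids,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export / import


def export_world(world: SyntheticWorld, directory) -> None:
    """Write the world to standard text formats; re-importable by load_world."""
    os.makedirs(directory, exist_ok=True)
    j = lambda *p: os.path.join(directory, *p)
    write_fasta(world.genome, j("genome.fa"))
    write_te_bed(world.copies, j("te_annotation.bed"))
    with open(j("tss.bed"), "w") as fh:
        for gene, iv in sorted(world.tss.items()):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\t0\t+\n")
    os.makedirs(j("peaks"), exist_ok=True)
    for sample, ps in world.peaksets.items():
        for assay, peaks in ps.by_assay.items():
            safe = assay.replace(":", "_")
            with open(j("peaks", f"{sample}_{safe}.bed"), "w") as fh:
                for p in peaks:
                    iv = p.interval
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{assay}\t{p.signal:.6g}\t.\n")
    pd.Series(world.atac_signal, name="atac_signal").rename_axis("copy_id").to_csv(
        j("atac_signal.tsv"), sep="\t"
    )
    with open(j("te_minus_regions.bed"), "w") as fh:
        for rid, iv, lineage in world.te_minus_regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rid}\t0\t.\t{lineage}\n")
    write_fragments_tsv(world.fragments, j("fragments.tsv"))
    write_interactions_tsv(world.interactions, j("interactions.tsv"))
    world.expression.rename_axis("gene").to_csv(j("expression.tsv"), sep="\t")
    pd.Series(world.sample_tissue, name="tissue").rename_axis("sample").to_csv(
        j("samples.tsv"), sep="\t"
    )
    world.methylation.to_csv(j("methylation.tsv"), sep="\t", index=False)
    world.allelic_peaks.to_csv(j("allelic_peaks.tsv"), sep="\t", index=False)
    world.allelic_expression.to_csv(j("allelic_expression.tsv"), sep="\t")
    world.crispri.to_csv(j("crispri.tsv"), sep="\t", index=False)
    world.truth.to_csv(j("truth.tsv"), sep="\t", index=False)
    with open(j("params.json"), "w") as fh:
        json.dump(dataclasses.asdict(world.params), fh, indent=1, default=str)


def load_world(directory) -> SyntheticWorld:
    """Re-import an exported world directory."""
    j = lambda *p: os.path.join(directory, *p)
    with open(j("params.json")) as fh:
        raw = json.load(fh)
    raw["spacer_range"] = tuple(raw["spacer_range"])
    params = WorldParams(**raw)
    genome = read_fasta(j("genome.fa"))
    copies_raw = read_repeatmasker(j("te_annotation.bed"))
    truth = pd.read_csv(j("truth.tsv"), sep="\t").fillna({"linked_gene": "", "family": ""})
    # restore stable copy_ids from the truth table (BED reader synthesises ids)
    id_by_coord = {
        (r.chrom, int(r.start), int(r.end)): r.element_id
        for r in truth.itertuples()
        if r.family
    }
    copies = []
    for c in copies_raw:
        key = (c.interval.chrom, c.interval.start, c.interval.end)
        copies.append(
            TECopy(c.interval, c.subfamily, id_by_coord.get(key, c.copy_id))
        )
    tss = {}
    with open(j("tss.bed")) as fh:
        for line in fh:
            f = line.split("\t")
            tss[f[3]] = GenomicInterval(f[0], int(f[1]), int(f[2]), "+")
    peaksets: Dict[str, PeakSet] = {}
    for fn in sorted(os.listdir(j("peaks"))):
        sample, rest = fn.split("_", 1)
        assay = rest[:-4]  # strip .bed
        if assay.startswith("TF_"):
            assay = "TF:" + assay[3:]
        ps = peaksets.setdefault(sample, PeakSet(sample))
        ps.by_assay.setdefault(assay, [])  # register even when empty
        with open(j("peaks", fn)) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                ps.add(
                    Peak(
                        GenomicInterval(f[0], int(f[1]), int(f[2])),
                        f[3],
                        float(f[4]),
                    )
                )
    atac_signal = (
        pd.read_csv(j("atac_signal.tsv"), sep="\t").set_index("copy_id")["atac_signal"].to_dict()
    )
    te_minus_regions = []
    with open(j("te_minus_regions.bed")) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            te_minus_regions.append(
                (f[3], GenomicInterval(f[0], int(f[1]), int(f[2])), f[6])
            )
    fragments = read_fragments_tsv(j("fragments.tsv"))
    interactions = read_interactions_tsv(j("interactions.tsv"))
    expression = pd.read_csv(j("expression.tsv"), sep="\t").set_index("gene")
    sample_tissue = (
        pd.read_csv(j("samples.tsv"), sep="\t").set_index("sample")["tissue"].to_dict()
    )
    methylation = pd.read_csv(j("methylation.tsv"), sep="\t")
    allelic_peaks = pd.read_csv(j("allelic_peaks.tsv"), sep="\t")
    allelic_expression = pd.read_csv(j("allelic_expression.tsv"), sep="\t").set_index("gene")
    crispri = pd.read_csv(j("crispri.tsv"), sep="\t")
    duplicated = set(truth.loc[truth["label"] == "duplicated_TE", "element_id"])
    return SyntheticWorld(
        params=params,
        genome=genome,
        copies=copies,
        tss=tss,
        peaksets=peaksets,
        atac_signal=atac_signal,
        te_minus_regions=te_minus_regions,
        fragments=fragments,
        interactions=interactions,
        expression=expression,
        sample_tissue=sample_tissue,
        methylation=methylation,
        allelic_peaks=allelic_peaks,
        allelic_expression=allelic_expression,
        crispri=crispri,
        truth=truth,
        duplicated_ids=duplicated,
    )
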