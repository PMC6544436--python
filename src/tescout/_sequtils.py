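"""Small sequence helpers shared across modules.

Genomes are held in memory as plain ``{name: str}`` dicts (uppercase DNA);
everything in this package operates at desk scale (a few megabases), so no
indexed/random-access backend is needed.
"""

from __future__ import annotations

import io
from typing import Dict, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC nucleotide codes -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iupac_match(pattern: str, site: str) -> bool:
    """True if ``site`` matches an IUPAC ``pattern`` of the same length."""
    if len(pattern) != len(site):
        return False
    return all(b in IUPAC.get(p, "") for p, b in zip(pattern, site))


def kmer_counts(genome: Mapping[str, str], k: int) -> Dict[str, int]:
    """Count canonical k-mer occurrences across a genome.

    A k-mer's multiplicity across both strands equals the count of its
    canonical form: each genomic locus contributes exactly once, and a locus
    showing the k-mer on the forward strand shows its reverse complement on
    the reverse strand at the same place. A k-mer is "unique in the genome"
    iff its canonical count is 1. Windows containing non-ACGT bases are
    skipped.
    """
    counts: Dict[str, int] = {}
    for seq in genome.values():
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            key = canonical(kmer)
            counts[key] = counts.get(key, 0) + 1
    return counts


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into a ``{name: uppercase sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def fasta_string(seqs: Mapping[str, str]) -> str:
    buf = io.StringIO()
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()
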