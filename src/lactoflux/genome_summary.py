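"""Assembly summary statistics from a nucleotide FASTA.

Reports the three numbers routinely quoted for a draft genome: contig count,
total assembly length (also in Mbp, 2 decimals), and GC content (1 decimal).
GC is computed case-insensitively as 100*(G+C)/(A+C+G+T); IUPAC ambiguity
codes (N, R, Y, ...) are excluded from both numerator and denominator by
default, switchable to an all-bases denominator via ``gc_denominator="all"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model_io import ValidationError

logger = logging.getLogger(__name__)

_PROTEIN_HINT = set("EFILPQZ")  # residues that never occur in nucleotide IUPAC


@dataclass
class GenomeSummary:
    n_contigs: int
    total_length_bp: int
    gc_percent: float  # to 1 decimal

    @property
    def total_length_mbp(self) -> float:
        return round(self.total_length_bp / 1e6, 2)

    def as_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "total_length_bp": self.total_length_bp,
            "total_length_mbp": self.total_length_mbp,
            "gc_percent": self.gc_percent,
        }


def summarize_fasta(path, gc_denominator: str = "acgt") -> GenomeSummary:
    """Summarize a nucleotide FASTA assembly.

    Total length counts every base including ambiguous ones; GC content uses
    unambiguous A/C/G/T only unless ``gc_denominator="all"``.
    """
    from Bio import SeqIO

    if gc_denominator not in ("acgt", "all"):
        raise ValueError("gc_denominator must be 'acgt' or 'all'")
    n_contigs = 0
    total = 0
    gc = 0
    acgt = 0
    suspicious = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        n_contigs += 1
        total += len(seq)
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
        suspicious += sum(seq.count(b) for b in _PROTEIN_HINT)
    if n_contigs == 0:
        raise ValidationError([f"'{path}' contains no FASTA records"])
    if total and suspicious / total > 0.05:
        logger.warning(
            "'%s' looks like amino-acid sequence (%.1f%% non-nucleotide letters)",
            path, 100 * suspicious / total,
        )
    denom = acgt if gc_denominator == "acgt" else total
    gc_percent = round(100.0 * gc / denom, 1) if denom else 0.0
    return GenomeSummary(
        n_contigs=n_contigs, total_length_bp=total, gc_percent=gc_percent
    )
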