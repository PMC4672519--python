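"""Assembly statistics from a FASTA file.

Writes a tiny synthetic assembly and summarizes it. Point the same call at a
real draft assembly to reproduce the contig count / Mbp / GC% trio quoted for
deposited genomes.
"""

import tempfile
from pathlib import Path

from lactoflux import summarize_fasta

fasta = Path(tempfile.mkdtemp()) / "toy_assembly.fasta"
fasta.write_text(">contig1\nATGCATGCGGCC\n>contig2\nAATTNNGC\n")

summary = summarize_fasta(fasta)
print(f"contigs:       {summary.n_contigs}")
print(f"total length:  {summary.total_length_bp} bp "
      f"({summary.total_length_mbp} Mbp)")
print(f"GC content:    {summary.gc_percent} %")
# GC excludes ambiguous bases (the two Ns) from numerator and denominator;
# pass gc_denominator="all" to count every base in the denominator instead
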