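"""Small published datasets bundled for worked examples.

``PSHCP_TRANSCRIPTS`` holds the measured RT-qPCR copy counts (copies per
ng of RNA template) for nested amplicons spanning the *pshcp* genomic
region in three marine picocyanobacteria: *Prochlorococcus marinus* MED4
and MIT 9313 and *Synechococcus* sp. WH 8102.  Product classes are
ordered by increasing 5' extent of the forward primer, from the *pshcp*
coding region alone out to the full upstream *rpl19* gene.  The printed
per-strain totals are retained separately because they were computed
from unrounded underlying values and can differ from the column sums by
one count.
"""

from __future__ import annotations

from .qpcr import AmpliconTable

TRANSCRIPT_CLASSES = [
    "hcp_only",
    "hcp_5prime",
    "hcp_trp",
    "hcp_trp_5prime",
    "hcp_trp_rpl19_3end",
    "hcp_trp_rpl19_full",
]

#: Product classes whose amplicon extends into the rpl19 coding sequence
#: far enough to demonstrate a full rpl19–pshcp co-transcript.
LONG_RPL19_CLASSES = {"hcp_trp_rpl19_full"}

PSHCP_TRANSCRIPTS: dict[str, dict] = {
    "MED4": {
        "copies": {
            "hcp_only": 2826,
            "hcp_5prime": 629,
            "hcp_trp": 1566,
            "hcp_trp_5prime": 900,
            "hcp_trp_rpl19_3end": 684,
            "hcp_trp_rpl19_full": 0,
        },
        "total": 6606,
    },
    "MIT 9313": {
        "copies": {
            "hcp_only": 96,
            "hcp_5prime": 1329,
            "hcp_trp": 201,
            "hcp_trp_5prime": 0,
            "hcp_trp_rpl19_3end": 121,
            "hcp_trp_rpl19_full": 29,
        },
        "total": 1776,
    },
    "WH 8102": {
        "copies": {
            "hcp_only": 0,
            "hcp_5prime": 679,
            "hcp_trp": 13,
            "hcp_trp_5prime": 43,
            "hcp_trp_rpl19_3end": 93,
            "hcp_trp_rpl19_full": 8,
        },
        "total": 837,
    },
}


def pshcp_transcript_table(strain: str) -> AmpliconTable:
    """The nested-amplicon copy-count table for one strain."""
    if strain not in PSHCP_TRANSCRIPTS:
        raise ValueError(
            f"unknown strain {strain!r}; available: {', '.join(PSHCP_TRANSCRIPTS)}"
        )
    entry = PSHCP_TRANSCRIPTS[strain]
    return AmpliconTable(
        strain=strain,
        classes=list(TRANSCRIPT_CLASSES),
        copies=dict(entry["copies"]),
        total=entry["total"],
    )
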