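"""Packaged example dataset: the printed mutation table for guide sgRNA1.

Nineteen sequenced canavanine-resistant isolates from a strain expressing
dCas9 and sgRNA1 (protospacer at coding positions 277-296, transcribed
strand).  Sixteen isolates carry a single mutation event and three carry two
events each (complex mutations), for 22 events in total.
"""

from __future__ import annotations

from .records import MutationTable, table_from_notations
from .targets import GuideTarget

SGRNA1 = GuideTarget(id="sgRNA1", start=277, end=296, designated_strand="TS",
                     pam_side="upstream")

#: notation strings, one per isolate, in printed order
SGRNA1_NOTATIONS: tuple[str, ...] = (
    "259G>T",
    "263T>G",
    "282T>A, 286–287del",
    "286–287del",
    "287T>A",
    "287T>A, 289G>C",
    "290C>A",
    "290ins(22 bp)",
    "291C>G, 294T>A",
    "292del",
    "294ins(T)",
    "591C>A",
    "801–808del",
    "809G>A",
    "892del",
    "923G>T",
    "973G>T",
    "1035C>A",
    "1068C>A",
)


def sgrna1_table() -> MutationTable:
    """The 19-isolate sgRNA1 mutation table as parsed records."""
    return table_from_notations(SGRNA1_NOTATIONS, guide_id="sgRNA1", genotype="WT",
                                prefix="sgRNA1-")
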