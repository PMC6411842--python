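"""Synthetic stand-ins for external inputs the analysis expects.

Everything in this module is SYNTHETIC.  The real reporter coding sequence,
the full supplementary per-isolate mutation lists for guides sgRNA2/4/6 and
the deaminase-derived inactivating-substitution catalog are external inputs
that this package does not ship.  The stand-ins below are constructed so
that the pipeline's summary statistics on them equal the summary counts the
study text reports, which makes them useful end-to-end fixtures:

* a deterministic 1773-nt coding sequence whose bases agree with every
  printed mutation's reference allele, whose sgRNA2-like protospacer
  contains exactly 6 cytosines on the non-target strand (out of 20), and
  whose sgRNA6-like protospacer overlaps a 6-nt T homopolymer;
* guide definitions: sgRNA1 (printed coordinates 277-296, TS) plus
  synthetic placements for sgRNA2 (289-308, NTS), sgRNA4 (721-740, NTS) and
  sgRNA6 (1331-1350, NTS);
* supplementary-style isolate tables reproducing, by construction, the
  reported tallies — sgRNA2: 16/21 isolates within 10 nt, 14/21 inside the
  protospacer, 10 of the 14 in-target events at non-target-strand C (6 C>T,
  2 C>G, 2 C>A); sgRNA4: 7/20 within 2 nt; sgRNA6: 20/25 in-target, 6 of 20
  complex, 10 of 20 single-nt homopolymer indels;
* a small synthetic inactivating-substitution catalog under which the
  guides score between 0 (sgRNA1) and 5 (sgRNA2) potential inactivating
  cytosines.
"""

from __future__ import annotations

import numpy as np

from .catalog import CatalogEntry, InactivatingCatalog
from .datasets import SGRNA1
from .records import MutationTable, table_from_notations
from .targets import GuideTarget, ReferenceRegion

REFERENCE_LENGTH = 1773  # length of the reporter coding sequence

SGRNA2 = GuideTarget(id="sgRNA2", start=289, end=308, designated_strand="NTS",
                     pam_side="downstream")
SGRNA4 = GuideTarget(id="sgRNA4", start=721, end=740, designated_strand="NTS",
                     pam_side="downstream")
SGRNA6 = GuideTarget(id="sgRNA6", start=1331, end=1350, designated_strand="NTS",
                     pam_side="downstream")

GUIDES: tuple[GuideTarget, ...] = (SGRNA1, SGRNA2, SGRNA4, SGRNA6)

# fully specified windows (coding strand); the sgRNA2-like protospacer
# (289-308) carries exactly six C's and the sgRNA6-like one overlaps a
# maximal TTTTTT run at 1337-1342
_REGIONS: dict[int, str] = {
    289: "GCCACTGCTACGTACGTGTA",   # 289-308
    1331: "GACATGTTTTTTGGCTCAGCAGT",  # 1331-1353
}

# single-base constraints implied by the mutation notations used in the
# packaged and synthetic tables (so every table validates against the
# reference)
_BASES: dict[int, str] = {
    100: "G", 259: "G", 263: "T", 282: "T", 285: "G", 287: "T",
    455: "G", 480: "G", 520: "C", 591: "C", 730: "C", 809: "G",
    923: "G", 973: "G", 1035: "C", 1068: "C", 1101: "C", 1120: "C",
    1200: "G", 1500: "T",
}


def synthetic_reference(name: str = "reporter_cds") -> ReferenceRegion:
    """Deterministic synthetic reporter coding sequence (1773 nt)."""
    rng = np.random.default_rng(1773)
    seq = list(rng.choice(list("ACGT"), size=REFERENCE_LENGTH))
    seq[0:3] = list("ATG")
    for start, block in _REGIONS.items():
        seq[start - 1 : start - 1 + len(block)] = list(block)
    for pos, base in _BASES.items():
        seq[pos - 1] = base
    return ReferenceRegion(name=name, coding_sequence="".join(seq))


# --- supplementary-style isolate tables (synthetic) -----------------------

SGRNA2_NOTATIONS: tuple[str, ...] = (
    # 14 isolates with one event inside the protospacer (289-308):
    # 10 substitutions at non-target-strand C (6 C>T, 2 C>G, 2 C>A) ...
    "293C>T", "296C>T", "299C>T", "293C>T", "296C>T", "299C>T",
    "291C>G", "303C>G",
    "290C>A", "293C>A",
    # ... plus 2 A>G at the 308 hotspot and 2 small deletions
    "308A>G", "308A>G",
    "298del", "300–301del",
    # 2 isolates within 10 nt of the protospacer but outside it
    "285G>A", "312del",
    # 5 dispersed background isolates
    "100G>T", "520C>A", "700del", "1200G>A", "1500T>C",
)

SGRNA4_NOTATIONS: tuple[str, ...] = (
    # 7 isolates within 2 nt of the protospacer (window 719-742); deletions
    # dominate and the single in-target substitution is C>G
    "730C>G",
    "722del", "725del", "727–728del", "735del", "741del", "742del",
    # 13 dispersed background isolates
    "90del", "210del", "455G>T", "610del", "880del", "980del", "1010del",
    "1101C>T", "1250del", "1422del", "1555del", "1630del", "1701del",
)

SGRNA6_NOTATIONS: tuple[str, ...] = (
    # 4 single C>T substitutions at non-target-strand C in the protospacer
    "1333C>T", "1345C>T", "1347C>T", "1350C>T",
    # 10 single-nt indels anchored in the TTTTTT run at 1337-1342
    "1337del", "1338del", "1339del", "1340del", "1341del", "1342del",
    "1337ins(T)", "1339ins(T)", "1340ins(T)", "1341ins(T)",
    # 6 complex isolates (two substitutions within 10 nt)
    "1335T>A, 1343G>A",
    "1332A>T, 1336G>C",
    "1344G>C, 1346T>A",
    "1334A>C, 1343G>T",
    "1331G>A, 1336G>T",
    "1348A>G, 1353T>C",
    # 5 dispersed background isolates
    "250del", "480G>T", "890del", "1120C>A", "1600del",
)


def synthetic_supplement_table(guide_id: str) -> MutationTable:
    """Synthetic supplementary-style isolate table for one guide."""
    notations = {
        "sgRNA2": SGRNA2_NOTATIONS,
        "sgRNA4": SGRNA4_NOTATIONS,
        "sgRNA6": SGRNA6_NOTATIONS,
    }
    if guide_id not in notations:
        raise KeyError(f"no synthetic supplement table for {guide_id!r}")
    return table_from_notations(
        notations[guide_id], guide_id=guide_id, genotype="WT",
        prefix=f"{guide_id}-", ref=synthetic_reference(),
    )


def synthetic_catalog() -> InactivatingCatalog:
    """Synthetic inactivating-substitution catalog (coding-strand entries).

    Under this catalog the guide scores span 0 (sgRNA1, a TS guide whose
    non-target strand carries no cataloged cytosine) to 5 (sgRNA2).
    """
    entries = [
        CatalogEntry(291, "C", "G", "synthetic"),
        CatalogEntry(293, "C", "T", "synthetic"),
        CatalogEntry(296, "C", "T", "synthetic"),
        CatalogEntry(299, "C", "T", "synthetic"),
        CatalogEntry(303, "C", "G", "synthetic"),
        CatalogEntry(730, "C", "G", "synthetic"),
        CatalogEntry(1333, "C", "T", "synthetic"),
        CatalogEntry(1345, "C", "T", "synthetic"),
        CatalogEntry(1347, "C", "T", "synthetic"),
    ]
    return InactivatingCatalog(entries, provenance="synthetic")
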