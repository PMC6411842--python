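"""Coordinate system for the reporter coding region and guide targets.

All positions are 1-based inclusive coordinates on the reporter *coding*
sequence (position 1 = first base of the start codon).  A guide target is a
20-nt protospacer interval on that sequence together with a strand
designation: ``NTS`` means the protospacer (and PAM) lie on the
non-transcribed (coding, mRNA-like) strand, ``TS`` means they lie on the
transcribed (template) strand.

Strand bookkeeping follows a single configurable convention
(:class:`StrandConvention`).  Under the default rule the designated strand is
the protospacer-bearing strand; because the guide RNA hybridizes to the
*complement* of its protospacer, the displaced single-stranded (non-target)
strand of the R-loop is the designated strand itself.  Hence for an
NTS-designated guide the non-target strand *is* the coding strand, and
non-target-strand bases read directly off the coding sequence; for a
TS-designated guide they are the complements of the coding bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    """Complement of a single upper-case DNA base."""
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


@dataclass(frozen=True)
class ReferenceRegion:
    """A reporter coding sequence with 1-based inclusive coordinates."""

    name: str
    coding_sequence: str

    def __post_init__(self) -> None:
        seq = self.coding_sequence.upper()
        object.__setattr__(self, "coding_sequence", seq)
        if len(seq) < 1:
            raise ValueError("coding sequence must be non-empty")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"coding sequence contains non-ACGT characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.coding_sequence)

    def base(self, pos: int) -> str:
        """Coding-strand base at a 1-based position."""
        if not 1 <= pos <= len(self):
            raise ValueError(f"position {pos} outside reference {self.name} (1..{len(self)})")
        return self.coding_sequence[pos - 1]


@dataclass(frozen=True)
class StrandConvention:
    """Mapping from a guide's designated strand to the physical non-target strand.

    ``guide_bears_protospacer=True`` (default): the designated strand carries
    the protospacer, so the displaced non-target strand equals the designated
    strand.  Setting it to ``False`` adopts the opposite reading (the guide
    anneals to its designated strand), which complements every non-target
    base call.  The convention in force is recorded in all report output.
    """

    guide_bears_protospacer: bool = True

    def non_target_is_coding(self, designated_strand: str) -> bool:
        """True iff the physical non-target strand is the coding strand."""
        if designated_strand not in ("NTS", "TS"):
            raise ValueError(f"unknown strand designation: {designated_strand!r}")
        coding_designated = designated_strand == "NTS"
        return coding_designated if self.guide_bears_protospacer else not coding_designated


DEFAULT_CONVENTION = StrandConvention()


@dataclass(frozen=True)
class GuideTarget:
    """A guide-RNA protospacer interval on the reporter coding sequence.

    Parameters
    ----------
    id : str
        Guide identifier (e.g. ``sgRNA1``).
    start, end : int
        1-based inclusive protospacer bounds in coding coordinates.
    designated_strand : {"NTS", "TS"}
        Strand the guide is said to target.
    pam_side : {"upstream", "downstream"}
        Side of the protospacer, in coding coordinates, carrying the 3-nt
        PAM.  Recorded for reporting; window arithmetic uses the protospacer
        interval only.
    spacer_length : int
        Expected protospacer length (default 20); validated against the
        interval.
    """

    id: str
    start: int
    end: int
    designated_strand: str
    pam_side: str = "downstream"
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if self.designated_strand not in ("NTS", "TS"):
            raise ValueError(f"guide {self.id}: strand must be NTS or TS, got {self.designated_strand!r}")
        if self.pam_side not in ("upstream", "downstream"):
            raise ValueError(f"guide {self.id}: pam_side must be upstream or downstream")
        if self.end - self.start + 1 != self.spacer_length:
            raise ValueError(
                f"guide {self.id}: interval [{self.start}, {self.end}] is "
                f"{self.end - self.start + 1} nt, expected spacer_length={self.spacer_length}"
            )

    def validate_against(self, ref: ReferenceRegion) -> None:
        if self.start < 1 or self.end > len(ref):
            raise ValueError(
                f"guide {self.id}: protospacer [{self.start}, {self.end}] outside "
                f"reference {ref.name} (1..{len(ref)})"
            )


def window(guide: GuideTarget, margin: int, ref_length: int | None = None) -> tuple[int, int]:
    """Protospacer interval widened by ``margin`` nt on each side.

    Margin 0 returns the protospacer itself.  When ``ref_length`` is given
    the interval is clipped to ``[1, ref_length]``.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    lo = guide.start - margin
    hi = guide.end + margin
    lo = max(1, lo)
    if ref_length is not None:
        hi = min(ref_length, hi)
    return lo, hi


def non_target_base(
    guide: GuideTarget,
    pos: int,
    ref: ReferenceRegion,
    convention: StrandConvention = DEFAULT_CONVENTION,
) -> str:
    """Base at ``pos`` on the physical non-target (displaced) strand."""
    coding = ref.base(pos)
    if convention.non_target_is_coding(guide.designated_strand):
        return coding
    return complement(coding)


def find_homopolymers(ref: ReferenceRegion, min_run: int) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases with length >= ``min_run``.

    Returns ``(start, end, base)`` triples, 1-based inclusive, sorted by
    start.  Runs are maximal and therefore disjoint.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    seq = ref.coding_sequence
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i + 1, j + 1, seq[i]))
        i = j + 1
    return runs


def read_reference(path: str | Path, name: str | None = None) -> ReferenceRegion:
    """Load a single-record FASTA file as a :class:`ReferenceRegion`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return ReferenceRegion(name=name or rec.id, coding_sequence=str(rec.seq))


def write_reference(ref: ReferenceRegion, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        seq = ref.coding_sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


GUIDE_COLUMNS = ["id", "start", "end", "strand", "pam_side"]


def read_guides(path: str | Path, ref: ReferenceRegion | None = None) -> list[GuideTarget]:
    """Load guide definitions from TSV (columns id, start, end, strand, pam_side)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GUIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing guide columns {missing}")
    guides = []
    for _, row in df.iterrows():
        g = GuideTarget(
            id=str(row["id"]),
            start=int(row["start"]),
            end=int(row["end"]),
            designated_strand=str(row["strand"]),
            pam_side=str(row["pam_side"]),
            spacer_length=int(row["end"]) - int(row["start"]) + 1,
        )
        if ref is not None:
            g.validate_against(ref)
        guides.append(g)
    ids = [g.id for g in guides]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate guide ids")
    return guides


def write_guides(guides: Iterable[GuideTarget], path: str | Path) -> None:
    rows = [
        {"id": g.id, "start": g.start, "end": g.end, "strand": g.designated_strand, "pam_side": g.pam_side}
        for g in guides
    ]
    pd.DataFrame(rows, columns=GUIDE_COLUMNS).to_csv(path, sep="\t", index=False)
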