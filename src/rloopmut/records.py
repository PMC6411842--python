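"""Per-isolate mutation records in compact coordinate notation.

Each sequenced canavanine-resistant isolate carries one or more mutation
events written in a compact notation on coding coordinates::

    259G>T            substitution (position, ref base > alt base)
    286–287del        deletion of an inclusive range (single position: 292del)
    294ins(T)         insertion of known sequence 3' of the anchor position
    290ins(22 bp)     insertion of known length but unknown sequence

Multiple events in one isolate are comma-separated ("282T>A, 286–287del").
Both the en-dash (–) and the ASCII hyphen are accepted as range separators;
canonical output uses the en-dash.  Insertions are anchored 3' of the stated
position: the inserted material lies between ``pos`` and ``pos + 1``, and
interval arithmetic treats the insertion as located at its anchor.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .targets import ReferenceRegion

logger = logging.getLogger(__name__)

EN_DASH = "–"


class MutationParseError(ValueError):
    """Raised for a malformed notation term; the message names the term."""


class MutationValidationError(ValueError):
    """Raised when a parsed event contradicts the supplied reference."""


@dataclass(frozen=True)
class MutationEvent:
    """One mutation event on the coding sequence (1-based inclusive).

    For insertions ``start == end`` is the anchor position and
    ``insert_length`` is always known even when the inserted sequence is not
    (``alt_allele`` empty).
    """

    kind: str  # substitution | deletion | insertion
    start: int
    end: int
    ref_allele: str = ""
    alt_allele: str = ""
    insert_length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise ValueError(f"unknown event kind: {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")
        if self.kind == "substitution":
            if not self.ref_allele or not self.alt_allele:
                raise ValueError("substitution requires ref and alt alleles")
            if self.ref_allele == self.alt_allele:
                raise ValueError("substitution ref == alt")
            if len(self.ref_allele) != len(self.alt_allele):
                raise ValueError("substitution ref/alt length mismatch")
            if len(self.ref_allele) != self.end - self.start + 1:
                raise ValueError("substitution allele length != interval length")
        elif self.kind == "deletion":
            if self.alt_allele:
                raise ValueError("deletion carries no alt allele")
        else:  # insertion
            if self.start != self.end:
                raise ValueError("insertion anchor must satisfy start == end")
            if self.insert_length < 1:
                raise ValueError("insertion length must be >= 1")
            if self.alt_allele and len(self.alt_allele) != self.insert_length:
                raise ValueError("insertion sequence length != insert_length")

    @property
    def sequence_known(self) -> bool:
        return self.kind != "insertion" or bool(self.alt_allele)


@dataclass
class IsolateRecord:
    """One sequenced resistant isolate: >=1 mutation events, sorted by start."""

    isolate_id: str
    guide_id: str | None
    genotype: str
    events: list[MutationEvent]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"isolate {self.isolate_id}: at least one event required")
        self.events = sorted(self.events, key=lambda e: (e.start, e.end))


@dataclass
class MutationTable:
    """Container for isolate records plus provenance metadata."""

    records: list[IsolateRecord]
    source: str | None = None
    reference_name: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.isolate_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate isolate ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, guide_id: str | None = None, genotype: str | None = None) -> "MutationTable":
        recs = [
            r
            for r in self.records
            if (guide_id is None or r.guide_id == guide_id)
            and (genotype is None or r.genotype == genotype)
        ]
        return MutationTable(recs, source=self.source, reference_name=self.reference_name,
                             metadata=dict(self.metadata))

    @property
    def n_events(self) -> int:
        return sum(len(r.events) for r in self.records)


_SUB_RE = re.compile(r"^(\d+)([ACGT]+)>([ACGT]+)$", re.IGNORECASE)
_DEL_RE = re.compile(r"^(\d+)(?:[–-](\d+))?del$", re.IGNORECASE)
_INS_SEQ_RE = re.compile(r"^(\d+)ins\(([ACGT]+)\)$", re.IGNORECASE)
_INS_LEN_RE = re.compile(r"^(\d+)ins\((\d+)\s*bp\)$", re.IGNORECASE)


def _parse_term(term: str) -> MutationEvent:
    compact = term.strip()
    m = _SUB_RE.match(compact.replace(" ", ""))
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
        if ref == alt:
            raise MutationParseError(f"substitution with identical alleles: {term!r}")
        return MutationEvent("substitution", pos, pos + len(ref) - 1, ref, alt)
    m = _DEL_RE.match(compact.replace(" ", ""))
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise MutationParseError(f"zero- or negative-length deletion range: {term!r}")
        return MutationEvent("deletion", start, end)
    m = _INS_SEQ_RE.match(compact.replace(" ", ""))
    if m:
        pos, seq = int(m.group(1)), m.group(2).upper()
        return MutationEvent("insertion", pos, pos, alt_allele=seq, insert_length=len(seq))
    m = _INS_LEN_RE.match(compact)
    if m:
        pos, length = int(m.group(1)), int(m.group(2))
        if length < 1:
            raise MutationParseError(f"insertion of length zero: {term!r}")
        return MutationEvent("insertion", pos, pos, insert_length=length)
    raise MutationParseError(f"cannot parse mutation term: {term!r}")


def parse_mutation(notation: str, ref: ReferenceRegion | None = None) -> list[MutationEvent]:
    """Parse a comma-separated notation string into sorted mutation events.

    If a reference is supplied, stated ref alleles (and deletion intervals)
    are validated against it.
    """
    if not notation or not notation.strip():
        raise MutationParseError("empty mutation notation")
    events = [_parse_term(t) for t in notation.split(",")]
    events.sort(key=lambda e: (e.start, e.end))
    if ref is not None:
        for ev in events:
            validate_event(ev, ref)
    return events


def validate_event(ev: MutationEvent, ref: ReferenceRegion) -> None:
    if ev.end > len(ref):
        raise MutationValidationError(
            f"event at [{ev.start}, {ev.end}] outside reference {ref.name} (1..{len(ref)})"
        )
    if ev.kind == "substitution":
        observed = ref.coding_sequence[ev.start - 1 : ev.end]
        if observed != ev.ref_allele:
            raise MutationValidationError(
                f"ref allele mismatch at {ev.start}: notation says {ev.ref_allele}, "
                f"reference has {observed}"
            )


def _format_event(ev: MutationEvent) -> str:
    if ev.kind == "substitution":
        return f"{ev.start}{ev.ref_allele}>{ev.alt_allele}"
    if ev.kind == "deletion":
        if ev.start == ev.end:
            return f"{ev.start}del"
        return f"{ev.start}{EN_DASH}{ev.end}del"
    if ev.sequence_known:
        return f"{ev.start}ins({ev.alt_allele})"
    return f"{ev.start}ins({ev.insert_length} bp)"


def format_mutation(events: Sequence[MutationEvent]) -> str:
    """Canonical comma-separated notation; inverse of :func:`parse_mutation`."""
    ordered = sorted(events, key=lambda e: (e.start, e.end))
    return ", ".join(_format_event(e) for e in ordered)


TABLE_COLUMNS = ["isolate_id", "guide_id", "genotype", "mutations"]


def read_table(path: str | Path, ref: ReferenceRegion | None = None) -> MutationTable:
    """Read an isolate mutation table from TSV.

    Expected columns: isolate_id, guide_id (empty for no-guide controls),
    genotype, mutations (notation string).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[IsolateRecord] = []
    for idx, row in df.iterrows():
        notation = row["mutations"]
        try:
            events = parse_mutation(notation, ref=ref)
        except (MutationParseError, MutationValidationError) as exc:
            raise type(exc)(f"{path}, row {idx + 2}, column 'mutations': {exc}") from exc
        records.append(
            IsolateRecord(
                isolate_id=row["isolate_id"],
                guide_id=row["guide_id"] or None,
                genotype=row["genotype"],
                events=events,
            )
        )
    if not records:
        logger.warning("%s: empty mutation table", path)
    return MutationTable(records, source=str(path), reference_name=ref.name if ref else None)


def write_table(table: MutationTable, path: str | Path) -> None:
    rows = [
        {
            "isolate_id": r.isolate_id,
            "guide_id": r.guide_id or "",
            "genotype": r.genotype,
            "mutations": format_mutation(r.events),
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def table_from_notations(
    notations: Sequence[str],
    guide_id: str | None = None,
    genotype: str = "WT",
    prefix: str = "iso",
    ref: ReferenceRegion | None = None,
) -> MutationTable:
    """Build a table from bare notation strings (isolate ids auto-assigned)."""
    records = [
        IsolateRecord(f"{prefix}{i + 1:03d}", guide_id, genotype, parse_mutation(n, ref=ref))
        for i, n in enumerate(notations)
    ]
    return MutationTable(records)


def export_vcf_like(table: MutationTable, ref: ReferenceRegion) -> pd.DataFrame:
    """Express the table as VCF-style records on the coding sequence.

    Substitutions map directly; deletions and insertions are left-anchored at
    ``start - 1`` with the anchor base per VCF convention.  A deletion
    starting at position 1 has no left anchor and is emitted right-anchored
    (logged).  Sequence-unknown insertions use the symbolic allele ``<INS>``
    with an ``SVLEN`` INFO key.  Each event becomes one record; events from
    the same isolate share an ``ISOLATE=`` INFO key.
    """
    rows = []
    for rec in table.records:
        for ev in rec.events:
            validate_event(ev, ref)
            info = f"ISOLATE={rec.isolate_id}"
            if ev.kind == "substitution":
                pos, vref, valt = ev.start, ev.ref_allele, ev.alt_allele
            elif ev.kind == "deletion":
                deleted = ref.coding_sequence[ev.start - 1 : ev.end]
                if ev.start == 1:
                    # no left anchor: right-anchor on the base after the deletion
                    anchor = ref.base(ev.end + 1)
                    pos, vref, valt = 1, deleted + anchor, anchor
                    logger.info("deletion at position 1 right-anchored for isolate %s", rec.isolate_id)
                else:
                    anchor = ref.base(ev.start - 1)
                    pos, vref, valt = ev.start - 1, anchor + deleted, anchor
            else:
                anchor_pos = ev.start
                anchor = ref.base(anchor_pos)
                if ev.sequence_known:
                    pos, vref, valt = anchor_pos, anchor, anchor + ev.alt_allele
                else:
                    pos, vref, valt = anchor_pos, anchor, "<INS>"
                    info += f";SVLEN={ev.insert_length}"
            rows.append(
                {"CHROM": ref.name, "POS": pos, "ID": ".", "REF": vref, "ALT": valt,
                 "QUAL": ".", "FILTER": ".", "INFO": info}
            )
    return pd.DataFrame(rows, columns=["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"])


def write_vcf(table: MutationTable, ref: ReferenceRegion, path: str | Path) -> None:
    """Write the VCF-like export as a minimal VCF 4.2 text file."""
    df = export_vcf_like(table, ref)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={len(ref)}>\n")
        fh.write('##INFO=<ID=ISOLATE,Number=1,Type=String,Description="Source isolate id">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Insertion length">\n')
        fh.write('##ALT=<ID=INS,Description="Insertion of unknown sequence">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in df.iterrows():
            fh.write("\t".join(str(row[c]) for c in df.columns) + "\n")
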