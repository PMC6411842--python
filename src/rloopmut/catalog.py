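"""Scoring guides by their potential reporter-inactivating cytosines.

A deamination event at a cytosine on the displaced non-target strand of the
R-loop can only yield a resistant colony if the resulting substitution
abolishes reporter function.  Which substitutions do so is taken from a
user-supplied catalog of known inactivating coding-strand substitutions
(e.g. compiled from deaminase-mutagenesis screens of the same reporter);
building such a catalog is outside this package's scope.

For each guide, every protospacer position whose non-target-strand base is C
is checked: the configured deamination outcomes (C>T always; C>G and C>A
arise from error-prone processing of the uracil/abasic lesion) are mapped
back onto the coding strand through the strand convention and looked up in
the catalog.  A position counts if at least one outcome is cataloged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .targets import (
    DEFAULT_CONVENTION,
    GuideTarget,
    ReferenceRegion,
    StrandConvention,
    complement,
    window,
)

DEAMINATION_OUTCOMES = ("C>T", "C>G", "C>A")
UNG_DEFICIENT_OUTCOMES = ("C>T",)  # uracil not excised: only direct C>T miscoding


@dataclass(frozen=True)
class CatalogEntry:
    position: int
    ref: str
    alt: str
    source: str = ""


@dataclass
class InactivatingCatalog:
    """Set of coding-strand substitutions known to inactivate the reporter."""

    entries: list[CatalogEntry]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [(e.position, e.ref, e.alt) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate catalog entries")
        self._index = frozenset(keys)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: tuple[int, str, str]) -> bool:
        return key in self._index

    def validate_against(self, ref: ReferenceRegion) -> None:
        for e in self.entries:
            if not 1 <= e.position <= len(ref):
                raise ValueError(f"catalog position {e.position} outside reference")
            if ref.base(e.position) != e.ref:
                raise ValueError(
                    f"catalog ref mismatch at {e.position}: catalog {e.ref}, "
                    f"reference {ref.base(e.position)}"
                )


def read_catalog(path: str | Path, ref: ReferenceRegion | None = None) -> InactivatingCatalog:
    """Load a catalog TSV (columns position, ref, alt, optional source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("position", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing catalog column {col!r}")
    entries = [
        CatalogEntry(int(r["position"]), r["ref"].upper(), r["alt"].upper(),
                     str(r.get("source", "") or ""))
        for _, r in df.iterrows()
    ]
    cat = InactivatingCatalog(entries, provenance=str(path))
    if ref is not None:
        cat.validate_against(ref)
    return cat


def write_catalog(catalog: InactivatingCatalog, path: str | Path) -> None:
    rows = [
        {"position": e.position, "ref": e.ref, "alt": e.alt, "source": e.source}
        for e in catalog.entries
    ]
    pd.DataFrame(rows, columns=["position", "ref", "alt", "source"]).to_csv(
        path, sep="\t", index=False
    )


def potential_inactivating_cytosines(
    guide: GuideTarget,
    ref: ReferenceRegion,
    catalog: InactivatingCatalog,
    outcomes: Sequence[str] = DEAMINATION_OUTCOMES,
    convention: StrandConvention = DEFAULT_CONVENTION,
) -> tuple[int, list[int]]:
    """Count protospacer positions where a cataloged deamination outcome exists.

    Returns ``(count, positions)`` where positions are coding coordinates of
    non-target-strand cytosines with at least one configured outcome in the
    catalog.
    """
    guide.validate_against(ref)
    for o in outcomes:
        if o not in DEAMINATION_OUTCOMES:
            raise ValueError(f"unsupported deamination outcome: {o!r}")
    on_coding = convention.non_target_is_coding(guide.designated_strand)
    lo, hi = window(guide, 0, len(ref))
    hits: list[int] = []
    for pos in range(lo, hi + 1):
        coding = ref.base(pos)
        nt_base = coding if on_coding else complement(coding)
        if nt_base != "C":
            continue
        for outcome in outcomes:
            alt_nt = outcome.split(">")[1]
            if on_coding:
                key = (pos, "C", alt_nt)
            else:
                key = (pos, coding, complement(alt_nt))
            if key in catalog:
                hits.append(pos)
                break
    return len(hits), hits


def rank_guides(
    guides: Sequence[GuideTarget],
    ref: ReferenceRegion,
    catalog: InactivatingCatalog,
    outcomes: Sequence[str] = DEAMINATION_OUTCOMES,
    convention: StrandConvention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Score every guide; rows sorted by count descending, ties in input order."""
    rows = []
    for g in guides:
        count, positions = potential_inactivating_cytosines(
            g, ref, catalog, outcomes=outcomes, convention=convention
        )
        rows.append(
            {"guide_id": g.id, "strand": g.designated_strand,
             "count": count, "positions": ",".join(map(str, positions))}
        )
    df = pd.DataFrame(rows, columns=["guide_id", "strand", "count", "positions"])
    return df.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
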