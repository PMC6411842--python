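"""Spectrum classification of isolates and events relative to a guide target.

The analysis questions mirror how reporter-gene mutation spectra are read:
how many isolates carry a mutation inside (or within a margin of) the
protospacer; which of those are *complex* (two or more events within 10 nt
of each other, the signature of translesion synthesis by pol zeta); what the
substitution spectrum looks like when re-expressed on the displaced
non-target strand of the R-loop (where cytosine deamination acts); and how
many target-site mutations are single-nucleotide slippage indels inside a
homopolymer run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .records import IsolateRecord, MutationEvent, MutationTable
from .targets import (
    DEFAULT_CONVENTION,
    GuideTarget,
    ReferenceRegion,
    StrandConvention,
    complement,
    find_homopolymers,
    window,
)

DEFAULT_MARGINS = (0, 2, 10)
COMPLEX_DISTANCE = 10


def _event_interval(ev: MutationEvent) -> tuple[int, int]:
    # insertions occupy their anchor position only
    if ev.kind == "insertion":
        return ev.start, ev.start
    return ev.start, ev.end


def event_in_window(ev: MutationEvent, guide: GuideTarget, margin: int,
                    ref_length: int | None = None) -> bool:
    lo, hi = window(guide, margin, ref_length)
    s, e = _event_interval(ev)
    return s <= hi and e >= lo


def in_window(record: IsolateRecord, guide: GuideTarget, margin: int,
              ref_length: int | None = None) -> bool:
    """True iff any event of the isolate intersects the widened protospacer."""
    return any(event_in_window(ev, guide, margin, ref_length) for ev in record.events)


def _pair_distance(a: MutationEvent, b: MutationEvent) -> int:
    """Gap between nearest endpoints of two events (0 for overlap/adjacency)."""
    (s1, e1), (s2, e2) = _event_interval(a), _event_interval(b)
    if s1 > s2:
        (s1, e1), (s2, e2) = (s2, e2), (s1, e1)
    return max(0, s2 - e1)


def is_complex(record: IsolateRecord, distance: int = COMPLEX_DISTANCE) -> bool:
    """True iff >=2 events lie within ``distance`` nt of each other.

    Grouping is transitive: a chain a–b–c where consecutive gaps are within
    the threshold counts as a single cluster.  (With a single threshold any
    qualifying chain already contains a qualifying pair, so the check
    reduces to a pairwise scan; transitivity matters only for reporting
    cluster membership.)
    """
    evs = record.events
    for i in range(len(evs)):
        for j in range(i + 1, len(evs)):
            if _pair_distance(evs[i], evs[j]) <= distance:
                return True
    return False


@dataclass
class Fraction:
    """A reported numerator/denominator pair; value is None when undefined."""

    numerator: int
    denominator: int

    @property
    def value(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        v = "undefined" if self.value is None else f"{self.value:.3f}"
        return f"{self.numerator}/{self.denominator} ({v})"


@dataclass
class SpectrumSummary:
    """All per-guide spectrum tallies produced by :func:`summarize`."""

    guide_id: str | None
    n_isolates: int
    n_events: int
    n_in_window: dict[int, int]                # margin -> isolates with an event in window
    n_events_in_window: dict[int, int]         # margin -> events in window
    class_counts: dict[str, int]               # event kind -> count (all events)
    class_counts_in_target: dict[str, int]     # event kind -> count (margin-0 window)
    n_complex: int                             # complex isolates, whole table
    n_complex_in_target: int                   # complex isolates among margin-0 in-window isolates
    substitution_spectrum_nt: dict[str, int]   # non-target-strand spectrum of in-target substitutions
    n_in_target_events_at_nt_C: int            # in-target substitution events at non-target-strand C
    homopolymer_indel_isolates: int
    per_position: dict[int, int]
    per_codon: dict[int, int]
    margins: tuple[int, ...]
    convention: str
    complex_distance: int
    homopolymer_min_run: int

    def deamination(self) -> Fraction:
        """In-target substitutions at non-target-strand C over all in-target events."""
        return Fraction(self.n_in_target_events_at_nt_C, self.n_events_in_window.get(0, 0))

    def to_dict(self) -> dict:
        return {
            "guide_id": self.guide_id,
            "n_isolates": self.n_isolates,
            "n_events": self.n_events,
            "n_in_window": {str(k): v for k, v in self.n_in_window.items()},
            "n_events_in_window": {str(k): v for k, v in self.n_events_in_window.items()},
            "class_counts": self.class_counts,
            "class_counts_in_target": self.class_counts_in_target,
            "n_complex": self.n_complex,
            "n_complex_in_target": self.n_complex_in_target,
            "substitution_spectrum_nt": self.substitution_spectrum_nt,
            "n_in_target_events_at_nt_C": self.n_in_target_events_at_nt_C,
            "homopolymer_indel_isolates": self.homopolymer_indel_isolates,
            "margins": list(self.margins),
            "convention": self.convention,
            "complex_distance": self.complex_distance,
            "homopolymer_min_run": self.homopolymer_min_run,
        }


def _nt_substitution(ev: MutationEvent, guide: GuideTarget, ref: ReferenceRegion,
                     convention: StrandConvention) -> list[tuple[str, str]]:
    """Per-base (ref, alt) pairs of a substitution re-expressed on the non-target strand."""
    pairs = []
    on_coding = convention.non_target_is_coding(guide.designated_strand)
    for r, a in zip(ev.ref_allele, ev.alt_allele):
        if on_coding:
            pairs.append((r, a))
        else:
            pairs.append((complement(r), complement(a)))
    return pairs


def summarize(
    table: MutationTable,
    guide: GuideTarget | None,
    ref: ReferenceRegion,
    margins: Sequence[int] = DEFAULT_MARGINS,
    complex_distance: int = COMPLEX_DISTANCE,
    homopolymer_min_run: int = 6,
    convention: StrandConvention = DEFAULT_CONVENTION,
) -> SpectrumSummary:
    """Produce the full spectrum summary of a table against one guide.

    Substitutions inside the margin-0 window are re-expressed on the
    physical non-target strand before tallying the substitution spectrum.
    Multi-nucleotide substitutions and deletions increment every covered
    position in the positional histograms (each mutated nucleotide counted
    individually); codon index is ``ceil(pos / 3)``.  With ``guide=None``
    (no-guide control) all window-relative fields are empty.
    """
    margins = tuple(sorted(set(margins) | {0}))  # margin 0 always tallied
    n_isolates = len(table)
    n_events = table.n_events

    class_counts = {"substitution": 0, "deletion": 0, "insertion": 0}
    per_position: dict[int, int] = {}
    per_codon: dict[int, int] = {}
    n_complex = sum(1 for r in table if is_complex(r, complex_distance))

    for rec in table:
        for ev in rec.events:
            class_counts[ev.kind] += 1
            s, e = _event_interval(ev)
            for pos in range(s, e + 1):
                per_position[pos] = per_position.get(pos, 0) + 1
                codon = math.ceil(pos / 3)
                per_codon[codon] = per_codon.get(codon, 0) + 1

    if guide is None:
        return SpectrumSummary(
            guide_id=None, n_isolates=n_isolates, n_events=n_events,
            n_in_window={}, n_events_in_window={},
            class_counts=class_counts, class_counts_in_target={},
            n_complex=n_complex, n_complex_in_target=0,
            substitution_spectrum_nt={}, n_in_target_events_at_nt_C=0,
            homopolymer_indel_isolates=0,
            per_position=per_position, per_codon=per_codon,
            margins=margins,
            convention=f"guide_bears_protospacer={convention.guide_bears_protospacer}",
            complex_distance=complex_distance, homopolymer_min_run=homopolymer_min_run,
        )

    guide.validate_against(ref)
    L = len(ref)
    n_in_window = {m: sum(1 for r in table if in_window(r, guide, m, L)) for m in margins}
    n_events_in_window = {
        m: sum(1 for r in table for ev in r.events if event_in_window(ev, guide, m, L))
        for m in margins
    }

    class_counts_in_target = {"substitution": 0, "deletion": 0, "insertion": 0}
    spectrum: dict[str, int] = {}
    n_at_c = 0
    for rec in table:
        for ev in rec.events:
            if not event_in_window(ev, guide, 0, L):
                continue
            class_counts_in_target[ev.kind] += 1
            if ev.kind == "substitution":
                pairs = _nt_substitution(ev, guide, ref, convention)
                for r, a in pairs:
                    key = f"{r}>{a}"
                    spectrum[key] = spectrum.get(key, 0) + 1
                if any(r == "C" for r, _ in pairs):
                    n_at_c += 1

    n_complex_in_target = sum(
        1 for r in table if in_window(r, guide, 0, L) and is_complex(r, complex_distance)
    )
    hp = homopolymer_indel_count(table, guide, ref, min_run=homopolymer_min_run)

    return SpectrumSummary(
        guide_id=guide.id, n_isolates=n_isolates, n_events=n_events,
        n_in_window=n_in_window, n_events_in_window=n_events_in_window,
        class_counts=class_counts, class_counts_in_target=class_counts_in_target,
        n_complex=n_complex, n_complex_in_target=n_complex_in_target,
        substitution_spectrum_nt=spectrum, n_in_target_events_at_nt_C=n_at_c,
        homopolymer_indel_isolates=hp,
        per_position=per_position, per_codon=per_codon,
        margins=margins,
        convention=f"guide_bears_protospacer={convention.guide_bears_protospacer}",
        complex_distance=complex_distance, homopolymer_min_run=homopolymer_min_run,
    )


def deamination_fraction(summary: SpectrumSummary) -> Fraction:
    """Fraction of in-target events that are substitutions at a non-target-strand C.

    The denominator is *all* in-target mutation events, including deletions
    and insertions, matching how the reported spectra count their totals.
    """
    return summary.deamination()


def composition_enrichment(n_at_c: int, n_total: int, c_fraction: float) -> float:
    """One-sided exact binomial tail P(X >= n_at_c), X ~ Binomial(n_total, c_fraction).

    Formalizes the sequence-composition argument: could the observed number
    of C-associated mutations arise from the cytosine content of the window
    alone?
    """
    if not 0 <= n_at_c <= n_total:
        raise ValueError("require 0 <= n_at_c <= n_total")
    if not 0.0 <= c_fraction <= 1.0:
        raise ValueError("c_fraction must be a proportion")
    if n_at_c == 0:
        return 1.0
    return float(stats.binom.sf(n_at_c - 1, n_total, c_fraction))


def homopolymer_indel_count(
    table: MutationTable,
    guide: GuideTarget,
    ref: ReferenceRegion,
    min_run: int = 6,
    margin: int = 0,
) -> int:
    """Isolates whose target-site mutations include a 1-nt indel in a long homopolymer.

    Counts in-window isolates with at least one single-nucleotide insertion
    or deletion anchored inside, or immediately adjacent to, a homopolymer
    run of length >= ``min_run`` that overlaps the guide window.
    """
    L = len(ref)
    lo, hi = window(guide, margin, L)
    runs = [
        (s, e, b) for s, e, b in find_homopolymers(ref, min_run) if s <= hi and e >= lo
    ]
    if not runs:
        return 0
    count = 0
    for rec in table:
        if not in_window(rec, guide, margin, L):
            continue
        hit = False
        for ev in rec.events:
            one_nt_del = ev.kind == "deletion" and ev.end == ev.start
            one_nt_ins = ev.kind == "insertion" and ev.insert_length == 1
            if not (one_nt_del or one_nt_ins):
                continue
            if not event_in_window(ev, guide, margin, L):
                continue
            anchor = ev.start
            for s, e, _ in runs:
                if s - 1 <= anchor <= e + 1:
                    hit = True
                    break
            if hit:
                break
        count += hit
    return count
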