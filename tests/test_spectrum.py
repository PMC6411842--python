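"""Window membership, complex-mutation calling and spectrum summaries."""

import math

import numpy as np
import pytest

from rloopmut.records import MutationEvent, IsolateRecord, MutationTable, table_from_notations
from rloopmut.spectrum import (
    composition_enrichment,
    deamination_fraction,
    homopolymer_indel_count,
    in_window,
    is_complex,
    summarize,
)
from rloopmut.synthetic_supplement import SGRNA2, SGRNA6
from rloopmut.targets import GuideTarget, ReferenceRegion, StrandConvention

G1 = GuideTarget("g1", 277, 296, "TS")


def record(notation, ref=None):
    return table_from_notations([notation], ref=ref).records[0]


class TestInWindow:
    @pytest.mark.parametrize(
        "notation,margin,expected",
        [
            ("287T>A", 0, True),
            ("259G>T", 0, False),
            ("259G>T", 18, True),
            ("276del", 0, False),
            ("276del", 1, True),
            ("290ins(22 bp)", 0, True),  # insertion located at its anchor
            ("297ins(T)", 0, False),
        ],
    )
    def test_examples(self, notation, margin, expected):
        assert in_window(record(notation), G1, margin) is expected

    def test_spanning_event_intersects(self):
        # deletion straddling the window edge counts as inside
        assert in_window(record("270–280del"), G1, 0)


class TestIsComplex:
    @pytest.mark.parametrize(
        "notation,expected",
        [
            ("282T>A, 286–287del", True),
            ("287T>A, 289G>C", True),
            ("259G>T", False),
            ("100A>T, 150A>T", False),  # gap 50 > 10
            ("100A>T, 111del", False),  # gap exactly 11
            ("100A>T, 110del", True),   # gap exactly 10
        ],
    )
    def test_examples(self, notation, expected):
        assert is_complex(record(notation)) is expected

    def test_single_event_never_complex(self):
        for distance in (0, 10, 10_000):
            assert not is_complex(record("259G>T"), distance)

    def test_transitive_chain_counts_once(self):
        rec = record("100A>T, 108A>T, 116A>T")
        assert is_complex(rec)


class TestPairwiseOracle:
    """in_window / is_complex agree with an exhaustive brute-force check."""

    def _oracle_in_window(self, rec, guide, margin, L):
        lo, hi = max(1, guide.start - margin), min(L, guide.end + margin)
        for ev in rec.events:
            s = ev.start
            e = ev.start if ev.kind == "insertion" else ev.end
            if any(lo <= p <= hi for p in range(s, e + 1)):
                return True
        return False

    def _oracle_is_complex(self, rec, distance):
        evs = rec.events
        for i, a in enumerate(evs):
            for b in evs[i + 1 :]:
                ae = a.start if a.kind == "insertion" else a.end
                be = b.start if b.kind == "insertion" else b.end
                gap = max(0, max(a.start, b.start) - min(ae, be))
                if gap <= distance:
                    return True
        return False

    def test_random_tables(self):
        rng = np.random.default_rng(2022)
        L = 400
        guide = GuideTarget("g", 180, 199, "NTS")
        for trial in range(1000):
            n_events = int(rng.integers(1, 4))
            events = []
            for _ in range(n_events):
                start = int(rng.integers(1, L - 30))
                kind = ["substitution", "deletion", "insertion"][int(rng.integers(3))]
                if kind == "substitution":
                    events.append(MutationEvent(kind, start, start, "A", "T"))
                elif kind == "deletion":
                    events.append(MutationEvent(kind, start, start + int(rng.integers(0, 12))))
                else:
                    events.append(MutationEvent(kind, start, start, insert_length=1))
            rec = IsolateRecord(f"i{trial}", "g", "WT", events)
            margin = int(rng.integers(0, 15))
            distance = int(rng.integers(0, 15))
            assert in_window(rec, guide, margin, L) == self._oracle_in_window(
                rec, guide, margin, L
            )
            assert is_complex(rec, distance) == self._oracle_is_complex(rec, distance)


class TestSummarize:
    def test_empty_table_zero_summary(self, ref):
        s = summarize(MutationTable([]), SGRNA2, ref)
        assert s.n_isolates == 0 and s.n_events == 0
        assert all(v == 0 for v in s.n_in_window.values())
        assert s.substitution_spectrum_nt == {}

    def test_window_counts_monotone_in_margin(self, ref):
        table = table_from_notations(
            ["287del", "312del", "320del", "100del"], guide_id="sgRNA2"
        )
        s = summarize(table, SGRNA2, ref, margins=(0, 2, 5, 10, 20, 40))
        counts = [s.n_in_window[m] for m in sorted(s.n_in_window)]
        assert counts == sorted(counts)

    def test_isolate_counted_once_with_two_in_target_events(self, ref):
        table = table_from_notations(["293C>T, 296C>T"], guide_id="sgRNA2")
        s = summarize(table, SGRNA2, ref)
        assert s.n_in_window[0] == 1
        assert s.n_events_in_window[0] == 2

    def test_multi_nt_events_count_each_position(self, ref):
        table = table_from_notations(["300–302del"])
        s = summarize(table, SGRNA2, ref)
        assert s.per_position == {300: 1, 301: 1, 302: 1}
        assert s.per_codon == {100: 1, 101: 2}  # ceil(300/3)=100, 301 and 302 -> 101

    def test_strand_flip_complements_spectrum_only(self, ref):
        table = table_from_notations(
            ["293C>T", "296C>G", "308A>G", "298del", "285G>A"], guide_id="sgRNA2"
        )
        base = summarize(table, SGRNA2, ref)
        flipped = summarize(
            table, SGRNA2, ref, convention=StrandConvention(guide_bears_protospacer=False)
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = {
            f"{comp[k[0]]}>{comp[k[2]]}": v
            for k, v in base.substitution_spectrum_nt.items()
        }
        assert flipped.substitution_spectrum_nt == expected
        assert flipped.n_in_window == base.n_in_window
        assert flipped.class_counts == base.class_counts
        assert flipped.n_complex == base.n_complex

    def test_no_guide_control_omits_window_stats(self, ref):
        table = table_from_notations(["259G>T", "100G>T"])
        s = summarize(table, None, ref)
        assert s.n_in_window == {} and s.guide_id is None
        assert s.class_counts["substitution"] == 2


class TestDeaminationFraction:
    def test_constructed_four_of_five(self, ref):
        table = table_from_notations(
            ["293C>T", "296C>T", "299C>T", "290C>T", "308A>G"], guide_id="sgRNA2"
        )
        frac = deamination_fraction(summarize(table, SGRNA2, ref))
        assert (frac.numerator, frac.denominator) == (4, 5)
        assert frac.value == pytest.approx(0.8)

    def test_all_deletions_zero_numerator(self, ref):
        table = table_from_notations(["292del", "298del", "300–301del"], guide_id="sgRNA2")
        frac = deamination_fraction(summarize(table, SGRNA2, ref))
        assert frac.numerator == 0 and frac.denominator == 3

    def test_empty_denominator_flagged_undefined(self, ref):
        frac = deamination_fraction(summarize(MutationTable([]), SGRNA2, ref))
        assert frac.value is None


class TestCompositionEnrichment:
    def _oracle(self, k, n, p):
        return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))

    @pytest.mark.parametrize("k,n,p", [(10, 14, 0.30), (3, 20, 0.25), (1, 5, 0.5)])
    def test_matches_direct_summation(self, k, n, p):
        assert composition_enrichment(k, n, p) == pytest.approx(self._oracle(k, n, p))

    def test_degenerate_cases(self):
        assert composition_enrichment(0, 14, 0.3) == 1.0
        assert composition_enrichment(14, 14, 1.0) == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            composition_enrichment(15, 14, 0.3)
        with pytest.raises(ValueError):
            composition_enrichment(1, 14, 1.5)


class TestHomopolymerIndelCount:
    def test_one_nt_deletion_in_run_counted(self, ref):
        table = table_from_notations(["1339del"], guide_id="sgRNA6")
        assert homopolymer_indel_count(table, SGRNA6, ref) == 1

    def test_adjacent_anchor_counted(self, ref):
        # anchored immediately left of the 1337-1342 run
        table = table_from_notations(["1336ins(T)"], guide_id="sgRNA6")
        assert homopolymer_indel_count(table, SGRNA6, ref) == 1

    def test_two_nt_deletion_not_counted(self, ref):
        table = table_from_notations(["1339–1340del"], guide_id="sgRNA6")
        assert homopolymer_indel_count(table, SGRNA6, ref) == 0

    def test_no_run_in_window_gives_zero(self, ref):
        table = table_from_notations(["293del"], guide_id="sgRNA2")
        assert homopolymer_indel_count(table, SGRNA2, ref) == 0
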