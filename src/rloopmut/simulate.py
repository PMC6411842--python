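"""Seeded forward simulator of reporter mutagenesis data.

The generator emulates the statistical structure of the assay at two
levels.

**Isolate level** — every simulated isolate is a resistant colony carrying
at least one loss-of-function mutation.  With probability ``p_target`` the
inactivating mutation is *target-associated* and is drawn from one of four
event classes that mirror the mechanisms by which a bound dCas9 R-loop
mutagenizes its target: a deamination-type substitution at a
non-target-strand cytosine in the protospacer (outcome C>T, or C>G / C>A
from error-prone processing of the uracil lesion), a single-nucleotide
slippage indel in a homopolymer run overlapping the target, a complex
cluster (two events within 10 nt, the translesion-synthesis signature), or
a generic small indel in the window.  Otherwise the mutation is a
*background* event dispersed over the gene (uniformly, or over a supplied
catalog of known inactivating substitutions).  Genotype toggles modify the
machinery: ``ung1`` (uracil-glycosylase-deficient) collapses deamination
outcomes to pure C>T; ``rev3`` (pol-zeta-deficient) removes the complex
class.

**Culture level** — plating counts for the fluctuation-style frequency
assay are Poisson: a culture of ``culture_cells`` cells with true mutant
frequency ``f`` plated at fold-dilutions ``d_sel`` / ``d_nonsel`` yields
``n_sel ~ Poisson(culture_cells * f / d_sel)`` and
``n_nonsel ~ Poisson(culture_cells / d_nonsel)``.

All randomness flows from one integer seed; identical seeds reproduce
outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import InactivatingCatalog
from .frequency import PlatingMeasurement
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

_BASES = "ACGT"


class SimulationConfigError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the isolate-level generator.

    Default mixture weights mirror the strongest reported target: 76% of
    isolates target-associated, with in-target events dominated by
    deamination substitutions (outcome split 0.6 / 0.2 / 0.2 across
    C>T / C>G / C>A, echoing a 6:2:2 observed split) and the remainder
    split between complex clusters and other small indels.  The
    homopolymer-indel class defaults to 0 because the default target does
    not overlap a long homopolymer; enable it for homopolymer-overlapping
    guides.
    """

    reference: ReferenceRegion
    guide: GuideTarget | None
    n_isolates: int = 21
    p_target: float = 0.76
    p_deamination: float = 0.70
    p_homopolymer_indel: float = 0.0
    p_complex: float = 0.15
    p_other_indel: float = 0.15
    outcome_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # C>T, C>G, C>A
    genotype: str = "WT"          # WT | ung1 | rev3 (Δ suffixes accepted)
    complex_max_offset: int = 10
    homopolymer_min_run: int = 6
    background_catalog: InactivatingCatalog | None = None
    convention: StrandConvention = DEFAULT_CONVENTION

    def resolved(self) -> "SimulationConfig":
        """Apply genotype toggles and validate."""
        cfg = replace(self)
        geno = cfg.genotype.rstrip("Δ").lower()
        if geno == "ung1":
            cfg.outcome_probs = (1.0, 0.0, 0.0)
        elif geno == "rev3":
            removed = cfg.p_complex
            cfg.p_complex = 0.0
            rest = cfg.p_deamination + cfg.p_homopolymer_indel + cfg.p_other_indel
            if rest > 0:
                scale = (rest + removed) / rest
                cfg.p_deamination *= scale
                cfg.p_homopolymer_indel *= scale
                cfg.p_other_indel *= scale
        elif geno != "wt":
            raise SimulationConfigError(f"unknown genotype: {self.genotype!r}")
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        if not 0.0 <= self.p_target <= 1.0:
            raise SimulationConfigError("p_target must be in [0, 1]")
        class_probs = (self.p_deamination, self.p_homopolymer_indel,
                       self.p_complex, self.p_other_indel)
        if any(p < 0 for p in class_probs) or any(p < 0 for p in self.outcome_probs):
            raise SimulationConfigError("probabilities must be non-negative")
        if self.p_target > 0 and abs(sum(class_probs) - 1.0) > 1e-9:
            raise SimulationConfigError("target class probabilities must sum to 1")
        if abs(sum(self.outcome_probs) - 1.0) > 1e-9:
            raise SimulationConfigError("deamination outcome probabilities must sum to 1")
        if self.n_isolates < 0:
            raise SimulationConfigError("n_isolates must be >= 0")
        if self.p_target > 0 and self.guide is None:
            raise SimulationConfigError("p_target > 0 requires a guide")
        if self.guide is not None:
            self.guide.validate_against(self.reference)
            if self.p_target > 0 and self.p_deamination > 0 and not self._nt_c_positions():
                raise SimulationConfigError(
                    f"guide {self.guide.id}: no non-target-strand C in protospacer "
                    "but deamination probability > 0"
                )
            if self.p_target > 0 and self.p_homopolymer_indel > 0 and not self._runs():
                raise SimulationConfigError(
                    f"guide {self.guide.id}: no homopolymer run (>= {self.homopolymer_min_run} nt) "
                    "overlaps the target but homopolymer-indel probability > 0"
                )

    def _nt_c_positions(self) -> list[int]:
        lo, hi = window(self.guide, 0, len(self.reference))
        on_coding = self.convention.non_target_is_coding(self.guide.designated_strand)
        want = "C" if on_coding else "G"  # coding-strand base whose NT-strand base is C
        return [p for p in range(lo, hi + 1) if self.reference.base(p) == want]

    def _runs(self) -> list[tuple[int, int, str]]:
        lo, hi = window(self.guide, 0, len(self.reference))
        return [
            (s, e, b)
            for s, e, b in find_homopolymers(self.reference, self.homopolymer_min_run)
            if s <= hi and e >= lo
        ]


def _random_substitution(ref: ReferenceRegion, pos: int, rng: np.random.Generator) -> MutationEvent:
    r = ref.base(pos)
    alt = rng.choice([b for b in _BASES if b != r])
    return MutationEvent("substitution", pos, pos, r, str(alt))


def _deamination_event(cfg: SimulationConfig, rng: np.random.Generator) -> MutationEvent:
    positions = cfg._nt_c_positions()
    pos = int(rng.choice(positions))
    alt_nt = str(rng.choice(["T", "G", "A"], p=list(cfg.outcome_probs)))
    on_coding = cfg.convention.non_target_is_coding(cfg.guide.designated_strand)
    if on_coding:
        return MutationEvent("substitution", pos, pos, "C", alt_nt)
    return MutationEvent("substitution", pos, pos, cfg.reference.base(pos), complement(alt_nt))


def _homopolymer_event(cfg: SimulationConfig, rng: np.random.Generator) -> MutationEvent:
    s, e, base = cfg._runs()[int(rng.integers(len(cfg._runs())))]
    lo, hi = window(cfg.guide, 0, len(cfg.reference))
    anchor = int(rng.integers(max(s, lo), min(e, hi) + 1))
    if rng.random() < 0.5:
        return MutationEvent("deletion", anchor, anchor)
    return MutationEvent("insertion", anchor, anchor, alt_allele=base, insert_length=1)


def _other_indel_event(cfg: SimulationConfig, rng: np.random.Generator) -> MutationEvent:
    lo, hi = window(cfg.guide, 0, len(cfg.reference))
    pos = int(rng.integers(lo, hi + 1))
    if rng.random() < 0.5:
        length = int(rng.integers(1, 4))
        end = min(pos + length - 1, len(cfg.reference))
        return MutationEvent("deletion", pos, end)
    return MutationEvent("insertion", pos, pos, alt_allele=str(rng.choice(list(_BASES))),
                         insert_length=1)


def _complex_events(cfg: SimulationConfig, rng: np.random.Generator) -> list[MutationEvent]:
    if cfg.p_deamination > 0 and cfg._nt_c_positions():
        primary = _deamination_event(cfg, rng)
    else:
        lo, hi = window(cfg.guide, 0, len(cfg.reference))
        primary = _random_substitution(cfg.reference, int(rng.integers(lo, hi + 1)), rng)
    offset = int(rng.integers(1, cfg.complex_max_offset + 1))
    side = 1 if rng.random() < 0.5 else -1
    pos2 = min(max(1, primary.start + side * offset), len(cfg.reference))
    if pos2 == primary.start:
        pos2 = min(primary.start + 1, len(cfg.reference))
    secondary = _random_substitution(cfg.reference, pos2, rng)
    return [primary, secondary]


def _background_event(cfg: SimulationConfig, rng: np.random.Generator) -> MutationEvent:
    if cfg.background_catalog is not None and len(cfg.background_catalog) > 0:
        entry = cfg.background_catalog.entries[int(rng.integers(len(cfg.background_catalog)))]
        return MutationEvent("substitution", entry.position, entry.position, entry.ref, entry.alt)
    pos = int(rng.integers(1, len(cfg.reference) + 1))
    return _random_substitution(cfg.reference, pos, rng)


def simulate_isolates(config: SimulationConfig, seed: int | np.random.Generator) -> MutationTable:
    """Generate a mutation table of ``n_isolates`` resistant isolates."""
    cfg = config.resolved()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    class_probs = np.array(
        [cfg.p_deamination, cfg.p_homopolymer_indel, cfg.p_complex, cfg.p_other_indel]
    )
    records = []
    guide_id = cfg.guide.id if cfg.guide is not None else None
    for i in range(cfg.n_isolates):
        if cfg.p_target > 0 and rng.random() < cfg.p_target:
            cls = int(rng.choice(4, p=class_probs))
            if cls == 0:
                events = [_deamination_event(cfg, rng)]
            elif cls == 1:
                events = [_homopolymer_event(cfg, rng)]
            elif cls == 2:
                events = _complex_events(cfg, rng)
            else:
                events = [_other_indel_event(cfg, rng)]
        else:
            events = [_background_event(cfg, rng)]
        records.append(
            IsolateRecord(f"sim{i + 1:04d}", guide_id, cfg.genotype, events)
        )
    return MutationTable(
        records,
        source="simulate_isolates",
        reference_name=cfg.reference.name,
        metadata={
            "p_target": cfg.p_target,
            "genotype": cfg.genotype,
            "convention": f"guide_bears_protospacer={cfg.convention.guide_bears_protospacer}",
        },
    )


@dataclass
class GroupSpec:
    """One strain/guide group in the simulated frequency assay."""

    group: str
    true_frequency: float
    n_cultures: int = 6


@dataclass
class FrequencyAssayConfig:
    """Parameters of the culture-level plating simulator.

    Defaults model a saturated culture of 2e8 cells, a 1:10-diluted aliquot
    on selective plates and a 1:1e6-diluted aliquot on nonselective plates,
    so a true frequency of 1e-5 yields ~200 colonies on each plate type.
    """

    groups: list[GroupSpec]
    culture_cells: float = 2e8
    d_selective: float = 10.0
    d_nonselective: float = 1e6

    def _validate(self) -> None:
        for g in self.groups:
            if g.true_frequency < 0:
                raise SimulationConfigError(f"group {g.group}: negative frequency")
            if g.n_cultures < 0:
                raise SimulationConfigError(f"group {g.group}: negative n_cultures")
        if self.d_selective < 1 or self.d_nonselective < 1:
            raise SimulationConfigError("dilution factors must be >= 1")


def simulate_frequency_assay(
    config: FrequencyAssayConfig, seed: int | np.random.Generator
) -> list[PlatingMeasurement]:
    """Generate Poisson plating counts for every culture of every group."""
    config._validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[PlatingMeasurement] = []
    for spec in config.groups:
        lam_sel = config.culture_cells * spec.true_frequency / config.d_selective
        lam_non = config.culture_cells / config.d_nonselective
        for c in range(spec.n_cultures):
            out.append(
                PlatingMeasurement(
                    culture_id=f"{spec.group}-c{c + 1}",
                    group=spec.group,
                    n_selective=int(rng.poisson(lam_sel)),
                    d_selective=config.d_selective,
                    n_nonselective=int(rng.poisson(lam_non)),
                    d_nonselective=config.d_nonselective,
                )
            )
    return out
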