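"""Asparagine-ladder extraction, conservation grading, and SD/TD/TTD classification.

The continuous hydrogen-bond network formed by the asparagines at motif
position 9 of consecutive LRR modules (the asparagine ladder) stabilizes the
ectodomain horseshoe.  Where every ladder position carries a hydrogen-donor
residue the ectodomain is a single rigid domain (SD); a ladder interrupted in
the central subdomain yields the three-domain architecture (TD); a ladder
broken in both terminal subdomains but intact centrally is trans-three-domain
(TTD).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .io import GAP, MultipleAlignment
from .lrr import EctodomainAnnotation

#: Residues able to donate the ladder hydrogen bond: asparagine itself plus
#: the threonine/serine/cysteine substitutes observed in intact ladders.
COMPETENT_RESIDUES = frozenset("NTSC")

#: Aromatics accepted for the convex-face phenylalanine spine.
SPINE_RESIDUES = frozenset("FYW")

N_GRADES = 9
N_AMINO_ACIDS = 20


def ladder_competence(residue: str) -> bool:
    """True iff the residue can maintain the ladder hydrogen bond (N, T, S or C)."""
    if len(residue) != 1:
        raise ValueError("expected a single residue letter")
    return residue.upper() in COMPETENT_RESIDUES


@dataclass(frozen=True)
class Segmentation:
    """Tercile split of the module list into N-terminal / central / C-terminal
    subdomains; 1-based inclusive module-index ranges, remainder to the center."""

    n_terminal: tuple[int, int]
    central: tuple[int, int]
    c_terminal: tuple[int, int]

    def segment_of(self, module_index: int) -> str:
        for name, (lo, hi) in zip(("N-terminal", "central", "C-terminal"), self.ranges):
            if lo <= module_index <= hi:
                return name
        raise ValueError(f"module index {module_index} outside segmentation")

    @property
    def ranges(self) -> tuple[tuple[int, int], ...]:
        return (self.n_terminal, self.central, self.c_terminal)


def segment_modules(n_modules: int) -> Segmentation:
    """Split ``n_modules`` ordinals into contiguous terciles, remainder to the center."""
    if n_modules < 6:
        raise ValueError(f"too few modules to segment into subdomains: {n_modules} < 6")
    terminal = n_modules // 3
    central = n_modules - 2 * terminal
    return Segmentation(
        n_terminal=(1, terminal),
        central=(terminal + 1, terminal + central),
        c_terminal=(terminal + central + 1, n_modules),
    )


@dataclass(frozen=True)
class BreakRule:
    """A segment's ladder counts as broken when incompetent positions form a
    run of at least ``min_run`` or exceed a fraction ``min_fraction``."""

    min_run: int = 2
    min_fraction: float = 0.4


@dataclass
class SegmentDiagnostics:
    name: str
    modules: tuple[int, int]
    incompetent_fraction: float
    longest_incompetent_run: int
    broken: bool


@dataclass
class ArchitectureCall:
    verdict: str  # SD | TD | TTD | AMBIGUOUS
    segments: list[SegmentDiagnostics]

    @property
    def broken_flags(self) -> tuple[bool, bool, bool]:
        return tuple(s.broken for s in self.segments)


def _longest_run(flags: Sequence[bool], value: bool = False) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f == value else 0
        best = max(best, run)
    return best


def classify_architecture(competence: Sequence[bool],
                          segmentation: Optional[Segmentation] = None,
                          rule: BreakRule = BreakRule()) -> ArchitectureCall:
    """Classify an ectodomain from its ordered ladder competence flags.

    SD: no segment broken.  TD: central broken, both terminals intact.
    TTD: both terminals broken, central intact.  Anything else is AMBIGUOUS,
    with per-segment diagnostics retained for inspection.
    """
    flags = [bool(f) for f in competence]
    if segmentation is None:
        segmentation = segment_modules(len(flags))
    if segmentation.c_terminal[1] != len(flags):
        raise ValueError("segmentation does not cover the competence vector")
    diags = []
    for name, (lo, hi) in zip(("N-terminal", "central", "C-terminal"), segmentation.ranges):
        seg = flags[lo - 1 : hi]
        frac = sum(1 for f in seg if not f) / len(seg)
        run = _longest_run(seg, value=False)
        broken = run >= rule.min_run or frac >= rule.min_fraction
        diags.append(SegmentDiagnostics(name=name, modules=(lo, hi),
                                        incompetent_fraction=frac,
                                        longest_incompetent_run=run, broken=broken))
    nb, cb, cbend = diags[0].broken, diags[1].broken, diags[2].broken
    if not (nb or cb or cbend):
        verdict = "SD"
    elif cb and not nb and not cbend:
        verdict = "TD"
    elif nb and cbend and not cb:
        verdict = "TTD"
    else:
        verdict = "AMBIGUOUS"
    return ArchitectureCall(verdict=verdict, segments=diags)


def conservation_grade(column: Sequence[str]) -> Optional[int]:
    """Nine-grade ordinal conservation of an alignment column.

    The score is one minus the Shannon entropy of the residue frequencies
    normalized by log 20; grades run 1 (most variable) to 9 (most conserved).
    Columns with fewer than two non-gap residues are ungradeable (None).
    """
    residues = [c.upper() for c in column if c.upper() != GAP]
    if len(residues) < 2:
        return None
    counts = Counter(residues)
    total = len(residues)
    entropy = -sum((c / total) * math.log(c / total) for c in counts.values())
    score = 1.0 - entropy / math.log(N_AMINO_ACIDS)
    return min(N_GRADES, 1 + int(math.floor(8 * score)))


@dataclass
class LadderEntry:
    module_index: int
    modal_residue: str
    modal_frequency: float
    competent: bool
    grade: Optional[int]


@dataclass
class LadderProfile:
    """Per-module consensus of the ladder column across an ortholog alignment."""

    entries: list[LadderEntry]
    segmentation: Segmentation

    @property
    def competence(self) -> list[bool]:
        return [e.competent for e in self.entries]

    def classify(self, rule: BreakRule = BreakRule()) -> ArchitectureCall:
        return classify_architecture(self.competence, self.segmentation, rule)


def _map_positions_to_columns(gapped_row: str) -> dict[int, int]:
    """Map 1-based ungapped positions to 1-based alignment columns."""
    mapping = {}
    pos = 0
    for col, ch in enumerate(gapped_row, start=1):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def _modal_residue(column: str, reference_residue: str) -> tuple[str, float]:
    """Most frequent non-gap residue and its frequency; ties prefer the
    reference residue, then alphabetical order."""
    residues = [c for c in column if c != GAP]
    if not residues:
        return reference_residue, 1.0
    counts = Counter(residues)
    top = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == top)
    modal = reference_residue if reference_residue in tied else tied[0]
    return modal, top / len(residues)


def consensus_ladder_profile(alignment: MultipleAlignment,
                             annotation: EctodomainAnnotation,
                             reference_id: str) -> LadderProfile:
    """Build a ladder profile from an ortholog alignment.

    The reference record's ladder positions (from its LRR annotation, which
    refers to the ungapped reference sequence) are mapped through alignment
    columns; per module the modal non-gap residue, its frequency, its ladder
    competence and the column's conservation grade are reported.
    """
    ref = alignment.row(reference_id)  # KeyError if absent
    mapping = _map_positions_to_columns(ref.sequence)
    entries = []
    for mod in annotation.modules:
        try:
            col_idx = mapping[mod.ladder_position]
        except KeyError:
            raise ValueError(
                f"ladder position {mod.ladder_position} beyond ungapped reference {reference_id!r}"
            ) from None
        column = alignment.column(col_idx)
        modal, freq = _modal_residue(column, mod.ladder_residue)
        entries.append(
            LadderEntry(module_index=mod.index, modal_residue=modal,
                        modal_frequency=freq, competent=ladder_competence(modal),
                        grade=conservation_grade(column))
        )
    return LadderProfile(entries=entries, segmentation=segment_modules(len(entries)))


def phenylalanine_spine_profile(annotation: EctodomainAnnotation,
                                alignment: MultipleAlignment,
                                reference_id: str,
                                spine_offset: int = 11) -> list[bool]:
    """EXPERIMENTAL: per-module convex-face aromatic spine presence flags.

    The spine column is taken at ``spine_offset`` residues past the motif
    start (default: the position immediately after the 11-mer motif); a module
    is flagged when the modal residue there is aromatic (F/Y/W).
    """
    ref = alignment.row(reference_id)
    mapping = _map_positions_to_columns(ref.sequence)
    ungapped = ref.ungapped()
    flags = []
    for mod in annotation.modules:
        pos = mod.motif_start + spine_offset
        if pos > len(ungapped) or pos not in mapping:
            flags.append(False)
            continue
        column = alignment.column(mapping[pos])
        modal, _ = _modal_residue(column, ungapped[pos - 1])
        flags.append(modal in SPINE_RESIDUES)
    return flags
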