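"""LRR module detection by concave-surface motif scoring and chain dynamic programming.

The concave face of each leucine-rich repeat carries the 11-position motif
``LxxLxLxxN/CxL``: hydrophobics at positions 1, 4, 6 and 11, and the ladder
residue (asparagine or cysteine in the canonical pattern) at position 9.
Candidate motif windows above a score threshold are chained into the
maximum-total-score set of non-overlapping modules whose spacing respects the
module length bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

# Index (0-based) of each constrained motif position within the 11-mer.
HYDROPHOBIC_POSITIONS = (0, 3, 5, 10)   # motif positions 1, 4, 6, 11
LADDER_OFFSET = 8                       # motif position 9 (the N/C of LxxLxLxxN/CxL)
MOTIF_LENGTH = 11


@dataclass(frozen=True)
class MotifParams:
    """Scoring and chaining parameters for the LRR concave-surface motif.

    ``weights`` has one entry per motif position; unconstrained ('x')
    positions contribute nothing regardless of weight.  The ladder position
    earns its full weight for N/C and ``partial_credit`` of it for T/S
    (hydrogen-donating substitutes).  The canonical module is 24 residues;
    spacing between chained motif starts must lie in [min_len, max_len].
    """

    hydrophobic: frozenset = frozenset("LIVFM")
    weights: tuple = (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0)
    ladder_full: frozenset = frozenset("NC")
    ladder_partial: frozenset = frozenset("TS")
    partial_credit: float = 0.5
    min_len: int = 20
    max_len: int = 30
    canonical_len: int = 24
    min_score: float = 3.0

    def __post_init__(self) -> None:
        if len(self.weights) != MOTIF_LENGTH:
            raise ValueError("need exactly 11 position weights")
        if not (self.min_len <= self.canonical_len <= self.max_len):
            raise ValueError("module length bounds must bracket the canonical length")
        if sum(self.weights) <= 0:
            raise ValueError("weights must sum to a positive value")

    @property
    def max_score(self) -> float:
        return sum(self.weights[i] for i in HYDROPHOBIC_POSITIONS) + self.weights[LADDER_OFFSET]


@dataclass
class LrrModule:
    """One detected LRR module (all positions 1-based, spans inclusive)."""

    index: int
    start: int
    end: int
    motif_start: int
    ladder_position: int
    ladder_residue: str
    motif_score: float


@dataclass
class EctodomainAnnotation:
    record_id: str
    modules: list[LrrModule]
    lrrnt: Optional[tuple[int, int]] = None
    lrrct: Optional[tuple[int, int]] = None
    total_score: float = 0.0
    no_candidates: bool = False

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def ladder_residues(self) -> str:
        return "".join(m.ladder_residue for m in self.modules)


def score_motif_window(window: str, params: MotifParams = MotifParams()) -> float:
    """Score an 11-residue window against the concave-surface motif template."""
    if len(window) != MOTIF_LENGTH:
        raise ValueError(f"window must be exactly {MOTIF_LENGTH} residues, got {len(window)}")
    window = window.upper()
    score = 0.0
    for pos in HYDROPHOBIC_POSITIONS:
        if window[pos] in params.hydrophobic:
            score += params.weights[pos]
    ladder = window[LADDER_OFFSET]
    if ladder in params.ladder_full:
        score += params.weights[LADDER_OFFSET]
    elif ladder in params.ladder_partial:
        score += params.partial_credit * params.weights[LADDER_OFFSET]
    return score


def find_candidates(seq: str, params: MotifParams = MotifParams()) -> list[tuple[int, float]]:
    """All (1-based motif start, score) windows with score >= min_score."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - MOTIF_LENGTH + 1):
        s = score_motif_window(seq[i : i + MOTIF_LENGTH], params)
        if s >= params.min_score:
            out.append((i + 1, s))
    return out


class _Chain:
    """DP state: total score, module count, motif-start tuple (for tie-breaks)."""

    __slots__ = ("score", "starts")

    def __init__(self, score: float, starts: tuple):
        self.score = score
        self.starts = starts

    def better_than(self, other: "_Chain") -> bool:
        # max score; ties -> more modules; ties -> leftmost start tuple
        if self.score != other.score:
            return self.score > other.score
        if len(self.starts) != len(other.starts):
            return len(self.starts) > len(other.starts)
        return self.starts < other.starts


def chain_candidates(candidates: list[tuple[int, float]],
                     params: MotifParams = MotifParams()) -> list[tuple[int, float]]:
    """Best-scoring chain of candidates with consecutive starts spaced within
    [min_len, max_len]; deterministic tie-breaking (more modules, then
    leftmost starts).  Returns the chosen (start, score) list in order.
    """
    if not candidates:
        return []
    cands = sorted(candidates)
    score_of = dict(cands)
    n = len(cands)
    best_ending: list[_Chain] = []
    for i, (si, sc_i) in enumerate(cands):
        best = _Chain(sc_i, (si,))
        for j in range(i):
            sj = cands[j][0]
            gap = si - sj
            if params.min_len <= gap <= params.max_len:
                cand = _Chain(best_ending[j].score + sc_i, best_ending[j].starts + (si,))
                if cand.better_than(best):
                    best = cand
        best_ending.append(best)
    overall = best_ending[0]
    for ch in best_ending[1:]:
        if ch.better_than(overall):
            overall = ch
    return [(s, score_of[s]) for s in overall.starts]


def detect_lrr_modules(seq: str, params: MotifParams = MotifParams(),
                       record_id: str = "query") -> EctodomainAnnotation:
    """Detect LRR modules in an ectodomain sequence.

    Each module's span runs from its motif start to one residue before the
    next module's motif start; the last module spans the canonical length,
    truncated at the sequence end.  Flanking cysteine caps are delimited
    afterwards with :func:`delimit_caps`.
    """
    seq = seq.upper()
    if len(seq) < params.min_len:
        raise ValueError(f"sequence shorter than the minimum module length {params.min_len}")
    chain = chain_candidates(find_candidates(seq, params), params)
    if not chain:
        warnings.warn(f"{record_id}: no motif window above threshold {params.min_score}")
        return EctodomainAnnotation(record_id=record_id, modules=[], no_candidates=True)
    modules = []
    for k, (start, score) in enumerate(chain):
        if k + 1 < len(chain):
            end = chain[k + 1][0] - 1
        else:
            end = min(start + params.canonical_len - 1, len(seq))
        ladder_pos = start + LADDER_OFFSET
        modules.append(
            LrrModule(index=k + 1, start=start, end=end, motif_start=start,
                      ladder_position=ladder_pos,
                      ladder_residue=seq[ladder_pos - 1], motif_score=score)
        )
    ann = EctodomainAnnotation(record_id=record_id, modules=modules,
                               total_score=sum(m.motif_score for m in modules))
    ann.lrrnt, ann.lrrct = delimit_caps(seq, modules)
    return ann


def delimit_caps(seq: str, modules: list[LrrModule],
                 min_cap_len: int = 10, min_cysteines: int = 2
                 ) -> tuple[Optional[tuple[int, int]], Optional[tuple[int, int]]]:
    """Delimit cysteine-rich LRRNT/LRRCT caps flanking the module stack.

    A cap is any flank of at least ``min_cap_len`` residues containing at
    least ``min_cysteines`` cysteines before the first / after the last
    module; 1-based inclusive spans, or None.
    """
    if not modules:
        raise ValueError("cap delimitation needs at least one module")
    seq = seq.upper()
    lrrnt = lrrct = None
    n_flank = seq[: modules[0].start - 1]
    if len(n_flank) >= min_cap_len and n_flank.count("C") >= min_cysteines:
        lrrnt = (1, modules[0].start - 1)
    c_flank = seq[modules[-1].end :]
    if len(c_flank) >= min_cap_len and c_flank.count("C") >= min_cysteines:
        lrrct = (modules[-1].end + 1, len(seq))
    return lrrnt, lrrct
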