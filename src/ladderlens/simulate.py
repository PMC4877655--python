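"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the statistical structure of real receptor data at
desk scale: LRR-structured ectodomains whose ladder pattern encodes an SD/TD/
TTD architecture, star-tree ortholog families with per-site rate
heterogeneity, codon alignments evolved under a known omega, and
horseshoe-like CA traces with an optional central distortion.  Every
generator is seed-deterministic and returns a :class:`SyntheticTruth`
alongside its output.

Background ('x') and cap residues are drawn from a hydrophilic 12-letter
set (no L/I/V/F/M, C or aromatics), mirroring the hydrophilic convex face of
real LRR modules; this keeps the concave-motif signal confined to the planted
positions so noise-free scans are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import CodonRecord, CaResidue, CaTrace, MultipleAlignment, ProteinRecord
from .ladder import COMPETENT_RESIDUES, Segmentation, segment_modules
from .lrr import HYDROPHOBIC_POSITIONS, LADDER_OFFSET, MOTIF_LENGTH

ARCHITECTURES = ("SD", "TD", "TTD")

#: Hydrophilic background used for 'x' positions, caps and inter-motif residues.
BACKGROUND = "ADEGHKNPQRST"
HYDROPHOBIC = "LIVFM"
#: Competent ladder substitutes drawn when the planted residue is not N.
COMPETENT_SUBSTITUTES = "TSC"
#: Hydrogen-bond-incompetent ladder replacements for planted breaks.
INCOMPETENT_RESIDUES = "AGDEKRQH"

SPINE_OFFSET = 11  # residue just past the 11-mer motif carries the F spine


@dataclass
class SyntheticTruth:
    """Ground truth attached to every simulation; fully determines the output
    together with the seed."""

    seed: Optional[int]
    architecture: Optional[str] = None
    module_spans: Optional[list[tuple[int, int]]] = None
    ladder_positions: Optional[list[int]] = None
    ladder_residues: Optional[str] = None
    competence: Optional[list[bool]] = None
    segmentation: Optional[Segmentation] = None
    lrrnt: Optional[tuple[int, int]] = None
    lrrct: Optional[tuple[int, int]] = None
    spine_present: Optional[list[bool]] = None
    site_rates: Optional[np.ndarray] = None
    branch_length: Optional[float] = None
    omega: Optional[float] = None
    divergence: Optional[float] = None
    kappa: Optional[float] = None
    tree: Optional[str] = None


def _draw(rng: np.random.Generator, letters: str) -> str:
    return letters[rng.integers(len(letters))]


# ---------------------------------------------------------------------------
# Ectodomain sequences
# ---------------------------------------------------------------------------

def _planted_competence(architecture: str, seg: Segmentation) -> list[bool]:
    n = seg.c_terminal[1]
    lo, hi = seg.central
    if architecture == "SD":
        return [True] * n
    if architecture == "TD":
        return [not (lo <= i <= hi) for i in range(1, n + 1)]
    if architecture == "TTD":
        return [lo <= i <= hi for i in range(1, n + 1)]
    raise ValueError(f"unknown architecture {architecture!r}; expected one of {ARCHITECTURES}")


def simulate_ectodomain(architecture: str, n_modules: int = 21,
                        seed: Optional[int] = None, noise: float = 0.0,
                        cap_nt_len: int = 12, cap_ct_len: int = 14
                        ) -> tuple[ProteinRecord, SyntheticTruth]:
    """Simulate one LRR ectodomain with a planted ladder architecture.

    Modules are 22–26 residues built on the concave 11-mer template
    (hydrophobics at motif positions 1/4/6/11); the ladder residue at motif
    position 9 is competent (N, occasionally T/S/C) or incompetent according
    to the architecture's tercile plan.  ``noise`` flips each module's
    competence independently.  Cysteine-bearing LRRNT/LRRCT caps flank the
    stack.  Central modules of TD ectodomains lack the phenylalanine spine.
    """
    if n_modules < 6:
        raise ValueError("need at least 6 modules")
    rng = np.random.default_rng(seed)
    seg = segment_modules(n_modules)
    competence = _planted_competence(architecture, seg)
    if noise > 0:
        flips = rng.random(n_modules) < noise
        competence = [c ^ bool(f) for c, f in zip(competence, flips)]

    central_lo, central_hi = seg.central
    spine_present = [not (architecture == "TD" and central_lo <= i + 1 <= central_hi)
                     for i in range(n_modules)]

    def cap(length: int, cys_at: tuple[int, int]) -> str:
        residues = [_draw(rng, BACKGROUND) for _ in range(length)]
        for pos in cys_at:
            residues[pos] = "C"
        return "".join(residues)

    parts = [cap(cap_nt_len, (1, 4))]
    pos = cap_nt_len
    spans, ladder_positions, ladder_residues = [], [], []
    for m in range(n_modules):
        length = int(rng.integers(22, 27))
        module = [_draw(rng, BACKGROUND) for _ in range(length)]
        for off in HYDROPHOBIC_POSITIONS:
            module[off] = _draw(rng, HYDROPHOBIC)
        if competence[m]:
            ladder = "N" if rng.random() >= 0.05 else _draw(rng, COMPETENT_SUBSTITUTES)
        else:
            ladder = _draw(rng, INCOMPETENT_RESIDUES)
        module[LADDER_OFFSET] = ladder
        if spine_present[m]:
            module[SPINE_OFFSET] = "F"
        parts.append("".join(module))
        spans.append((pos + 1, pos + length))
        ladder_positions.append(pos + LADDER_OFFSET + 1)
        ladder_residues.append(ladder)
        pos += length
    parts.append(cap(cap_ct_len, (2, 7)))
    sequence = "".join(parts)

    record = ProteinRecord(id=f"{architecture}_n{n_modules}_s{seed}", sequence=sequence)
    truth = SyntheticTruth(
        seed=seed, architecture=architecture, module_spans=spans,
        ladder_positions=ladder_positions, ladder_residues="".join(ladder_residues),
        competence=competence, segmentation=seg,
        lrrnt=(1, cap_nt_len), lrrct=(pos + 1, pos + cap_ct_len),
        spine_present=spine_present,
    )
    return record, truth


# ---------------------------------------------------------------------------
# Ortholog families (star-tree protein evolution)
# ---------------------------------------------------------------------------

def simulate_ortholog_family(root: ProteinRecord, n: int,
                             site_rates: Sequence[float], branch_length: float,
                             seed: Optional[int] = None
                             ) -> tuple[MultipleAlignment, SyntheticTruth]:
    """Evolve ``n`` descendants of ``root`` on a star tree (gap-free).

    Per column, a descendant substitutes with probability
    1 - exp(-rate * branch_length); replacements are uniform over the other
    19 amino acids.  The root itself is kept as the first alignment row so it
    can serve as the annotated reference downstream.
    """
    if n < 2:
        raise ValueError("need at least 2 descendants")
    rates = np.asarray(site_rates, dtype=float)
    if rates.shape != (len(root.sequence),):
        raise ValueError("site_rates length must match the root sequence")
    if np.any(rates < 0):
        raise ValueError("site rates must be nonnegative")
    rng = np.random.default_rng(seed)
    p_sub = 1.0 - np.exp(-rates * branch_length)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rows = [ProteinRecord(id=root.id, sequence=root.sequence)]
    for k in range(1, n + 1):
        seq = list(root.sequence)
        hits = np.flatnonzero(rng.random(len(seq)) < p_sub)
        for col in hits:
            choices = alphabet.replace(seq[col], "")
            seq[col] = _draw(rng, choices)
        rows.append(ProteinRecord(id=f"{root.id}_{k}", sequence="".join(seq)))
    truth = SyntheticTruth(seed=seed, site_rates=rates,
                           branch_length=branch_length, tree="star")
    return MultipleAlignment(rows), truth


# ---------------------------------------------------------------------------
# Codon evolution (minimal MG94-flavored process)
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_RATE_CACHE: dict[tuple[float, float], tuple] = {}


def _codon_rates(omega: float, kappa: float):
    """Per-codon neighbor lists and jump rates, scaled so the neutral
    expectation is one substitution per nucleotide site per unit time."""
    from .dnds import SENSE_CODONS, STOP_CODONS, translate

    key = (omega, kappa)
    if key in _RATE_CACHE:
        return _RATE_CACHE[key]

    def build(w: float):
        neighbors, rates = {}, {}
        for codon in SENSE_CODONS:
            nbrs, rts = [], []
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    mutant = codon[:pos] + nt + codon[pos + 1 :]
                    if mutant in STOP_CODONS:
                        continue
                    rate = kappa if (codon[pos], nt) in _TRANSITIONS else 1.0
                    if translate(mutant) != translate(codon):
                        rate *= w
                    nbrs.append(mutant)
                    rts.append(rate)
            neighbors[codon] = nbrs
            rates[codon] = np.array(rts)
        return neighbors, rates

    neighbors, rates = build(omega)
    _, neutral_rates = build(1.0)
    mean_neutral = float(np.mean([r.sum() for r in neutral_rates.values()]))
    scale = 3.0 / mean_neutral  # 3 nt sites per codon
    rates = {c: r * scale for c, r in rates.items()}
    totals = {c: float(r.sum()) for c, r in rates.items()}
    _RATE_CACHE[key] = (neighbors, rates, totals)
    return _RATE_CACHE[key]


def _evolve_codons(codons: list[str], t: float, omega: float, kappa: float,
                   rng: np.random.Generator) -> list[str]:
    neighbors, rates, totals = _codon_rates(omega, kappa)
    out = []
    for codon in codons:
        elapsed = 0.0
        while True:
            total = totals[codon]
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                break
            r = rates[codon]
            codon = neighbors[codon][rng.choice(len(r), p=r / r.sum())]
        out.append(codon)
    return out


def _random_ancestor(n_codons: int, rng: np.random.Generator) -> list[str]:
    from .dnds import SENSE_CODONS

    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return [SENSE_CODONS[i] for i in idx]


def simulate_codon_pair(n_codons: int, omega: float, t: float,
                        kappa: float = 1.0, seed: Optional[int] = None
                        ) -> tuple[CodonRecord, CodonRecord, SyntheticTruth]:
    """Two coding sequences diverged by total time ``t`` under a known omega.

    A random sense-codon ancestor evolves along two independent lineages of
    length t/2 under a continuous-time codon process (transitions weighted by
    kappa, nonsynonymous changes by omega, stops excluded); t is in expected
    neutral substitutions per nucleotide site.
    """
    if omega <= 0 or t <= 0:
        raise ValueError("omega and t must be positive")
    rng = np.random.default_rng(seed)
    ancestor = _random_ancestor(n_codons, rng)
    a = _evolve_codons(ancestor, t / 2.0, omega, kappa, rng)
    b = _evolve_codons(ancestor, t / 2.0, omega, kappa, rng)
    truth = SyntheticTruth(seed=seed, omega=omega, divergence=t, kappa=kappa, tree="pair")
    return (CodonRecord(id="lineage_a", sequence="".join(a)),
            CodonRecord(id="lineage_b", sequence="".join(b)), truth)


def simulate_codon_family(n_seqs: int, n_codons: int, omega: float, t: float,
                          kappa: float = 1.0, seed: Optional[int] = None
                          ) -> tuple[list[CodonRecord], SyntheticTruth]:
    """A star-tree codon alignment: ``n_seqs`` lineages of length t/2 from one
    ancestor, so every pair is separated by total time t."""
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    if omega <= 0 or t <= 0:
        raise ValueError("omega and t must be positive")
    rng = np.random.default_rng(seed)
    ancestor = _random_ancestor(n_codons, rng)
    records = []
    for k in range(n_seqs):
        tip = _evolve_codons(ancestor, t / 2.0, omega, kappa, rng)
        records.append(CodonRecord(id=f"seq_{k + 1}", sequence="".join(tip)))
    truth = SyntheticTruth(seed=seed, omega=omega, divergence=t, kappa=kappa, tree="star")
    return records, truth


# ---------------------------------------------------------------------------
# Horseshoe CA traces
# ---------------------------------------------------------------------------

def simulate_horseshoe(n_modules: int = 21, central_distortion: bool = False,
                       noise_sigma: float = 0.0, seed: Optional[int] = None,
                       ca_per_module: int = 3, radius: float = 40.0,
                       sweep_deg: float = 280.0, distortion_height: float = 8.0,
                       radius_factor: float = 0.8) -> tuple[CaTrace, SyntheticTruth]:
    """A horseshoe-like CA trace: points on a circular arc, one group of
    ``ca_per_module`` points per LRR module.

    With ``central_distortion`` the central tercile is pulled out of plane by
    ``distortion_height`` Å and its radius shrunk by ``radius_factor``,
    emulating the smaller radii and central distortion of TD ectodomains.
    Residue letters are copied from a matching simulated ectodomain, so the
    trace carries a sequence usable for alignment seeding.
    """
    if n_modules < 6:
        raise ValueError("need at least 6 modules")
    if ca_per_module < 1:
        raise ValueError("need at least one CA point per module")
    rng = np.random.default_rng(seed)
    architecture = "TD" if central_distortion else "SD"
    record, ecto_truth = simulate_ectodomain(architecture, n_modules, seed=seed)
    seg = ecto_truth.segmentation
    central_lo, central_hi = seg.central
    central_len = central_hi - central_lo + 1

    if ca_per_module > MOTIF_LENGTH:
        raise ValueError(f"at most {MOTIF_LENGTH} CA points per module")
    # motif offsets sampled within each module for the CA points; the ladder
    # anchor (motif position 9) is always among them
    offsets = sorted({int(round(v)) for v in np.linspace(0, 10, ca_per_module)})
    if LADDER_OFFSET not in offsets:
        nearest = min(offsets, key=lambda o: abs(o - LADDER_OFFSET))
        offsets[offsets.index(nearest)] = LADDER_OFFSET
        offsets = sorted(set(offsets))

    sweep = math.radians(sweep_deg)
    residues = []
    idx = 0
    for m in range(n_modules):
        module_index = m + 1
        distorted = central_distortion and central_lo <= module_index <= central_hi
        r = radius * (radius_factor if distorted else 1.0)
        z_base = 0.0
        if distorted:
            phase = (module_index - central_lo + 1) / (central_len + 1)
            z_base = distortion_height * math.sin(math.pi * phase)
        for k, off in enumerate(offsets):
            frac = (m + (k + 1) / (len(offsets) + 1)) / n_modules
            theta = sweep * frac
            x = r * math.cos(theta)
            y = r * math.sin(theta)
            z = z_base
            if noise_sigma > 0:
                x, y, z = (v + rng.normal(0.0, noise_sigma) for v in (x, y, z))
            span_start = ecto_truth.module_spans[m][0]
            letter = record.sequence[span_start - 1 + off]
            idx += 1
            residues.append(CaResidue(index=idx, amino_acid=letter, x=x, y=y, z=z))
    trace = CaTrace(id=f"horseshoe_{architecture}_n{n_modules}_s{seed}", residues=residues)
    truth = SyntheticTruth(seed=seed, architecture=architecture,
                           segmentation=seg, module_spans=ecto_truth.module_spans)
    return trace, truth
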