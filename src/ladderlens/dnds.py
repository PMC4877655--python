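"""Pairwise and per-locus dN/dS by Nei–Gojobori (1986) pathway counting.

Synonymous and nonsynonymous site counts per codon are the fractions of the
three possible single-nucleotide changes at each position that are synonymous,
excluding changes to stop codons from the denominator.  Differences between a
codon pair are attributed by averaging over all minimal mutational pathways
(orderings of the differing positions) that avoid stop codons, each valid
pathway weighted equally.  Proportions are corrected with the Jukes–Cantor
formula, and per-locus means over all sequence pairs get percentile bootstrap
confidence intervals by resampling codon columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io import CodonRecord

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
NUCLEOTIDES = "ACGT"

#: The 61 sense codons of the standard genetic code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
           if a + b + c not in _STANDARD_TABLE.stop_codons)
)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)


def translate(codon: str) -> str:
    return _STANDARD_TABLE.forward_table[codon]


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Per position, the synonymous fraction is the share of the three possible
    single-nucleotide changes that are synonymous, among those not producing a
    stop codon; the three fractions sum to s, and n = 3 - s.
    """
    codon = codon.upper()
    if codon not in _CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = non_stop = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            non_stop += 1
            if translate(mutant) == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return 3.0 - s, s


def pathway_difference_counts(a: str, b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) difference counts between two sense codons,
    averaged over all stop-avoiding minimal mutational pathways.

    If every pathway passes through a stop codon (does not occur between
    sense codons of the standard code, but kept as a guard), all pathways are
    used unweighted.
    """
    a, b = a.upper(), b.upper()
    for c in (a, b):
        if c not in _CODON_INDEX:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        current = a
        nd = sd = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                # blocked pathway; steps touching a stop count as
                # nonsynonymous in the all-blocked fallback
                hit_stop = True
                nd += 1
            elif translate(current) == translate(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if hit_stop else valid).append((nd, sd))
    pool = valid if valid else blocked
    nd = sum(p[0] for p in pool) / len(pool)
    sd = sum(p[1] for p in pool) / len(pool)
    return nd, sd


# ---------------------------------------------------------------------------
# Precomputed tables (built lazily, indexed by SENSE_CODONS order)
# ---------------------------------------------------------------------------

_TABLES: dict[str, np.ndarray] = {}


def _tables() -> dict[str, np.ndarray]:
    if not _TABLES:
        k = len(SENSE_CODONS)
        n_sites = np.empty(k)
        s_sites = np.empty(k)
        for i, c in enumerate(SENSE_CODONS):
            n_sites[i], s_sites[i] = codon_site_counts(c)
        nd = np.zeros((k, k))
        sd = np.zeros((k, k))
        for i, a in enumerate(SENSE_CODONS):
            for j in range(i + 1, k):
                ndij, sdij = pathway_difference_counts(a, SENSE_CODONS[j])
                nd[i, j] = nd[j, i] = ndij
                sd[i, j] = sd[j, i] = sdij
        _TABLES.update(n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd)
    return _TABLES


def encode_codons(record: CodonRecord) -> np.ndarray:
    """Codon indices into SENSE_CODONS; -1 for gap/ambiguous/stop codons."""
    return np.array([_CODON_INDEX.get(c, -1) for c in record.codons()], dtype=int)


# ---------------------------------------------------------------------------
# Pairwise estimate
# ---------------------------------------------------------------------------

@dataclass
class DndsEstimate:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    dn: Optional[float]
    ds: Optional[float]
    omega: Optional[float]
    n_codons: int

    @property
    def saturated(self) -> bool:
        """True when a difference proportion is at or beyond the JC limit."""
        return self.pn >= 0.75 or self.ps >= 0.75


def jukes_cantor(p: float) -> Optional[float]:
    """JC-corrected distance; undefined (None) at or beyond saturation p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def pairwise_dnds(a: CodonRecord, b: CodonRecord) -> DndsEstimate:
    """NG86 dN/dS between two aligned in-frame coding sequences.

    Codon columns where either sequence is gapped, ambiguous or a stop are
    skipped.  Site counts are averaged over the two sequences; omega is
    undefined when dS = 0 or a proportion is saturated.
    """
    if len(a.sequence) != len(b.sequence):
        raise ValueError(f"unequal CDS lengths: {a.id!r} {len(a)} vs {b.id!r} {len(b)}")
    t = _tables()
    ca, cb = encode_codons(a), encode_codons(b)
    valid = (ca >= 0) & (cb >= 0)
    if not valid.any():
        raise ValueError(f"no comparable codons between {a.id!r} and {b.id!r}")
    ia, ib = ca[valid], cb[valid]
    n_sites = float((t["n_sites"][ia] + t["n_sites"][ib]).sum()) / 2.0
    s_sites = float((t["s_sites"][ia] + t["s_sites"][ib]).sum()) / 2.0
    nd = float(t["nd"][ia, ib].sum())
    sd = float(t["sd"][ia, ib].sum())
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    dn = jukes_cantor(pn)
    ds = jukes_cantor(ps)
    omega = None
    if dn is not None and ds is not None and ds > 0:
        omega = dn / ds
    return DndsEstimate(n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
                        pn=pn, ps=ps, dn=dn, ds=ds, omega=omega,
                        n_codons=int(valid.sum()))


# ---------------------------------------------------------------------------
# Per-locus summary with codon-column bootstrap
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    locus: str
    mean_omega: float
    ci_low: float
    ci_high: float
    n_sequences: int
    n_pairs: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.mean_omega <= self.ci_high + 1e-12):
            raise ValueError("bootstrap CI does not bracket the mean")


def _pair_column_arrays(records: Sequence[CodonRecord]):
    """Per-pair, per-codon-column contribution arrays for fast resampling."""
    t = _tables()
    codes = np.stack([encode_codons(r) for r in records])
    n_seq, n_col = codes.shape
    pairs = [(i, j) for i in range(n_seq) for j in range(i + 1, n_seq)]
    nd = np.zeros((len(pairs), n_col))
    sd = np.zeros_like(nd)
    nsite = np.zeros_like(nd)
    ssite = np.zeros_like(nd)
    for p, (i, j) in enumerate(pairs):
        ci, cj = codes[i], codes[j]
        valid = (ci >= 0) & (cj >= 0)
        ia, ja = ci[valid], cj[valid]
        nd[p, valid] = t["nd"][ia, ja]
        sd[p, valid] = t["sd"][ia, ja]
        nsite[p, valid] = (t["n_sites"][ia] + t["n_sites"][ja]) / 2.0
        ssite[p, valid] = (t["s_sites"][ia] + t["s_sites"][ja]) / 2.0
    return pairs, nd, sd, nsite, ssite


def _mean_omega(nd, sd, nsite, ssite, cols=None) -> Optional[float]:
    if cols is not None:
        nd, sd = nd[:, cols], sd[:, cols]
        nsite, ssite = nsite[:, cols], ssite[:, cols]
    N = nsite.sum(axis=1)
    S = ssite.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pn = np.where(N > 0, nd.sum(axis=1) / N, np.nan)
        ps = np.where(S > 0, sd.sum(axis=1) / S, np.nan)
        dn = np.where(pn < 0.75, -0.75 * np.log1p(-4.0 * pn / 3.0), np.nan)
        ds = np.where(ps < 0.75, -0.75 * np.log1p(-4.0 * ps / 3.0), np.nan)
        omega = np.where(ds > 0, dn / ds, np.nan)
    defined = omega[np.isfinite(omega)]
    if defined.size == 0:
        return None
    return float(defined.mean())


def locus_mean_dnds(records: Sequence[CodonRecord], n_boot: int = 1000,
                    seed: Optional[int] = None, locus: str = "locus") -> LocusSummary:
    """Mean pairwise omega at a locus, with a codon-column bootstrap 95% CI.

    All sequence pairs with a defined omega contribute to the mean; the CI
    resamples codon columns of the alignment (jointly across pairs) and takes
    the 2.5/97.5 percentiles of the recomputed means.  Loci with fewer than
    five sequences are summarized with a warning.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    if len(records) < 5:
        warnings.warn(f"{locus}: fewer than 5 sequences; estimates will be noisy")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("records are not aligned (unequal lengths)")
    pairs, nd, sd, nsite, ssite = _pair_column_arrays(records)
    mean = _mean_omega(nd, sd, nsite, ssite)
    if mean is None:
        raise ValueError(f"{locus}: no sequence pair has a defined omega")
    rng = np.random.default_rng(seed)
    n_col = nd.shape[1]
    boots = []
    for _ in range(n_boot):
        cols = rng.integers(0, n_col, size=n_col)
        m = _mean_omega(nd, sd, nsite, ssite, cols)
        if m is not None:
            boots.append(m)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, mean), max(hi, mean)
    else:
        lo = hi = mean
    return LocusSummary(locus=locus, mean_omega=mean, ci_low=float(lo),
                        ci_high=float(hi), n_sequences=len(records),
                        n_pairs=len(pairs))
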