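"""Shared domain types and readers/writers for the standard formats the pipeline touches.

Sequences are held in lightweight validated records; trees are dendropy
``Tree`` objects; CA traces are plain coordinate lists extracted from PDB
files.  All coordinates and sequence indices exposed by this package are
1-based with closed intervals, matching PDB/biology convention.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import dendropy
import gemmi
import numpy as np
from Bio import SeqIO

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
GAP = "-"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised when an input file or record violates a format contract."""


@dataclass
class ProteinRecord:
    """An amino-acid sequence with optional species / TLR-type metadata.

    'X' is allowed and scores as a mismatch everywhere downstream; '-' is
    permitted so alignment rows can be carried in the same record type.
    """

    id: str
    sequence: str
    species: Optional[str] = None
    tlr_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: sequence must be non-empty")
        self.sequence = self.sequence.upper()
        allowed = PROTEIN_ALPHABET | {GAP}
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: illegal protein character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass
class CodonRecord:
    """An in-frame coding sequence.

    Length must be divisible by 3 and no in-frame sense codon may be a stop;
    codons containing 'N' or gaps are tolerated and skipped downstream.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: sequence must be non-empty")
        allowed = NUCLEOTIDE_ALPHABET | {GAP}
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"record {self.id!r}: illegal nucleotide {ch!r} at position {pos}"
                )
        if len(self.sequence) % 3 != 0:
            raise FormatError(
                f"record {self.id!r}: length {len(self.sequence)} not divisible by 3"
            )
        n_codons = len(self.sequence) // 3
        for i in range(n_codons):
            codon = self.sequence[3 * i : 3 * i + 3]
            if GAP in codon or "N" in codon:
                continue
            if codon in STOP_CODONS and i < n_codons - 1:
                raise FormatError(
                    f"record {self.id!r}: internal stop codon {codon} at codon {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


@dataclass
class MultipleAlignment:
    """A gapped protein alignment: equal-length rows, at least two of them."""

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 rows")
        ncol = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != ncol:
                raise FormatError(
                    f"alignment row {rec.id!r} has length {len(rec.sequence)}, expected {ncol}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate id {dup!r} in alignment")

    @property
    def n_cols(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` (gaps included), top to bottom."""
        return "".join(rec.sequence[col - 1] for rec in self.records)

    def row(self, record_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(f"record {record_id!r} not in alignment")


@dataclass(frozen=True)
class CaResidue:
    index: int
    amino_acid: str
    x: float
    y: float
    z: float


@dataclass
class CaTrace:
    """An ordered CA-only trace of one chain."""

    id: str
    residues: list[CaResidue]

    def __post_init__(self) -> None:
        prev = None
        for res in self.residues:
            if prev is not None and res.index <= prev:
                raise FormatError(
                    f"trace {self.id!r}: residue indices not strictly increasing at {res.index}"
                )
            if not all(math.isfinite(v) for v in (res.x, res.y, res.z)):
                raise FormatError(f"trace {self.id!r}: non-finite coordinate at residue {res.index}")
            prev = res.index

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of CA coordinates in Å."""
        return np.array([[r.x, r.y, r.z] for r in self.residues], dtype=float)

    @property
    def letters(self) -> str:
        return "".join(r.amino_acid for r in self.residues)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise FormatError("distance matrix not symmetric within 1e-9")
        if np.any(np.diag(self.values) != 0.0):
            raise FormatError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise FormatError("distance matrix entries must be nonnegative")
        # store an exactly symmetric copy
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: Literal["protein", "nucleotide"]):
    """Read a FASTA file into ``ProteinRecord`` or ``CodonRecord`` objects.

    Sequences are upper-cased; a single trailing '*' (translated stop) is
    stripped from nucleotide CDS reads.  Duplicate ids and illegal characters
    are errors naming the offending record.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FormatError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    out = []
    for entry in entries:
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if alphabet == "protein":
            out.append(ProteinRecord(id=entry.id, sequence=seq))
        else:
            out.append(CodonRecord(id=entry.id, sequence=seq))
    return out


def write_fasta(records: Iterable[ProteinRecord | CodonRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | os.PathLike) -> MultipleAlignment:
    return MultipleAlignment(read_fasta(path, "protein"))


# ---------------------------------------------------------------------------
# PDB CA traces
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_ca_trace(path: str | os.PathLike, chain: str) -> CaTrace:
    """Extract the CA trace of one chain from a PDB file.

    Only ATOM records are used; for residues with alternate locations the
    first altLoc encountered is kept.  Residues are returned ordered by
    residue number.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise FormatError(f"{path}: no models")
    model = structure[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None:
        raise FormatError(f"{path}: chain {chain!r} not found")
    residues = []
    for res in target:
        if res.het_flag != "A":  # ATOM records only
            continue
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom
                break  # first altLoc kept
        if ca is None:
            continue
        aa = _THREE_TO_ONE.get(res.name, "X")
        residues.append(
            CaResidue(index=res.seqid.num, amino_acid=aa,
                      x=ca.pos.x, y=ca.pos.y, z=ca.pos.z)
        )
    if not residues:
        raise FormatError(f"{path}: chain {chain!r} has no CA atoms")
    residues.sort(key=lambda r: r.index)
    trace_id = f"{os.path.splitext(os.path.basename(str(path)))[0]}_{chain}"
    return CaTrace(id=trace_id, residues=residues)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick with branch lengths; round-trips through read."""
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True).strip()
    if not s.endswith(";"):
        s += ";"
    return s


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# TSV report helpers (shared by downstream modules)
# ---------------------------------------------------------------------------

def write_tsv(path: str | os.PathLike, header: Sequence[str],
              rows: Iterable[Sequence]) -> None:
    """UTF-8, tab-delimited, header row; floats rendered with repr-stable %g."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(v) for v in row) + "\n")


def _cell(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
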