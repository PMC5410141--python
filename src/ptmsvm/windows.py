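"""Peptide windows around candidate modification sites.

A candidate post-translational-modification (PTM) site is a serine,
threonine or tyrosine residue in a protein.  The local context of a site
is represented by a fixed-width peptide window: ``flank`` residues
upstream, the central S/T/Y, and ``flank`` residues downstream (21
residues total at the default ``flank=10``).  Windows that run past a
protein terminus are padded with ``X``, which BLOSUM62 scores as the
least-informative residue.

This module reads protein sequences (FASTA) and per-site annotation
tables, extracts windows, and exposes the canonical NCBI BLOSUM62
substitution scores used by the sequence kernel.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Pad symbol for window positions outside the protein.
PAD = "X"

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residues a candidate site may occupy.
SITE_RESIDUES = frozenset("STY")

#: Ambiguity/rare codes tolerated on input and remapped before scoring.
_REMAP = str.maketrans({"U": "X", "O": "X"})

SITE_TABLE_COLUMNS = ("protein_id", "position", "residue", "annotations", "task_label")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One candidate site: position, residue, known PTM labels, task label.

    ``annotations`` is the set of PTM/kinase-group names the site is
    experimentally known to carry (possibly empty).  ``task_label`` is
    +1/-1 for the binary prediction task at hand, or ``None`` for an
    unlabeled candidate.
    """

    protein_id: str
    position: int  # 1-based
    residue: str
    annotations: frozenset[str] = field(default_factory=frozenset)
    task_label: int | None = None

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}:{self.position}"


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-width local sequence centred on a candidate site."""

    site_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) % 2 == 0:
            raise ValueError("window length must be odd")
        if self.central not in SITE_RESIDUES:
            raise ValueError(
                f"window {self.site_id!r}: central residue {self.central!r} "
                f"is not one of S/T/Y"
            )

    @property
    def central(self) -> str:
        return self.residues[len(self.residues) // 2]

    def __len__(self) -> int:
        return len(self.residues)


class SubstitutionMatrix:
    """Symmetric integer substitution scores over a fixed symbol alphabet.

    Wraps a score table so windows can be vector-encoded once and scored
    through ``score_table`` by the kernel code.
    """

    def __init__(self, alphabet: str, scores: np.ndarray):
        scores = np.asarray(scores)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise ValueError("score table shape does not match alphabet")
        if not np.array_equal(scores, scores.T):
            raise ValueError("substitution scores must be symmetric")
        self.alphabet = alphabet
        self.score_table = scores.astype(np.int64)
        self._index = {s: i for i, s in enumerate(alphabet)}

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def score(self, a: str, b: str) -> int:
        for s in (a, b):
            if s not in self._index:
                raise KeyError(f"symbol {s!r} not supported by the substitution matrix")
        return int(self.score_table[self._index[a], self._index[b]])

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to integer indices into ``score_table``."""
        try:
            return np.array([self._index[s] for s in residues], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"symbol {exc.args[0]!r} not supported by the substitution matrix") from None


@functools.cache
def blosum62() -> SubstitutionMatrix:
    """The canonical NCBI BLOSUM62 matrix (20 residues + B, Z and the X pad)."""
    m = substitution_matrices.load("BLOSUM62")
    alphabet = "".join(s for s in m.alphabet if s != "*")
    idx = [m.alphabet.index(s) for s in alphabet]
    table = np.asarray(m)[np.ix_(idx, idx)]
    return SubstitutionMatrix(alphabet, table)


def blosum62_score(a: str, b: str) -> int:
    """BLOSUM62 score for an (unordered) pair of residue symbols."""
    return blosum62().score(a, b)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Duplicate ids and headerless content are errors.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected a FASTA header ('>'), "
                    f"got {line.strip()[:30]!r}"
                )
            break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper()))
    return records


def read_site_table(
    path: str | Path, proteins: Iterable[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read and validate a per-site annotation TSV.

    Expected columns: ``protein_id  position  residue  annotations
    task_label``; annotations are semicolon-separated names (may be
    empty), task_label is +1/-1 or empty for unlabeled candidates.
    Every row is validated against its protein sequence; all offending
    rows are reported together.
    """
    path = Path(path)
    by_id = {p.id: p for p in proteins}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    sites: list[SiteAnnotation] = []
    problems: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = row.protein_id
        prot = by_id.get(pid)
        if prot is None:
            problems.append(f"row {row_no}: unknown protein_id {pid!r}")
            continue
        try:
            pos = int(row.position)
        except ValueError:
            problems.append(f"row {row_no}: non-integer position {row.position!r}")
            continue
        if not 1 <= pos <= len(prot):
            problems.append(
                f"row {row_no}: position {pos} out of range for {pid!r} "
                f"(length {len(prot)})"
            )
            continue
        residue = row.residue.strip().upper()
        if prot.sequence[pos - 1] != residue:
            problems.append(
                f"row {row_no}: residue {residue!r} does not match sequence "
                f"character {prot.sequence[pos - 1]!r} at {pid}:{pos}"
            )
            continue
        annotations = frozenset(
            a.strip() for a in row.annotations.split(";") if a.strip()
        )
        label_text = row.task_label.strip()
        if label_text in ("", "NA"):
            label: int | None = None
        elif label_text in ("+1", "1"):
            label = 1
        elif label_text == "-1":
            label = -1
        else:
            problems.append(f"row {row_no}: bad task_label {label_text!r}")
            continue
        sites.append(SiteAnnotation(pid, pos, residue, annotations, label))
    if problems:
        raise ValueError(f"{path}: invalid site rows:\n  " + "\n  ".join(problems))
    return sites


def extract_window(
    protein: ProteinRecord, position: int, flank: int = 10
) -> PeptideWindow:
    """Extract the ``2*flank+1``-residue window centred at a 1-based position.

    Positions outside the protein are padded with :data:`PAD`; U/O are
    remapped to X so every character is scoreable under BLOSUM62.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} out of range for protein {protein.id!r} "
            f"(length {len(protein)})"
        )
    central = protein.sequence[position - 1]
    if central not in SITE_RESIDUES:
        raise ValueError(
            f"{protein.id}:{position}: central residue {central!r} is not S/T/Y"
        )
    start = position - 1 - flank
    end = position + flank
    left_pad = max(0, -start)
    right_pad = max(0, end - len(protein))
    core = protein.sequence[max(0, start) : min(len(protein), end)]
    residues = (PAD * left_pad + core + PAD * right_pad).translate(_REMAP)
    return PeptideWindow(f"{protein.id}:{position}", residues)


def extract_windows(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    flank: int = 10,
) -> list[PeptideWindow]:
    """Extract windows for a list of sites, in site order."""
    by_id = {p.id: p for p in proteins}
    out = []
    for site in sites:
        prot = by_id.get(site.protein_id)
        if prot is None:
            raise ValueError(f"unknown protein_id {site.protein_id!r}")
        out.append(extract_window(prot, site.position, flank))
    return out
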