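"""Readers and writers for every on-disk representation the pipeline touches.

Dialects are deliberately rigid so round-trips are bit-stable:

* sequences — standard FASTA (via Biopython);
* alignment sets — one aligned sequence per line, plain text, every row
  exactly the target length;
* contact maps — whitespace-delimited square real matrix, row per line,
  C-locale decimal point (``.npy`` accepted as an equivalent binary
  container, auto-detected by extension);
* label manifests — two-column TSV ``id<TAB>label`` with labels in {0,1};
* metric reports — flat JSON.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical, plus 'X'
#: for unknown/ambiguous residues (the 21st one-hot slot).
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = STANDARD_RESIDUES + "X"
_ALPHABET_SET = frozenset(ALPHABET)

#: Read tolerance for contact-map entries nominally in [0, 1].
_CLIP_TOL = 1e-6


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


def sanitize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map any non-standard letter to 'X'.

    Ambiguity and rare codes (B, Z, U, O, J, '*', ...) all collapse onto
    the 21st alphabet symbol; a warning is logged when this happens.
    """
    seq = seq.upper()
    if all(c in _ALPHABET_SET for c in seq):
        return seq
    mapped = "".join(c if c in _ALPHABET_SET else "X" for c in seq)
    bad = sorted({c for c in seq if c not in _ALPHABET_SET})
    logger.warning("mapped non-standard residue symbols %s to 'X'", bad)
    return mapped


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an optional binary DNA-binding label.

    ``label`` is 1 for DNA-binding ("positive") and 0 for non-DNA-binding
    ("negative"); ``None`` marks an unlabeled record (inference mode).
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = {c for c in self.sequence if c not in _ALPHABET_SET}
        if bad:
            raise ValueError(
                f"record {self.id!r}: symbols outside the 21-letter alphabet: {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentSet:
    """Aligned homologous sequences for one target protein.

    Every row has exactly the target's length L; N is the row count.
    Rows feed the position frequency matrix, so they are sanitized to the
    21-letter alphabet on construction.
    """

    target_id: str
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValueError(f"alignment set for {self.target_id!r}: no rows")
        L = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise ValueError(
                    f"alignment set for {self.target_id!r}: row {i} has length "
                    f"{len(row)}, expected {L}"
                )

    @property
    def N(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class ContactMap:
    """Square symmetric matrix of residue-residue contact probabilities.

    Entry (i, j) is the probability that residues i and j are in spatial
    contact; values lie in [0, 1], the diagonal is forced to 0 (the graph
    convolution adds the self-loop analytically, so a probability-1
    diagonal must not double-count).
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"contact map must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("contact map must be symmetric")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("contact-map entries must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.values.shape[0]


def read_fasta(path) -> List[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; characters outside the 21-symbol alphabet
    are mapped to 'X' with a logged warning.  An empty file or a
    duplicated id is an error.
    """
    records: List[ProteinRecord] = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=sanitize_sequence(str(entry.seq))))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records: Sequence[ProteinRecord]) -> None:
    """Write records as FASTA (inverse of :func:`read_fasta` on valid input)."""
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(entries, str(path), "fasta")


def read_contact_map(path, expected_length: int) -> ContactMap:
    """Load a contact-probability map and normalize it to the internal contract.

    Accepts a whitespace-delimited text matrix or a ``.npy`` array
    (auto-detected by extension).  The matrix must be square with side
    ``expected_length``; entries within ``1e-6`` outside [0, 1] are
    clipped, anything further out is an error.  The matrix is
    symmetrized as ``S = (V + V.T) / 2`` and the diagonal zeroed.
    """
    path = Path(path)
    if path.suffix == ".npy":
        v = np.load(path)
    else:
        v = np.loadtxt(path, dtype=float, ndmin=2)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise FormatError(f"{path}: contact map is not square (shape {v.shape})")
    if v.shape[0] != expected_length:
        raise FormatError(
            f"{path}: contact map has dimension {v.shape[0]}, expected {expected_length}"
        )
    if v.min() < -_CLIP_TOL or v.max() > 1 + _CLIP_TOL:
        raise FormatError(
            f"{path}: entries outside [{-_CLIP_TOL}, {1 + _CLIP_TOL}] "
            f"(min {v.min()}, max {v.max()})"
        )
    v = np.clip(v, 0.0, 1.0)
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return ContactMap(values=v)


def write_contact_map(path, cmap: ContactMap) -> None:
    """Write a contact map in the text dialect (or ``.npy`` by extension).

    Text uses ``%.17g`` so re-reading reproduces values to 1e-9 exactly.
    """
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, cmap.values)
    else:
        np.savetxt(path, cmap.values, fmt="%.17g")


def read_alignment_set(path, target: ProteinRecord) -> AlignmentSet:
    """Read an alignment set: one aligned sequence per line.

    Each line must have exactly the target's length.  An empty file falls
    back to a single row holding the target sequence itself, so the PPM
    is always computable.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        return AlignmentSet(target_id=target.id, rows=(target.sequence,))
    L = len(target)
    rows = []
    for k, line in enumerate(lines, start=1):
        if len(line) != L:
            raise FormatError(
                f"{path}: line {k} has length {len(line)}, expected target length {L}"
            )
        rows.append(sanitize_sequence(line))
    return AlignmentSet(target_id=target.id, rows=tuple(rows))


def write_alignment_set(path, alignment: AlignmentSet) -> None:
    Path(path).write_text("\n".join(alignment.rows) + "\n")


def read_label_manifest(path) -> Dict[str, int]:
    """Read a two-column TSV ``id<TAB>label`` into an id → {0,1} mapping."""
    mapping: Dict[str, int] = {}
    for k, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {k}: expected 2 tab-separated fields")
        pid, raw = parts[0].strip(), parts[1].strip()
        try:
            label = int(raw)
        except ValueError:
            raise FormatError(f"{path}: line {k}: non-integer label {raw!r}") from None
        if label not in (0, 1):
            raise FormatError(f"{path}: line {k}: label must be 0 or 1, got {label}")
        if pid in mapping:
            raise FormatError(f"{path}: duplicate id {pid!r}")
        mapping[pid] = label
    if not mapping:
        raise FormatError(f"{path}: empty label manifest")
    return mapping


def write_label_manifest(path, mapping: Dict[str, int]) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in mapping.items()))
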