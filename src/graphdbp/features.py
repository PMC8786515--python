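"""Per-residue node featurization: the M×54 feature matrix.

Each residue (node) gets 54 features in three fixed column blocks:

* ``[0, 21)``  — one-hot encoding of the residue symbol over the
  21-letter alphabet (20 standard residues + 'X');
* ``[21, 42)`` — the residue's column of the position probability matrix
  (PPM), a pseudocount-smoothed per-column residue distribution computed
  from the target's alignment set; this block plays the role of the
  evolutionary "PSSM" features and can be zeroed for ablation;
* ``[42, 54)`` — 12 physicochemical properties: five mutually exclusive
  category flags (aliphatic, aromatic, polar-neutral, acidic-charged,
  basic-charged) and seven scalars (molecular weight, pK of the –COOH
  and –NH3 groups, pK of the side group, isoelectric-point pH, and
  hydrophobicity indices at pH 2 and pH 7), each scalar min-max
  normalized to [0, 1] over the 20 standard residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import numpy as np

from .io_formats import ALPHABET, AlignmentSet, ProteinRecord

ALPHABET_INDEX: Dict[str, int] = {c: i for i, c in enumerate(ALPHABET)}

N_ONE_HOT = 21
N_PPM = 21
N_PROPS = 12
N_FEATURES = N_ONE_HOT + N_PPM + N_PROPS  # 54

#: Default pseudocount added (as p/4) to every frequency count.
DEFAULT_PSEUDOCOUNT = 0.8

CATEGORY_ORDER = ("aliphatic", "aromatic", "polar_neutral", "acidic", "basic")
SCALAR_COLUMNS = ("weight", "pk_cooh", "pk_nh3", "pk_side", "pi", "hydro_ph2", "hydro_ph7")


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 21×L occurrence counts over alignment columns.

    Every column sums to N, the alignment-set depth (each row contributes
    exactly one symbol per column).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValueError(f"PFM must be a 2-D count matrix, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")


@dataclass(frozen=True)
class PPM:
    """Position probability matrix: pseudocount-smoothed column distributions.

    Entry (k, j) equals ``(count[k, j] + p/4) / (N + p)`` — strictly
    positive for any p > 0, so downstream features never hit exact zeros.
    """

    probs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def L(self) -> int:
        return self.probs.shape[1]


class ResiduePropertyTable:
    """Physicochemical lookup: category flags and normalized scalars per residue.

    Scalars are min-max normalized to [0, 1] across the 20 standard
    residues; the 'X' row carries no category flag and column-mean
    scalars, so unknown residues sit at the centroid of the property
    space.
    """

    def __init__(self, vectors: Dict[str, np.ndarray]):
        self.vectors = vectors

    @classmethod
    def from_tsv(cls, path=None) -> "ResiduePropertyTable":
        """Load the bundled (or a user-supplied) property TSV."""
        if path is None:
            ref = resources.files("graphdbp").joinpath("data/residue_properties.tsv")
            text = ref.read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        rows: Dict[str, Dict[str, str]] = {}
        header = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            rec = dict(zip(header, parts))
            rows[rec["residue"]] = rec
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(rows)
        if missing:
            raise ValueError(f"property table missing residues {sorted(missing)}")

        residues = sorted(rows)
        scalars = np.array(
            [[float(rows[r][c]) for c in SCALAR_COLUMNS] for r in residues], dtype=float
        )
        lo, hi = scalars.min(axis=0), scalars.max(axis=0)
        normed = (scalars - lo) / np.where(hi > lo, hi - lo, 1.0)

        vectors: Dict[str, np.ndarray] = {}
        for i, r in enumerate(residues):
            flags = np.zeros(len(CATEGORY_ORDER))
            cat = rows[r]["category"]
            if cat not in CATEGORY_ORDER:
                raise ValueError(f"unknown category {cat!r} for residue {r}")
            flags[CATEGORY_ORDER.index(cat)] = 1.0
            vectors[r] = np.concatenate([flags, normed[i]])
        # 'X': flagless, scalar columns at the standard-residue mean.
        vectors["X"] = np.concatenate(
            [np.zeros(len(CATEGORY_ORDER)), normed.mean(axis=0)]
        )
        return cls(vectors)

    def __getitem__(self, residue: str) -> np.ndarray:
        return self.vectors[residue]


_default_table: Optional[ResiduePropertyTable] = None


def default_property_table() -> ResiduePropertyTable:
    global _default_table
    if _default_table is None:
        _default_table = ResiduePropertyTable.from_tsv()
    return _default_table


def compute_pfm(alignment: AlignmentSet) -> PFM:
    """Count residue occurrences per alignment column.

    ``counts[k, j]`` is the number of alignment rows whose j-th character
    equals alphabet symbol k.  Symbols outside the alphabet are mapped to
    'X' (consistent with I/O sanitization), never an error.
    """
    L = alignment.L
    counts = np.zeros((len(ALPHABET), L), dtype=np.int64)
    x_idx = ALPHABET_INDEX["X"]
    for row in alignment.rows:
        for j, c in enumerate(row):
            counts[ALPHABET_INDEX.get(c, x_idx), j] += 1
    return PFM(counts=counts)


def compute_ppm(pfm: PFM, N: int, p: float = DEFAULT_PSEUDOCOUNT,
                per_symbol_pseudocount: bool = False) -> PPM:
    """Smooth a PFM into a position probability matrix.

    The smoothing is ``(count + p/4) / (N + p)`` with p = 0.8 by default.
    The /4 split of the pseudocount is kept verbatim even though the
    residue alphabet has 21 symbols; setting ``per_symbol_pseudocount``
    distributes p over the alphabet size instead (p/21), which makes
    columns sum to exactly 1.
    """
    if N < 1:
        raise ValueError("alignment depth N must be >= 1")
    if p <= 0:
        raise ValueError("pseudocount p must be positive")
    split = len(ALPHABET) if per_symbol_pseudocount else 4
    probs = (pfm.counts.astype(float) + p / split) / (N + p)
    return PPM(probs=probs, pseudocount=p)


def one_hot(residue: str) -> np.ndarray:
    """Unit basis vector at the residue's fixed alphabet index."""
    try:
        idx = ALPHABET_INDEX[residue]
    except KeyError:
        raise ValueError(f"symbol {residue!r} outside the 21-letter alphabet") from None
    v = np.zeros(N_ONE_HOT)
    v[idx] = 1.0
    return v


def property_vector(residue: str, table: Optional[ResiduePropertyTable] = None) -> np.ndarray:
    """12-vector of category flags + normalized physicochemical scalars."""
    if table is None:
        table = default_property_table()
    if residue not in ALPHABET_INDEX:
        raise ValueError(f"symbol {residue!r} outside the 21-letter alphabet")
    return table[residue].copy()


def build_node_features(record: ProteinRecord, ppm: PPM,
                        table: Optional[ResiduePropertyTable] = None,
                        use_pssm: bool = True) -> np.ndarray:
    """Assemble the M×54 node-feature matrix for one protein.

    Row m concatenates the one-hot encoding of residue m, column m of
    the PPM, and residue m's property vector.  With ``use_pssm=False``
    the PPM block is zeroed but the width stays 54, so architectures are
    comparable across the ablation.
    """
    M = len(record)
    if ppm.L != M:
        raise ValueError(f"PPM has {ppm.L} columns but sequence has length {M}")
    if table is None:
        table = default_property_table()
    X = np.zeros((M, N_FEATURES))
    for m, c in enumerate(record.sequence):
        X[m, :N_ONE_HOT] = one_hot(c)
        if use_pssm:
            X[m, N_ONE_HOT:N_ONE_HOT + N_PPM] = ppm.probs[:, m]
        X[m, N_ONE_HOT + N_PPM:] = table[c]
    return X


def featurize(record: ProteinRecord, alignment: AlignmentSet,
              table: Optional[ResiduePropertyTable] = None,
              p: float = DEFAULT_PSEUDOCOUNT, use_pssm: bool = True) -> np.ndarray:
    """Convenience: alignment → PFM → PPM → node-feature matrix."""
    pfm = compute_pfm(alignment)
    ppm = compute_ppm(pfm, N=alignment.N, p=p)
    return build_node_features(record, ppm, table=table, use_pssm=use_pssm)
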