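"""Synthetic sequences, alignments, contact maps and labeled datasets.

The generator emulates the three upstream inputs the classifier needs —
protein sequences, per-protein alignment sets, and symmetric residue
contact-probability maps — with a controllable, plantable class signal,
so the whole pipeline (featurization through training) can be exercised
end to end without external databases or structure predictors.

Class signal is planted at the *input* level, never by relabeling
outputs:

* channel ``"ppm"`` — alignment substitutions in the positive class are
  drawn from a mixture biased toward a fixed motif composition
  (lysine/arginine-rich, echoing the charged patches of DNA-binding
  interfaces), so the signal lives only in the PPM feature block; the
  target sequences themselves are identically distributed across
  classes, keeping the one-hot block signal-free.
* channel ``"contacts"`` — the positive class receives a higher
  long-range contact density, so the signal lives in graph topology.

``effect_size`` 0 collapses both channels onto the no-signal null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import featurize
from .graph_build import ProteinGraph, assemble_graph, binarize_contact_map
from .io_formats import (
    STANDARD_RESIDUES,
    AlignmentSet,
    ContactMap,
    ProteinRecord,
    write_alignment_set,
    write_contact_map,
    write_fasta,
    write_label_manifest,
)

#: Substitution target composition for the "ppm" signal channel.
MOTIF_COMPOSITION: Dict[str, float] = {"K": 0.5, "R": 0.5}

_RESIDUES = np.array(list(STANDARD_RESIDUES))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic two-class dataset.

    Defaults give a minutes-scale dataset: 60 proteins of 30–60
    residues, alignment depth 5, a short-range contact band of width 2
    plus 5% long-range contact density.
    """

    n_positive: int = 30
    n_negative: int = 30
    length_range: Tuple[int, int] = (30, 60)
    alignment_depth: int = 5
    mutation_rate: float = 0.4
    band_width: int = 2
    longrange_density: float = 0.05
    signal_channel: str = "ppm"
    effect_size: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one graph per class")
        for name in ("mutation_rate", "longrange_density"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_channel not in ("ppm", "contacts"):
            raise ValueError(f"unknown signal channel {self.signal_channel!r}")
        if not (0 <= self.effect_size <= 1):
            raise ValueError("effect_size must lie in [0, 1]")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_sequence(length: int, seed, id: str = "sim",
                      composition: Optional[Sequence[float]] = None) -> ProteinRecord:
    """I.i.d. residues over the 20 standard letters (uniform by default)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    seq = "".join(rng.choice(_RESIDUES, size=length, p=composition))
    return ProteinRecord(id=id, sequence=seq)


def simulate_alignment(target: ProteinRecord, N: int, mutation_rate: float, seed,
                       substitution_bias: float = 0.0) -> AlignmentSet:
    """Mutate the target into an alignment set of depth N.

    Row 0 is the unmutated target; each other row substitutes every
    position independently with probability ``mutation_rate``.  A
    substitution draws uniformly from the 19 other residues, except that
    with probability ``substitution_bias`` it draws from the motif
    composition instead (the planted "ppm" signal).
    """
    if N < 1:
        raise ValueError("alignment depth N must be >= 1")
    rng = _rng(seed)
    motif_res = np.array(list(MOTIF_COMPOSITION))
    motif_p = np.array(list(MOTIF_COMPOSITION.values()))
    rows = [target.sequence]
    for _ in range(N - 1):
        chars = list(target.sequence)
        for j, c in enumerate(chars):
            if rng.random() >= mutation_rate:
                continue
            if substitution_bias > 0 and rng.random() < substitution_bias:
                chars[j] = str(rng.choice(motif_res, p=motif_p))
            else:
                others = [r for r in STANDARD_RESIDUES if r != c]
                chars[j] = others[rng.integers(len(others))]
        rows.append("".join(chars))
    return AlignmentSet(target_id=target.id, rows=tuple(rows))


def simulate_contact_map(length: int, band_width: int, longrange_density: float,
                         seed) -> ContactMap:
    """Banded short-range contacts plus sparse random long-range contacts.

    Pairs within ``band_width`` of the diagonal get probabilities in
    [0.55, 1) (always above the 0.5 binarization threshold); each distant
    pair independently gets a probability in [0.5, 1) with probability
    ``longrange_density`` and in [0, 0.5) otherwise, so the expected
    distant-pair edge fraction equals the density exactly.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    v = np.zeros((length, length))
    for i in range(length):
        for j in range(i + 1, length):
            if j - i <= band_width:
                p = rng.uniform(0.55, 1.0)
            elif rng.random() < longrange_density:
                p = rng.uniform(0.5, 1.0)
            else:
                p = rng.uniform(0.0, 0.5)
            v[i, j] = v[j, i] = p
    return ContactMap(values=v)


@dataclass(frozen=True)
class SimulatedProtein:
    """One generated protein with all of its upstream artifacts."""

    record: ProteinRecord
    alignment: AlignmentSet
    contact_map: ContactMap


def _simulate_protein(pid: str, label: int, spec: SimulationSpec,
                      rng: np.random.Generator) -> SimulatedProtein:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    record = ProteinRecord(
        id=pid, sequence=simulate_sequence(length, rng).sequence, label=label
    )
    bias = spec.effect_size if (label == 1 and spec.signal_channel == "ppm") else 0.0
    alignment = simulate_alignment(record, spec.alignment_depth, spec.mutation_rate,
                                   rng, substitution_bias=bias)
    density = spec.longrange_density
    if label == 1 and spec.signal_channel == "contacts":
        density = min(1.0, density + spec.effect_size)
    cmap = simulate_contact_map(length, spec.band_width, density, rng)
    return SimulatedProtein(record=record, alignment=alignment, contact_map=cmap)


def simulate_proteins(spec: SimulationSpec) -> List[SimulatedProtein]:
    """Generate all raw per-protein artifacts for a dataset spec.

    Each protein draws from its own child generator spawned off the spec
    seed, so the dataset is byte-reproducible and individual proteins do
    not depend on generation order.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_positive + spec.n_negative)
    proteins = []
    labels = [1] * spec.n_positive + [0] * spec.n_negative
    width = len(str(len(labels)))
    for i, (label, child) in enumerate(zip(labels, children)):
        pid = f"sim{i:0{width}d}"
        proteins.append(_simulate_protein(pid, label, spec, np.random.default_rng(child)))
    return proteins


def simulate_dataset(spec: SimulationSpec) -> Tuple[List[ProteinGraph], Dict]:
    """Generate a labeled graph dataset through the *real* pipeline.

    Sequences, alignments and contact maps are produced per the spec,
    then featurized (PFM → PPM → 54-column node features) and binarized
    into graphs exactly as external inputs would be.  Returns the graphs
    plus a provenance manifest recording every parameter.
    """
    proteins = simulate_proteins(spec)
    graphs = []
    for prot in proteins:
        features = featurize(prot.record, prot.alignment)
        adjacency = binarize_contact_map(prot.contact_map)
        graphs.append(assemble_graph(prot.record, features, adjacency))
    manifest = {"generator": "graphdbp.synthetic_data", "spec": asdict(spec)}
    return graphs, manifest


def write_dataset_dir(spec: SimulationSpec, outdir) -> None:
    """Emit a dataset directory in the standard on-disk dialects.

    Layout: ``sequences.fasta``, ``<id>.aln.txt``, ``<id>.cmap.txt``,
    ``labels.tsv``, ``manifest.json``.  Identical spec + seed gives a
    byte-identical directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = simulate_proteins(spec)
    write_fasta(outdir / "sequences.fasta", [p.record for p in proteins])
    labels = {}
    for p in proteins:
        write_alignment_set(outdir / f"{p.record.id}.aln.txt", p.alignment)
        write_contact_map(outdir / f"{p.record.id}.cmap.txt", p.contact_map)
        labels[p.record.id] = p.record.label
    write_label_manifest(outdir / "labels.tsv", labels)
    manifest = {"generator": "graphdbp.synthetic_data", "spec": asdict(spec)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
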