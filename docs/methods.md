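# Methods

## The model

`graphdbp` classifies a protein as DNA-binding or not from two inputs that
are both functions of its sequence: a set of aligned homologous sequences
(for evolutionary features) and a residue–residue contact-probability map
(for structure). The protein becomes an undirected graph whose nodes are
residues, whose edges are thresholded contacts, and whose node attributes
are 54 per-residue features; a graph convolutional network (GCN) then
produces a graph-level probability of the positive class.

### Node features (width 54)

| block | columns | content |
|---|---|---|
| one-hot | 0–20 | residue identity over A C D E F G H I K L M N P Q R S T V W Y X |
| PPM | 21–41 | the residue's column of the position probability matrix |
| properties | 42–53 | 5 category flags + 7 normalized physicochemical scalars |

The position frequency matrix (PFM) counts residue occurrences per
alignment column, `PFM[k, j] = Σ_i 1{A[i, j] = k}`; the position
probability matrix (PPM) smooths it with a pseudocount p = 0.8:

    PPM[k, j] = (PFM[k, j] + p/4) / (N + p)

where N is the alignment depth. The `p/4` split of the pseudocount is kept
verbatim even though the residue alphabet has 21 symbols (it descends from
a four-letter nucleotide formulation); consequently 21-letter columns sum
to `(N + 21p/4)/(N + p)` rather than 1. `compute_ppm(...,
per_symbol_pseudocount=True)` distributes p over the alphabet size
instead, restoring exact unit column sums; it is off by default because
fidelity to the smoothing rule as defined takes precedence, and a constant
column-sum factor is irrelevant to a scale-learning classifier.

The alphabet has 21 symbols: the 20 standard residues plus `X`, onto which
all ambiguity/rare codes (B, Z, U, O, J, `*`) are mapped at I/O time. The
21st PPM row therefore only receives counts from mapped non-standard
symbols.

Category flags partition the 20 standard residues conventionally:
aliphatic {A,G,I,L,P,V}, aromatic {F,W,Y}, polar-neutral {C,M,N,Q,S,T},
acidic {D,E}, basic {H,K,R}. The seven scalars — molecular weight, pK of
the α-COOH and α-NH3 groups, pK of the side group, isoelectric-point pH,
and hydrophobicity indices at pH 2 and pH 7 — come from a standard
free-amino-acid reference table bundled as
`src/graphdbp/data/residue_properties.tsv` and are min-max normalized to
[0, 1] across the 20 standard residues. Two conventions were open and are
resolved as follows: residues without an ionizable side group get a
neutral pK placeholder of 7.00 before normalization, and the `X` row
carries no category flag and column-mean scalars, placing unknown residues
at the centroid of property space.

### Graph construction

Contact maps are symmetrized on load as `(V + Vᵀ)/2` (a contact
probability is a single pairwise quantity; the graph is undirected), the
diagonal is zeroed (the convolution adds the self-loop analytically, so a
probability-1 diagonal would double-count), and edges are the pairs with
probability ≥ 0.5. The threshold is inclusive. Isolated residues stay in
the graph — the self-loop keeps their features propagating. Sequence
neighbors are *not* force-connected; edges come from the contact map
alone (`backbone`-style augmentation would be an experiment, not the
model).

### Architecture

Each convolution layer computes

    H^{l+1} = σ( D̂^{-1/2} (A + I) D̂^{-1/2} H^l W^{l+1} )

with σ = ReLU and layer dimensions (54, 54), (54, 108), (108, 216). The
216-wide node representations are pooled to one graph vector (mean by
default; sum and max selectable — the readout is a genuinely open choice
and mean is robust to protein length), followed by two fully connected
layers (216 → 64 → 2) with inverted dropout (default 0.2) on the hidden
activation during training, and a two-class softmax reported as the
positive-class probability. The decision rule is positive iff probability
≥ 0.5. Biases are included in every layer by default; `use_bias=False`
gives the strict propagation rule, which the dense-oracle tests exercise.

The network and its gradients are implemented directly in numpy. The
model is small (≈45k parameters) and graphs are modest (hundreds of
nodes), so dense per-graph products are exact, fast, and dependency-free;
backpropagation through the propagation rule uses the symmetry of the
normalized adjacency (`∂L/∂H^l = N (∂L/∂Z) Wᵀ` with N symmetric) and is
verified against central finite differences in the test suite.

## Training

Mini-batch Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on two-class
cross-entropy — the standard loss for a probability-emitting classifier
head. Defaults: 1000 epochs, batch size 128, learning rate 0.001. A stratified `validation_fraction` (default
10%) is held aside for epoch selection.

**Epoch selection.** The returned parameters are those of the epoch with
the best validation MCC, with ties broken by lower validation
cross-entropy. The tie-break matters at desk scale: a small validation
split saturates MCC at 1.0 within a few epochs, long before the model has
converged, and MCC alone would freeze that barely-trained epoch.
Optional early stopping halts after `early_stop_patience` epochs without
improvement under the same criterion.

Training is bit-reproducible from the seed on one thread: the split, the
weight initialization, the shuffling and every dropout mask derive from
one generator.

**MCC convention.** When any factor of the MCC denominator is zero the
metric is undefined; it is reported as 0 and flagged in
`EvalMetrics.undefined`, likewise SN or SP with an empty class.

## The synthetic-data generator

The generator emulates the three upstream inputs — sequences, alignment
sets, contact maps — so the whole pipeline is testable without external
databases, alignment searches, or a contact predictor.

* **Sequences**: i.i.d. uniform over the 20 standard residues.
* **Alignments**: row 0 is the unmutated target; each other row
  substitutes every position independently with probability
  `mutation_rate` (default 0.4) by a uniform random *other* residue;
  depth N = 5.
* **Contact maps**: pairs within `band_width` = 2 of the diagonal draw
  probabilities in [0.55, 1) (a short-range backbone-like band, always
  above threshold); each distant pair independently draws from [0.5, 1)
  with probability `longrange_density` = 0.05 and from [0, 0.5)
  otherwise, so the expected distant-pair edge rate equals the density
  exactly.

Class signal is planted at the input level, never by relabeling outputs,
so recovery exercises featurization, graph construction and training end
to end:

* channel `"ppm"` — positive-class alignment substitutions draw from a
  lysine/arginine-rich motif composition with probability `effect_size`
  (default 0.9). Because the *target* sequences are identically
  distributed across classes, the one-hot block carries no signal; only
  the PPM block does. This is what makes the PSSM ablation ordering a
  forced expectation.
* channel `"contacts"` — the positive class's long-range density is
  raised by `effect_size`; the signal lives in graph topology.

`effect_size = 0` collapses both channels onto an exact null.

**What the generator does not emulate:** real amino-acid composition,
phylogenetic correlation between alignment rows, biophysically realistic
contact geometry, or a contact predictor's error characteristics. Passing
tests therefore demonstrate that the pipeline recovers signal it is
designed to represent — not benchmark-level performance on curated
protein datasets, which additionally requires database alignments and
predicted contact maps as external inputs.

## Experiment scale

The recovery, null-calibration and ablation experiments run on datasets
of 60 proteins of 30–60 residues (alignment depth 5) with a scaled-down
optimizer configuration: 200 epochs, batch 16, validation fraction 0.15,
early-stop patience 40. These sizes keep a full 20-replicate experiment
in the minutes range while leaving the planted-signal ordering
comfortably resolved; the full-scale defaults (1000 epochs, batch 128)
remain the package defaults for real-data use.

## Numerical notes

* Contact-map entries within 1e-6 outside [0, 1] are clipped on read;
  anything further is an error. Text round-trips use `%.17g`.
* Softmax is computed shift-invariantly; the log in the loss is clamped
  at 1e-300 to keep a diagnosable loss rather than a silent `inf`.
* Degenerate inputs: single-residue proteins (1×54 features, 1×1
  adjacency) and edgeless graphs are valid throughout; an edgeless
  graph's normalized adjacency is the identity, reducing the conv stack
  to a per-node feed-forward network (asserted in tests).
* Max pooling routes gradients to each channel's argmax node; ties take
  the lowest index (numpy convention).

## Known limitations

* No ROC/AUC or cross-validation protocols — evaluation mirrors a single
  stratified train/test protocol.
* The PPM block uses probabilities, not log-odds against background
  frequencies; no alignment search tool is run.
* Weighted-edge (probability-retaining) graphs are out of scope; the
  contact map is binarized by design.
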