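# graphdbp

Predicting whether a protein binds DNA, from its sequence alone, using a
graph convolutional network over residue contact maps.

DNA-binding proteins drive replication, transcription and chromatin
organization; telling them apart from non-binders computationally saves
structure determination and assay work. `graphdbp` implements a
structure-aware sequence pipeline: a protein of length M becomes a graph
whose M nodes are residues, whose edges are residue pairs with predicted
contact probability ≥ 0.5, and whose node attributes are 54 features —
a 21-way residue one-hot, the residue's column of a pseudocount-smoothed
position probability matrix (PPM, the evolutionary "PSSM" block), and 12
physicochemical properties. A three-layer GCN

    H^{l+1} = σ( D̂^{-1/2} (A + I) D̂^{-1/2} H^l W^{l+1} )

with layer dimensions (54, 54), (54, 108), (108, 216), mean pooling, and
two fully connected layers with dropout emits the probability that the
protein is a binder. Training uses Adam on cross-entropy (defaults:
1000 epochs, batch 128, learning rate 0.001); evaluation reports
sensitivity, specificity, accuracy and the Matthews correlation
coefficient. The whole network, including backpropagation, is
implemented in numpy — no deep-learning framework required.

A synthetic-data module generates sequences, alignment sets and contact
maps with a plantable class signal, so every stage is testable end to end
without external databases or a contact predictor. Real inputs (FASTA,
per-protein alignment text, contact-map matrices, a label TSV) drop into
the same pipeline.

## Worked example

```python
from graphdbp import (SimulationSpec, TrainConfig, simulate_dataset,
                      holdout_experiment)

# 60 synthetic proteins; the positive class's alignments are enriched in
# K/R substitutions, so the signal lives only in the PPM feature block.
graphs, manifest = simulate_dataset(SimulationSpec(seed=1))

tc = TrainConfig(epochs=200, batch_size=16, seed=1,
                 validation_fraction=0.15, early_stop_patience=40)
metrics, result = holdout_experiment(graphs, train_config=tc)
print(f"held-out ACC={metrics.ACC:.3f} MCC={metrics.MCC:.3f} "
      f"SN={metrics.SN:.3f} SP={metrics.SP:.3f}")
```

prints

```
held-out ACC=1.000 MCC=1.000 SN=1.000 SP=1.000
```

i.e. the classifier perfectly recovers the planted evolutionary signal on
the 16-protein held-out split: every binder and non-binder is classified
correctly (MCC = 1 is the upper end of its [−1, 1] range). With
`effect_size=0.0` in the spec the same experiment yields held-out MCC
scattered around 0, as a null should.

The same pipeline is scriptable from a shell:

```bash
graphdbp simulate --out data/ --seed 1
graphdbp featurize --fasta data/sequences.fasta --alignments data/ --out feats/
graphdbp build-graphs --fasta data/sequences.fasta --features feats/ \
    --contact-maps data/ --labels data/labels.tsv --out graphs/
graphdbp train --graphs graphs/ --checkpoint model.npz \
    --config epochs=200 --config batch_size=16
graphdbp evaluate --graphs graphs/ --checkpoint model.npz
graphdbp sweep-dropout --graphs graphs/     # dropout comparison table
graphdbp ablate-pssm  --graphs graphs/      # with/without the PPM block
```

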