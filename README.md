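# carbsite

Residue- and protein-level prediction of noncovalent carbohydrate binding
from protein structure.

Carbohydrate recognition is central to cell adhesion, signaling, immunity
and metabolism, yet most of the protein–carbohydrate interactome is
uncharted: structural databases capture only strong, crystallizable
complexes, and sequence-based lectin catalogs cover a single protein
family.  `carbsite` implements a pair of geometric deep-learning predictors
for this problem, for structural bioinformaticians who want to annotate
binding sites on individual structures or screen whole sets of predicted
structures:

* **residue head** — labels each residue of a structure with the
  likelihood that it contacts a bound carbohydrate;
* **protein head** — classifies the whole protein as carbohydrate binder
  or nonbinder.

## Model

A protein is a directed k-nearest-neighbor graph over its Cβ trace
(Cα for glycine).  Node features are per-residue sequence embeddings
(1,280-dim contract, pluggable embedder).  Edge features are invariant
under rigid motion: 16 Gaussian RBFs of the distance on [0, 20] Å, the
unit displacement in the source residue's local frame, and the relative
frame orientation as a quaternion.  Both heads share a trunk of 12
residual equivariant graph convolutional layers (dim 128), where layer
updates are

    h_i' = h_i + MLP_h([h_i, Σ_j MLP_e([h_i, h_j, e_ij])])

The residue head (k = 16 throughout) ends in a two-layer dense decoder
per residue; the protein head widens its neighborhood over depth
(k = 10/20/40/60 per 3-layer stage), adaptively pools the sequence to a
fixed 150×128 map and classifies it with two convolutions and three dense
layers.  The default configurations have exactly 1,600,387 (residue) and
1,798,895 (protein) trainable parameters.

Residue training minimizes `L = 1 − d` with `d` the soft Dice–Sørensen
coefficient (the positive class is ~5% of residues); protein training uses
binary cross entropy.  Evaluation reports per-protein Dice
`2TP/(2TP+FP+FN)` and MCC (averaged across proteins), and BACC/TPR/TNR at
the protein level.  Everything runs on CPU in numpy (autograd for
gradients); no GPU framework is needed.

See `docs/methods.md` for the full model description, training protocol
and design rationale.

## Worked example

Generate a small synthetic corpus (helical toy proteins, each with a
planted glucose-like ligand), label it with the 4.2 Å contact rule, and
train a tiny residue predictor on the planted signal:

```python
import numpy as np
from carbsite.synthetic import SyntheticSpec, generate_dataset, featurize
from carbsite.embeddings import StubEmbedder
from carbsite.models import Capsif2, ModelConfig
from carbsite.training import TrainConfig, train_cycle
from carbsite.metrics import soft_dice

spec = SyntheticSpec(n_proteins=30, seed=11, binder_fraction=1.0)
proteins, entries = generate_dataset(spec)
emb = StubEmbedder(dim=32, seed=3, signal_strength=3.0)
data = [(featurize(lp, emb, k_values=(16,), with_signal=True), lp.residue_labels)
        for lp in proteins]

config = ModelConfig(n_layers=2, embed_dim=16, input_dim=32, msg_hidden=32,
                     upd_hidden=32, decoder_hidden=16, picap_k_schedule=(16, 16),
                     conv_channels=(2, 2), dense_widths=(8, 8))
model = Capsif2(config, seed=0)
history = train_cycle(model, data[:24], data[24:27],
                      TrainConfig(lr=1e-3, weight_decay=1e-4,
                                  max_epochs=40, patience=29, loss="dice"))
held_out = [float(soft_dice(model.forward(g), y)) for g, y in data[27:]]
print(f"epochs run: {len(history.val_losses)}")
print(f"best validation Dice loss: {history.best_val_loss:.3f}")
print(f"held-out soft Dice: {np.mean(held_out):.3f}")
```

This prints (exactly, given the fixed seeds):

```
epochs run: 40
best validation Dice loss: 0.037
held-out soft Dice: 0.923
```

A best validation Dice loss of 0.037 means the model recovers ~96% Dice
overlap with the planted binding pockets on validation proteins, and the
held-out soft Dice of 0.923 confirms the learned rule transfers to
structures never seen in training — at toy scale, the planted signal is
recovered almost completely.

The same models are exposed on the command line: `carbsite predict` writes
per-residue TSV and per-protein CSV reports for PDB/mmCIF inputs given a
checkpoint, `carbsite proteome` batch-annotates a directory of predicted
structures (trimming residues at pLDDT ≤ 70 by default), and
`carbsite evaluate` scores predictions against contact-derived labels.

## Acceptance script

`scripts/acceptance.py` rebuilds both default architectures from their
configuration and recounts their trainable parameters at run time:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The JSON maps target ids to the recomputed totals.
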