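# Methods

## Problem

Most carbohydrate–protein recognition is mediated by shallow surface sites
dominated by CH–π stacking against pyranose rings plus hydrogen-bond
networks. `carbsite` implements two complementary predictors over the same
representation of a protein structure:

* a **residue-level head** that scores every residue's likelihood of
  contacting a noncovalently bound carbohydrate, and
* a **protein-level head** that scores whether the protein binds
  carbohydrates at all,

together with the data machinery around them: contact labeling from bound
ligands, dataset curation rules, redundancy-aware splitting, the two-cycle
training protocol, and a synthetic-fixture generator that makes the whole
pipeline testable on a laptop with no downloads.

## Representation

A protein is reduced to its Cβ trace (Cα for glycine).  Nodes carry a
per-residue sequence embedding supplied by a pluggable embedder; the
production contract is 1,280 values per residue (the width of large
protein-language-model embeddings), consumed through an `embed(sequence)`
interface so tests can run on a deterministic stub.

Edges connect each residue to its k nearest neighbors in space (directed;
k-NN graphs are not symmetric).  Edge attributes are invariant under any
global rotation and translation:

* 16 Gaussian radial basis functions of the distance, centers evenly spaced
  on [0, 20] Å, width equal to the spacing;
* the unit displacement vector expressed in the source residue's local
  frame (3 values);
* the relative orientation of the two residues' frames as a unit quaternion
  (4 values, scalar-first, sign fixed by a nonnegative scalar part).

Local frames are built by Gram–Schmidt on the sequence-adjacent Cβ
displacements `(x[i+1]-x[i], x[i-1]-x[i])` with a cross-product third axis;
terminal residues copy the frame of their unique sequence neighbor.  Frames
from a Cβ trace (rather than backbone N/Cα/C atoms) keep the input contract
to the single coordinate per residue the models consume.

Because every model input is invariant, both heads are rigid-motion
invariant by construction; the test suite verifies this numerically at
≤ 1e-5 relative.

## Architectures

Both heads share a trunk of 12 **residual equivariant graph convolutional
layers** (EGCL) at embedding dimension 128, preceded by a linear projection
1280 → 128.  One layer computes messages `m_ij = MLP_e([h_i, h_j, e_ij])`
over the k neighbors, sums them, and applies the residual update
`h_i' = h_i + MLP_h([h_i, Σ_j m_ij])`.  Coordinates are never updated —
the prediction targets and all edge features are invariant, so the
coordinate stream of the general EGNN formulation is unnecessary.

* **Residue head**: fixed k = 16; after the trunk a two-layer dense decoder
  (128 → 33 → 1) with a sigmoid per residue.  1,600,387 trainable
  parameters.
* **Protein head**: a widening neighborhood schedule — k = 10 for layers
  1–3, 20 for 4–6, 40 for 7–9, 60 for 10–12 — then adaptive average
  pooling of the residue features to a fixed 150 × 128 map, treated as a
  one-channel image: two 3×3 stride-2 convolutions (channels 1 → 9 → 3)
  and three dense layers (3648 → 55 → 31 → 1) to a single sigmoid.
  1,798,895 trainable parameters.

The two totals are the only published size ground truth; the internal
widths (MLP_e hidden 156, MLP_h hidden 144, decoder hidden 33, conv
channels 9/3, dense 55/31) were calibrated once by integer search so both
totals are reproduced exactly, and are frozen in the default `ModelConfig`.
Activations are SiLU (sigmoid outputs), recorded in the config as a
swappable choice.  Before the convolutional head the pooled map passes
through a parameter-free compressive squash `sign(x)·log1p(|x|)`
(`pool_norm="log"`): after trunk transplant the inherited activations can
be orders of magnitude larger than the freshly initialized head expects,
and the squash keeps the head's operating range sane without erasing the
absolute-magnitude contrast between a flat map and one with a binding
bump.  Plain standardization was tried and rejected — dividing by the
map's own standard deviation amplifies noise on near-flat (nonbinder) maps
and destroys exactly the cue the classifier needs.

The implementation is numpy + `autograd` in float64 with a hand-written
Adam.  No GPU framework is required; at the desk scales this package
targets (proteins of tens to hundreds of residues, corpora of tens to
hundreds of structures) CPU execution is seconds per forward pass even at
the full 1.6M-parameter configuration.

## Labels

A residue is a binding residue iff the minimum heavy-atom–to–ligand-atom
distance is ≤ 4.2 Å for any noncovalent flagged ligand.  Heavy atoms only
(hydrogens are absent from most crystal structures) and an inclusive
cutoff.  Covalent attachment — any ligand atom within 1.8 Å of a protein
heavy atom, the upper bound of common covalent bond lengths — excludes the
whole ligand group from labeling (e.g. N-linked glycans).  "Carbohydrate"
is operational: a HET-code vocabulary seeded with the dominant pyranose
monosaccharides (GLC, BGC, GAL, MAN, XYS/XYP, FUC, SIA, NAG, NGA, KDO, …),
user-extensible via YAML.  Waters and monoatomic ions are never ligands.

pLDDT comparisons are strict: proteome runs keep residues with pLDDT > 70;
predicted structures enter training augmentation only when their minimum
retained pLDDT exceeds 80.

## Dataset rules, clustering, splits

Small-molecule "nonbinder" entries whose ligand set contains a noncovalent
carbohydrate are reassigned to the binder class.  Antibody antigens with an
N-glycosylation sequon N-X-(S/T) are excluded from the nonbinder pool; X is
taken as any residue except proline, matching the biological sequon (the
rule's source states only "NX(S/T)").

Sequences are clustered greedily at 60% identity (longest-first centroid
clustering; identity = matches / alignment length of a global alignment
with match +1, mismatch 0, gap open −10, extend −0.5, via Biopython's
`PairwiseAligner`).  An external clusterer (e.g. MMseqs) can stand behind
the same contract through `clusters_from_tsv`.  Whole clusters are
assigned to train/validation/test at 80/5/15 **by entry count** (greedy
largest-deficit fill over seed-shuffled clusters), with pinned entries
forcing their whole cluster into a named split; a cluster pinned to two
splits is an error, so no ≥60%-identity pair can straddle a split.

Each training epoch draws one entry uniformly per cluster; entries with a
predicted-structure counterpart use it with probability 0.6, else the
crystal structure.

## Training protocol

Two cycles, Adam, batch size 1, max 1,000 epochs, early stopping after 35
epochs without a strict improvement of the running validation minimum
(ties count as non-improvement), best-validation weights restored:

1. **Cycle 1** — residue architecture from scratch (all weights i.i.d.
   N(0, 0.02)) on small-molecule contact labels; lr 2e-6, weight decay
   1e-7, Dice loss `L = 1 − d` with the soft (sums-of-products) Dice `d`.
2. **Cycle 2a** — the same model fine-tuned on carbohydrate-only
   complexes; lr 2e-5, weight decay 1e-6, Dice loss.
3. **Cycle 2b** — the protein head: trunk tensors transplanted from cycle
   1, pooling head freshly initialized N(0, 0.02), all weights trainable;
   lr 2e-5, weight decay 1e-6, binary cross entropy.

Weight decay is applied as an L2 term added to the gradient; Adam β/ε are
the conventional defaults (0.9/0.999/1e-8).  Both are unstated in the
protocol's source and recorded in `TrainConfig`.

## The synthetic world

`SyntheticSpec` defaults define the stated test world: proteins of 30–120
residues on an ideal helix (rise 1.5 Å, radius 2.3 Å, 100°/residue, Cβ
offset 1.5 Å radially outward); binders carry a GLC-coded ligand cluster of
8 atoms planted so each of the 5 pocket residues' nearest ligand atom lies
within 3.5 Å while the helix geometry keeps all other residues outside the
4.2 Å shell; binder fraction 0.5; stub embeddings with channel 0 of pocket
residues shifted by +3.0.  Labels always come from the production contact
labeler run on the constructed coordinates — never set directly — so the
fixtures and the labeler cannot drift apart.

What a green synthetic test establishes: the geometry/labeling path is
exact, the optimization machinery can recover a planted, linearly
accessible signal end-to-end through both heads, and the two-cycle
protocol (including trunk transplant) functions.  What it does not
establish: any performance claim on real structures — the helical
geometry, additive single-channel signal and clean labels are far easier
than crystallographic reality, and the stub embedder carries none of the
evolutionary information a protein language model provides.

Toy training runs use toy optimization scales (lr 1e-3 and weight decay
1e-4 for the residue stages, lr 3e-3 for the head stage, tens of epochs):
at tens of epochs on ~50-protein corpora the production learning rate
(2e-6) cannot move the loss measurably.  The production rates remain the
shipped `TrainConfig` defaults; tests assert the 10× stage-2/stage-1
ratio from those defaults.

Two further toy-scale adaptations of the head stage, both off by default
in the production path: the transplanted trunk is frozen and the head
trains over trunk features cached once per protein
(`two_stage_train(freeze_trunk_2b=True)`) — joint fine-tuning of a
transplanted trunk on tens of proteins is noise-dominated and
reproducibly degrades it — and the head uses full-batch gradients
(`batch_size` covering the corpus) rather than batch size 1: on a small
balanced binary corpus the per-sample gradients of alternating classes
nearly cancel, and a batch-1 optimizer oscillates without ever
accumulating the weak discriminative direction.  Neither adaptation
changes the architecture or the parameter counts.

## Numerical choices

* Float64 throughout; sigmoid/SiLU in tanh form (stable for |x| ≳ 700).
* Saturated tanh backward overflows `cosh²` to inf, giving gradient 0 —
  the correct limit; only that overflow warning is silenced in training.
* Soft Dice uses an epsilon (machine eps) in the denominator; the hard
  coefficient is defined as 0 with a warning when labels and calls contain
  no positive.  MCC is 0 when any marginal is empty; BACC raises on an
  empty class instead of silently imputing.
* k-NN ties break deterministically by lower index (distances rounded to
  1e-9 before the lexsort).  Quaternion sign fixed by a nonnegative scalar
  part.  Binary calls use `probability ≥ threshold`.
* Degenerate inputs raise typed errors: < 2 residues (graph), < 3 residues
  (frames), coincident consecutive Cβ (frames/edges), all residues below a
  pLDDT cutoff (filter), empty sugar vocabulary (flagging).

## Known limitations

* The internal widths are calibrated to the published parameter totals but
  are not uniquely determined by them; other width combinations reproduce
  the same counts.
* The greedy centroid clusterer is O(n²) alignments at worst and is meant
  for corpus sizes up to a few thousand; production-scale redundancy
  removal should use the external-tool adapter.
* The numpy/autograd backend is single-core and optimizes at toy scale
  only; reproducing published benchmark numbers would require the full
  ~30k-structure corpus, real 1,280-dim language-model embeddings and
  GPU-scale training, all out of scope here.
* Multi-model (NMR) files are reduced to model 1; altloc A only.
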