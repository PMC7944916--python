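# Methods

This note documents the models implemented in `divmolgen`, the parameter
choices that matter, the synthetic data used for testing, and the known
limitations.

## SMILES representation

SMILES strings are tokenized greedily left to right. Multi-character
units are kept intact: the two-letter elements `Cl`/`Br`, bracket atoms
`[...]`, and `%NN` ring closures. Concatenating the tokens always
reproduces the input string exactly; a dangling `[` or `%` is a parse
error. The vocabulary is rebuilt from whatever corpus the generator is
trained on (specials first, then observed tokens in sorted order) and
persisted with every checkpoint, rather than hard-coded: published
descriptions of comparable generators quote a 45-token vocabulary for a
large ZINC-derived corpus but do not list the tokens, and the same
sources quote an output-layer width (43) inconsistent with that count,
so every layer here is sized from the actual vocabulary.

Sequences are framed as `G <tokens> E` and padded with spaces to a fixed
length (65 at full scale; 32 for the desk-scale fixture corpus, whose
molecules tokenize to at most ~30 tokens). Molecules that do not fit are
dropped at curation with a logged count. The generator consumes one-hot
encodings; the QSAR recurrent model consumes integer indices through an
embedding.

## Generator

A stacked-LSTM language model (2 layers, 256 units and dropout 0.3 at
full scale) with a dense softmax head over the vocabulary. Pre-training
is teacher forcing with Adam (lr 1e-3, batch 16, 25 epochs at full
scale) and elementwise gradient clipping to [−3, 3]. The loss is the
elementwise (binary-form) cross-entropy summed over the vocabulary
dimension,

    −(1/T) Σ_t [ y_t·log ŷ_t + (1−y_t)·log(1−ŷ_t) ],

averaged over unmasked timesteps; pad positions are masked out so they
contribute neither loss nor gradient. Probabilities inside logarithms
are floored at 1e-8. This form is equivalent to categorical
cross-entropy up to the (1−y) competing-token terms; its exact gradient
is propagated through the softmax.

Sampling is autoregressive from `G`, stopping at `E` or the length cap
(non-terminated samples are flagged, not dropped). The softmax is
temperature-scaled; the pad and start tokens are excluded from the
sampling support so no mid-string padding can occur. Per-token natural
log-probabilities of the sampled tokens are recorded under the sampling
distribution. One integer seed derives independent substreams for
weight initialization, shuffling, dropout and sampling.

## QSAR predictor

Two families, both standardizing labels (pIC50) on their training
portion only:

- **SMILES-GRU**: embedding (128) → 2×GRU(128) → dense ReLU (128) →
  linear output at full scale. Trained with Adam on MSE of standardized
  labels, clipping to [−3, 3], early stopping (patience 10 epochs) on an
  internal 15% validation split with best-validation weights restored.
- **ECFP baselines** over 4096-bit radius-3 Morgan fingerprints:
  SVR (poly kernel, C = 0.125, γ = 8), random forest (500 trees, sqrt
  features), KNN (k = 11, Euclidean) via scikit-learn, and a fully
  connected net (8000/4000/2000 ReLU units, dropout 0.25 between hidden
  layers) implemented with the same NumPy layer stack as the generator.
  The published hyperparameter table for the classical baselines renders
  ambiguously in extraction; the values above follow the column order
  and are all exposed as estimator parameters.

Evaluation protocol (`train_qsar`): 15% of the data is held out as the
test set; the remaining 85% is partitioned into 5 disjoint folds; model
k trains on the complement of fold k (neural variants additionally split
their training portion 85/15 for early stopping). Each fold model is
scored on the held-out test set with MSE and Q² = 1 − SS_res/SS_tot,
SS_tot taken around the *test-set* mean (the reference description does
not fix the centering; the test-set mean is the stricter, self-contained
choice). The fitted ensemble predicts with the fold mean, de-standardized.

## Reinforcement learning

`ReinforceOptimizer.fit(G_u)` copies the pre-trained policy into G_b and
runs 85 iterations of 10-molecule batches sampled at temperature 0.9.
Rewards: `exp(p/4 − 1)` for pIC50 maximization; `exp((2 − p)/4)` for
minimization (the published work states only that minimization was run;
the offset 2 keeps rewards on a comparable positive scale);
for the logP window, 3 inside [1, 4] and `3·exp(−d)` at distance `d`
outside (flat desirable plateau, smooth positive decay). Chemically
invalid molecules take reward 0 (configurable) and never enter the
diversity memory.

The policy-gradient loss discounts over token positions, `γ^j` with j
from 1 (default γ = 0.97, never specified in the source description). A
per-molecule-index variant `γ^i` — the form as literally printed in the
source equation — is available via `discount_indexing="molecule"`, but
it only rescales whole molecules by their arbitrary batch position, so
the token indexing is the default. Log-probabilities are taken under
G_b's temperature-scaled, special-masked sampling distribution for every
token, including tokens delegated to G_u; each sampled batch is pushed
back through G_b ("decompose and reconstruct") so gradients reflect the
current parameters. Gradients are clipped elementwise to [−3, 3] and
applied with Adam (lr 1e-3).

**Exploration schedule.** λ is frozen per batch: with fewer than three
recorded batch means it is τ[2]; otherwise two consecutive positive
deltas select τ[0], two negative select τ[1], anything else τ[2]. ε is
drawn per token. Both policies are stepped on the same shared prefix so
either can take over at any position.

**Diversity memory.** A FIFO of the fingerprints of the last 30 valid
molecules. A new molecule whose mean Tanimoto distance to the memory is
below κ (default 0.75) has its reward multiplied by 0.85 exactly; it
enters the memory either way. The source text's penalty sentence
compares "the reward" with κ, but κ's stated search range [0.7, 0.75]
and the surrounding discussion concern Tanimoto diversity, so the
threshold is implemented on the diversity.

**Checkpoint selection.** Optional periodic snapshots (every
`eval_every` iterations, 500 samples) record desirability and internal
Tanimoto diversity; `select_checkpoint` returns the iteration maximizing
their product, earliest on ties — the best policy is often not the final
one.

## Evaluation metrics

- Validity: RDKit sanitization, with zero-atom parses (e.g. the empty
  string) counted invalid.
- Uniqueness: unique canonical forms divided by the number of *valid*
  molecules, so it is independent of validity.
- Desirability: predicted pIC50 ≥ 6.5, or logP ∈ [1, 4] for the
  partition-coefficient objective, evaluated on valid molecules.
- SAS: the published fragment-contribution synthetic-accessibility
  score (RDKit contrib implementation), clamped to [1, 10]; > 6 flags a
  hard-to-synthesize molecule.
- Diversity: mean pairwise distance under 1 − Tanimoto (one fingerprint
  everywhere: 4096-bit, radius-3 Morgan, shared with the predictor and
  the RL memory), unnormalized Levenshtein on raw SMILES strings
  (computed with edlib; an independent DP implementation serves as the
  test oracle), and 1 − MCS ratio
  `mcs/(atoms_a + atoms_b − mcs)` over heavy atoms (RDKit FMCS, 10 s
  timeout per pair, the lower bound reported on timeout). Internal
  diversity keeps the 1/n² normalization with self-pairs included;
  external diversity averages over A×B.

## Synthetic data and desk-scale study conditions

The fixture corpus generator emulates a curated small-molecule corpus at
toy scale: linear chains, branched chains and simple 5/6-membered rings
over {C, N, O, S, F, Cl} with single/double bonds — no stereochemistry,
isotopes, charges or aromatic systems. Every fixture molecule passes
sanitization by construction; a 2,000-molecule draw is ~70% unique with
logP centered near 1, leaving genuine headroom for the logP-window
objective. The synthetic structure–activity table sets
pIC50 = 4 + 2·(heteroatom fraction) + N(0, 0.1), a rule a competent
QSAR must recover (test Q² > 0.5 at n = 500).

Desk-scale runs (tests and `scripts/acceptance.py`) use a 2×64-unit
LSTM with padded length 32 and 5 pre-training epochs, and a 32-unit
GRU/32-dim embedding QSAR model — sizes chosen so the full pipeline
fits a single CPU in about a minute while leaving the RL protocol at
its full budget (85 iterations × 10 molecules, T = 0.9, lr 1e-3,
clip ±3, τ₂ = [0.05, 0.2, 0.1], κ = 0.75). Passing at this scale
demonstrates the mechanics and the exploration-vs-exploitation contrast
(the pure-exploitation baseline reproducibly collapses uniqueness while
the scheduled run preserves it); it does not certify the headline
validity/diversity percentages reported for half-million-molecule
training corpora, aromatic chemistry coverage, or real bioactivity data.

## Known limitations

- NumPy recurrent cores are single-threaded-BLAS bound; full-scale
  (500K-molecule, 2×256) training is possible but slow.
- The fixture chemistry excludes aromatic rings, so desk-scale
  vocabularies are much smaller than real-corpus vocabularies.
- The MCS ratio depends on the FMCS search settings (default ring
  matching); different settings give slightly different ratios.
- Reward minimization and multi-objective composition beyond a single
  property oracle are out of scope.
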