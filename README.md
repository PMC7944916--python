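# divmolgen

Diversity-oriented deep reinforcement learning for targeted de novo
molecule generation.

`divmolgen` is a small research toolkit for drug-discovery groups that
want to bias a generative SMILES model toward a property objective —
binding affinity (pIC50) against a receptor, or a physicochemical window
such as logP — **without collapsing the chemical diversity of what it
generates**. It implements, end to end:

- a character/token-level **SMILES language model** (stacked LSTM policy)
  pre-trained with teacher forcing on a molecule corpus;
- **QSAR activity prediction** from SMILES (embedding + GRU regressor)
  alongside classical ECFP baselines (SVR, random forest, KNN, FCNN),
  evaluated with a held-out test split and 5-fold cross-validation;
- **REINFORCE fine-tuning** of the generator against a reward
  `R = exp(pIC50/4 − 1)` (or a logP-window reward), with two diversity
  devices: a *dual-generator* exploration schedule and a *memory-based
  reward penalty*;
- an **evaluation suite**: validity, uniqueness, desirability, synthetic
  accessibility (SAS), and internal/external diversity under three
  distances (1 − Tanimoto over Morgan fingerprints, Levenshtein on raw
  SMILES, 1 − MCS ratio).

All recurrent models are implemented in NumPy inside the package
(forward, backpropagation through time, Adam, gradient clipping), so the
whole pipeline runs on a single CPU with no deep-learning framework.

## The method

Let `G_u` be the pre-trained (unbiased) policy and `G_b` a copy being
fine-tuned. Each RL iteration samples a batch of molecules token by
token from the temperature-scaled softmax (T = 0.9). At every token a
uniform draw ε delegates the step to `G_u` when ε < λ; λ is chosen per
batch from a triple τ = (λ_rising, λ_falling, λ_mixed) according to the
trend of the last batch rewards — exploitation when the reward is
rising, more exploration when it falls. Each valid molecule is scored by
the property oracle and converted to a reward; if its mean Tanimoto
distance to the last 30 generated molecules falls below κ, the reward is
cut by 15%. The policy gradient minimizes

    J(θ) = −(1/n) Σ_i Σ_j R_i · γ^j · ln p(s_j | s_0…s_{j−1}, θ)

with log-probabilities taken under `G_b` and elementwise gradient
clipping to [−3, 3].

## Worked example

```python
from divmolgen import (SmilesGenerator, ReinforceOptimizer, RewardSpec,
                       generate_fixture_corpus, evaluate_generated_set)
from divmolgen.rl_engine import logp_oracle
from divmolgen.metrics import desirability_logp

corpus = generate_fixture_corpus(2000, seed=7)
gen = SmilesGenerator(recurrent_layers=2, recurrent_units=64, dropout=0.3,
                      max_len=32, epochs=5, random_state=1).fit(corpus)

spec = RewardSpec(mode="logp_range", property_oracle=logp_oracle)
engine = ReinforceOptimizer(objective=spec, iterations=85, batch_size=10,
                            temperature=0.9, tau=(0.05, 0.2, 0.1),
                            kappa=0.75, random_state=11).fit(gen)

for model, name in [(gen, "unbiased"), (engine.generator_, "biased")]:
    smiles = [s.smiles for s in model.sample(500, temperature=0.9, seed=21)]
    rep = evaluate_generated_set(smiles, desirability_rule=desirability_logp(),
                                 compute_sas=False)
    print(f"{name:9s} valid {rep.pct_valid:.1f}%  unique {rep.pct_unique:.1f}%"
          f"  desirable {rep.pct_desirable:.1f}%"
          f"  diversity {rep.internal_diversity['tanimoto']:.3f}")
```

Output from this exact run:

```
unbiased  valid 78.8%  unique 79.4%  desirable 56.1%  diversity 0.920
biased    valid 91.4%  unique 68.7%  desirable 78.3%  diversity 0.881
```

Fine-tuning roughly halves the fraction of molecules outside the logP
window (desirable 56.1% → 78.3%) while the internal Tanimoto diversity
stays high (0.920 → 0.881) — the trade-off the exploration schedule and
memory penalty are designed to protect. Running the same RL budget with
τ = (0, 0, 0) and the penalty disabled (pure exploitation) collapses
uniqueness to ~16–29% at the same desirability, which is the failure
mode the method addresses.

A command-line interface mirrors the library
(`divmolgen train-generator / train-predictor / rl-train / sample /
evaluate / report`); every stage writes a manifest with input hashes and
seeds for reproducibility.

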