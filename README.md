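# fluorogen

Adaptive β-VAE molecule generation and latent-vector property prediction
for organic fluorophore design.

Finding organic emitters with a target emission energy and a usable
photoluminescence quantum yield (PLQY) is a search over a huge discrete
space of molecular graphs. `fluorogen` implements the
generator–predictor strategy for that search: a variational autoencoder
(VAE) over robust molecular token strings embeds molecules into a
continuous latent space, gradient-boosted tree regressors trained
*separately* on the latent vectors predict emission energy (eV) and PLQY,
and candidate molecules are found by perturbing, interpolating, and
searching latent points — every decoded point is a valid molecule by
construction of the token grammar.

The core objective is the β-weighted ELBO

```
L_β = −E_{q(z|x)}[log p(x|z)] + β · KL(q(z|x) ‖ N(0, I))
```

with β *scheduled* during training rather than fixed: β = 1 is the
standard VAE (structured latent space, weaker reconstruction), β = 0 a
reconstruction-only autoencoder, and the adaptive schedule — by default
exponential decay `β(t) = max(β_end, β_start·ρᵗ)` with ρ = 0.95 — moves
from global latent structuring to local reconstruction accuracy as
training progresses. Linear, piecewise, and performance-monitored
schedules are also provided. See `docs/methods.md` for the full model
description, defaults, and limitations.

Intended users: cheminformatics / ML-for-molecules researchers who want a
small, fully reproducible (NumPy, single-seed, bit-deterministic)
reference implementation of KL-annealed molecular VAEs with downstream
property prediction and latent-space search.

## Worked example

```python
import numpy as np
from fluorogen import (
    FixtureSpec, generate_molecules, assign_properties,
    BetaSchedule, TrainConfig, train_generator, reconstruction_rate,
    perturb_generate, neighborhood_search,
    PredictorConfig, train_property_model, evaluate,
)
from fluorogen.fusion import split_indices
from fluorogen.predictor import featurize_batch

# 300 synthetic C/N/O/F molecules with latent-linked emission labels
spec = FixtureSpec(n_molecules=300, max_tokens=10, seed=11, noise_sd=0.05)
mols = generate_molecules(spec)

cfg = TrainConfig(
    schedule=BetaSchedule(kind="exponential", beta_start=1.0,
                          beta_end=0.01, rho=0.95),
    latent_dim=32, hidden_dim=200, epochs=150, batch_size=64,
    seed=0, lr=1.5e-3)
model = train_generator(mols, cfg)
print(f"reconstruction rate: {reconstruction_rate(model, mols):.3f}")

gen = perturb_generate(model, mols[:10], sigma=0.5, n_samples=50, rng_seed=1)
print(f"perturbation: {gen.n_valid} valid decodes, "
      f"{gen.n_distinct} distinct new molecules")

recs, truth = assign_properties(mols, spec, model)
X = featurize_batch(model, recs)
y = np.array([r.emission_ev for r in recs])
tr, va, te = split_indices(len(recs), seed=0)
pm = train_property_model(X[tr], y[tr], "emission_ev",
                          PredictorConfig(rounds=1000, depth=3, lr=0.1, seed=0))
rep = evaluate(pm, X[te], y[te])
print(f"emission predictor: held-out MAE {rep.mae:.3f} eV, "
      f"Pearson r {rep.pearson_r:.3f}")

report = neighborhood_search(model, pm, mols[0], target_energy=3.1,
                             radius=6.0, n_samples=150, rng_seed=2)
top = report.candidates[0]
print(f"search around {mols[0].smiles}: {len(report.candidates)} candidates; "
      f"top {top['smiles']} predicted {top['predicted_ev']:.2f} eV "
      f"(complexity {top['complexity']})")
```

Output:

```
reconstruction rate: 1.000
perturbation: 500 valid decodes, 8 distinct new molecules
emission predictor: held-out MAE 0.090 eV, Pearson r 0.945
search around NO: 26 candidates; top N#CF predicted 3.12 eV (complexity 3)
```

Reading it: the adaptively-annealed VAE reconstructs all 300 training
molecules exactly (canonical-SMILES identity after greedy decoding);
perturbing ten of them with σ = 0.5 latent noise yields 500 decodes, all
valid molecules, 8 of them new distinct structures; the GBRT emission
regressor recovers the held-out labels to 0.09 eV mean absolute error;
and the neighborhood search ranks nearby decoded molecules by how close
their predicted emission is to the 3.1 eV target.

The same workflow is scriptable from the shell via the `fluorogen` CLI
(`make-fixtures`, `train`, `train-predictor`, `generate`, `search`,
`predict`); run `fluorogen --help`.

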