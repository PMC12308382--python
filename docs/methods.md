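# Methods

## The problem and the model

Designing organic fluorophores means searching an enormous discrete space
of molecular graphs for structures with target photophysics (emission
energy, photoluminescence quantum yield). `fluorogen` follows the
generator–predictor strategy: a variational autoencoder (VAE) embeds
molecules into a continuous latent space, and separately trained
gradient-boosted tree regressors map latent vectors to properties, so that
candidate molecules can be found by *sampling and scoring latent points*
rather than enumerating graphs.

The VAE maximizes the evidence lower bound with a weighted regularizer,

    L_beta = -E_{q(z|x)}[log p(x|z)] + beta * KL(q(z|x) || N(0, I)),

over fixed-shape one-hot token matrices. `beta = 1` is the standard VAE,
`beta = 0` a reconstruction-only autoencoder ("optimized AE"). The
package's central feature is *scheduling* beta during training: start high
(a well-regularized, globally structured latent space), decay toward a
small floor (late-training reconstruction fidelity). Four schedules are
implemented:

- **exponential** (default): `beta(t) = max(beta_end, beta_start * rho^t)`
  with `beta_start = 1`, `beta_end = 0.01`, `rho = 0.95`. The floor is kept
  strictly positive so the latent prior never fully decouples.
- **linear**: affine descent to `beta_end` over a configurable horizon,
  then clamped.
- **piecewise**: `beta_high` for epochs `t < T_switch`, `beta_low` from
  `T_switch` on (the boundary epoch is already low).
- **performance**: multiplicative nudges — beta is increased by a factor
  (default 1.1) when the epoch-mean KL drops below `kl_floor` (default
  `0.1 * d`, guarding against posterior collapse) and decreased when the
  epoch-mean reconstruction log-likelihood is worse than it was `window`
  (default 3) epochs earlier, clamped to `[beta_end, beta_start]`. The
  thresholds are package defaults; only the qualitative rule is canonical.

## Molecular representation

Molecules are represented as sequences over a self-referencing token
grammar (the SELFIES family of representations): bracketed atom tokens
carrying the bond order to their predecessor, plus branch and ring tokens
whose numeric payload is spelled with the same 16-token inventory in base
16. Decoding clamps every structural request against remaining valences,
so **every** token sequence — including the argmax rows of an arbitrary
real matrix — decodes to a valid (possibly empty) molecule. This totality
is what makes greedy decoding from any latent point safe. The grammar is
implemented in-package and covers neutral, closed-shell C/N/O/F molecules
(the element set of small-organic benchmark sets); encoding kekulizes and
drops stereo flags, so stereoisomers map to their flat skeleton — a known
limitation, irrelevant for the synthetic corpora, which never carry
stereo. Charged species, radicals, isotopes and multi-fragment inputs
raise errors at encoding time.

Reconstruction success is canonical-SMILES equality (RDKit
canonicalization, stereo-sensitive) between the input and the greedy
(mean-latent, argmax) decode; the reconstruction rate is the fraction of
molecules meeting it. Argmax ties break to the lowest token index; the
padding token sits at index 0 and is stripped wherever it appears.

## Architecture and training

The encoder and decoder are single-hidden-layer tanh networks over the
flattened `L x V` one-hot input (hidden width 200 by default), emitting the
posterior mean and log-variance (latent dimension `d = 64` by default;
the bundled study protocol uses 32) and per-position token logits
respectively. The implementation is plain NumPy float64 with explicit
gradients and Adam, which keeps training bit-reproducible from a single
seed (weight init, shuffling and reparameterization noise all derive from
it). Padding positions are included in the reconstruction likelihood by
default — for fixed-shape targets the pad tail is real "stop" structure —
with a masked variant behind a flag. The per-epoch history records beta
exactly as the schedule defines it, plus epoch-mean reconstruction
log-likelihood, KL, and the composite loss (the identity
`loss = -recon + beta * kl` holds for every logged epoch).

## Dataset assembly

`fusion` pools molecule sources under a configurable heavy-atom cap
(default 30; hydrogens never count), deduplicates by canonical SMILES with
first-seen properties retained (the same molecule in different solvents is
one generator record), and splits 80/10/10 with largest-remainder rounding
(so 10 records split 8/1/1 and 2280 split 1824/228/228), deterministically
per seed. Similarity-based augmentation from external compound databases
is deliberately out of the library core: any pre-fetched set enters as an
ordinary `DatasetSource`.

## Predictors

Property models are scikit-learn gradient-boosted trees (GBRT) trained on
the encoder *mean* vector (never a stochastic sample), optionally
concatenated with a 3-component solvent descriptor (dielectric constant,
dipole moment, refractive index; a small bundled table of ten common
solvents, zeros with a warning for unknown ones). A one-hot featurizer
(flattened `L x V` matrix) is available behind the same training call.
Boosting defaults: 500 rounds, depth 5, learning rate 0.05, subsample 0.8;
the bundled protocol uses 1000 rounds at depth 3 with learning rate 0.1,
which recovers smooth latent-linear targets slightly better at these
sample sizes. Training a predictor never touches generator weights (the
suite checks the checksum).

Two domain rules are fixed: a PLQY prediction counts as practically
accurate iff `|error| < 0.3 * true + 0.1` (a 30% relative band with an
absolute 0.1 floor so near-dark molecules are judged fairly), and the
bright/dark dichotomy thresholds PLQY at 0.25 with the boundary assigned
to "bright". Pearson r is reported as `None` (not NaN) when either side is
constant.

## Latent-space generation and search

- **Perturbation**: additive isotropic Gaussian noise (default sigma 0.5)
  on each seed's latent mean; distinct counting is over canonical SMILES
  excluding the seeds.
- **Interpolation**: greedy decodes along the straight line between two
  latent means; endpoints reproduce the inputs whenever the model
  reconstructs them.
- **Neighborhood search**: Gaussian draws (scale `radius / sqrt(d)`)
  rejected outside the radius, decoded, deduplicated (first hit keeps its
  distance), scored by the predictor on the decoded molecule's own latent
  mean, filtered by a synthesis-complexity cap (default score: grammar
  token count, with a hook for any external synthetic-accessibility
  score), and ranked by |prediction − target| with SMILES as a
  deterministic tie-break. No surviving candidate yields a structured
  empty report, not an exception.
- `embed_2d` exposes a t-SNE projection of latent vectors purely as a
  plotting convenience; it carries no tested numerics.

## Synthetic corpora

`fixtures` draws random token streams (atom tokens weighted 3:1 over
structural tokens), decodes, canonicalizes and deduplicates — valid
molecules by construction, at most one heavy atom per token. Labels are
synthesized with exposed ground truth: emission energy as a linear
function of the first 4 latent coordinates, standardized to a 0.4 eV
spread around 3.0 eV, plus per-solvent offsets (evenly spaced over
±0.1 eV) and optional Gaussian noise, clipped to the visible/near-UV
window [1.5, 4.5] eV; PLQY through a logistic link so both regression and
the 0.25 threshold are exercised. A size-based rule (no model needed) and
a pure-noise rule are also provided. At zero noise the labels are exactly
reproducible from the returned weights. These corpora test the
statistical machinery, not chemistry: they contain no stereochemistry, no
charged species, no realistic photophysics, and far smaller molecules than
experimental fluorophore sets, so passing tests demonstrate correctness of
the pipeline, not predictive accuracy on real materials.

## Study protocol sizes

The bundled comparison protocol (tests and `scripts/acceptance.py`) uses
500-molecule corpora (max 10 tokens), latent dimension 32, hidden width
200, 150 epochs, batch 64, learning rate 1.5e-3; perturbation sigma 0.5
with 50 samples around 20 seed molecules; predictor checks at n = 500 with
label noise 0.05 and at n = 1000 for the noise-free limit (where the
remaining error is purely the tree ensemble's approximation of an oblique
linear function); neighborhood search at radius 6 with 150 samples. These
sizes were chosen as the smallest at which the qualitative contrasts are
stable across seeds.

## Known limitations

- The grammar covers C/N/O/F without charges, stereo or isotopes; real
  fluorophore datasets (S-, Cl-, B-containing dyes) need an extended
  inventory before encoding.
- The dense architecture caps usable sequence lengths; a recurrent
  encoder/decoder would scale better but would not be bit-reproducible
  without framework-level determinism.
- At toy scale the fixed beta=1 VAE reconstructs poorly, so its perturbed
  decodes scatter widely; raw distinct counts for that variant measure
  noise as much as diversity and should be read together with its
  reconstruction rate.
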