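# Methods

## Overview

`moldesign` implements a pipeline for de novo design of bioactive small
molecules: a conditional SMILES variational autoencoder (VAE) generates
drug-like molecules; partitioned transfer learning focuses the generator on
an activity target domain; fingerprint QSAR models supply activity
predictions; and a screening stage ranks candidates and selects
synthesizable leads. All stages run offline on synthetic corpora produced by
the package's own fragment-grammar generator.

## The generator

A SMILES string is tokenized character-wise (the two-character elements `Cl`
and `Br` are kept as single tokens, which prevents the decoder from emitting
fragments of an element symbol) and framed with start/end tokens over a
corpus-derived alphabet. The encoder embeds tokens (dimension `embedding_dim`,
default 200), passes them through a stack of LSTM layers
(`encoder_rnn_layers` = 3 of width 512 by default) and maps the hidden state
at the final sequence position through two linear heads to the posterior
parameters mu and log sigma of a `latent_dim`-dimensional Gaussian (default
200). The reparameterised draw is z = mu + exp(log sigma) * eps with
eps ~ N(0, I).

The feature-property-correlation (FPC) network is a small attention module:
[z; c] — the latent code concatenated with the scalar condition property c
(the molecule's QED) — is passed through two tanh hidden layers (widths
`fpc_hidden_dims`, default 64/64) to a `latent_dim`-wide energy vector whose
softmax gives one nonnegative score per latent dimension, summing to one.
The conditioned code is the elementwise product Zc = scores * z. Because a
probability vector shrinks the code by roughly 1/latent_dim, the
`fpc_rescale` flag (off by default) multiplies Zc by `latent_dim`; the
desk-scale profile below turns it on so the decoder receives a latent signal
of usable magnitude.

The decoder receives the context [Zc; c] concatenated to the teacher-forced
token embedding at every timestep (per-step injection was chosen over
initial-state injection so the conditioning cannot be forgotten over long
sequences), runs its own LSTM stack and a linear head to alphabet-sized
logits per position.

The loss is masked mean per-token cross-entropy plus `kl_weight` times the
closed-form KL divergence of the posterior from the standard normal prior,
KL = -1/2 * sum_d (1 + 2 log sigma_d - mu_d^2 - exp(2 log sigma_d)),
averaged over the batch. An optional linear KL annealing ramp
(`kl_anneal_steps`) is available and off by default.

Training uses Adam (base rate 5e-4, betas 0.9/0.999, eps 1e-8) with the rate
multiplied by 0.97 every 1000 steps, batch size 64. Training stops at
`max_epochs` (default 8) or as soon as teacher-forced token accuracy (over
non-pad positions) exceeds the threshold delta = 0.95 for 500 consecutive
steps, whichever comes first.

Sampling draws z from the standard normal prior — the encoded latents are
approximately per-dimension normal, and the prior is the only distribution
the KL term anchors — applies the FPC network at the requested condition
value, and decodes token-by-token (greedy at temperature 0, multinomial
otherwise) until the end token or the length cap. Raw strings are returned;
validity is judged downstream.

## Autodiff backend

The recurrent networks are trained with a small reverse-mode autodiff engine
on numpy (`moldesign._autodiff`). The LSTM layer is a single fused node whose
backprop-through-time pass is hand-written, which keeps tapes short and
training fast on one CPU. Gradient correctness of every op, including the
fused LSTM, is asserted against central finite differences in the test suite
(relative tolerance 1e-4).

## Activity-domain partition

An activity dataset with per-molecule QED and IC50 (micromolar) is split into
four sub-domains: A (QED > 0.6 and ic50_min < IC50 < ic50_split), B
(QED > 0.6 and ic50_split <= IC50 <= ic50_max), C and D (the same activity
bands at QED <= 0.6). The default cut points are 1/10 uM (a cytotoxicity-type
assay) and 50/100 uM (a cell-based release assay); both presets ship as
`PartitionThresholds.CRC` and `.AD`. QED exactly at the split is
non-drug-like; IC50 exactly at the split falls in the low-activity band;
IC50 at or below ic50_min or above ic50_max is reported separately, never
silently dropped.

## Transfer learning

PTL finetunes the pretrained generator through an ordered list of stage
domains (high-activity branch: C then A). Each stage re-initialises the
optimizer with the pretraining settings (the schedule restarts; nothing in
the method requires a stage to inherit a decayed rate) and stops when the
mean epoch loss has not decreased for `impatience_n` consecutive epochs
(default 5 — the optimum is task-dependent, so it is a plain config knob),
restoring the parameters of the minimum-mean-loss epoch. A per-stage epoch
cap (default 100) bounds runtime; the plateau stop almost always fires
first.

PRTL repeats: finetune, sample `samples_per_repetition` x `repetitions`
molecules (64 x 10), qualify them (valid, deduplicated by canonical SMILES,
QED above threshold, predicted active when a model is supplied, absent from
the training and finetune reference sets), accumulate the qualifiers, fold
them into the target domain, and carry the parameters forward. The loop ends
when no molecule qualifies (the target domain does not update) or after 50
recurrences. Domain updates default to `append` (the union of the previous
domain and the new qualifiers) for stability; `replace` is available to
probe drift. The high- and low-activity branches are independent runs from
the pretrained checkpoint.

## QSAR models

Fingerprints: RDKit topological (1024 bits, path lengths 1-7), ECFP4
(Morgan radius 2, 1024 bits), Avalon (1024 bits) and Morgan-2048, all
without chirality. Feature selection is either a plug-in mutual-information
ranking (natural log; binary feature vs binary label; top-k columns with
MI > 0 kept) or a lasso fit over the alpha grid 0.001-0.1 in steps of 0.001,
keeping columns with nonzero coefficients. When selection is enabled it is
re-fit inside every CV training fold, so reported fold metrics carry no
selection leakage (this is conservative relative to a single global
selection).

Model families and search spaces: SVM (C log-uniform 0.001-1000; kernel in
{linear, rbf, sigmoid, poly}; gamma log-uniform 0.0001-8 or 1/n_features),
random forest (trees 50-100, depth 5-30, max features 5-20) and gradient
boosting (trees 50-100, depth 5-20, learning rate 0.05-0.15, subsample
0.7-1.0). Hyperparameters are tuned by seeded random search over these
distributions (the number of trials defaults to 20-50 and is configurable)
with fivefold cross-validation; classification maximises the mean of train-
and test-fold accuracy, regression minimises mean test-fold RMSE (accuracy
is undefined for regression, so the corresponding objective is read as the
error analogue). The winner is refit on all data.

Metrics: Acc = (TP+TN)/all, F1 = 2TP/(2TP+FN+FP), MRE = mean(|err|/y),
MAE = mean|err|, RMSE = sqrt(mean err^2); MRE rejects zero targets.

## Generation metrics and screening

Per sampling repetition: Validity (valid/sampled), Uniqueness
(unique-valid/valid, on canonical SMILES so respellings are duplicates),
QEDrequest (QED > 0.6 among unique-valid), Leadrequest (predicted active
among QED-qualified), Novelty (absent from training+finetune among
active-qualified), each also reported as a count via the product identities,
which equal the direct counts exactly per repetition; a report averages ten
repetitions of 64 samples. A degenerate denominator (no valid molecules,
say) defines the downstream ratio as 0 with a logged warning.

Similarity is Tanimoto on Morgan-2048 fingerprints; chemical-space maps use
t-SNE on the same fingerprints with a fixed random state. The synthetic-
accessibility score (1 = easy to 10 = hard; fragment contributions plus a
complexity penalty) is computed through the RDKit Contrib SA-score module
bundled with the installed RDKit.

Screening takes candidates with external scores: novelty against
user-supplied local reference sets (a surrogate for a commercial registry
search — it can only know what the supplied sets contain), a stable sort by
predicted pIC50 descending or docking score ascending (docking scores are
ingested from a CSV, never computed), ties broken by canonical-SMILES order,
and one pick per rank window (Top 1-10, Top 11-20) by minimum SA score.
Novelty filtering precedes ranking.

## Synthetic data

The corpus generator composes molecules from a fragment grammar: one- and
two-slot ring cores (benzene, pyridine, furan, cyclohexane, piperidine) with
drug-like substituents over C/N/O/F/S/Cl/Br. Every string is valid by
construction, is re-verified with the toolkit, and satisfies the default
filter criteria (length <= 120, 5-70 heavy atoms, element whitelist). About
10% of molecules carry a sulfur-bearing marker fragment by default;
`marker_fraction=1.0` produces marker-only target domains for transfer
experiments. The grammar's distinct-molecule capacity is a few tens of
thousands; requesting more unique molecules than it holds degrades to
duplicates with a warning.

Activity datasets draw pIC50 = 5.5 + sum of substructure-count weights
(hydroxyl 0.45, F/Cl 0.35, amide 0.5, aromatic N 0.25, sulfur 0.6) plus
N(0, sigma) noise (default sigma 0.3, a typical assay-replicate spread on
the log scale); IC50 follows as 10^(6 - pIC50) uM and binary labels
threshold IC50 at 1 uM, which lands near a balanced split under the default
rule. The generating rule is returned with the data so recovery tests can
score models against the truth. These generators emulate the structural and
statistical assumptions the pipeline needs — valid strings, a learnable
token distribution, a fingerprint-visible activity signal — and not the
property distributions of a real screening library; passing tests therefore
demonstrate correctness and learnability of the machinery, not performance
on real assay data.

## Desk-scale profile and problem sizes

Tests and the acceptance script use a reduced generator profile chosen to
train in about two minutes on one CPU: embedding 32, single 64-unit LSTM
layers, latent 16, FPC hidden 16/16, `fpc_rescale` on, `kl_weight` 0.02,
learning rate 1e-3, 300 epochs over a 500-molecule corpus. The small KL
weight with rescaled FPC conditioning keeps the posterior informative (pure
prior matching collapses the posterior and caps teacher-forced accuracy at
the decoder's language-model ceiling) while keeping prior samples decodable.
Transfer experiments finetune on an 80-molecule marker domain (plateau
patience 5, epoch cap 60) and compare marker prevalence over 640 samples.
QSAR experiments use 200-250 molecules with 5-10 search trials.

## Known limitations

- The full-scale configuration (3x512 LSTM stacks, latent 200, millions of
  molecules) is supported by the same code paths but is not exercised by the
  test suite; numbers from the desk-scale profile do not transfer to it.
- Sampling validity of the desk-scale generator is in the 50-85% range, far
  below what large-corpus pretraining achieves; the metric cascade treats
  invalid strings as ordinary attrition.
- The exact token alphabets of large public corpora depend on the corpus;
  the builder grows the alphabet to fit whatever it is given rather than
  targeting a fixed size.
- Uniqueness deduplicates within each repetition (matching the per-sample
  framing of the metric definitions), not across repetitions.
- No structure standardisation beyond canonicalisation: salts, tautomers and
  stereo-normalisation are out of scope.
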