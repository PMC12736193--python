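# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `agentmol`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model and preprocessing

The atomic record is a ligand–protein pair: a SMILES string, an uppercase
one-letter amino-acid sequence, and an affinity as Ki (nM) and/or pKi. The
transform is the standard molar-scale convention

    pKi = −log10(Ki[M]) = 9 − log10(Ki[nM]),

monotonically decreasing in Ki; its inverse is `Ki = 10^(9−pKi)`. Filtering
keeps pairs with combined SMILES+protein length ≤ 800 characters and
pKi ≤ 10 (both bounds inclusive: the exclusions are "more than 800" and
"greater than 10"), preserving row order; duplicates are retained. The
70/30 split shuffles with a caller-supplied seed and assigns
`floor(0.7·n)` pairs to training. Summaries report mean, sample sd
(ddof = 1; defined as 0 for a single record, so a singleton dataset has a
well-defined, degenerate summary), min/max and linearly interpolated
quartiles of pair length and pKi.

## Tokenization

Two encoders serve the two networks:

* **BPE tokenizer** (language model). Trained from scratch on
  `protein SMILES` lines: whitespace pre-tokenization (so protein and
  SMILES tokens never merge across the separator), greedy merging of the
  most frequent adjacent symbol pair until the vocabulary budget
  (default 30,000) is reached or no pair attains the minimum frequency
  (default 2). Specials are `<bos> <eos> <pad> <unk>`; the literal space is
  itself a vocabulary token, which makes decoding an exact inverse on
  corpus text. Unknown characters encode to `<unk>` (no byte-level
  fallback). Training examples are laid out
  `<bos> protein <space> smiles <eos>`, padded or hard-truncated to 128
  tokens with a truncation flag kept for corpus diagnostics; a generation
  prompt is the unpadded prefix `<bos> protein <space>`. Protein-first
  order is forced by autoregressive conditioning: the model must see the
  target before emitting the ligand.

* **Character vocabulary** (regressor). Distinct characters of the corpus
  (protein then SMILES, first-seen order) get ids 1..K, capped at 70, with
  0 reserved for padding; more than 70 distinct characters is an error
  naming the surplus. A pair encodes as the separator-free concatenation
  protein+SMILES mapped character-wise, unknown characters to 0,
  post-padded/truncated to exactly 800 positions.

## Chemical language model

A decoder-only transformer (pre-norm blocks, learned positional
embeddings, causal multi-head attention, GELU MLPs, weight-tied output
head) trained with the shifted next-token cross-entropy objective, pad
targets masked. The optimizer is AdamW (decay 0.1 on matrix-shaped
parameters) under a linear-warmup + cosine-decay schedule; gradient
accumulation is supported. The default configuration mirrors the
full-scale recipe (10 epochs, batch 64, lr 5e-4, 1000 warmup steps,
accumulation 8, eval every 5000 steps, 1024-token context).

At fixture scale those settings are miscalibrated — 1000 warmup steps
exceeds the ~130 total optimizer steps of a 200-pair/10-epoch run, so the
learning rate would never leave the warmup ramp. `tiny_clm_config()`
(2 layers, 4 heads, width 64, batch 16, lr 1e-3, warmup 20, no
accumulation) is the preset used throughout the tests;
`full_scale_clm_config()` exposes a GPT-2-small-like 12×12×768 preset
whose depth/width are our choice, since only the context window is pinned
by the recipe.

**Sampling.** The prompt is `<bos> protein <space>`; up to
`max_new_tokens` (default 100) tokens are sampled at the configured
temperature (default 1.0), stopping at `<eos>` when early stopping is on —
early stopping is a sampling-termination rule here, not a training
criterion. Temperatures ≤ 1e-6 switch to greedy argmax decoding. Only the
newly generated tokens are decoded. Determinism is per-seed; batch
generation derives independent per-item seeds from the batch seed.

**Trimming repair.** Raw samples over-generate. The repair removes one
*character* (not token) at a time from the end until RDKit's sanitizing
parser accepts the string or it becomes empty; an already-valid string is
returned unchanged, and the output is always a prefix of the input.
Because the training layout contains a separator, anything from the first
whitespace onward is dropped before trimming (a SMILES cannot contain
whitespace). The empty string is never valid. This guarantees validity
1.0 among non-empty repaired outputs — which is exactly what the
acceptance script measures — while the *pre-trim* validity fraction is
logged per batch as a diagnostic.

## Affinity regressor

Architecture, in order: embedding (vocab ≤ 71 → 8 dims); six blocks of
[1-D convolution, kernel 8, "same" padding → batch normalization → leaky
ReLU (slope 0.01) → max-pool (size 2)], filter counts (32, 32, 32, 64, 64,
64) — the simplest monotone assignment spanning the stated 32–64 range;
positions 800 → 400 → 200 → 100 → 50 → 25 → 12 (floor division on the odd
length); flatten (12 × 64 = 768) → dense 512 → dense 10 (both leaky ReLU)
→ linear scalar. Batch norm precedes the activation (the conventional
order); inference uses running statistics with momentum 0.9, chosen so the
statistics converge within the few hundred optimizer steps of a
fixture-scale run, and makes prediction independent of batch composition.
Conv "same" padding for the even kernel pads 3 left / 4 right. Training is
RMSprop (lr 0.001, rho 0.9) on MSE or MAE; per-epoch history records
training loss and inference-mode validation loss/RMSE/R²/R.

Evaluation metrics are the field's standard trio: sample Pearson R
(undefined and rejected for constant targets), R² = 1 − SS_res/SS_tot, and
RMSE. The repeat protocol re-splits 70/30 with per-repeat seeds, trains a
fresh model per split, scores both sets after the first and final epoch,
and reports mean and sample SD per metric.

## Synthetic fixtures

The generator emulates paired affinity records, not BindingDB chemistry:

* **SMILES** are assembled from a closed grammar — optional ring scaffold
  (cyclohexane, benzene, cyclopentane or none), `depth` chain segments from
  {C, CC, CCC, N, O, C(C), C(N), C(O), C(=O)}, optional terminal
  (Cl, F, O, N, C) — every composition of which is valence-legal, so
  generated strings are valid by construction.
* **Proteins** are uniform random strings over the 20-letter alphabet with
  lengths in a configurable range.
* **Affinity** is `clip(2 + 1.5·#N(smiles) + 6·frac_K(protein) + ε, 0, 10)`
  with Gaussian noise ε; the clip range mirrors the pKi ≤ 10 exclusion
  bound. Ki is back-computed through the inverse transform so the
  round-trip is exact, and every fixture pair passes the default filters.

Defaults (chosen once): grammar depth 3, protein lengths 10–50, noise 0.
Short proteins keep fixture-scale training cheap while giving the
K-fraction term real variance; depth 3 spreads the nitrogen count over
0–4, so the affinity signal has sd ≈ 1.2 dominated by a character-count
term both networks can represent. Because the signal is a pure
character-count function, recovering it demonstrates that the training
loop, encodings and backpropagation are correct — it does **not**
demonstrate that the architecture captures real structure–activity
relationships, pharmacophores or 3-D binding determinants, which the
fixtures deliberately lack.

## Scaled-down study conditions

All tests run on one CPU at fixture scale, as the package's own standard
conditions: the language model trains on 200 pairs (seed 7) for 10 epochs
and generates from 100 protein prompts; the signal-recovery experiment
trains the regressor on 500 noise-free pairs for 30 epochs with batch 16
and MAE loss, reaching validation Pearson R ≥ 0.9 — MAE with small batches
recovers the signal more reliably at this n than MSE/batch-32 (more
optimizer steps per epoch; robustness to the clipped-target tails), and
both losses are first-class in the reference protocol. The memorization
checks use a single repeated pair (language model) and five pairs with
non-degenerate target spread (regressor).

## Agent orchestration

The pipeline threads a mutable state through fixed stages: retrieve →
extract names → choose first name → fetch first sequence → generate →
trim → predict. Providers (LLM, retriever, sequence source) are plain
callables behind a bundle, with file-backed mocks so the graph runs
offline; the extraction prompt appends a fixed instruction asking for
`*`-bulleted protein name abbreviations, and the parser keeps only
bulleted lines, deduplicating while preserving order. The LLM is invoked
once over the concatenated abstracts. "Best match" selection is
first-listed name, and the first sequence record wins, uppercased and
validated against the amino-acid alphabet (plus X). A failing stage
appends a failure to the trace and halts downstream stages without
raising; an empty trimmed SMILES completes with a warning and no pKi.
Given fixed providers, models and seeds the pipeline is a pure function of
its inputs.

## Known limitations

* Character-level trimming guarantees syntactic validity, not chemical
  sensibility; one-atom survivors (e.g. a lone halogen) count as valid.
* With near-constant targets, batch-norm's running-statistics offset
  bounds how exactly the regressor can memorize a tiny set.
* The BPE tokenizer has no byte-level fallback: unseen characters become
  `<unk>` and are unrecoverable on decode.
* The internal-diversity definition (radius-2/2048-bit Morgan, Tanimoto)
  is one field-standard choice among several; absolute values are not
  comparable across fingerprint settings.
* Paper-scale presets (GPT-2-small dimensions, 200-epoch regressor
  training, batch 256) are provided by configuration but not exercised by
  the tests, which run entirely at fixture scale.
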