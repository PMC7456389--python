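# Methods

## The problem

Chinese breast-cancer treatment narratives mention chemotherapy regimens
in author-specific surface forms: the regimen canonically called `EC-TH`
may appear as `EC ×4-TH ×4` (cycle multipliers), `EC 序贯 TH` (a Chinese
connective standing in for the hyphen), or with component letters permuted
(`CEF ×3-P ×3` for `FEC-P`).  Treatment entity *normalization* (TEN) maps
every such mention onto a controlled vocabulary of canonical regimen
names.  Because Chinese has no word boundaries and the text freely mixes
scripts, the task is posed at the character level: each character of a
sentence receives either `"O"` or the canonical name of the regimen whose
mention contains it.  The auxiliary *recognition* task (TER) tags the same
characters with BIO mention-boundary tags.  A predicted mention counts as
correct only under exact match: canonical label, start index and end index
(0-based, half-open) must all equal a gold span's.

## Model

The model is a pseudo-cascade: the auxiliary head's output is fed into the
primary head's input, but the two are trained jointly rather than as a
pipeline, so recognition errors are soft (a probability distribution)
rather than hard commitments.

1. **Embedding.**  Each character index selects a row of a learned
   embedding matrix (d_e = 200).  Index 0 is padding and its row is pinned
   at zero; index 1 is the unknown character.
2. **Gated convolutional encoder.**  Four 1-d convolutional layers of
   kernel width 3 with filter widths (128, 256, 256, 256).  Every layer is
   a gated linear unit: two parallel convolutions B = C∗W+b and G = C∗M+g
   combine as h(C) = B ⊙ σ(G).  Layer 1 projects the embedding width to
   128 with no residual path; a 1×1 linear projection lifts 128 → 256, and
   layers 2–4 are residual blocks (output C + h(C)) at width 256.  This
   wiring realizes both stated counts — four convolutional layers and
   three residual blocks — with width-consistent residual sums.
   Convolutions use symmetric zero "same" padding: the task is offline
   labeling, so non-causal context is available.  The stack's receptive
   radius is 4·(3−1)/2 = 4 characters on each side.
3. **Auxiliary recognition head.**  A linear layer plus softmax over the
   three BIO tags per position.
4. **Fusion.**  The full TER probability vector is concatenated onto each
   256-dim context vector (fused width 259).  Fusing the distribution
   rather than an argmax one-hot keeps the cascade differentiable
   end-to-end; hard one-hot fusion is available behind a config flag.
   No gradient blocking is applied between the heads.
5. **Linear-chain CRF.**  Emissions are a linear projection of the fused
   vectors; the score of a labeling adds adjacent-label transition
   parameters T[y_i, y_{i−1}].  There is no start/stop state: the first
   position contributes its emission only.  The partition function is
   computed by the forward algorithm in log space (log-sum-exp at every
   step); decoding is Viterbi with ties broken toward the lowest label
   index, which makes decoding deterministic.  Padded positions are
   excluded from both the gold-path score and the recursions.

Single-task ablations drop the auxiliary head (CRF on the context vectors
alone) or replace the CRF with an independent per-character softmax.

## Losses

* **TER loss** is the element-wise binary cross-entropy between the gold
  one-hot tags and the predicted distribution, exactly as the objective is
  stated — not the categorical cross-entropy, although that variant is
  available behind a flag.  Probabilities are clamped to [1e-7, 1−1e-7].
* **TEN loss** is the CRF negative log-likelihood, log Z − score(gold).
* **Biased loss** L_BL = γ·L_TEN + (1−γ)·L_TER with γ ∈ (0, 1), default
  0.9 (the best-performing value of the published sweep).  Both component
  losses are summed over positions but *averaged over the sentences of a
  batch*, so γ keeps the same meaning at any batch size; a sum reduction
  is switchable.

## Training

Everything is plain numpy with hand-derived backward passes: im2col
convolutions, softmax/GLU chain rules, and forward–backward CRF gradients
(emission gradient = marginals − gold one-hots; transition gradient =
expected − observed transition counts).  The test suite verifies every
variant's joint gradient against central finite differences at float64.

The optimizer is standard Adam (the lazily-updated variant it stands in
for differs only in sparse-embedding update scheduling, not semantics).
Parameters are Xavier-initialized, biases zero.  Dropout 0.5 is applied to
each block's output — after the residual sum — during training only.
Early stopping monitors validation entity-F1; the best-validation
checkpoint is returned.

Two presets:

| preset | batch | lr    | max epochs | intended regime |
|--------|-------|-------|------------|-----------------|
| paper  | 256   | 1e-3  | 30         | ~200k-sentence corpora |
| desk   | 32    | 5e-3  | 20         | single CPU, ~2k sentences |

The desk preset raises the learning rate because Adam steps have magnitude
≈ lr regardless of gradient scale, so total parameter movement is bounded
by lr × number of updates.  A 2,000-sentence corpus at batch 32 sees ~63
updates per epoch — an order of magnitude fewer than the reference regime
— and the CRF transition penalties that veto label switches inside long
mentions (whose tails lie outside the encoder's receptive radius) need
room to grow to veto strength within the epoch budget.

Batches are built by sorting sentences into length buckets (shuffled
bucket order, random tie-break within equal lengths) and padding only to
the longest sentence in the batch.  This is purely an efficiency choice —
all losses are masked — and the masking-invariance tests assert that
padding content cannot influence any valid position.

Numerical guards: gate pre-activations are clipped to ±30 before the
sigmoid, and sub-1e-30 float32 gradient entries are flushed to zero before
the convolution backward GEMMs.  Both are far below signal scale; the
flush exists because denormal floats push BLAS onto a slow scalar path.

## Synthetic data

The generator emulates the statistical structure of real treatment
narratives without any clinical data:

* **Templates** — 24 short bilingual narrative templates (rendered length
  roughly 10–120 characters) with zero, one or two mention slots, shipped
  as a package data file.
* **Regimen vocabulary** — 10 canonical names (AC, EC, TH, EC-TH, AC-T,
  FEC-P, FEC-T, EC-T, TC, TAC), small enough for brute-force CRF oracles
  yet containing confusable pairs (EC-T vs FEC-T vs AC-T) that exercise
  the same error modes reported for real data.
* **Surface variants** — deterministic rules: cycle multipliers (`×2/3/4/6`,
  one value per mention), Chinese connectives replacing the hyphen,
  fixed-table component permutations (FEC↔CEF, TAC↔TCA), whitespace
  variants, and rule combinations.  Variant 0 is always the canonical
  form; every variant maps unambiguously back to its canonical regimen.
* **Mention count** per sentence ~ Binomial(2, rate/2), mean
  `mention_rate` (default 1.2).
* **Noise** — with probability `noise_rate` (default 0.1) one typographic
  perturbation outside gold spans: drop a punctuation connective,
  duplicate a space, or substitute a visually similar ASCII character.
  Spans are shifted through insertions/deletions so gold labels stay exact.
* **Splits** — patients are partitioned 8:2 into train and test pools
  before any sentence is drawn, so no patient contributes to both;
  validation sentences (10% of the training pool) come from training
  patients only.  Explicit per-split sentence counts can override the
  ratio-derived counts.  Identical config + seed gives byte-identical
  corpora.

What the generator does *not* emulate: real narrative diversity (24
templates vs unbounded clinical prose), label noise from imperfect human
annotation, out-of-vocabulary regimens, sentence-length distribution out
to 256 characters, and cross-sentence context.  Passing the synthetic
end-to-end test therefore shows that the architecture, losses, inference
and evaluation machinery work and that the cascade beats the single-task
softmax baseline under controlled conditions — not that the model reaches
any particular accuracy on real clinical text.

## Scaled experiment sizes

The end-to-end experiment trains on 2,000 / 200 / 500 generated
train/valid/test sentences (corpus seed 7) with the desk preset — sizes
chosen so a full multi-seed comparison runs on one CPU core in minutes.
At this scale the full cascade reaches mean entity-exact-match F1 ≥ 0.90
over three training seeds and clearly dominates the single-task softmax
baseline (~0.45), reproducing the direction of the published single- vs
multi-task comparison at two orders of magnitude less data.

## Degenerate inputs and conventions

* Sentences longer than 256 characters are truncated with a warning
  (reader and batch encoder both).
* Empty corpus files parse to empty corpora; an empty training corpus is
  an error.
* Precision (recall) is defined as 0 when there are no predictions (no
  gold spans); F1 is 0 when both components are 0.  Scores are
  micro-averaged over the corpus.
* Duplicate identical predicted spans are counted once, with a warning.
* The outside label `"O"` is pinned at index 0 of the label set, so the
  all-zero model decodes every character to "outside".

## Known limitations

* CPU-only numpy training: practical up to a few thousand sentences; the
  paper-scale regime (hundreds of thousands of sentences) would need hours.
* No pretrained embeddings or external domain knowledge; characters seen
  fewer than `min_count` times fall back to a single UNK vector.
* The CRF has no start/stop parameters; for length-1 sentences the model
  reduces to a per-character classifier.
* Two adjacent mentions of the same regimen are separable only through
  the TER "B" tag; without TER tags they merge into one span.
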