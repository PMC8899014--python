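# Methods

## Problem

Given the free-text discharge summaries of a hospital admission, predict
a binary clinical event (re-admission or death within some horizon).
Admission documents are long — around 2,000 tokens on average — while
attention-based encoders process a bounded window (512 tokens in the
clinical preset), so the central modelling question is how to combine
per-window encodings into one document decision. `longnote` implements
the full model ladder (bag-of-words → mean-pooled n-gram embeddings →
CNN/GRU → windowed attention encoder with seven segment-combination
heads), the shared evaluation protocol, and a synthetic corpus generator
that makes every mechanism testable without access to restricted
clinical records.

## Text preparation

Multiple summaries per admission are concatenated in dataset order,
joined by a single space (the separator is not semantically meaningful;
a single space keeps token counts predictable). The tokenizer is a
deterministic word-level scheme — lowercase; letter runs, digit runs,
apostrophe suffixes and single punctuation marks as tokens — chosen so
the package has no dependency on external subword vocabularies; a
subword tokenizer can be plugged in through the same interface.
Vocabulary admission requires unigrams to appear in at least
`min_doc_freq` documents (default 10) and n-grams (orders 2..n_max) to
reach `min_count` occurrences (default 5). No stemming, no stopword
removal, no weighting. Out-of-vocabulary tokens are dropped at encoding
time. Documents are cut into non-overlapping windows; concatenating a
document's segments reproduces its token sequence exactly, a property
the tests enforce.

## Models

**Bag-of-words.** Unigram counts (word order discarded) feed a logistic
regression with L2 regularization (scikit-learn's solver; objective
`sum CE + l2/2·||w||²`, intercept unpenalized). A squared-error-on-
sigmoid variant exists behind `loss="squared"` for fidelity comparisons,
because the two readings of "logistic regression minimizing L2 loss"
differ; the cross-entropy reading is the reference.

**Mean-pooling n-gram embeddings.** Every vocabulary unit (unigrams and
n-grams up to order 3) owns a trainable vector; a document is the
arithmetic mean over unit *instances* (duplicates count), fed to a
2-way softmax layer. Empty documents pool to the zero vector so scoring
is total. No subwords, no pretrained vectors.

**CNN / GRU baselines.** The CNN is embeddings → parallel convolutions
of widths {3,4,5} (100 maps each by default) → max-over-time →
dropout → linear; pooling only considers windows fully inside the true
sequence, making scores invariant to batch padding. The recurrent
baseline is a GRU read out at the final (length-masked) state.

**Attention encoder.** Layer i output is
`v'_i = tanh(W · Σ_t α_t v_t)` with
`α_t = softmax((v_i · W' v_t)/√D)`: a single attention head, no
residuals, no layer norm, no feed-forward sublayer — the bare
mechanism, implemented literally. Consequences worth knowing: all
layer outputs lie strictly in (−1,1), and without residual paths deep
stacks train slowly, which is why the presets keep L small. The √D
scaling is the standard convention. Positional embeddings are learned
rows added to token embeddings; a reserved CLS id occupies position 0
and its top vector carries the segment decision `argmax(W₁·v₀)` (ties
toward label 0). A `block="standard"` mode (residual + layer norm)
exists for robustness studies and is not the reference path. Two
forwards exist — a per-segment NumPy path and a padded-batch autodiff
path — and the tests pin them to each other and to a brute-force
double-loop oracle at 1e-6.

**Segment-combination heads.** Documents are windowed (window − 1
content tokens per segment, one slot for CLS) up to `max_segments`
(default 6, covering ~2,000-token documents at window 512; longer
documents are tail-truncated). Seven heads produce `v_d`: LSTM over CLS
vectors; LSTM over all top-layer vectors (frozen encoder required —
backpropagating through every position is the expensive case);
concatenation of all top vectors (also frozen by default, relaxable by
flag); concatenation of CLS vectors; elementwise mean, min and max of
CLS vectors. Concatenating heads pad with zero encodings to exactly S
segments; recurrent heads stop at the last real segment. With a frozen
encoder, encoder tensors are excluded from the optimizer entirely, so
freezing is exact (bitwise), not approximate.

**Fusion.** Non-text admission attributes are flattened into a
fixed-order boolean vector by a rule schema (thresholds and category
membership; missing values encode 0; treatment descriptors excluded).
The attribute-only model is a single softmax layer. The combined model
concatenates the bits after the head's document representation, before
the final classifier, trained end to end. The clinical preset schema
has dimension 255 with realistic attribute families; its category
values are synthetic placeholders.

## Training and evaluation protocol

All neural models train with Adam (default step 1e-3; the document
models use 3e-3, chosen for reliable convergence within the fixed
budget), batch size 32, for exactly 5 epochs; the epoch snapshot with
the highest validation AUC is restored and the test AUC computed once.
Splits are 75/10/15 with whole admission groups confined to one
partition; target sizes follow largest-remainder apportionment, so
1,000 singleton groups split exactly 750/100/150. Training sets are
balanced by oversampling the minority class in whole without-replacement
passes plus one final without-replacement draw (the only procedure
consistent with "random oversampling without replacement"); validation
and test stay unbalanced. AUC is the Mann-Whitney pair statistic with
half credit for ties — identical to trapezoidal ROC integration but
with a trivially verifiable oracle. Model comparison uses a paired
stratified bootstrap (default 2,000 replicates) of the AUC difference
with a two-sided p-value; repeated-resplit cross-validation is available
with a configurable repeat count (default 5).

Every source of randomness (corpus generation, initialization, batch
order, dropout, oversampling, bootstrap) flows from explicit seeds;
same-seed runs reproduce losses exactly.

## Synthetic corpora

The generator reproduces the *shape* of an admission corpus — document
lengths lognormal around a configurable mean (clinical preset 2,000
tokens), Zipf(1.1) background vocabulary, rare positive labels with
presets matching the published per-target prevalences (e.g. 7-day
re-admission ≈ 0.0241) — and plants a known class signal: positives
receive K ~ Poisson(λ) reserved signal tokens, λ = base_rate·(e^β − 1),
placed uniformly, in the head window, in the tail window, or in a
chosen segment. Labels optionally flip with probability ε. Attribute
bits depend on the true label through per-attribute log-odds,
independent of the text signal, so fusion gains are provable.

Because signal tokens never occur in background text, the exact
posterior is monotone in the signal count and the best achievable AUC
(`bayes_auc`) is computable by enumeration; with ε = 0 it equals
1 − P(K=0)/2. Trained models are tested to approach this ceiling from
below, and placement controls let position-sensitive and position-blind
models disagree in predictable directions.

What the generator does **not** emulate: syntax, discourse structure,
correlated or distributed signal phrases, subword noise, and label
signal carried by word *order*. Passing tests therefore demonstrate the
mechanics (optimization, pooling, placement sensitivity, leakage
control, calibration) — not clinical-grade performance on real notes.

## Reference experiment conditions

Desk-scale experiments use the test-scale encoder preset (D=32, L=2,
window 64, LSTM hidden 32) on corpora of 1,200–2,000 documents with
lengths of roughly 3–4 windows, prevalence 0.3, and β = 2.0 (Bayes
ceiling ≈ 0.98) for the recovery, placement and head-comparison
experiments; the fusion experiment uses single-window documents with
β = 1.2 and 12 attribute bits of comparable strength. At these
conditions the encoder + LSTM-over-CLS pipeline recovers the planted
signal to within 0.02 of the ceiling, tail-placed signal gives the
tail-window model a ≥ 0.15 AUC advantage over the head-window model,
and the fused model matches or beats the best single modality.

## Numerical choices and edge cases

Float64 throughout (gradient checks at 1e-4 relative need the
headroom). Softmax and log-sum-exp are max-shifted. Attention over
padded positions is masked with additive −1e30 before the softmax;
min/max segment pooling masks padding the same way. Empty documents
yield one CLS-only segment. Ties in `argmax` readouts break toward
label 0; AUC ties earn half credit. `pad_or_truncate` keeps the first S
segments and zero-pads on the right. Oversampling with an already
balanced training set is the identity.

## Known limitations

No pretrained-weight import (the simplified block's shapes differ from
standard transformer checkpoints); no subword tokenization out of the
box; single-label targets only; the literal attention block without
residuals is not meant to be competitive on real corpora at depth; CNN
scores for sequences shorter than the widest filter see one
padding-containing window.
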