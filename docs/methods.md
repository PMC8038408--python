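# Methods

## Model

`fragnet` couples a SimCLR-style contrastive objective with a sequence
autoencoder over SMILES.

**Augmentation.** A molecule's canonical SMILES is re-written from a
uniformly random atom permutation (`RenumberAtoms` + non-canonical
writer), giving an alternative string for the same molecular graph.
Each training example is a pair of two independent enumeration draws of
one molecule; the two draws are retried up to 10 times to be textually
distinct, after which duplicates are accepted (small or highly
symmetric molecules such as benzene admit only one string, so strict
distinctness cannot be guaranteed).

**Encoder.** Token embedding (atomwise tokens: bracket atoms, Cl/Br,
ring digits, bonds, branches) plus sinusoidal positional encoding
(PE[pos, 2i] = sin(pos/10000^{2i/d}), PE[pos, 2i+1] = cos(·)), followed
by `n_blocks` post-norm transformer blocks (multi-head self-attention →
add & norm → position-wise feed-forward → add & norm). Padded positions
are excluded from attention as keys, so appending padding never changes
the representation of real tokens.

**Projection head.** The L × d_model representation is flattened (pad
rows zeroed first, making the latent independent of padding) and passed
through four affine layers, each followed by ReLU — the last included.
The final ReLU is deliberate: it permits exact zeros in the latent
vector, which is what makes the dimension-population (sparsity) traces
well defined. Hidden widths default to [4·d_model, 2·d_model, d_model],
a geometric taper; they are a configuration knob (`proj_hidden`), not a
claim.

**Contrastive loss.** NT-Xent over the 2N projections of a batch of N
molecules, with cosine similarity and temperature τ:
ℓ(i,j) = −log[exp(sim(z_i,z_j)/τ) / Σ_{k≠i} exp(sim(z_i,z_k)/τ)],
averaged over all 2N anchors. The implementation is numerically
stabilized by max-subtraction; a cosine involving a zero vector is
defined as 0 and logged (possible in principle with an all-ReLU head).
Both views pass through one weight-shared encoder.

**Unprojection and decoder.** The unprojection head mirrors the
projection (three affine+ReLU layers, one final linear layer — the
decoder memory must not be sign-restricted) and reshapes to
L × d_model. The decoder stacks `n_blocks` blocks of causally masked
self-attention, cross-attention whose K and V come from the
unprojection memory, and a feed-forward sublayer, each with add & norm;
a final linear + softmax yields per-position token probabilities.
Reconstruction is teacher-forced: position t predicts token t+1 of the
view's own augmented input, with pad positions excluded from the
cross-entropy. Greedy decoding runs autoregressive argmax from the
start token and stops at the first end token.

**Total loss** is `contrastive_weight · L_NTXent +
recon_weight · L_CE`, both 1 by default; setting either weight to 0
recovers a pure-contrastive or pure-autoencoder model.

## Implementation

The network, losses and Adam optimizer are implemented in numpy on a
small reverse-mode autodiff engine (`fragnet.autodiff`) written for
exactly the operator set the model needs (broadcast arithmetic, batched
matmul, softmax/log-softmax, layer norm, embedding scatter, fused
masked token cross-entropy). Every operator's gradient is verified
against central finite differences in the test suite. Training is
bit-reproducible on fixed hardware: one master seed fans out (via
`SeedSequence.spawn`) into independent streams for weight
initialization, shuffling/splitting, and augmentation.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| d_model | 64 | embedding width = latent dimensionality |
| n_blocks | 4 | encoder and decoder depth |
| n_heads | 4 | attention heads per block |
| dropout | 0.20 | applied to embeddings, attention, sublayer outputs (training only) |
| temperature τ | 0.05 | NT-Xent sharpness; smaller τ tightens clusters |
| learning_rate | 1e-5 | Adam step size |
| ff_dim | 4·d_model | feed-forward width (standard transformer ratio) |
| epochs | 1 | single-pass ("one-shot") regime |
| recon/contrastive weight | 1.0 / 1.0 | loss mixing |

The 3:2 train/validation split and drop-last batching reproduce the
reference arithmetic: 4,643 molecules at batch 50 give 92 batches;
150,000 at batch 20 give 7,500; a 5/6 fraction of 150,000 gives
125,000/25,000.

The desk-scale experiment configurations used by the tests and the
acceptance script override the defaults where the mechanism, not the
production schedule, is under test: learning rate 1e-3 (1e-5 is far too
slow for a few hundred steps), d_model 32, max_len 24–64. The
memorization run (5 short molecules, 2,000 steps, dropout 0 — it is an
overfitting probe) is scored by exact greedy round-trip of the
canonical SMILES; the clustering run (24 molecules in 3 scaffold
families, τ = 0.05, 700 steps, batch 8) is scored by within- versus
between-family cosine similarity of canonical-SMILES latents and by
held-out positive- versus mismatched-pair cosine.

Both experiments are evaluated as single seed-pinned training
trajectories, not seed-averaged statistics: at a few hundred to a few
thousand steps the outcome of so small a run varies with
initialization, and exact-string round-trip is a deliberately strict
score — a near-miss typically decodes to a *different valid SMILES of
the correct molecule* (the contrastive term pulls enumerated views of
one molecule together in latent space, so the decoder may emit a
non-canonical variant). The acceptance script therefore reports the
same-molecule round-trip count alongside the exact-string count.

## Synthetic corpora

The generator instantiates ring scaffolds (benzene, cyclohexane,
pyridine) with substituents drawn without replacement from a fixed
pool, validating and canonicalizing every member. It emulates the one
property the contrastive experiments need from real chemical corpora:
within-family structural (Tanimoto) similarity strictly exceeds
between-family similarity, which the test suite asserts. It does *not*
emulate the size distribution, functional-group diversity, stereo
chemistry or property distributions of real drug/metabolite/natural
product collections — passing tests show the mechanism recovers planted
family structure at desk scale, not that the learned space reproduces
any particular large-corpus embedding.

## Numerical choices and edge cases

- "Nonzero" in the dimension-population traces means |v| > ε with
  ε = 0 by default — exact zeros are produced by the ReLU head;
  ε is configurable for thresholded variants.
- Neighbor ranking ties break lexicographically by molecule id
  (deterministic output ordering).
- Histogram bins are equal-width over the observed range of one
  dimension; representatives per bin are the ids nearest the bin
  center. A constant column degenerates to a single occupied bin.
- Over-length molecules raise an error naming the offender — silent
  truncation would corrupt the round-trip contract.
- Cross-entropy over an all-masked target raises instead of returning
  0/0.
- Fingerprints are RDKit path-based (`RDKFingerprint`), 2048 bits,
  max path 7, configurable; Tanimoto values are fingerprint-relative,
  so tests compare against set arithmetic on the extracted bit sets
  rather than frozen constants.

## Known limitations

- Desk-scale only: pure-numpy training is single-threaded; the
  configurations above train in minutes, but corpora of 10⁵ molecules
  would need a GPU framework.
- Greedy decoding may emit invalid SMILES for latent vectors far from
  the training distribution; callers should validate.
- The latent space is not an invariance class: a molecule and its
  enumerated variant embed to *different* (if nearby, after training)
  vectors, since nothing architectural forces string-order invariance.
- Parameter totals depend on the unspecified projection-head widths,
  so no particular parameter count is targeted.
- Whether tokenization should be atomwise or character-level is
  empirically undecidable from vocabulary sizes alone; atomwise is the
  default, a character-level fallback exists in the tokenizer's
  single-character path.
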