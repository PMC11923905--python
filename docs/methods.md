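# Methods

## The diffusion model

The package's core quantity is the diffusion profile: the expected signed
perturbation a drug induces at every gene of a fixed universe when its
effect propagates from its targets through a signed interaction network.

The walker is a multi-start random walk with restart and geometric decay.
Each target T is an independent start point carrying Sign(T) ∈ {+1, −1}.
Per step, restart happens with probability α; otherwise a uniformly random
incident edge is traversed and βⁿ · Sign(T) · (−1)^parity is added to the
node reached at step n, where parity counts inhibitory edges since the
last (re)start.  Defaults: α = 0.3, β = 0.95, 15 epochs of 15 steps per
target.

Semantics that the update rule alone does not pin down, resolved here as
follows:

- **Restart** teleports to the start gene, deposits nothing, resets the
  parity, and still consumes a step — the decay index keeps advancing.
  This keeps the deposit formula literally true for every maximal
  restart-free path segment.  (`DiffusionConfig` exposes no alternative;
  the choice is part of the model.)
- **Direction** — edges are walked both ways on undirected networks and
  along out-edges only when the network is flagged directed; a node with
  no walkable edge forces a restart.
- **Aggregation** — epochs and targets *sum*, never average, matching the
  accumulation used for combinations ("without resetting values between
  drugs").  Profile scale therefore grows with epochs and target count;
  the scorer is always trained on profiles produced under one
  configuration.  No normalisation is applied.
- **Universe alignment** — the network may contain nodes outside the gene
  universe; they participate in the walk (paths may pass through them)
  and are dropped only at projection.  Universe genes never visited score 0.
- **Randomness** — each (drug key, target gene) pair derives its own
  substream from the global seed via CRC32 hashing into a `SeedSequence`.
  Consequences: combination profiles equal the elementwise sum of member
  profiles bit for bit, are invariant to drug order, and every run is
  reproducible from one integer seed.

`expected_profile_oracle` computes the exact expectation by iterating the
transition operator on the lifted state space (node × parity): restart
mass α (plus all mass on sinks) moves to (start, 0) without depositing;
(1−α)/deg spreads over incident edges flipping parity on inhibitory ones;
arrivals at step n contribute βⁿ·Sign(T)·(−1)^parity.  Cost is
O(steps · (2|V|)²) — a verification and signal-planting tool for networks
up to a few hundred nodes, not a production path.

## Classifiers

Both neural stages are compact feed-forward networks implemented on NumPy
with Adam (weight decay added to the gradient), batch normalisation on
hidden layers, inverted dropout, and full seeding; identical data and seed
reproduce identical parameters.

**Target calling** (activation / inhibition / irrelevant): input is the
600-d concatenation [drug 300 | gene 300], architecture 600→1024→3 with
ELU, 20% dropout, focal loss (1−p_t)^γ(−ln p_t) with γ = 2 (γ is
configurable; 2 is the standard operating point for this loss).  The
published optimiser statement is internally inconsistent (lr/weight-decay
appear once as 1e-4/1e-3 and once swapped); the default here is lr = 1e-4,
wd = 1e-3, both configurable.  Class probabilities are softmax over the
three outputs.  Calls use the asymmetric thresholds p_inh ≥ 0.88,
p_act ≥ 0.44; the two thresholds can both be satisfied, and inhibition is
checked first because its threshold is the stricter claim (`order=
"act-first"` is available).  Curated targets always override predicted
calls for the same gene.

**Drug-disease scoring**: input [diffusion profile | disease embedding]
(19,277-d at the published scale), hidden layers 4096/1024/256/64, leaky
ReLU, batch norm, 50% dropout, BCE-with-logits, Adam with lr = wd = 1e-3.
The sign of the output logit is the decision.  Training keeps the
per-epoch checkpoint with the highest F1.  The F1 is computed on the
*training* set by default: computing it on the validation set — which is
also the set all metrics are reported on — selects for validation noise
and measurably lifts the label-permuted control above 0.5.  The
`selection="val"` option restores validation-side selection; few-shot
fine-tuning uses it, since the published few-shot protocol reports on the
same validation subset that guides selection.

**Imbalance protocol**: negatives are sampled uniformly without
replacement from unknown drug×disease pairs at 10 per positive; the
merged set is split 80/20 (unstratified); SMOTE (k = 5, Euclidean) then
synthesises minority rows on the training portion only, interpolating
x + λ(x_nn − x) with λ ~ U[0,1] between minority nearest neighbours.
Random down-sampling and "none" are first-class alternatives; other
balancing schemes can be plugged in by calling any external resampler on
the training rows before `train_ddi_net`.

## Embeddings

Gene and disease networks are embedded by node2vec: second-order biased
walks (return p, in-out q; defaults 1/1 make the walk unbiased) over the
*unsigned, undirected* view — edge signs matter only in diffusion — then
skip-gram with negative sampling (unigram^0.75 noise, 5 negatives, linear
lr decay, logits clipped at ±8 for stability; batches of 256 pair updates
approximate sequential SGD).  Window 5 and 5 epochs are package defaults;
the embedding dimension defaults to 300.  Molecule vectors come from a
deterministic structural fingerprint: canonical SMILES → hashed circular
atom environments (radius 2) counted into `dim` buckets, L2-normalised —
a pure function of the molecular graph, so spelling variants of one
molecule embed identically.  Precomputed molecule vectors can be supplied
through an `EmbeddingTable` instead; graph-contrastive pre-training is
deliberately out of scope.

## Disease-specific networks

DE genes: Welch two-sample t-test on case vs control, Benjamini-Hochberg
at 0.05 (raw-p mode available), ordered by adjusted p.  Edges: Pearson
correlation among DE genes on case samples (configurable to all samples),
exact t-distribution two-sided p-values; a pair becomes an edge iff
p < 0.05 and |r| clears the threshold (0 or 0.5), signed by the
correlation direction.  Plain correlation is used on purpose — the
procedure being reproduced is a correlation-matrix-with-p-value filter,
not soft-thresholded module detection.  Swapping this network into
diffusion while holding every other stage fixed isolates the contribution
of the network itself; the evaluation protocol for a disease is balanced
(equal positives and sampled negatives, 80/20 split, accuracy at
threshold 0).

## The synthetic world

The generators produce seeded, desk-scale data with the statistical
structure each stage assumes.  The standard world: 220-node signed
network (660 edges, 19% inhibitory — the ratio in curated signaling
maps), of which the first 200 nodes form the gene universe (the rest
model off-universe signaling nodes); 60 drugs with 3 signed targets each;
20 diseases; 80 positive combination therapies.

The drug-disease signal is planted **through the diffusion oracle**: each
disease carries a sparse signature (12 genes, Gaussian weights), the true
affinity of a pair is ⟨expected profile, signature⟩, pairs above the 0.93
affinity quantile are positive, and 1% of labels are flipped to emulate
curation noise.  The quantile is tied to the 10:1 protocol: on a fully
labelled pair grid, drawing 10 negatives per positive requires the
positive fraction to stay below 1/11.  The scorer sees only noisy
versions of the signatures (sd 0.1) as disease embeddings and
Monte-Carlo (not expected) profiles as drug features, so recovery
genuinely exercises the stochastic pipeline.

Two similarity structures make the signal learnable at this sample size,
mirroring properties real data has and a pair-concatenation scorer relies
on: drugs fall into 12 families drawing targets from small shared pools
(pharmacological classes), and disease signatures jitter around 5
prototypes (related conditions).  With fully independent drugs and
diseases the same architecture memorises its 1,000-row training set
without generalising — a regime real repositioning data, with its tens of
thousands of correlated pairs, is not in.

What the planted world does **not** emulate: real degree distributions
(beyond the scale-free option), edge confidence weights, dosage, any
chemistry-target relationship (synthetic drug embeddings are random unit
vectors), or ontology structure in disease embeddings.  Passing tests
show the mechanism and protocol are implemented correctly — not that the
published real-data performance transfers.

## Desk-scale experiment choices

The experiment harness scales the published protocol to the synthetic
world: feature rows are standardised (scaler fitted on the training
portion), the scorer uses hidden layers (64, 16) with 50% dropout,
weight decay 1e-2, batches of 64 and 150 epochs — the published
architecture's shape and regularisation adapted to 400-d features and
~10³ rows.  The label-permuted control permutes labels within the
training and validation portions independently *after* the split and
reports the mean over 20 replicates: permuting before the split lets both
sides share the permutation's chance per-entity positive rates (a real,
generalisable signal worth ~0.05–0.10 AUC), and a single replicate's AUC
carries ~0.07 sampling noise at 235 validation rows.  The few-shot
experiment builds one perturbed negative per positive combination,
splits 3:1 (225/76 at the published scale), and fine-tunes all layers at
lr = 1e-4 for 20 epochs.

## Numerical details and degenerate inputs

- Focal loss clamps p_t at 1e-12 (warned) so certain-wrong predictions
  stay finite; γ = 0 reduces to cross-entropy within 1e-12.
- BCE is computed from logits with the log1p-exp form; no probability is
  ever materialised in the loss.
- SMOTE requires k+1 minority rows and fails with advice otherwise; two
  identical minority points synthesise copies of themselves.
- AUC uses mid-ranks (ties count ½); precision and F1 are defined as 0
  when nothing is predicted positive; AUC/AUPR raise on single-class
  inputs rather than returning a default.
- Zero-variance genes are skipped (with a warning) in correlation
  networks; expression rows with missing values are dropped at load.
- Isolated nodes yield length-1 walks in node2vec and force restarts in
  diffusion; neither is an error.
- Duplicate edges resolve last-wins, duplicate universe genes first-wins,
  duplicate records drop — each logged exactly once.

## Known limitations

- The stochastic profile at 15×15 walk budget carries ~10% relative noise
  on well-visited nodes; the planted-world AUC (≈0.85–0.92 across seeds)
  reflects that budget, the 1% label noise, and the small validation set
  (~24 positives), not a ceiling of the method.
- The exact oracle is dense and quadratic in network size; it is not
  usable on genome-scale networks.
- The in-package skip-gram is tuned for desk-scale graphs (≲10⁴ nodes);
  industrial corpora would need a negative-sampling table and threading.
- Fine-tuning improvement on combinations is modest (median +0.03–0.05
  F1 across seeds) because the zero-shot model already sees additive
  profiles; the gain comes mainly from recalibrating to the doubled
  profile scale.
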