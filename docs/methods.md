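# Methods

## Problem and approach

Classical bit fingerprints encode local substructure without any notion of
*which chemistry* matters for a task.  `npfp` trains feed-forward networks
to distinguish natural products (NPs) from synthetic decoys and reads a
molecular representation off the trained network: the activations of the
last hidden layer become a dense, NP-aware fingerprint, and the activation
of the NP output neuron becomes an NP-likeness score.  Networks trained on
the NP/decoy discrimination implicitly embed NP-relevant information, so
similarity search with the extracted fingerprint favours natural products
in a way raw structural similarity cannot.

## Fragment-frequency NPL score

The classical, fragment-based NP-likeness scorer is both a curation tool
(gating decoys) and the comparator for the neural score.

* Fragments are Morgan atom environments of radii 0..R (default R = 2),
  counted as multisets per molecule.
* Contribution of fragment *f*:
  `clip( log10( ((n_NP(f)+a)/N_NP) / ((n_syn(f)+a)/N_syn) ), -c, +c )`
  with pseudocount a = 1 (Laplace smoothing so unseen fragments are
  defined) and clip c = 3 (bounds any single fragment's influence).
* A molecule's score is the **mean** contribution over its fragment
  multiset.  The mean (rather than a sum) makes the score independent of
  molecular size, which matches the classical scorer's near-zero
  correlation with molecular weight.
* Scores are comparable only within one fitted table; no rescaling to any
  published range is attempted, so thresholds (0 for the decoy gate, 1 for
  the benchmark pre-filter) are parameters, not constants.

Swapping the two reference sets negates every contribution and hence every
score, which the tests assert exactly.

## Decoy curation

Queries are natural products; the library is synthetic.  Both pass a
filter that removes unparseable SMILES, canonical-SMILES duplicates, and
molecules the NPL scorer cannot score (zero fragments).  Library stereo
information is stripped (synthetic-catalogue stereo assignments are often
unreliable); NP stereo is retained.  Per query, library molecules need

* ECFP4 (2048-bit) Tanimoto ≥ 0.5 to the query (inclusive) — keeps the
  negative class structurally challenging;
* NPL < 0 (strict) — keeps mislabelled natural material out; molecules
  failing this gate are skipped and do not count toward the cap;
* rank within the 10 most similar accepted candidates (cap prevents
  popular chemotypes from dominating).

Decoys found from several queries keep one record; provenance points to
the highest-similarity query, ties broken by lexicographically smallest
query id, which makes assembly invariant to query order.  Exclusion
screening (against canonical-SMILES sets) runs after mining.  The
similarity index is exact exhaustive Tanimoto; a faster backend can plug
into the same two-method interface, but exactness is the default contract.
An audit helper recomputes every invariant from scratch and is used by the
tests.

## Architectures

All three networks share the encoder

    input(2048) -> [Linear -> ReLU -> Dropout -> BatchNorm] x H
                -> Linear(64) -> BatchNorm -> Tanh        <- fingerprint

with H = 2 hidden layers of widths (1024, 256) by default and dropout 0.2.
The 64-unit Tanh layer is the fingerprint layer; activations are taken
*after* batch-norm and Tanh, so every fingerprint entry lies in (-1, 1)
and extraction is bounded.  (Tapping before the Tanh would give an
unbounded variant; the bounded reading is used because it makes cosine
similarities well-behaved.)  One further Linear + ReLU sits between the
fingerprint and the prediction heads:

* **baseline**: one NP logit;
* **aux**: NP logit + 48 linear regression outputs for surface
  descriptors;
* **ae**: NP logit + a decoder mirroring the encoder widths
  (64→256→1024→2048) reconstructing the input bits (logits, bitwise
  sigmoid at loss time).

Heads emit raw logits; sigmoids are applied only in losses and scoring.
Hidden widths, dropout and the optimizer settings are configurable; the
defaults above are the package's choices for a two-stage funnel into the
64-unit layer.

## Losses

* Classification: binary cross-entropy with logits (numerically stable
  form).
* Regression: RMSE computed per descriptor, then averaged — so "each task
  contributes equally" holds task-wise rather than being dominated by
  high-variance descriptors.
* aux: `loss = (1/(1+K)) BCE + (K/(1+K)) mean_d RMSE_d` with K = 48; each
  of the 1+K tasks carries equal weight.
* ae: `loss = BCE_NP + 100 * mean_over_bits(BCE_bit)`, i.e. NP loss to
  *total* reconstruction loss is 1:100; with 2048 input bits one NP
  example weighs ≈ 20.5× one reconstructed bit.

The tests verify, to float precision, that each composite equals the
weighted sum of independently computed per-task losses.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) under a one-cycle learning-rate schedule:
cosine ramp from lr_max/25 to lr_max over the first 30% of steps, cosine
anneal to lr_max/10⁴ afterwards.  Defaults: lr_max 1e-3, 30 epochs, batch
256.  Evaluation uses random-split (unstratified) 5-fold cross-validation,
80/20 per fold; reported metrics are the held-out NP AUC and the same AUC
restricted to molecules with NPL < 0, the region where the two classes
genuinely overlap.  Descriptor regression targets are standardized with
the training fold's mean/SD only; validation reuses that standardizer, so
nothing leaks across the split.

Everything is seeded: parameter init from the spec seed, batch shuffling
and dropout from a per-fold derived seed.  Two runs with the same
seed/config/data produce identical metrics to full precision on one
machine.  Batch-norm uses running statistics at inference, so fingerprints
are batch-size invariant and single-molecule extraction is well-defined.

The networks are implemented directly in NumPy — hand-written forward and
backward passes with a flat parameter store.  Backprop is verified against
finite differences in the tests.

## Surface descriptors

The aux targets are 48 two-dimensional "surface" descriptors computed with
RDKit: the full VSA families (SlogP_VSA 1–12, SMR_VSA 1–10, PEOE_VSA 1–14,
EState_VSA 1–11) plus TPSA.  This is a synthetic stand-in list assembled
for this package — any 48 descriptors capturing surface/shape/
electrostatics would serve — and is overridable via the `descriptor_set`
argument.  Non-finite descriptor values are imputed with the fitting-set
column median, which keeps every molecule usable as a regression target
without dropping rows.

## Evaluation protocols

* **AUC** is computed as the Mann–Whitney concordance probability (average
  ranks), so score ties contribute 1/2 per active–inactive pair and the
  result is independent of how a sort breaks ties.  The tests check it
  against an O(n²) pairwise count to 1e-12.
* **EF x%** uses a top window of ⌈x·N⌉ molecules (never zero):
  `(actives_in_window / window) / (actives / N)`; bounded by 1/x, invariant
  under monotone transforms of the similarity.
* **1-nn identification**: each held-out molecule is scored by its nearest
  training neighbour's label, 10-fold CV, mean AUC; cosine similarity for
  dense fingerprints, Tanimoto for bit fingerprints; neighbour ties go to
  the lowest input index (deterministic).
* **Per-target screen**: every active serves once as the query; the query
  is removed from its own library (self-similarity would trivially inflate
  enrichment).  AUC and EF1% are averaged over queries within a target and
  then over targets.
* **NPL pre-filter**: natural-class records with NPL strictly above the
  threshold (default 1) are dropped before a mixed-benchmark screen, so
  the search cannot succeed by NP-likeness alone; synthetic records pass
  untouched.

## Fixture generator

The generator produces the study conditions for all tests: molecules
assembled from SMILES fragment grammars, validated by RDKit, fully
deterministic in (n, seed).

* *NP grammar*: fused saturated cores (decalin, hydrindane, pyranose,
  δ-lactone, bridged bicycles, a linear tricycle) decorated with sp³,
  oxygen-rich substituents.
* *Synthetic grammar*: 60% flat aromatic amide/sulfonamide/biaryl
  chemistry, 40% "decoy-like" — NP cores carrying synthetic decorations
  (halogen, nitrile, sulfonyl, aryl).  The decoy-like fraction is what
  makes similarity-matched mining possible on fixtures at all: those
  molecules are ECFP-similar to NP queries while their fragment statistics
  lean synthetic.
* *Activity benchmark*: per target, a distinctive NP core is chosen
  (successive targets take chemically distant cores — sugar, bridged
  terpene, decalin — so chemotypes do not collide); actives are NP-style
  decorations of that core; an equal-plus population of *confusers*
  carries the same core with NP decoration plus one synthetic group, so a
  bit-fingerprint search cannot separate them from actives by scaffold;
  the rest of the library is inactive background from both grammars, with
  natural background drawn from *other* cores (reusing the target core
  would plant structural actives with inactive labels).

The class contrast is structural (grammar), not label noise, so
separability claims in the tests are constructed properties of the data.
What the grammars do **not** emulate: real NP scaffold diversity,
stereochemistry-rich chemistry, ionization states, reagent-like fragments,
or assay noise.  Passing tests therefore demonstrate that the machinery
behaves as specified under a controlled contrast — not that the measured
effect sizes transfer to Coconut/ZINC-scale data.

## Problem sizes and scaled-down conditions

The package's test and acceptance runs use: 200-molecule reference sets
per class for the NPL table; a 50-NP / 500-synthetic curation library; a
2000-molecule (1000 + 1000) training set; benchmarks of 3 targets × 200
molecules (10 actives each); 10 benchmark replicates for the
neural-vs-ECFP4 comparison.  Training in the shared test fixtures runs the
aux model at the default 30 epochs (its classification term is 1/49 of the
loss, so it converges slowest) and baseline/ae for 10 (they converge
within a few epochs on the separable fixture task).  The screening
comparison in the test suite uses one trained aux model across the 10
benchmark replicates (the replicate seeds vary the benchmark, which is the
quantity the comparison concerns); the acceptance script averages the
neural side over three CV folds, mirroring the fold-averaged screening
protocol.

## Numerical choices and edge cases

* Tanimoto of two all-zero fingerprints is defined as 1.0 (identical
  empty patterns); configurable.
* Cosine of an all-zero vector raises rather than returning 0 — a zero
  fingerprint is a pipeline error, not a similarity statement.
* Ranking ties: stable sort on input order; AUC's 1/2 tie convention makes
  the choice irrelevant to AUC.
* Zero-fragment molecules raise `ScoreUndefinedError` in the NPL scorer
  and are filtered (reason `"npl"`) during curation.
* RMSE gradients use an ε = 1e-12 guard so a perfectly fitted descriptor
  contributes a zero, not undefined, gradient.
* Training aborts with `TrainingDivergedError` on a non-finite loss.
* Model serialization stores the spec, all parameters, batch-norm running
  statistics, and the descriptor standardizer; a reloaded model reproduces
  predictions bit-identically.

## Known limitations

* The grammars generate a narrow slice of chemistry; absolute metric
  values on fixtures say nothing about real-database performance.
* The NPL scorer targets functional equivalence with the classical
  fragment-score family (ordering, sign, antisymmetry), not bit-exact
  reproduction of any published implementation.
* Graph-convolution variants are out of scope, as is the third-party
  NC_MFP fingerprint.
* Training is CPU-only NumPy; it is sized for 10³–10⁴-molecule datasets,
  not the 10⁵-scale runs a GPU framework would handle.
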