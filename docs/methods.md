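# Methods

This note records the model, the defaults and the design decisions behind
`bindtext`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not demonstrate.

## 1. From geometry to words

A complex is reduced to heavy atoms. Waters, hydrogens and alternate
locations are removed at parse time; the largest connected HETATM component
is the ligand. Bonds are inferred from element-pair distances (covalent
radii + 0.4 Å) when no explicit connectivity is given — the standard
heuristic, adequate for idealized and crystallographic geometries alike.

**Fragments.** Every N or O with at least two nearby heavy atoms defines a
three-atom fragment: the center plus its two nearest bonded heavy atoms
(padded with the nearest non-bonded atoms of the same molecule when the
center has fewer than two bonds, e.g. a carbonyl oxygen; ties break on atom
name). The donor/acceptor call is a minimal valence rule with no explicit
hydrogens:

- N with heavy-atom degree < 3 → donor (it carries an implicit H);
  fully substituted N → acceptor;
- O with degree ≤ 1 (carbonyl/carboxylate-like) → acceptor;
  O with degree 2 (hydroxyl/ether-like) → donor.

This rule reproduces backbone chemistry (amide N donates, carbonyl O
accepts) but deliberately ignores protonation states, tautomers, metals and
aromatic systems. A serine hydroxyl, bonded only to CB, is classified
acceptor by the degree rule even though chemically it can do both; the
classification only needs to be *consistent*, since words are compared to
words produced by the same rule.

**Contacts and words.** A residue fragment and a ligand fragment with
complementary roles whose centers lie within the cutoff (default 4.0 Å —
the upper end of hydrogen-bond heavy-atom distances; no distance criterion
is canonical for this representation) form one contact. Each discrete pair
is one word; sentences keep duplicates and are ordered by (residue order,
ligand fragment ordinal), which makes serialization deterministic.

The word grammar is
`{lig_idx}_{geom_bin}_{ligC}:{lig neighbors}-{aa}_{resAtom}:{res neighbors}`.
The two integers are the 1-based ligand fragment ordinal and the
center–center distance binned at 0.5 Å (`floor(d/0.5)`); the bin width is a
compromise between pose sensitivity (a 0.5 Å shift can change the word, so
pose clouds yield word variety) and stability (sub-0.1 Å noise usually does
not). Neighbor lists carry up to three symbols: the fragment's two
neighbors plus the next-nearest heavy atom for context. Ligand element
symbols are ordered by element priority (N > O > C) then distance; residue
atom names are ordered nearest-first. Any deterministic canonical order
would do; these make encode/parse a bijection, which the suite fuzz-tests.

**Shared words.** Two words are *shared* when all element/atom fields agree
— the numeric prefix (fragment ordinal, distance bin) is ignored, so the
same chemical contact observed at a slightly different distance counts as
the same word. The shared-word percentage is the Jaccard index × 100 over
element-collapsed word sets. (The alternative normalization by the query
set alone is not symmetric; the symmetric form is the one the percentage
formula defines.)

## 2. Corpus preparation

Sentences with five or fewer words are discarded: very short sentences come
from poses with almost no specific contacts and mostly add noise. The
filtered corpus is split 7:2:1 (train/validation/test) by a seeded
permutation with cumulative-rounded boundaries, so each part is within one
item of its exact share.

Two tokenizations are supported, both reserving `[PAD]`=0, `[SEP]`=1,
`[UNK]`=2. `[SEP]` is reserved but never inserted — samples are single
paragraphs, and inventing a separator position would add structure the
representation does not define.

- *Word-level*: each distinct word string is one token, ids by first
  occurrence. Unseen words encode to `[UNK]`.
- *BPE*: classic byte-pair encoding learned on the corpus text (character
  alphabet = byte alphabet for this ASCII grammar). Merges never cross a
  whitespace boundary, the most frequent pair wins (ties to the
  lexicographically first), and whitespace never enters the emitted token
  stream, so decoding reproduces a sentence's non-whitespace content
  exactly. Training stops at the target vocabulary size or when merges
  exhaust.

`max_seq_len` defaults to the token count of the longest training sample
(that is how a fixed published maximum length arises); shorter samples are
padded, over-length samples raise unless truncation is requested.

## 3. The language model

A decoder-only transformer in plain numpy: learned token + positional
embeddings, pre-LN blocks (causal multi-head attention, GELU MLP), final
layer norm, output head tied to the token embedding. Initialization is
N(0, 0.02) with residual projections scaled by 1/√(2·n_layers). The
attention mask excludes both future positions and `[PAD]` keys; the loss
ignores positions whose target is `[PAD]` (padding contributes exactly
zero, which the suite asserts).

Training is AdamW (β=0.9/0.999, weight decay 0.01 on matrices) with a
linear warmup to the peak learning rate followed by linear decay — the
schedule used for GPT-2-class training. Everything is seeded: batch order,
initialization, sampling. Writing the forward and backward passes by hand
keeps the package dependency-light and makes single-threaded runs
bit-reproducible; the cost is that only desk-scale configurations are
practical. Tiny shapes (hidden 32–64, 2 layers) are the first-class test
configuration; GPT-2 small/medium are provided as presets and their
parameter count is verified against the published closed form, but
full-scale training is out of scope.

**Generation** samples from `softmax(logits/temperature)` after the
standard repetition-penalty transform (positive logits of already-seen
tokens divided by the penalty, negative multiplied). With a word-level
vocabulary one token is one word; with BPE, sub-tokens are sampled until
the accumulated string parses as a complete grammar word (whitespace is
absent from the stream, so the grammar itself supplies the boundary),
capped at 32 sub-tokens.

**Sequence logits.** A sentence's embedding is the mean over its non-pad
positions of the full logit row — one length-V vector per sentence.
Averaging over positions (rather than over samples per token) is what
yields one vector per sentence and hence an N×V matrix to analyze.

## 4. Logit-matrix analysis

The pipeline mirrors single-cell practice: keep the `n_keep` columns with
the largest SD across rows (default `min(750, V−3)`; the column budget is a
parameter because the right threshold depends on the data), column-centered
PCA (components sign-fixed so the largest-magnitude loading is positive; up
to 100 components, fewer when N or the column count limits the rank), UMAP
to 2-D, and Louvain-style community detection (igraph `community_multilevel`,
resolution 1.0) on a k-nearest-neighbor graph (k = 15) built in PC space.
Markers are one-vs-rest rank-sum tests per token, BH-adjusted *within* each
cluster — the adjustment scope matches how the table is used (ranking
tokens inside one cluster), not a global error rate. Cluster grouping is
average-linkage hierarchy over per-cluster mean vectors cut into
`n_groups`. Enrichment is one-sided hypergeometric over-representation with
BH adjustment; terms observed in more than 10 clusters are dropped as
uninformative before the per-cluster representative (lowest q) is chosen.

**Projection of new data** re-runs selection → PCA → UMAP/Louvain on the
reference matrix plus the new row, with the reference run's parameters and
seed (joint re-embedding rather than transform-only projection, so the new
point participates in the manifold). The assigned cluster is the reference
label whose centroid (at the re-embedded coordinates) is nearest. Radar
weights over cluster groups are min–max-inverted centroid distances
(nearest group 1, farthest 0). Nearest-centroid assignment and min–max
normalization are the simplest deterministic choices; both are recorded
here because reasonable alternatives (graph membership, softmax weights)
exist.

**Target identification** is a k-NN majority vote (default k = 100, capped
at the reference size) by Euclidean distance in logit space, on the full
vectors or a selected-column subset (both supported; the full space is the
default). Ties break by summed inverse distance, then lexicographically.

## 5. Ligand similarity

Fingerprints are hashed linear-path fingerprints over heavy-atom paths
(rdkit `RDKFingerprint`), width 1024, path depth 6 — the defaults of the
classic path-fingerprint implementations. Tanimoto similarity is
|A∧B|/|A∨B| (two empty fingerprints give 0 with a warning). The TC map
partitions the embedding bounding box into a 10×10 grid (100 bins),
averages TC per bin and reports per-row/per-column marginal profiles; the
similarity network takes the 20 nearest rows to a query (2-D Euclidean,
ties by index) and keeps the 10 highest-TC pairs as edges.

## 6. Synthetic fixtures: what they emulate and what they do not

`make_synthetic_complex` builds a pocket of template residues (a fixed
five-member alphabet G/A/S/D/K with hand-placed heavy atoms) around a
zigzag O/C/N/C chain ligand, each residue anchored 2.7–3.1 Å from a
complementary ligand fragment so that contact detection always fires.
`perturb_pose` jitters ligand atoms with isotropic Gaussian noise of a
given RMS magnitude — a stand-in for pose resampling; real pose ensembles
have correlated, torsional moves that this rigid-free jitter does not
reproduce. `make_synthetic_corpus` renders target-specific word pools
through the real grammar with a controllable shared-vocabulary fraction: at
0 the targets are perfectly separable by vocabulary, at 1 they are
indistinguishable, which turns downstream recovery into a dialable
benchmark.

Consequently, passing the recovery experiments shows that the
implementation faithfully propagates vocabulary-level signal from geometry
to clustering — it does not show that real binding modes are separable, nor
that the language captures affinity. The fixtures contain no conformational
physics, no force field, no docking.

## 7. Desk-scale protocols and their sizes

- *Cluster recovery*: 3 targets × 50 sentences, disjoint vocabularies
  (~40 words per target), word-level tokens, model hidden 32 / 2 layers /
  2 heads, 60 epochs, seed 0. Under these conditions Louvain recovers the
  targets exactly (ARI 1.0 against the generating labels); at much shorter
  training the logit rows become near-duplicates and communities fragment.
  Held-out target identification uses the train+validation rows as the
  reference and k = 15.
- *Generation protocol*: a deterministic-successor corpus (30 words, 60
  sentences of length 12), 100 training epochs — enough to learn the
  successor structure while sampling still explores, so all four word
  categories occur. 1,000 generations at temperature 0.7 / repetition
  penalty 2 are categorized (exact next word / elsewhere in original /
  element-level variant / new, in that priority). The exact-next-word rate
  is compared with an identical model trained on a word-shuffled corpus
  (Fisher exact test); the related-vs-new AUC uses the generated word's
  prompt-conditioned logit as the score, categories 2∪3 as positives and
  category 4 as negatives. Exact hits answer the first measurement and are
  excluded from the second — counting them as negatives would punish a
  better model for being right.

## 8. Numerical conventions and degenerate inputs

Distances are Å in right-handed coordinates; residue numbering is 1-based.
All tie-breaks (fragment neighbors, SD column selection, nearest-neighbor
sets, TC edge ranking, vote ties) are deterministic, by name or index.
Degenerate cases are defined rather than undefined wherever a convention is
defensible: all-identical rows cluster as one community with a warning,
equidistant radar centroids give all-ones weights with a warning, empty
fingerprint pairs have TC 0 with a warning. Genuinely meaningless requests
(two empty word sets, single-class AUC, a ligand with fewer than three
atoms) raise.

## 9. Known limitations

- The donor/acceptor rule is heuristic; it diverges from chemistry for
  hydroxyls, histidine tautomers, and charged groups.
- The meaning of the second numeric word field (distance bin) and the
  neighbor-ordering conventions are this package's own canonical choices;
  other implementations of the same idea may serialize differently, so word
  strings are comparable only within one grammar.
- BPE generation relies on grammar-completeness to find word boundaries and
  can in principle stop early on a string that parses but would have been
  extended; word-level vocabularies do not have this ambiguity.
- UMAP coordinates are seed-stable but not metrically meaningful;
  quantities derived from them (TC maps, radar weights) are descriptive,
  not inferential.
- Joint re-embedding makes projection O(reference) per new sample.
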