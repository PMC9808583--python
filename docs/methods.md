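# Methods

## Problem and model

The package compares hospitalization reports — not whole patient
records — so that two documents are close when they describe similar
acute presentations.  A document is reduced to its positively asserted
medical concepts, each concept is routed to one or more organ-system
labels (the 22 MeSH category-C head chapters), and the document becomes
a family of per-label weighted point clouds in a term-embedding space:
on label *i*, the points are the distinct terms the document carries
under *i*, each point's mass is the term's occurrence count normalized
to sum 1, and the geometry is given by a fixed (context-free) vector
per term.

Two documents are compared per label with the earth mover's distance
(EMD): the minimal cost of transforming one weighted cloud into the
other, where moving mass *m* from term *u* to term *v* costs
*m* · (1 − cos(u, v)).  The global distance averages the per-label EMDs
with weights proportional to how much evidence both documents carry on
the label:

    D(HR₁, HR₂) = (1/n_labels) Σᵢ λᵢ · EMDᵢ ,
    λᵢ = (n₁ᵢ + n₂ᵢ) / (n₁ + n₂),

with n₁ᵢ the occurrence count document 1 carries on label *i* and n₁
its total count.  Two deliberate consequences: a label mentioned often
in either document dominates the comparison, and repeating a term
changes the masses and hence the distance — document length and
repetition are *not* normalized away, which is the intended behaviour
(a report dominated by cardiovascular vocabulary should match other
cardiovascular-heavy reports) but also a known failure mode when
boilerplate history is repeated without clinical relevance.

### Choices the formula leaves open

* **Which labels enter the sum.**  The per-label EMD requires at least
  one term on the label in each document.  By default only labels
  present in *both* documents are summed (`intersection`), matching the
  per-label precondition; `penalty` mode additionally charges a fixed
  EMD (default 1.0, configurable in [0, 2]) for labels carried by only
  one side, for users who want non-overlapping organ involvement to
  repel.  `n_labels` counts the labels actually included, not the
  constant 22 — with the constant, sparse notes would collapse toward
  zero distance regardless of content.
* **What n_HR counts.**  Occurrences, not distinct terms, consistent
  with masses that follow occurrence frequency.  A term with several
  labels appears under each of them but contributes once to n_HR; with
  single-labeled terms Σλᵢ = 1 exactly, with multilabel terms Σλᵢ ≥ 1.
* **Document vs patient.**  Representations are per document; patients
  are deduplicated only at retrieval time, keeping each patient's
  closest document.

### Metric caveat

Cosine distance 1 − cos θ is not a metric: it violates the triangle
inequality at large angles, so raw per-label EMD values can too.  On
normalized vectors 1 − cos θ = ‖û − v̂‖²/2, which makes the per-label
EMD equal to half the squared Wasserstein-2 distance; √(2·EMD) is
therefore a true metric, and that is the form in which the test suite
asserts the triangle inequality.  Non-negativity, symmetry and zero
self-distance hold for the raw value.  Values are deterministic and
exact: the solver is a transportation simplex (north-west-corner start,
MODI pivots), not an entropic approximation, and is cross-checked
against an independent generic LP formulation to 1e-8 on random
problems.  Clouds here are small (a handful of distinct terms per
label), so exactness costs little.

## Pipeline stages around the distance

**Extraction.**  The reference extractor matches a surface→canonical
lexicon case- and accent-insensitively (offsets always index the
original text), resolves overlaps longest-span-first (ties: leftmost),
and never matches inside a longer word token.  Assertion follows a
NegEx-style convention: a negation/hypothesis/family trigger projects
forward over `scope_window` word tokens (default 5) until a sentence
boundary (`.`, `;`, newline); precedence when several apply is
negated > family > hypothetical.  Only positive mentions proceed.  The
extractor is a contract, not a commitment: a neural NER system
producing the same asserted-mention output slots in unchanged.

**Labeling.**  A canonical→labels lexicon behind the same kind of
interface; a trained multilabel classifier can replace it.  Terms with
no label in the scheme cannot enter any per-label distance; they are
dropped from the representation and counted in the pipeline statistics
rather than silently discarded.  The default 22-chapter scheme excludes
mental-health chapters; the scheme is a one-label-per-line text file,
so extending it is trivial.

**Embedding.**  Vectors come from any word2vec-text file.  Multi-word
terms average their in-vocabulary token vectors; a fully
out-of-vocabulary term falls back to a deterministic character n-gram
(3–6) hash-bucket average, so repeated runs and separate processes give
identical vectors.  Stored vectors are not re-normalized (user files
round-trip bit-exactly); cosine handles norms.

**Clustering.**  Agglomerative Ward via the Lance–Williams recurrence
applied to the EMD matrix, as implemented in SciPy.  Ward formally
presumes Euclidean dissimilarities and EMD values are not Euclidean;
the matrix is treated as-if-Euclidean — a standard, documented practice
— and merge-height monotonicity is checked, with violations reported
rather than hidden.  The number of flat clusters is a user parameter;
there is no automatic selection.  Incomparable pairs (NA in the matrix)
must be resolved by the caller before clustering.

**Retrieval.**  The index document is a query; candidates are all
documents of other patients (the index patient's own documents are
excluded, including from the recall denominator).  The distance is
restricted to the phenotype's routed labels (shipped defaults:
osteoporosis → musculoskeletal + nutritional; nephritis in lupus →
urogenital + immune; ILD in systemic sclerosis → respiratory + immune;
lung infection → respiratory + infections).  Candidates sharing no
routed label with the index are dropped and counted.  Per patient, the
minimum-distance document is kept; ties break by document id for
reproducibility.  Metrics: precision@k (denominator stays k when fewer
patients are retrievable — conservative, logged), recall in the first
n ranks with n = the number of gold-positive patients in the pool, and
average precision (mean of precision at hit ranks).  Evaluation
rotates every gold-positive document as the index and reports the mean
with a normal-approximation 95% CI (mean ± 1.96·sd/√m, clamped to
[0, 1]); at least two positive patients are required.

## The synthetic corpus generator

The generator emulates the statistical structure the method relies on,
not the surface realism of clinical prose.  Conditions (defaults in
parentheses): 80 patients, one note each; four phenotypes at
prevalence 0.25 with the shipped label routings; per routed label,
2–4 planted positive mentions; one batch of incidental background
findings on every other label (rate 1.0); decoy mentions wrapped in
negation / hypothesis / family cues in 20% / 10% / 5% of notes;
embedding dimension 16.

Geometry: every (phenotype, label) pool and every per-label background
pool is a Gaussian blob on the unit sphere; blob centres sit at
`normalize(anchor + separation · u)` with `u` random unit (separation
default 4.0, i.e. well separated) and within-blob jitter 0.08.  Terms
are drawn by sampling a point from the note's blob and emitting the
nearest vocabulary term of that label (vocabulary: 30 terms per pool).
This indirection matters: it makes term *identity* carry exactly as
much phenotype information as the geometry does.  At separation 0 all
blobs coincide, draws become phenotype-independent, and ranked
retrieval is uninformative by construction — measured mean average
precision then sits at the random-ranking expectation (≈ 0.28 for 19
relevant of 79, itself slightly above the 0.24 pool prevalence because
average precision is upward-biased under random rankings at finite
sample size).  Incidental background findings mirror the per-label
count structure of phenotype terms so that support size is not a
phenotype cue either.  Decoy cue-wrapped terms are never taken from the
note's own phenotype pools, so a planted phenotype term can never occur
only under a cue.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: real French clinical prose (templates are
simple sentences), section structure, abbreviation noise, extraction
errors (the generator and extractor share the cue grammar, so
assertion recovery is perfect by construction), classifier errors
(labels come from a consistent lexicon), multi-document patients, and
realistic embedding anisotropy.  Results on the synthetic conditions
validate the *distance and retrieval machinery*, not end-to-end
performance on hospital text.

A frozen 12-note miniature corpus (2 phenotypes, 6 patients each,
seed fixed) ships with the package together with every intermediate
artifact of the full pipeline (mentions, representations, distance
matrix, linkage, dendrogram, ranked tables, metric report); the test
suite re-runs the pipeline and compares bit for bit, which pins the
whole numeric chain, including float formatting (9 decimal places in
CSV/JSON artifacts).

## Numerical and degenerate-input conventions

* Transport: marginals are validated non-negative and balanced (1e-6
  relative), then normalized; 1×n and m×1 problems short-circuit to
  dot products; reduced-cost tolerance 1e-11; a stalled pivot sequence
  (degenerate cycling, never observed in testing) falls back to the
  generic LP with a warning rather than failing.
* Cosine distances are clamped to [0, 2] against rounding; zero-norm
  vectors are rejected at construction, so the ground distance is
  always defined.
* Distance matrices mark incomparable pairs NA and list them; writers
  use `%.9f`.
* Two empty reports, a label absent from one side, k outside [1, n],
  fewer than two label carriers, and fewer than two positive patients
  are all errors with messages naming the offending object, never
  silent defaults.
* All randomness flows through explicit seeds; corpus generation,
  extraction and the solver are fully deterministic given their inputs.

## Scale of the shipped validation runs

The planted-cohort studies run the full pipeline on 80-patient corpora
over 10 seeds (separated regime) and 50 seeds (collapsed regime); the
solver and clustering cross-checks use 200 random transport problems
and 50 random 10×10 matrices.  These sizes give stable means (the
across-seed spread of the null-regime AP is ≈ 0.01) while keeping a
full validation run in the minutes range on a single CPU.
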