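# Methods and design notes

## Model

icdmap treats a clinical classification version as a forest of coded
concepts: each code has an opaque id, a short clinical label, an optional
parent, and a chapter label, with the chapter title modelled as the root
code of its chapter. Mapping is defined per source code as the target
code whose description denotes the same clinical concept, with the
one-to-one constraint that each source maps to at most one target; a
set-valued (one-to-many) mode relaxes this for broader source concepts.
Mapping is performed *chapterwise*: both systems are first restricted to
an equivalent chapter, which bounds the search space and mirrors how
cross-version alignment is curated in practice.

The pipeline is: build description variants → encode → fuse → cosine
argmax → resolve granularity mismatches → evaluate.

### Description variants

* **HA (hierarchy-augmented)**: `"D is P₁. P₁ is P₂. … P(j−1) is Pj."`,
  immediate parent first, chapter title last. A chapter root renders as
  its bare label, so the number of "is" sentences always equals the
  number of ancestors. The renderer prints the labels the system stores,
  verbatim — near-duplicate labels at different levels are a fact of real
  classifications and are not reconciled.
* **LG (generated)**: a concise clinical description obtained by
  prompting a text-generation backend with a configurable template
  (`lg_prompt_template`, literal `{X}` placeholder). The shipped default
  asks for a concise formal clinical description and nothing else; the
  template is a config value precisely because prompt wording is the one
  part users will want to tune per model. Generated text is
  whitespace-normalised only (no case folding — sentence encoders are
  case-sensitive).

Variant flags select baseline (raw label only), HA, LG, or HA+LG; with
both enabled the two encodings are fused by the elementwise mean. Fused
vectors are *not* re-normalised before cosine: cosine is scale-invariant,
and normalising before the mean would silently reweight the two variants.

### Similarity search and tie-breaking

Scores are cosine similarities computed on the normalised embedding
matrices. Ranking is by descending score with exact ties broken by
ascending target code id, which makes every run reproducible. Scores
within 10⁻¹² of ±1 are snapped to exactly ±1 so that identical texts
score exactly 1.0 under any deterministic encoder — the inclusive
`cos ≥ λ` threshold at λ = 1 and the exact-recovery checks rely on this.
Zero-norm vectors (possible with bag-of-tokens encoders on
out-of-vocabulary text) raise immediately rather than silently scoring 0.

### Granularity resolution

A source whose rank-1 target is a non-leaf is a *source-to-parent* case.
Two strategies:

* **Simple rule (SR)**: select the flagged parent's immediate child with
  the highest cosine to the source. One level deep, never rejects — it
  always produces a map even when the parent itself was wrong.
* **Prompting (PR)**: a multiple-choice prompt with the source label as
  anchor, the parent's immediate children as options (sorted by code id;
  labels A, B, C, …), and a final reject option ("None of the above",
  configurable, always last). The backend must answer one label.
  Responses are parsed by taking the first standalone valid label after
  stripping `<think>…</think>` reasoning segments; a bare "none" phrase
  counts as rejection; an unparseable response is recorded as a rejection
  with a warning rather than aborting the run. If the selected child is
  itself non-leaf, resolution re-applies one level down, at most
  `max_depth` (default 3) levels; if depth runs out, the last accepted
  non-leaf selection stands. Every final selection is verified to be a
  descendant of the flagged parent when the mapping is assembled.

PR applies whenever the rank-1 target is non-leaf, in either mapping
direction. A chapter root with no children counts as a leaf (degenerate
singleton chapter), so it never triggers resolution.

### One-to-many strategies

* **Threshold**: keep all targets with `cos ≥ λ` (inclusive; λ ∈ [−1, 1],
  default 0.90). Prediction sets may be empty, which lowers coverage.
* **Top-K**: keep the K best-ranked targets (defaults offered: 3, 5, 7).
  Coverage is 1 by construction.

### Evaluation

With N source codes in the restricted system and N_nm of them absent
from the ground-truth table (intermediate parents, codes mapping outside
the chapter), all denominators are N − N_nm:

* top-1 accuracy = correct / (N − N_nm); a prediction is correct iff it
  is a member of the (possibly set-valued) ground truth — any partial
  match counts — and a rejected evaluable source counts as wrong;
* classwise mean Jaccard = mean of |P∩G|/|P∪G| (empty prediction with
  non-empty truth contributes 0; 0/0 cannot occur for evaluable sources);
* mapping coverage = fraction of evaluable sources with ≥1 prediction;
* resolution confusion over source-to-parent cases: TP selected child in
  truth, FP selected child not in truth, TN rejected with no immediate
  child of the flagged parent in truth, FN rejected although one was.
  SR can never contribute TN or FN.

Ground-truth rows that map a source to a parent code are kept verbatim;
correctness is literal membership. Across repeated runs the report gives
the mean and *population* SD (divide by n — a descriptive spread over a
handful of runs, not an inferential estimate); runs with identical values
report SD exactly 0.

## Synthetic study conditions

The generator builds `n_chapters` full-depth chapters (default 3 chapters,
depth 3, 2–3 children per node) with descriptions of 2 tokens drawn from
a vocabulary of 66 synonym classes of clinically flavoured token pairs.
A code never reuses a synonym class used by an ancestor, and no two codes
share a class set, so descriptions stay distinguishable even after
synonym canonicalisation — exact recovery is then well-defined rather
than luck.

Deriving the target applies, per source leaf: synonym substitution
(per-token probability `p_synonym`, default 0.3), a split into 2–4
children under a parent carrying the source's label, each child extended
by a discriminator token with one residual "unspecified" child
(`p_split`, default 0.15), or consolidation of a sibling leaf group into
one target carrying the group parent's general label (`p_consolidate`,
default 0.15, decided per sibling group). Ground truth covers exactly the
source leaves: splits map to all children, consolidated groups share one
target. Internal nodes are copied and deliberately left out of ground
truth, feeding N_nm as real crosswalks do. The defaults keep every
scenario kind frequent enough to be exercised in a system of dozens of
codes; rates calibrated against real ICD version pairs are out of scope.

Scripted backends close the loop offline:

* **hashed bag-of-tokens encoder** — token counts scattered into a fixed
  4096-dimension index via a stable md5 hash (a grown vocabulary dict
  would make vectors depend on encoding order). Hash collisions are
  possible but negligible at these vocabulary sizes. With
  `canonicalize=True` tokens are first mapped to their synonym-class
  representative: an oracle under which synonymous labels coincide
  exactly, emulating what LG descriptions achieve against linguistic
  variation.
* **truth-aware choice responder** — parses the choice prompt, resolves
  anchor and options back to code ids by description, answers the label
  of a ground-truth child when present, else the reject label; an
  `error_rate` knob injects uniformly wrong answers, deterministic under
  seed. An always-reject responder and an echoing generator complete the
  set.

What passing on these conditions shows: the pipeline mechanics — HA
construction, argmax search, flagging, resolution, metrics, determinism —
are correct, and the qualitative direction (variation-normalised
descriptions beat raw labels; PR can reject wrong parents, SR cannot)
holds. What it does not show: performance on real ICD text under a real
sentence encoder and LLM, where synonymy is graded rather than exact,
hierarchies are deeper and uneven, and generated descriptions are noisy.

## Numerical and degenerate-input choices

* Ranking tie-break: ascending code id, everywhere (search, SR, top-K).
* λ comparison is inclusive (`≥`), keeping λ = 1 meaningful for exact
  twins.
* Evaluation with zero evaluable sources raises instead of returning NaN.
* Crosswalk composition drops (and warns about) sources whose entire
  intermediate set has no onward map — sequential crosswalks are
  expected to be incomplete, so this is not an error.
* Per-run seeds are `seed + r`; scripted backends honour them, real LLM
  backends may ignore them (their stochasticity is the reason the
  mean/SD aggregation exists).
* Artifact provenance echoes the configuration minus the output path, so
  identical experiments written to different directories are
  byte-identical.

## Known limitations

* The sentence-transformers adapter is untested in CI (optional heavy
  dependency); only its interface is exercised via scripted encoders.
* PR option lists are capped at 25 children (single-letter labels); real
  ICD parents rarely exceed this, but a labelled-pagination scheme would
  be needed for ones that do.
* The recursive PR descent assumes each level's options fit one prompt
  and does not revisit earlier levels on rejection deeper down.
* The synthetic generator models synonym drift, splits, and
  consolidations, but not chapter-crossing moves (represented only as
  omission from ground truth) or code-id syntax of real ICD releases.
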