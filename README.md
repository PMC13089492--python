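# icdmap

Embedding-based mapping between versions of hierarchical clinical
classification systems (ICD-style), for health-informatics teams who need
to carry coded data across versions (e.g. ICD-9-CM ↔ ICD-10-CM,
ICD-10-AM ↔ ICD-11) when no expert-curated crosswalk exists — and for
anyone studying automatic terminology alignment.

## The method

A code system is a forest `C = {(cᵢ, dᵢ, pᵢ)}` of codes with short
clinical labels `dᵢ` and ancestor chains `pᵢ`. Mapping a source system to
a target system means finding, for each source code, the target code
describing the same clinical concept. Two things make the naive
"embed the labels, take the nearest neighbour" approach fail:

1. **Linguistic variation** — equivalent concepts carry lexically
   different labels across versions ("Ornithosis with pneumonia" vs
   "Chlamydia psittaci infection").
2. **Granularity mismatch** — newer versions refine one code into several
   children (or consolidate several into one), so a source code's nearest
   target is often a *parent* code rather than any leaf.

icdmap addresses both:

* **Hierarchy-augmented (HA) descriptions** chain a label to its ancestors
  with "is" sentences — `"D is P₁. P₁ is P₂. … P(j−1) is Pj."` — adding
  the structural context short labels lack.
* **Generated (LG) descriptions** rephrase each label into a concise
  clinical description via a pluggable text-generation backend; rephrasing
  normalises lexical variation. Both variants are encoded by a pluggable
  sentence encoder and fused by the mean, `e = ½(e_HA + e_LG)`.
* **Cosine argmax** maps each source embedding to
  `argmax_j cos(sᵢ, tⱼ)` over the target embeddings.
* **Granularity resolution** handles *source-to-parent* cases (the argmax
  target is a non-leaf): the **simple rule** always selects the flagged
  parent's most similar immediate child, while the **prompting
  framework** builds a multiple-choice prompt (source label as anchor,
  the parent's children as options, an explicit "None of the above") and
  lets a generation backend select one option or reject all.
* **One-to-many strategies**: keep all targets with `cos ≥ λ`, or the
  top-K targets per source.
* **Metrics**: top-1 accuracy `C / (N − N_nm)` (partial matches count),
  classwise mean Jaccard similarity, mapping coverage, and
  selection/rejection confusion counts, aggregated as mean ± SD over
  repeated runs.

Real encoder (e.g. sentence-transformers `all-mpnet-base-v2`) and LLM
backends plug in behind two small interfaces; the package ships
deterministic scripted backends and a synthetic paired-system generator so
the entire pipeline runs and is tested fully offline.

## Worked example

`examples/02_map_synthetic_pair.py` generates a source system and a
target copy in which half the vocabulary tokens drift to synonyms, then
maps with HA descriptions under two encoders:

```
68 source codes, 43 ground-truth pairs
         plain encoder: top-1 accuracy = 0.581
canonicalising encoder: top-1 accuracy = 1.000
```

The plain bag-of-tokens encoder sees synonyms as unrelated words and
recovers only 58% of the pairs; the canonicalising encoder — an oracle
that nullifies linguistic variation, standing in for what good generated
descriptions achieve — recovers all of them. The other examples walk
through HA rendering (`01`), granularity resolution with the simple rule
vs the prompting framework (`03`: a truth-aware responder yields
FP = FN = 0; an always-reject responder turns all 38 split cases into
misses), and one-to-many strategies (`04`: top-K coverage is always 1.0).

## Command line

```sh
icdmap simulate --seed 9 --out sim/
icdmap map --source sim/source.tsv --target sim/target.tsv \
    --ground-truth sim/ground_truth.tsv --variant ha+lg \
    --encoder bag-canonical --synonyms sim/scenario_log.json \
    --resolution prompting --pr-backend truth --n-runs 5 --out run/
icdmap evaluate --source sim/source.tsv --target sim/target.tsv \
    --ground-truth sim/ground_truth.tsv --out run/
```

Code systems are 4-column UTF-8 TSVs
(`code_id  description  parent_id  chapter_id`; empty `parent_id` marks a
chapter root) and ground truth a 2-column TSV (`source_id  target_id`,
repeated sources accumulating into one-to-many sets). Convert official
release formats to this dialect first;
`icdmap.codesystem.compose_mappings` chains crosswalks through a pivot
version (sequential mapping).

## Layout

* `src/icdmap/codesystem.py` — data model, TSV I/O, chapter restriction,
  crosswalk composition
* `src/icdmap/descriptions.py` — HA construction, LG prompting and
  generation backends
* `src/icdmap/embeddings.py` — encoder backends, mean fusion, cosine
  similarity search
* `src/icdmap/mapping.py` — argmax mapping, resolution strategies,
  one-to-many, serialisation
* `src/icdmap/evaluation.py` — metrics, confusion counts, multi-run
  aggregation
* `src/icdmap/synthetic.py` — paired-system generator and scripted
  backends
* `src/icdmap/cli.py` — the `icdmap` command
* `docs/methods.md` — modelling and design notes
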