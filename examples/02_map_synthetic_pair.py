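"""Map a synthetic source system to a synonym-drifted target.

Generates a paired source/target where half the tokens are substituted
with synonyms, then maps with two encoders: a plain bag-of-tokens encoder
(which sees synonyms as different words) and a canonicalising one (which
nullifies the variation, emulating what good generated descriptions do).
"""

from icdmap import Variants, embed_code_system, evaluate_mapping
from icdmap.mapping import (
    assemble_final_mapping,
    detect_source_to_parent,
    initial_mapping,
    resolve_simple_rule,
)
from icdmap.synthetic import (
    SyntheticConfig,
    derive_mapped_system,
    generate_code_system,
    make_scripted_encoder,
)

cfg = SyntheticConfig(seed=42, p_synonym=0.5, p_split=0, p_consolidate=0)
source = generate_code_system(cfg)
target, truth, _ = derive_mapped_system(source, cfg)
print(f"{len(source)} source codes, {len(truth)} ground-truth pairs")

for canonical in (False, True):
    encoder = make_scripted_encoder(cfg.vocabulary, canonicalize=canonical)
    src_emb = embed_code_system(source, encoder, variants=Variants(ha=True, lg=False))
    tgt_emb = embed_code_system(target, encoder, variants=Variants(ha=True, lg=False))
    candidates = initial_mapping(src_emb, tgt_emb, target)
    parents = [c for c in candidates if detect_source_to_parent(c)]
    outcomes = [resolve_simple_rule(c, src_emb, tgt_emb, target) for c in parents]
    final = assemble_final_mapping(candidates, outcomes, target)
    metrics = evaluate_mapping(final, truth, source)
    label = "canonicalising" if canonical else "plain"
    print(f"{label:>14} encoder: top-1 accuracy = {metrics['top1']:.3f}")

# The canonicalising encoder recovers every pair (top-1 = 1.000); the
# plain encoder is degraded by exactly the synonym substitutions.
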