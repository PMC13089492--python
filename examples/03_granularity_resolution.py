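"""Resolve source-to-parent mappings: simple rule vs prompting framework.

Every source leaf is split into refined children in the target, so every
source code initially lands on a non-leaf target (a granularity
mismatch).  The simple rule always picks the most similar immediate
child; the prompting framework asks a responder backend to pick one
option or reject all, which lets it filter wrong parents.
"""

from icdmap import Variants, embed_code_system, resolution_confusion
from icdmap.mapping import (
    detect_source_to_parent,
    initial_mapping,
    resolve_simple_rule,
    resolve_with_prompting,
)
from icdmap.synthetic import (
    SyntheticConfig,
    derive_mapped_system,
    generate_code_system,
    make_reject_responder,
    make_scripted_encoder,
    make_scripted_responder,
)

cfg = SyntheticConfig(seed=7, p_synonym=0, p_split=1, p_consolidate=0)
source = generate_code_system(cfg)
target, truth, log = derive_mapped_system(source, cfg)

encoder = make_scripted_encoder(None, canonicalize=False)
src_emb = embed_code_system(source, encoder, variants=Variants(ha=True, lg=False))
tgt_emb = embed_code_system(target, encoder, variants=Variants(ha=True, lg=False))
candidates = initial_mapping(src_emb, tgt_emb, target)
parents = [c for c in candidates if detect_source_to_parent(c)]
print(f"{len(log.records)} split leaves; {len(parents)} source-to-parent cases flagged")

# one flagged case in detail
case = next(c for c in parents if c.source_id in truth.pairs)
print(f"\nsource {case.source_id} ({source.get(case.source_id).description!r})")
print(f"  initial target {case.target_id} is non-leaf, score {case.score:.3f}")

sr = resolve_simple_rule(case, src_emb, tgt_emb, target)
print(f"  simple rule selects child {sr.child_id}")

responder = make_scripted_responder(truth, 0.0, 1, source, target)
pr = resolve_with_prompting(case, responder, source, target, seed=1)
print(f"  prompting selects child {pr.child_id}")

# confusion over all flagged cases, per strategy
for name, backend in [("truth-aware", responder), ("always-reject", make_reject_responder())]:
    outs = [resolve_with_prompting(c, backend, source, target, 1) for c in parents]
    counts = resolution_confusion(parents, outs, truth, target)
    print(f"\n{name} responder confusion: TP={counts.tp} TN={counts.tn} "
          f"FP={counts.fp} FN={counts.fn}")

# A ground-truth-aware responder makes no wrong selections or rejections
# (FP = FN = 0); rejecting everything turns every case into a miss (FN).
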