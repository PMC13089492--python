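import numpy as np
import pytest

from icdmap.codesystem import GroundTruthMap
from icdmap.embeddings import EmbeddingSet, Variants, embed_code_system, encode_text
from icdmap.errors import ArgumentError, ChoiceParseError, ConsistencyError
from icdmap.mapping import (
    REJECTED,
    SELECTED,
    CandidateMap,
    assemble_final_mapping,
    build_choice_prompt,
    detect_source_to_parent,
    initial_mapping,
    load_mapping_tsv,
    map_one_to_many_threshold,
    map_one_to_many_topk,
    parse_choice_response,
    resolve_simple_rule,
    resolve_with_prompting,
)
from icdmap.synthetic import HashedBagEncoder, TruthChoiceResponder, make_reject_responder

from .conftest import brute_force_cosine, make_system

ENC = HashedBagEncoder()


def embed(system):
    return embed_code_system(system, ENC, variants=Variants(False, False))


@pytest.fixture
def typhoid_target():
    """Target with a refined typhoid block (split-style non-leaf)."""
    return make_system(
        "icd10",
        [
            ("A00-B99", "infectious diseases chapter", "", "ch"),
            ("A01.0", "typhoid fever", "A00-B99", "ch"),
            ("A01.01", "typhoid meningitis", "A01.0", "ch"),
            ("A01.03", "typhoid pneumonia", "A01.0", "ch"),
            ("A01.09", "typhoid fever unspecified", "A01.0", "ch"),
            ("A02", "salmonella enteritis", "A00-B99", "ch"),
        ],
    )


@pytest.fixture
def typhoid_source():
    return make_system(
        "icd9",
        [
            ("001-139", "infectious diseases chapter", "", "ch"),
            ("002.0", "typhoid fever", "001-139", "ch"),
            ("003.0", "salmonella enteritis", "001-139", "ch"),
        ],
    )


class TestInitialMapping:
    def test_identity_systems_map_to_self(self, typhoid_target):
        emb = embed(typhoid_target)
        cands = initial_mapping(emb, emb, typhoid_target)
        for cand in cands:
            assert cand.target_id == cand.source_id
            assert cand.score == pytest.approx(1.0)

    def test_non_leaf_target_flagged(self, typhoid_source, typhoid_target):
        cands = initial_mapping(
            embed(typhoid_source), embed(typhoid_target), typhoid_target
        )
        by_source = {c.source_id: c for c in cands}
        typhoid = by_source["002.0"]
        assert typhoid.target_id == "A01.0"
        assert not typhoid.target_is_leaf
        assert detect_source_to_parent(typhoid)
        assert by_source["003.0"].target_is_leaf
        assert not detect_source_to_parent(by_source["003.0"])

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            src_vecs = {f"s{i}": rng.normal(size=6) for i in range(5)}
            tgt_vecs = {f"t{j}": rng.normal(size=6) for j in range(7)}
            leaf_sys = make_system(
                "t", [(f"t{j}", f"desc {j}", "", f"t{j}") for j in range(7)]
            )
            cands = initial_mapping(
                EmbeddingSet("s", src_vecs), EmbeddingSet("t", tgt_vecs), leaf_sys
            )
            for cand in cands:
                best = min(
                    (
                        (-brute_force_cosine(src_vecs[cand.source_id], v), tid)
                        for tid, v in tgt_vecs.items()
                    ),
                )
                assert cand.target_id == best[1]


class TestSimpleRule:
    def test_selects_child_matching_source_text(self, typhoid_source, typhoid_target):
        src_emb, tgt_emb = embed(typhoid_source), embed(typhoid_target)
        cand = [
            c
            for c in initial_mapping(src_emb, tgt_emb, typhoid_target)
            if c.source_id == "002.0"
        ][0]
        out = resolve_simple_rule(cand, src_emb, tgt_emb, typhoid_target)
        assert out.decision == SELECTED
        # "typhoid fever unspecified" shares both anchor tokens
        assert out.child_id == "A01.09"
        assert out.method == "simple_rule"

    def test_single_child_always_selected(self):
        target = make_system(
            "t",
            [
                ("P", "stenotic valve", "", "P"),
                ("P.1", "totally unrelated words", "P", "P"),
            ],
        )
        source = make_system("s", [("s1", "stenotic valve", "", "s1")])
        cand = CandidateMap("s1", "P", 1.0, target_is_leaf=False)
        out = resolve_simple_rule(cand, embed(source), embed(target), target)
        assert out.child_id == "P.1"

    def test_leaf_candidate_rejected_as_input(self, typhoid_target):
        cand = CandidateMap("s", "A02", 1.0, target_is_leaf=True)
        with pytest.raises(ArgumentError):
            resolve_simple_rule(cand, None, None, typhoid_target)

    def test_matches_brute_force_over_children(self, typhoid_source, typhoid_target):
        src_emb, tgt_emb = embed(typhoid_source), embed(typhoid_target)
        cand = CandidateMap("002.0", "A01.0", 0.9, target_is_leaf=False)
        out = resolve_simple_rule(cand, src_emb, tgt_emb, typhoid_target)
        scores = {
            cid: brute_force_cosine(
                src_emb.vectors["002.0"], tgt_emb.vectors[cid]
            )
            for cid in typhoid_target.child_ids("A01.0")
        }
        assert out.child_id == min(scores, key=lambda c: (-scores[c], c))


class TestChoicePrompt:
    def test_labels_and_reject_option(self):
        prompt = build_choice_prompt(
            "Typhoid fever",
            ["Typhoid meningitis", "Typhoid pneumonia", "Typhoid fever unspecified"],
        )
        assert "Typhoid fever" in prompt
        assert "A. Typhoid meningitis" in prompt
        assert "B. Typhoid pneumonia" in prompt
        assert "C. Typhoid fever unspecified" in prompt
        assert "D. None of the above" in prompt

    def test_single_option_gets_reject_as_b(self):
        prompt = build_choice_prompt("anchor", ["only option"])
        assert "A. only option" in prompt
        assert "B. None of the above" in prompt

    def test_option_texts_verbatim_once(self):
        options = ["first option text", "second option text"]
        prompt = build_choice_prompt("anchor term", options)
        for text in options:
            assert prompt.count(text) == 1

    def test_empty_options_rejected(self):
        with pytest.raises(ArgumentError):
            build_choice_prompt("anchor", [])


class TestParseResponse:
    def test_bare_letter(self):
        assert parse_choice_response("B", 3) == 1

    def test_none_of_the_above_phrase(self):
        assert parse_choice_response("None of the above.", 3) == REJECTED

    def test_reject_label_letter(self):
        assert parse_choice_response("D", 3) == REJECTED

    def test_reasoning_segment_stripped(self):
        raw = "<think>A or B? no, surely the third.</think> The answer is C"
        assert parse_choice_response(raw, 3) == 2

    def test_unparsable_raises(self):
        with pytest.raises(ChoiceParseError):
            parse_choice_response("no idea whatsoever", 3)


class TestPromptingResolution:
    def make_truth_responder(self, source, target, pairs, error_rate=0.0):
        truth = GroundTruthMap(source.system_id, target.system_id, pairs)
        return TruthChoiceResponder(truth, source, target, error_rate, seed=0)

    def test_truth_responder_selects_ground_truth_child(
        self, typhoid_source, typhoid_target
    ):
        responder = self.make_truth_responder(
            typhoid_source, typhoid_target, {"002.0": {"A01.09"}}
        )
        cand = CandidateMap("002.0", "A01.0", 0.9, target_is_leaf=False)
        out = resolve_with_prompting(
            cand, responder, typhoid_source, typhoid_target, seed=1
        )
        assert out.decision == SELECTED
        assert out.child_id == "A01.09"
        assert "typhoid fever" in out.prompt_text

    def test_reject_responder_rejects(self, typhoid_source, typhoid_target):
        cand = CandidateMap("002.0", "A01.0", 0.9, target_is_leaf=False)
        out = resolve_with_prompting(
            cand, make_reject_responder(), typhoid_source, typhoid_target, seed=1
        )
        assert out.decision == REJECTED
        assert out.child_id is None

    def test_unparseable_response_counts_as_rejection(
        self, typhoid_source, typhoid_target, caplog
    ):
        class Garbage:
            backend_id = "garbage"

            def complete(self, prompt, seed=None):
                return "i cannot decide at all"

        cand = CandidateMap("002.0", "A01.0", 0.9, target_is_leaf=False)
        with caplog.at_level("WARNING"):
            out = resolve_with_prompting(
                cand, Garbage(), typhoid_source, typhoid_target, seed=1
            )
        assert out.decision == REJECTED
        assert "unparseable" in caplog.text

    def test_recurses_when_selected_child_is_non_leaf(self):
        # two-level refinement: the first selection lands on a non-leaf
        target = make_system(
            "t",
            [
                ("P", "typhoid fever", "", "P"),
                ("P.1", "typhoid fever abdominal", "P", "P"),
                ("P.1.1", "typhoid fever abdominal perforated", "P.1", "P"),
                ("P.1.2", "typhoid fever abdominal unspecified", "P.1", "P"),
                ("P.2", "typhoid fever cutaneous", "P", "P"),
            ],
        )
        source = make_system("s", [("s1", "typhoid fever", "", "s1")])
        responder = self.make_truth_responder(
            source, target, {"s1": {"P.1", "P.1.2"}}
        )
        cand = CandidateMap("s1", "P", 1.0, target_is_leaf=False)
        out = resolve_with_prompting(cand, responder, source, target, seed=0)
        assert out.decision == SELECTED
        assert out.child_id == "P.1.2"  # descended into P.1, then chose its child


class TestAssemble:
    def test_leaf_candidates_pass_through(self):
        cands = [
            CandidateMap("s1", "t1", 0.9, True),
            CandidateMap("s2", "t2", 0.8, True),
        ]
        fm = assemble_final_mapping(cands, [])
        assert fm.pairs() == {"s1": "t1", "s2": "t2"}
        assert fm.unmapped == set()

    def test_selected_outcome_replaces_parent(self, typhoid_target):
        from icdmap.mapping import ResolutionOutcome

        cands = [CandidateMap("s1", "A01.0", 0.9, False)]
        outs = [ResolutionOutcome("s1", SELECTED, "A01.09", "prompting")]
        fm = assemble_final_mapping(cands, outs, typhoid_target)
        assert fm.pairs() == {"s1": "A01.09"}

    def test_rejection_moves_source_to_unmapped(self):
        from icdmap.mapping import ResolutionOutcome

        cands = [CandidateMap("s1", "p1", 0.9, False)]
        outs = [ResolutionOutcome("s1", REJECTED, None, "prompting")]
        fm = assemble_final_mapping(cands, outs)
        assert fm.unmapped == {"s1"}
        assert fm.pairs() == {}
        assert fm.predictions() == {"s1": set()}

    def test_unknown_source_outcome_rejected(self):
        from icdmap.mapping import ResolutionOutcome

        with pytest.raises(ConsistencyError):
            assemble_final_mapping(
                [], [ResolutionOutcome("ghost", REJECTED, None, "prompting")]
            )

    def test_selected_child_must_descend_from_parent(self, typhoid_target):
        from icdmap.mapping import ResolutionOutcome

        cands = [CandidateMap("s1", "A01.0", 0.9, False)]
        outs = [ResolutionOutcome("s1", SELECTED, "A02", "prompting")]
        with pytest.raises(ConsistencyError):
            assemble_final_mapping(cands, outs, typhoid_target)

    def test_missing_outcome_for_parent_case_rejected(self):
        with pytest.raises(ConsistencyError):
            assemble_final_mapping([CandidateMap("s1", "p1", 0.9, False)], [])


class TestOneToMany:
    @pytest.fixture
    def sets(self):
        enc = HashedBagEncoder()
        src = EmbeddingSet("s", {"s1": encode_text(enc, "acute cholera")})
        tgt = EmbeddingSet(
            "t",
            {
                "t1": encode_text(enc, "acute cholera"),
                "t2": encode_text(enc, "acute nephritis"),
                "t3": encode_text(enc, "chronic dermatitis"),
            },
        )
        return src, tgt

    def test_threshold_one_keeps_exact_twin_only(self, sets):
        fm = map_one_to_many_threshold(*sets, lam=1.0)
        assert fm.predictions() == {"s1": {"t1"}}

    def test_threshold_above_all_scores_empties_predictions(self, sets):
        _, tgt = sets
        enc = HashedBagEncoder()
        src = EmbeddingSet("s", {"s1": encode_text(enc, "osseous fibrotic")})
        fm = map_one_to_many_threshold(src, tgt, lam=0.5)
        # source shares no token with any target: every score is 0 < λ
        assert fm.predictions() == {"s1": set()}
        assert fm.unmapped == {"s1"}

    def test_threshold_minus_one_keeps_everything(self, sets):
        fm = map_one_to_many_threshold(*sets, lam=-1.0)
        assert fm.predictions() == {"s1": {"t1", "t2", "t3"}}

    def test_threshold_out_of_range_rejected(self, sets):
        with pytest.raises(ArgumentError):
            map_one_to_many_threshold(*sets, lam=1.5)

    def test_topk_one_equals_initial_targets(self, sets):
        src, tgt = sets
        leaf_sys = make_system(
            "t", [(tid, f"d{tid}", "", tid) for tid in tgt.vectors]
        )
        fm = map_one_to_many_topk(src, tgt, k=1)
        cands = initial_mapping(src, tgt, leaf_sys)
        assert fm.predictions() == {c.source_id: {c.target_id} for c in cands}

    def test_topk_capped_at_target_count(self, sets):
        fm = map_one_to_many_topk(*sets, k=10)
        assert fm.predictions()["s1"] == {"t1", "t2", "t3"}

    def test_topk_exact_size(self):
        rng = np.random.default_rng(3)
        src = EmbeddingSet("s", {f"s{i}": rng.normal(size=4) for i in range(4)})
        tgt = EmbeddingSet("t", {f"t{j}": rng.normal(size=4) for j in range(10)})
        fm = map_one_to_many_topk(src, tgt, k=3)
        for sid, preds in fm.predictions().items():
            assert len(preds) == 3

    def test_invalid_k_rejected(self, sets):
        with pytest.raises(ArgumentError):
            map_one_to_many_topk(*sets, k=0)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, typhoid_target):
        from icdmap.mapping import ResolutionOutcome

        cands = [
            CandidateMap("s1", "A02", 0.75, True),
            CandidateMap("s2", "A01.0", 0.9, False),
        ]
        outs = [ResolutionOutcome("s2", REJECTED, None, "prompting")]
        fm = assemble_final_mapping(cands, outs, typhoid_target)
        path = tmp_path / "mapping.tsv"
        fm.to_tsv(path)
        again = load_mapping_tsv(path)
        assert again.predictions() == fm.predictions()
        assert again.unmapped == fm.unmapped
        assert again.mode == "one-to-one"

    def test_serialization_is_deterministic(self, tmp_path):
        cands = [CandidateMap(f"s{i}", f"t{i}", 0.5, True) for i in range(5)]
        fm = assemble_final_mapping(cands, [])
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        fm.to_tsv(p1)
        assemble_final_mapping(list(reversed(cands)), []).to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
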