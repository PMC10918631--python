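import pytest

from entnorm.cascade import normalize_batch
from entnorm.dictionary import build_dictionary
from entnorm.evaluation import score
from entnorm.matching import normalized_edit_distance
from entnorm.preprocessing import preprocess
from entnorm.synthetic import (
    DEFAULT_MIX,
    EXPECTED_STEP,
    KINDS,
    PerturbationSpec,
    SeparationError,
    make_dictionary,
    make_gold,
    perturb,
    write_fixtures,
)
from entnorm.loaders import load_gold, parse_synonym_table


class TestMakeDictionary:
    def test_seeded_determinism(self):
        assert make_dictionary(10, seed=7) == make_dictionary(10, seed=7)

    def test_different_seeds_differ(self):
        assert make_dictionary(10, seed=1) != make_dictionary(10, seed=2)

    def test_canonical_texts_distinct(self):
        pairs = make_dictionary(50, seed=0)
        texts = [preprocess(name).text for name, _ in pairs]
        assert len(set(texts)) == len(texts)

    def test_pairwise_separation(self):
        pairs = make_dictionary(30, seed=3)
        texts = [preprocess(name).text for name, _ in pairs]
        for i, a in enumerate(texts):
            for b in texts[i + 1 :]:
                assert normalized_edit_distance(a, b) > 0.4

    def test_identifiers_unique(self):
        pairs = make_dictionary(25, seed=0)
        ids = [i for _, i in pairs]
        assert len(set(ids)) == len(ids)

    def test_names_are_canonical(self):
        for name, _ in make_dictionary(20, seed=5):
            assert preprocess(name).text == name

    def test_impossible_separation_raises(self):
        with pytest.raises(SeparationError):
            make_dictionary(
                400, vocab_size=4, seed=0, max_attempts_per_entry=5
            )

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            make_dictionary(0)


class TestPerturb:
    SPEC_SEED = 99

    def test_identity(self):
        r = perturb("lung cancer", PerturbationSpec("identity", seed=1))
        assert r.text == "lung cancer"
        assert not r.fell_back

    def test_case_punct_preserves_canonical(self):
        for seed in range(20):
            r = perturb("lung cancer", PerturbationSpec("case_punct", seed=seed))
            assert preprocess(r.text).text == "lung cancer"

    def test_token_shuffle_changes_order_only(self):
        r = perturb("alpha beta gamma", PerturbationSpec("token_shuffle", seed=4))
        c = preprocess(r.text)
        assert c.text != "alpha beta gamma"
        assert sorted(c.tokens) == ["alpha", "beta", "gamma"]

    def test_token_shuffle_single_token_falls_back(self):
        r = perturb("imatinib", PerturbationSpec("token_shuffle", seed=4))
        assert r.fell_back
        assert r.effective_kind == "identity"
        assert r.text == "imatinib"

    def test_embed_keeps_name_contiguous(self):
        r = perturb("lung cancer", PerturbationSpec("embed_in_phrase", seed=2))
        assert "lung cancer" in preprocess(r.text).text
        assert preprocess(r.text).text != "lung cancer"

    def test_char_edit_distance_bound(self):
        # single edit on an 8-character name: distance exactly 1/len(result-or-source)
        for seed in range(25):
            r = perturb("imatinib", PerturbationSpec("char_edit", edit_count=1, seed=seed))
            nd = normalized_edit_distance(r.text, "imatinib")
            assert 0 < nd <= 1 / 8

    def test_char_edit_output_stays_canonical(self):
        for seed in range(25):
            r = perturb("lung cancer", PerturbationSpec("char_edit", edit_count=2, seed=seed))
            assert preprocess(r.text).text == r.text

    def test_seeded_determinism(self):
        for kind in KINDS:
            spec = PerturbationSpec(kind, edit_count=1, seed=42)
            assert perturb("alpha beta", spec) == perturb("alpha beta", spec)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec("reverse")

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            perturb("", PerturbationSpec("identity"))


@pytest.fixture(scope="module")
def gold():
    pairs = make_dictionary(60, seed=5)
    return make_gold(pairs, DEFAULT_MIX, n_records=120, seed=6)


class TestMakeGold:
    def test_record_count(self, gold):
        assert len(gold.records) == 120
        assert len(gold.expected_steps) == 120
        assert len(gold.specs) == 120

    def test_positive_identifiers_exist(self, gold):
        ids = {identifier for _, identifier in gold.dictionary_pairs}
        for record in gold.records:
            if not record.is_negative:
                assert record.expected in ids

    def test_expected_step_matches_spec_kind(self, gold):
        for step, spec in zip(gold.expected_steps, gold.specs):
            assert step == EXPECTED_STEP[spec.kind]

    def test_mix_allocation_exact(self, gold):
        from collections import Counter

        counts = Counter(spec.kind for spec in gold.specs)
        assert counts["identity"] == 24
        assert counts["case_punct"] == 24
        assert counts["token_shuffle"] == 24
        assert counts["embed_in_phrase"] == 12
        assert counts["char_edit"] == 24
        assert counts["unmatchable"] == 12

    def test_step_attribution_under_cascade(self, gold):
        d = build_dictionary(gold.dictionary_pairs)
        traces = normalize_batch([r.query for r in gold.records], d)
        for trace, expected in zip(traces, gold.expected_steps):
            assert trace.result.step == expected

    def test_perfect_scores(self, gold):
        d = build_dictionary(gold.dictionary_pairs)
        traces = normalize_batch([r.query for r in gold.records], d)
        m = score(gold.records, [set(t.result.identifiers) for t in traces])
        assert m.precision == 1.0 and m.recall == 1.0 and m.f1 == 1.0

    def test_char_edit_within_generator_bound(self, gold):
        sources = {preprocess(n).text: n for n, _ in gold.dictionary_pairs}
        id_to_text = {i: preprocess(n).text for n, i in gold.dictionary_pairs}
        for record, spec in zip(gold.records, gold.specs):
            if spec.kind == "char_edit":
                source = id_to_text[record.expected]
                nd = normalized_edit_distance(preprocess(record.query).text, source)
                assert 0 < nd <= gold.parameters["threshold"]

    def test_seeded_determinism(self):
        pairs = make_dictionary(20, seed=1)
        a = make_gold(pairs, DEFAULT_MIX, n_records=40, seed=2)
        b = make_gold(pairs, DEFAULT_MIX, n_records=40, seed=2)
        assert a.records == b.records
        assert a.specs == b.specs

    def test_all_identity_mix(self):
        pairs = make_dictionary(15, seed=0)
        mix = {"identity": 1.0}
        gold = make_gold(pairs, mix, n_records=30, seed=0)
        d = build_dictionary(pairs)
        traces = normalize_batch([r.query for r in gold.records], d)
        assert all(t.result.step == "exact" for t in traces)
        assert all(t.steps_attempted == ["exact"] for t in traces)

    def test_all_unmatchable_mix(self):
        pairs = make_dictionary(15, seed=0)
        gold = make_gold(pairs, {"unmatchable": 1.0}, n_records=25, seed=0)
        d = build_dictionary(pairs)
        traces = normalize_batch([r.query for r in gold.records], d)
        assert all(not t.result.matched for t in traces)
        m = score(gold.records, [set(t.result.identifiers) for t in traces])
        assert m.tn == 25

    def test_disabling_partial_drops_exactly_char_edits(self):
        from entnorm.matching import MatchConfig

        pairs = make_dictionary(40, seed=9)
        gold = make_gold(pairs, DEFAULT_MIX, n_records=80, seed=10)
        d = build_dictionary(pairs)
        config = MatchConfig(enable_partial=False)
        traces = normalize_batch([r.query for r in gold.records], d, config)
        for trace, spec in zip(traces, gold.specs):
            if spec.kind == "char_edit":
                assert not trace.result.matched
            elif spec.kind == "unmatchable":
                assert not trace.result.matched
            else:
                assert trace.result.matched

    def test_bad_mix_rejected(self):
        pairs = make_dictionary(5, seed=0)
        with pytest.raises(ValueError):
            make_gold(pairs, {"identity": 0.5}, n_records=10, seed=0)


class TestWriteFixtures:
    def test_round_trip_through_loaders(self, tmp_path):
        pairs = make_dictionary(20, seed=4)
        gold = make_gold(pairs, DEFAULT_MIX, n_records=40, seed=4)
        paths = write_fixtures(gold, tmp_path / "fx")
        loaded_pairs, skipped = parse_synonym_table(paths["dictionary"])
        assert skipped == 0
        assert loaded_pairs == pairs
        records = load_gold(paths["gold"])
        assert records == gold.records

    def test_byte_identical_across_runs(self, tmp_path):
        pairs = make_dictionary(10, seed=8)
        outputs = []
        for run in ("a", "b"):
            gold = make_gold(pairs, DEFAULT_MIX, n_records=20, seed=8)
            paths = write_fixtures(gold, tmp_path / run)
            outputs.append(
                tuple(paths[k].read_bytes() for k in ("dictionary", "gold", "manifest"))
            )
        assert outputs[0] == outputs[1]

    def test_manifest_records_parameters(self, tmp_path):
        import json

        pairs = make_dictionary(10, seed=3)
        gold = make_gold(pairs, DEFAULT_MIX, n_records=15, seed=3)
        paths = write_fixtures(gold, tmp_path / "fx")
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["seed"] == 3
        assert manifest["n_records"] == 15
        assert manifest["threshold"] == 0.2
        assert manifest["ngram_size"] == 2
        assert manifest["n_dictionary_entries"] == 10
        assert len(manifest["expected_steps"]) == 15
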