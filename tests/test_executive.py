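"""Theory presets, condition taxonomy, paradigms and sequence generation."""

import itertools
import random

import pytest

from npsim.dynamics import ConfigurationError
from npsim.executive import (CONDITIONS, THEORY_PRESETS, TheoryWeights,
                             build_paradigm, classify_condition,
                             generate_sequence, theory_preset)


class TestTheoryWeights:
    @pytest.mark.parametrize("name,expected", [
        ("distractor_inhibition", (0, 0, 0, 0, 0, 0, 0)),
        ("global_threshold", (0, 0, 1, 1, 0, 0, 0)),
        ("episodic_retrieval", (1, 1, 1, 0, 0, 0, 0)),
        ("response_retrieval", (1, 0, 1, 0, 0, 0, 0)),
        ("temporal_discrimination", (1, 1, 1, 0, 1, 1, 1)),
    ])
    def test_presets(self, name, expected):
        assert theory_preset(name).as_tuple() == expected

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ConfigurationError, match="distractor_inhibition"):
            theory_preset("quantum_interference")

    def test_presets_pairwise_distinct(self):
        tuples = [w.as_tuple() for w in THEORY_PRESETS.values()]
        assert len(set(tuples)) == len(tuples) == 5

    def test_configuration_space_is_128_and_contains_presets(self):
        space = {bits for bits in itertools.product((0, 1), repeat=7)}
        assert len(space) == 2 ** 7 == 128
        for w in THEORY_PRESETS.values():
            assert w.as_tuple() in space

    def test_non_binary_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            TheoryWeights(xi_er=0.5)


class TestClassifyCondition:
    @pytest.fixture(autouse=True)
    def _paradigm(self, voicekey):
        self.par = voicekey

    def disp(self, t, d):
        return self.par.make_display(t, d)

    @pytest.mark.parametrize("prime,probe,label", [
        (("tree", "bus"), ("bus", "ball"), "DT"),
        (("tree", "bus"), ("tree", "ball"), "TT"),
        (("tree", "bus"), ("ball", "tree"), "TD"),
        (("tree", "bus"), ("ball", "bus"), "DD"),
        (("tree", "bus"), ("tree", "bus"), "DDTT"),
        (("tree", "bus"), ("bus", "tree"), "DTTD"),
        (("tree", "bus"), ("ball", "book"), "CO"),
    ])
    def test_letter_scheme(self, prime, probe, label):
        assert classify_condition(self.disp(*prime), self.disp(*probe)) == label

    def test_agrees_with_brute_force_oracle_over_all_pairs(self):
        pool = self.par.object_pool

        def oracle(tp, dp, t, d):
            # enumerate the repetition structure explicitly
            both = (t == tp and d == dp)
            swapped = (t == dp and d == tp)
            if both:
                return "DDTT"
            if swapped:
                return "DTTD"
            if t == tp:
                return "TT"
            if t == dp:
                return "DT"
            if d == tp:
                return "TD"
            if d == dp:
                return "DD"
            return "CO"

        count = 0
        for tp, dp, t, d in itertools.product(pool, repeat=4):
            if tp == dp or t == d:
                continue
            assert classify_condition(self.disp(tp, dp), self.disp(t, d)) == \
                oracle(tp, dp, t, d)
            count += 1
        assert count == 30 * 30  # 6*5 ordered pairs on each side

    def test_malformed_display_rejected(self):
        with pytest.raises(ConfigurationError):
            self.par.make_display("tree", "tree")


class TestParadigms:
    def test_voicekey_structure(self, voicekey):
        assert voicekey.dimensions == ("color", "shape")
        assert len(voicekey.object_pool) == 6
        assert voicekey.actions[0] == "a0"
        assert set(voicekey.actions[1:]) == {f"name:{s}" for s in voicekey.object_pool}
        assert voicekey.target_defining == ("color", "green")

    def test_word_picture_structure(self, word_picture):
        assert word_picture.actions == ("a0", "yes", "no")
        assert "word" in word_picture.dimensions
        d = word_picture.make_display("tree", "bus", word="tree")
        assert d.correct_response == "yes"
        d = word_picture.make_display("tree", "bus", word="ball")
        assert d.correct_response == "no"

    def test_unknown_paradigm(self):
        with pytest.raises(ConfigurationError):
            build_paradigm("flanker")


class TestGenerateSequence:
    def test_condition_counts(self, voicekey):
        seq = generate_sequence(voicekey, ["CO", "DT", "TT", "DDTT", "DTTD"],
                                10, seed=3)
        assert len(seq) == 51
        labels = [d.condition for d in seq[1:]]
        for cond in ("CO", "DT", "TT", "DDTT", "DTTD"):
            assert labels.count(cond) == 10

    def test_chain_consistency(self, voicekey):
        """Every display's label matches its classification against the
        preceding display (continuous presentation)."""
        seq = generate_sequence(voicekey, list(CONDITIONS), 5, seed=11)
        for prime, probe in zip(seq, seq[1:]):
            assert classify_condition(prime, probe) == probe.condition

    def test_deterministic_for_fixed_seed(self, voicekey):
        a = generate_sequence(voicekey, ["CO", "DT"], 8, seed=5)
        b = generate_sequence(voicekey, ["CO", "DT"], 8, seed=5)
        assert a == b
        c = generate_sequence(voicekey, ["CO", "DT"], 8, seed=6)
        assert a != c

    def test_role_balance_within_one(self, voicekey):
        seq = generate_sequence(voicekey, ["CO", "DT", "TT", "TD", "DD"],
                                20, seed=1)
        t_cnt, d_cnt = {}, {}
        for disp in seq:
            t = disp.target.label("shape")
            d = disp.distractor.label("shape")
            t_cnt[t] = t_cnt.get(t, 0) + 1
            d_cnt[d] = d_cnt.get(d, 0) + 1
        for obj in voicekey.object_pool:
            assert abs(t_cnt.get(obj, 0) - d_cnt.get(obj, 0)) <= 1

    def test_comparison_response_relations(self, word_picture):
        seq = generate_sequence(word_picture, ["DTs", "DTr", "COs", "COr"],
                                5, seed=2)
        prev = seq[0]
        for disp in seq[1:]:
            if disp.response_relation == "r":
                assert disp.correct_response == prev.correct_response
            else:
                assert disp.correct_response != prev.correct_response
            prev = disp

    def test_relation_suffix_requires_comparison_paradigm(self, voicekey):
        with pytest.raises(ConfigurationError):
            generate_sequence(voicekey, ["DTs"], 2, seed=0)
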