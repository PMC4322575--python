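import itertools

import pytest

from cofreq.annotate import (
    ConceptMap,
    annotate_note,
    build_lexicon,
    flag_mentions,
    map_to_concepts,
    mentions_to_id_set,
    normalize_term,
)


@pytest.fixture()
def clinical_lexicon():
    lex, _ = build_lexicon(
        [
            ("chest pain", 7),
            ("myocardial infarction", 2),
            ("infarction", 8),
            ("pneumonia", 4),
            ("diabetes", 5),
            ("hydrocephalus", 6),
            ("clip", 1),
        ]
    )
    return lex


class TestBuildLexicon:
    def test_boundary_length_retained(self):
        lex, report = build_lexicon([("clip", 1), ("myocardial infarction", 2)])
        assert set(lex.terms) == {"clip", "myocardial infarction"}
        assert not any(report.values())

    @pytest.mark.parametrize(
        "entry, kwargs, reason",
        [
            (("mi", 3), {}, "too_short"),
            (("paige", 9), {"name_homonyms": {"paige"}}, "name_homonym"),
            (("with", 10), {"stop_words": {"with"}}, "stop_word"),
        ],
    )
    def test_suppression_rules(self, entry, kwargs, reason):
        lex, report = build_lexicon([entry, ("pneumonia", 4)], **kwargs)
        assert entry[0] not in lex.terms
        assert entry[0] in report[reason]
        assert "pneumonia" in lex.terms

    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            build_lexicon([("chest pain", 1), ("Chest  Pain", 2)])

    def test_empty_entries_rejected(self):
        with pytest.raises(ValueError):
            build_lexicon([])


class TestAnnotateNote:
    def test_single_match(self, clinical_lexicon):
        mentions = annotate_note("pt denies chest pain", clinical_lexicon)
        assert [m.term_id for m in mentions] == [7]
        assert mentions[0].start == 10 and mentions[0].end == 20

    def test_empty_text(self, clinical_lexicon):
        assert annotate_note("", clinical_lexicon) == []

    def test_case_insensitive_and_punctuation(self, clinical_lexicon):
        mentions = annotate_note("CHEST PAIN, pneumonia.", clinical_lexicon)
        assert sorted(m.term_id for m in mentions) == [4, 7]

    def test_longest_match_wins(self, clinical_lexicon):
        """Maximal munch: verified against exhaustive enumeration of all
        non-overlapping tokenizations of the fixture text."""
        text = "myocardial infarction"
        mentions = annotate_note(text, clinical_lexicon)
        assert [m.term_id for m in mentions] == [2]

        # brute-force oracle: every way to cover the 2 tokens with lexicon
        # entries; the maximal-munch result must be the one consuming the
        # most tokens from the left
        tokens = text.split()
        index = {normalize_term(s): tid for s, tid in clinical_lexicon.terms.items()}
        covers = []
        for split in range(len(tokens) + 1):
            left = tuple(tokens[:split])
            if split and left not in index:
                continue
            rest = tuple(tokens[split:])
            if rest and rest not in index:
                continue
            covers.append((split, [index[seg] for seg in (left, rest) if seg]))
        best = max(covers, key=lambda c: c[0])
        assert [m.term_id for m in mentions] == best[1]

    def test_order_independent_of_lexicon_insertion(self):
        entries = [("chest pain", 7), ("pain free", 9), ("pneumonia", 4)]
        text = "chest pain and pneumonia"
        results = set()
        for perm in itertools.permutations(entries):
            lex, _ = build_lexicon(list(perm))
            results.add(tuple(m.term_id for m in annotate_note(text, lex)))
        assert len(results) == 1

    def test_idempotent(self, clinical_lexicon):
        text = "hydrocephalus with chest pain"
        first = annotate_note(text, clinical_lexicon)
        second = annotate_note(text, clinical_lexicon)
        assert first == second


class TestFlagMentions:
    def _flags(self, text, lexicon):
        mentions = flag_mentions(text, annotate_note(text, lexicon))
        return {m.term_id: (m.negated, m.history, m.family_history) for m in mentions}

    def test_post_trigger_negation(self, clinical_lexicon):
        flags = self._flags("myocardial infarction was ruled out", clinical_lexicon)
        assert flags[2][0] is True

    def test_pre_trigger_negation(self, clinical_lexicon):
        flags = self._flags("no evidence of pneumonia", clinical_lexicon)
        assert flags[4][0] is True

    def test_affirmed_mention_not_negated(self, clinical_lexicon):
        flags = self._flags("patient presents with chest pain", clinical_lexicon)
        assert flags[7][0] is False

    def test_family_history_section(self, clinical_lexicon):
        flags = self._flags("FAMILY HISTORY: diabetes", clinical_lexicon)
        assert flags[5] == (False, False, True)

    def test_history_section_ends_at_next_marker(self, clinical_lexicon):
        text = "HISTORY: pneumonia. FAMILY HISTORY: diabetes"
        flags = self._flags(text, clinical_lexicon)
        assert flags[4] == (False, True, False)
        assert flags[5] == (False, False, True)

    def test_trigger_outside_window_does_not_negate(self, clinical_lexicon):
        text = "no x x x x x x x x pneumonia"
        flags = self._flags(text, clinical_lexicon)
        assert flags[4][0] is False

    def test_counting_policy_defaults(self, clinical_lexicon):
        text = "no pneumonia. FAMILY HISTORY: diabetes. HISTORY: hydrocephalus"
        mentions = flag_mentions(text, annotate_note(text, clinical_lexicon))
        assert mentions_to_id_set(mentions) == frozenset({6})
        assert mentions_to_id_set(
            mentions, include_negated=True, include_family_history=True
        ) == frozenset({4, 5, 6})


@pytest.fixture()
def concept_fixture():
    # 'clip' maps to a device and (suppressed) a drug; drug B normalises to
    # ingredient A
    cmap = ConceptMap(
        term_to_concepts={1: frozenset({101, 102}), 4: frozenset({103}), 8: frozenset()},
        concept_to_cui={101: "C0001", 102: "C0002", 103: "C0003", 104: "C0004"},
        concept_to_string={101: "clip device", 102: "CLIP peptide", 103: "drug B", 104: "ingredient A"},
        concept_group={101: "device", 102: "drug", 103: "drug", 104: "drug"},
        suppressed_pairs=frozenset({(1, 102)}),
        ingredient_map={103: 104},
    )
    return cmap


class TestMapToConcepts:
    def _mention(self, tid):
        from cofreq.annotate import TermMention

        return TermMention(term_id=tid, start=0, end=4)

    def test_suppressed_interpretation_removed(self, concept_fixture):
        out = map_to_concepts([self._mention(1)], concept_fixture)
        assert [c.concept_id for c in out] == [101]

    def test_unmapped_term_dropped_at_concept_level(self, concept_fixture):
        assert map_to_concepts([self._mention(8)], concept_fixture) == []

    def test_drug_normalised_to_ingredient(self, concept_fixture):
        out = map_to_concepts([self._mention(4)], concept_fixture)
        assert [c.concept_id for c in out] == [104]

    def test_group_restriction_requires_unambiguous(self, concept_fixture):
        # term 1 still maps to one concept after suppression -> kept if the
        # group matches, dropped otherwise
        kept = map_to_concepts(
            [self._mention(1)], concept_fixture, restrict_to_groups={"device"}
        )
        assert [c.concept_id for c in kept] == [101]
        dropped = map_to_concepts(
            [self._mention(1)], concept_fixture, restrict_to_groups={"drug", "disease"}
        )
        assert dropped == []

    def test_term_level_passthrough(self, concept_fixture):
        m = self._mention(1)
        assert map_to_concepts([m], concept_fixture, level="term") == [m]

    def test_missing_cui_is_error(self):
        with pytest.raises(ValueError, match="one-to-one"):
            ConceptMap(
                term_to_concepts={1: frozenset({101})},
                concept_to_cui={101: "C0001", 102: "C0001"},
            )


class TestLosslessRecovery:
    def test_annotation_recovers_ground_truth(self, small_corpus, small_lexicon):
        """Synthetic note text decodes exactly back to the planted term sets."""
        for note, planted in zip(small_corpus.notes, small_corpus.presence):
            recovered = mentions_to_id_set(annotate_note(note.text, small_lexicon))
            assert recovered == planted
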