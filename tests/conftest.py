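import pytest

from cofreq.annotate import annotate_note, mentions_to_id_set
from cofreq.binning import NoteRecord
from cofreq.simulate import (
    SimulationConfig,
    PlantedPair,
    generate_corpus,
    synthetic_lexicon,
)


def annotated_notes(corpus, via_annotator=False, lexicon=None):
    """Notes carrying term-ID sets: from ground truth, or through the
    dictionary matcher when via_annotator=True."""
    notes = []
    for note, ids in zip(corpus.notes, corpus.presence):
        if via_annotator:
            ids = mentions_to_id_set(annotate_note(note.text, lexicon))
        notes.append(
            NoteRecord(
                patient_id=note.patient_id,
                timestamp=note.timestamp,
                text="",
                term_ids=frozenset(ids),
            )
        )
    return notes


@pytest.fixture(scope="session")
def small_corpus():
    """20 patients, ~200 notes, one planted association."""
    cfg = SimulationConfig(
        n_patients=20,
        notes_per_patient=(8, 12),
        time_span_days=800.0,
        vocabulary_size=60,
        terms_per_note=(3, 6),
        planted_pairs=(PlantedPair(5, 9, 0.4),),
        seed=42,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_lexicon(small_corpus):
    return synthetic_lexicon(small_corpus.config)


@pytest.fixture(scope="session")
def validation_corpus():
    """The validation-design corpus: 1,000 notes over 100 patients."""
    cfg = SimulationConfig(
        n_patients=100,
        notes_per_patient=(10, 10),
        time_span_days=730.0,
        vocabulary_size=200,
        terms_per_note=(5, 15),
        planted_pairs=(PlantedPair(3, 11, 0.3),),
        seed=1,
    )
    return generate_corpus(cfg)
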