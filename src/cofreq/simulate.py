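"""Synthetic longitudinal note corpora with known term placements.

The generator emulates the validation design used for the counting
pipeline: simulate a stream of random "notes" for a cohort of simulated
patients, remember exactly which terms were planted in each note, and
derive the correct singleton/co-occurrence counts by exhaustive
enumeration so every downstream stage can be checked against a known
answer.

Note text is whitespace-joined term strings drawn verbatim from the
synthetic lexicon, interleaved with filler tokens that are absent from the
lexicon, so annotation is exactly invertible and any counting discrepancy
is attributable.  Planted pairwise associations are realised by
co-injecting both members of a pair into the same note with the configured
probability; background terms are drawn from the vocabulary EXCLUDING
planted-pair members, so a planted pair's per-note marginal probability
equals its joint probability and the analytic lift of the pair is exactly
``1/p`` when each note lands in its own bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotate import ConceptMap, Lexicon, build_lexicon
from .binning import NoteRecord, assign_bin
from .counting import AggregationMode, CoFrequencyMatrix, SingletonCounts
from . import formats


@dataclass(frozen=True)
class PlantedPair:
    """A pairwise association injected into the corpus: both terms appear
    together in a note with probability ``joint_probability`` per note."""

    term_x: int
    term_y: int
    joint_probability: float


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 100
    notes_per_patient: tuple[int, int] = (10, 10)
    time_span_days: float = 730.0
    vocabulary_size: int = 200
    terms_per_note: tuple[int, int] = (5, 15)
    planted_pairs: tuple[PlantedPair, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.vocabulary_size <= 0:
            raise ValueError("vocabulary_size must be positive")
        if self.time_span_days <= 0:
            raise ValueError("time_span_days must be positive")
        lo, hi = self.notes_per_patient
        if not (0 < lo <= hi):
            raise ValueError("notes_per_patient range must satisfy 0 < lo <= hi")
        lo, hi = self.terms_per_note
        if not (0 <= lo <= hi):
            raise ValueError("terms_per_note range must satisfy 0 <= lo <= hi")
        planted_ids = set()
        for pp in self.planted_pairs:
            if not (0.0 <= pp.joint_probability <= 1.0):
                raise ValueError(
                    f"planted pair ({pp.term_x},{pp.term_y}): joint probability "
                    f"{pp.joint_probability} outside [0,1] is unsatisfiable"
                )
            for tid in (pp.term_x, pp.term_y):
                if not (1 <= tid <= self.vocabulary_size):
                    raise ValueError(
                        f"planted pair ({pp.term_x},{pp.term_y}): term {tid} "
                        f"outside vocabulary 1..{self.vocabulary_size}"
                    )
            if pp.term_x == pp.term_y:
                raise ValueError(
                    f"planted pair ({pp.term_x},{pp.term_y}) is a self-pair"
                )
            planted_ids.update((pp.term_x, pp.term_y))
        if self.vocabulary_size - len(planted_ids) < self.terms_per_note[1]:
            raise ValueError(
                "vocabulary too small to draw background terms without "
                "replacement once planted terms are excluded"
            )


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated notes plus the generator's own record of what it planted.

    ``presence[i]`` is the exact term-ID set planted in ``notes[i]``; within
    each patient, note timestamps are non-decreasing in note order.
    """

    notes: list[NoteRecord]
    presence: list[frozenset[int]]
    config: SimulationConfig

    def ground_truth_presence(self) -> dict[str, list[frozenset[int]]]:
        out: dict[str, list[frozenset[int]]] = {}
        for note, ids in zip(self.notes, self.presence):
            out.setdefault(note.patient_id, []).append(ids)
        return out


def term_string(term_id: int) -> str:
    """Synthetic dictionary string for a term ID.

    Every fifth term is a two-word phrase so multi-token matching is
    exercised; all strings are >= 4 characters and mutually prefix-free.
    """
    if term_id % 5 == 0:
        return f"alpha{term_id:05d} beta{term_id:05d}"
    return f"term{term_id:05d}"


def synthetic_lexicon(config: SimulationConfig) -> Lexicon:
    entries = [(term_string(i), i) for i in range(1, config.vocabulary_size + 1)]
    lexicon, _ = build_lexicon(entries)
    return lexicon


def synthetic_concept_map(config: SimulationConfig) -> ConceptMap:
    """Identity-like term→concept map (concept i ↔ term i, CUI C{i:07d});
    alternating drug/disease groups."""
    v = config.vocabulary_size
    return ConceptMap(
        term_to_concepts={i: frozenset({i}) for i in range(1, v + 1)},
        concept_to_cui={i: f"C{i:07d}" for i in range(1, v + 1)},
        concept_to_string={i: term_string(i) for i in range(1, v + 1)},
        concept_group={i: ("drug" if i % 2 else "disease") for i in range(1, v + 1)},
    )


def generate_corpus(config: SimulationConfig) -> SyntheticCorpus:
    """Generate a corpus; deterministic for a fixed seed.

    Per patient: a note count uniform on ``notes_per_patient``, timestamps
    uniform on ``[0, time_span_days]`` then sorted.  Per note: each planted
    pair co-injects both terms with its joint probability, then background
    terms are drawn uniformly without replacement from the non-planted
    vocabulary; term strings and out-of-lexicon filler tokens are shuffled
    into the note text.
    """
    rng = np.random.default_rng(config.seed)
    planted_ids = sorted(
        {t for pp in config.planted_pairs for t in (pp.term_x, pp.term_y)}
    )
    background_vocab = np.array(
        [i for i in range(1, config.vocabulary_size + 1) if i not in set(planted_ids)]
    )
    notes: list[NoteRecord] = []
    presence: list[frozenset[int]] = []
    pid_digits = max(4, len(str(config.n_patients)))
    for k in range(config.n_patients):
        patient_id = f"P{k:0{pid_digits}d}"
        lo, hi = config.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        times = np.sort(rng.uniform(0.0, config.time_span_days, size=n_notes))
        for t in times:
            ids: set[int] = set()
            for pp in config.planted_pairs:
                if rng.random() < pp.joint_probability:
                    ids.add(pp.term_x)
                    ids.add(pp.term_y)
            lo_t, hi_t = config.terms_per_note
            n_bg = int(rng.integers(lo_t, hi_t + 1))
            if n_bg > 0:
                ids.update(
                    int(i)
                    for i in rng.choice(background_vocab, size=n_bg, replace=False)
                )
            units = [term_string(i) for i in sorted(ids)]
            n_filler = int(rng.integers(1, 4))
            units += [f"zz{int(rng.integers(0, 1000)):03d}" for _ in range(n_filler)]
            order = rng.permutation(len(units))
            text = " ".join(units[i] for i in order)
            notes.append(NoteRecord(patient_id=patient_id, timestamp=float(t), text=text))
            presence.append(frozenset(ids))
    return SyntheticCorpus(notes=notes, presence=presence, config=config)


def ground_truth_counts(
    corpus: SyntheticCorpus,
    width: float,
    mode: AggregationMode | str,
    offsets: dict[str, float],
) -> tuple[CoFrequencyMatrix, SingletonCounts]:
    """Known-answer counts by direct exhaustive enumeration.

    Recomputes bin membership from the planted presence sets and the exact
    offsets used by the binning run under test, independently of the
    annotation and counting modules.
    """
    mode = AggregationMode.parse(mode)
    per_patient = corpus.ground_truth_presence()
    times: dict[str, list[float]] = {}
    for note in corpus.notes:
        times.setdefault(note.patient_id, []).append(note.timestamp)
    missing = sorted(set(offsets) - set(per_patient))
    if missing:
        raise ValueError(f"patients in offsets missing from corpus: {missing}")

    bin_sets: dict[str, dict[int, set[int]]] = {}
    for patient_id, id_sets in per_patient.items():
        if patient_id not in offsets:
            raise ValueError(f"no offset supplied for patient {patient_id!r}")
        r = offsets[patient_id]
        ts = times[patient_id]
        t0 = min(ts)
        buckets: dict[int, set[int]] = {}
        for t, ids in zip(ts, id_sets):
            idx = 0 if math.isinf(width) else assign_bin(width, r, t - t0)
            buckets.setdefault(idx, set()).update(ids)
        bin_sets[patient_id] = buckets

    singles: dict[int, int] = {}
    pairs: dict[tuple[int, int], int] = {}
    n_bins = sum(len(b) for b in bin_sets.values())
    n_universe = n_bins if mode is AggregationMode.PER_BIN else len(bin_sets)
    for patient_id, buckets in bin_sets.items():
        if mode is AggregationMode.PER_BIN:
            iterable = list(buckets.values())
        else:
            # a patient contributes at most once per entity/pair
            p_singles: set[int] = set()
            p_pairs: set[tuple[int, int]] = set()
            for ids in buckets.values():
                p_singles.update(ids)
                ordered = sorted(ids)
                for i in range(len(ordered)):
                    for j in range(i + 1, len(ordered)):
                        p_pairs.add((ordered[i], ordered[j]))
            for tid in p_singles:
                singles[tid] = singles.get(tid, 0) + 1
            for key in p_pairs:
                pairs[key] = pairs.get(key, 0) + 1
            continue
        for ids in iterable:
            ordered = sorted(ids)
            for i, x in enumerate(ordered):
                singles[x] = singles.get(x, 0) + 1
                for y in ordered[i + 1 :]:
                    pairs[(x, y)] = pairs.get((x, y), 0) + 1
    matrix = CoFrequencyMatrix(counts=pairs, mode=mode, width=width, level="term", n=n_universe)
    singletons = SingletonCounts(
        counts=singles, mode=mode, width=width, level="term", n=n_universe
    )
    return matrix, singletons


# ---------------------------------------------------------------------------
# On-disk representation

def write_corpus(corpus: SyntheticCorpus, path) -> None:
    """Corpus as 3-column TSV: patient_id, timestamp_days, text."""
    body = "".join(
        f"{n.patient_id}\t{n.timestamp:.6f}\t{n.text}\n" for n in corpus.notes
    )
    formats._atomic_write(path, body)


def read_corpus(path) -> list[NoteRecord]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise formats.ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
            notes.append(
                NoteRecord(patient_id=parts[0], timestamp=float(parts[1]), text=parts[2])
            )
    return notes


def write_config(config: SimulationConfig, path) -> None:
    """Flat key=value file (lists as comma-joined triples x:y:p)."""
    pairs = ",".join(
        f"{pp.term_x}:{pp.term_y}:{pp.joint_probability}" for pp in config.planted_pairs
    )
    body = (
        f"n_patients={config.n_patients}\n"
        f"notes_per_patient={config.notes_per_patient[0]},{config.notes_per_patient[1]}\n"
        f"time_span_days={config.time_span_days}\n"
        f"vocabulary_size={config.vocabulary_size}\n"
        f"terms_per_note={config.terms_per_note[0]},{config.terms_per_note[1]}\n"
        f"planted_pairs={pairs}\n"
        f"seed={config.seed}\n"
    )
    formats._atomic_write(path, body)


def read_config(path) -> SimulationConfig:
    kv: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
    planted = []
    if kv.get("planted_pairs"):
        for chunk in kv["planted_pairs"].split(","):
            x, y, p = chunk.split(":")
            planted.append(PlantedPair(int(x), int(y), float(p)))
    npp = kv["notes_per_patient"].split(",")
    tpn = kv["terms_per_note"].split(",")
    return SimulationConfig(
        n_patients=int(kv["n_patients"]),
        notes_per_patient=(int(npp[0]), int(npp[1])),
        time_span_days=float(kv["time_span_days"]),
        vocabulary_size=int(kv["vocabulary_size"]),
        terms_per_note=(int(tpn[0]), int(tpn[1])),
        planted_pairs=tuple(planted),
        seed=int(kv["seed"]),
    )


def write_companion_lexicon(config: SimulationConfig, directory) -> dict[str, str]:
    """Write the dictionary file family for a synthetic corpus; returns the
    filename map."""
    from pathlib import Path

    directory = Path(directory)
    lexicon = synthetic_lexicon(config)
    cmap = synthetic_concept_map(config)
    files = {
        "terms": "terms.tsv",
        "concept_strings": "concept_strings.tsv",
        "concept_cuis": "concept_cuis.tsv",
        "term_concepts": "term_concepts.tsv",
        "stop_words": "stop_words.txt",
    }
    formats.write_term_file(lexicon.id_to_string(), directory / files["terms"])
    formats.write_concept_string_file(
        cmap.concept_to_string, cmap.concept_to_cui, directory / files["concept_strings"]
    )
    formats.write_concept_cui_file(cmap.concept_to_cui, directory / files["concept_cuis"])
    formats.write_term_concept_file(cmap.term_to_concepts, directory / files["term_concepts"])
    formats.write_stop_word_file([], directory / files["stop_words"])
    return files
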