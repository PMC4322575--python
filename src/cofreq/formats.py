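"""Readers/writers for the published tab-delimited data-record files.

Five file families:

* co-frequency files — three tab-delimited columns ``id_x  id_y  count``,
  one row per unordered pair (``id_x < id_y``);
* singleton files — two columns ``id  count``;
* dictionary files — File 1 (term_id → string), File 2a (concept_id →
  string, CUI), File 2b (concept_id → CUI), File 3 (term_id → concept_id,
  many-to-many), File 4 (stop words, one per line).

A complete term+concept export comprises 28 co-frequency files (7 widths ×
2 modes × 2 levels) and 16 singleton files (per-bin: 7 widths × 2 levels;
per-patient: one per level, since per-patient singleton counts do not
depend on the bin width).

Output is canonical: UTF-8, LF line endings, header-less, rows sorted by
ID, newline-terminated, no trailing whitespace — so a fixed input always
produces a byte-identical file.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable, Iterator

from .annotate import ConceptMap, Lexicon, build_lexicon
from .binning import CANONICAL_WIDTHS, width_token
from .counting import (
    AggregationMode,
    CoFrequencyMatrix,
    SingletonCounts,
    apply_count_threshold,
)


class ParseError(ValueError):
    """Malformed row in a data-record file (carries path and line number)."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _atomic_write(path: Path, body: str) -> None:
    """Write via a temp file + rename so a failure never leaves a truncated
    file behind."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(body)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cofrequency_file(
    matrix: CoFrequencyMatrix, path, threshold: int | None = None
) -> None:
    """Write a co-frequency file; rows sorted by (id_x, id_y).

    With ``threshold`` set, rows with count <= threshold are dropped at
    serialization time (the in-memory matrix is untouched).
    """
    m = matrix if threshold is None else apply_count_threshold(matrix, threshold)
    lines = []
    for (x, y) in sorted(m.counts):
        c = m.counts[(x, y)]
        if c <= 0:
            raise ValueError(f"pair ({x},{y}) has non-positive count {c}")
        if x >= y:
            raise ValueError(f"pair key ({x},{y}) is not canonical (id_x < id_y)")
        lines.append(f"{x}\t{y}\t{c}\n")
    _atomic_write(Path(path), "".join(lines))


def read_cofrequency_file(
    path,
    mode: AggregationMode | str = AggregationMode.PER_BIN,
    width: float | None = None,
    level: str = "term",
    n: int = 0,
) -> CoFrequencyMatrix:
    """Read a co-frequency file; metadata (mode/width/level/N) is supplied by
    the caller because the file itself carries only the three columns."""
    counts: dict[tuple[int, int], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
            try:
                x, y, c = (int(p) for p in parts)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer field in {parts!r}") from None
            if x >= y:
                raise ParseError(path, lineno, f"pair ({x},{y}) not canonical (id_x < id_y)")
            if (x, y) in counts:
                raise ParseError(path, lineno, f"duplicate pair ({x},{y})")
            counts[(x, y)] = c
    return CoFrequencyMatrix(
        counts=counts, mode=AggregationMode.parse(mode), width=width, level=level, n=n
    )


def write_singleton_file(
    singletons: SingletonCounts, path, threshold: int | None = None
) -> None:
    """Write a singleton file; rows sorted by id."""
    s = singletons if threshold is None else apply_count_threshold(singletons, threshold)
    lines = []
    for i in sorted(s.counts):
        c = s.counts[i]
        if c <= 0:
            raise ValueError(f"id {i} has non-positive count {c}")
        lines.append(f"{i}\t{c}\n")
    _atomic_write(Path(path), "".join(lines))


def read_singleton_file(
    path,
    mode: AggregationMode | str = AggregationMode.PER_BIN,
    width: float | None = None,
    level: str = "term",
    n: int = 0,
) -> SingletonCounts:
    counts: dict[int, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(path, lineno, f"expected 2 columns, got {len(parts)}")
            try:
                i, c = (int(p) for p in parts)
            except ValueError:
                raise ParseError(path, lineno, f"non-integer field in {parts!r}") from None
            if i in counts:
                raise ParseError(path, lineno, f"duplicate id {i}")
            counts[i] = c
    return SingletonCounts(
        counts=counts, mode=AggregationMode.parse(mode), width=width, level=level, n=n
    )


# ---------------------------------------------------------------------------
# Dictionary files (Fig.-2 style ID maps)

def write_term_file(id_to_string: dict[int, str], path) -> None:
    """File 1: term_id TAB string."""
    _atomic_write(
        Path(path), "".join(f"{i}\t{id_to_string[i]}\n" for i in sorted(id_to_string))
    )


def write_concept_string_file(
    concept_to_string: dict[int, str], concept_to_cui: dict[int, str], path
) -> None:
    """File 2a: concept_id TAB string TAB CUI."""
    _atomic_write(
        Path(path),
        "".join(
            f"{i}\t{concept_to_string[i]}\t{concept_to_cui[i]}\n"
            for i in sorted(concept_to_string)
        ),
    )


def write_concept_cui_file(concept_to_cui: dict[int, str], path) -> None:
    """File 2b: concept_id TAB CUI."""
    _atomic_write(
        Path(path), "".join(f"{i}\t{concept_to_cui[i]}\n" for i in sorted(concept_to_cui))
    )


def write_term_concept_file(term_to_concepts: dict[int, frozenset[int]], path) -> None:
    """File 3: term_id TAB concept_id, one row per mapping pair."""
    lines = []
    for tid in sorted(term_to_concepts):
        for cid in sorted(term_to_concepts[tid]):
            lines.append(f"{tid}\t{cid}\n")
    _atomic_write(Path(path), "".join(lines))


def write_stop_word_file(stop_words: Iterable[str], path) -> None:
    """File 4: one stop word per line."""
    _atomic_write(Path(path), "".join(f"{w}\n" for w in sorted(stop_words)))


def _read_tsv(path, arity: int) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != arity:
                raise ParseError(path, lineno, f"expected {arity} columns, got {len(parts)}")
            yield lineno, parts


def read_dictionaries(
    term_file,
    concept_string_file=None,
    concept_cui_file=None,
    term_concept_file=None,
    stop_word_file=None,
    min_term_length: int = 4,
) -> tuple[Lexicon, ConceptMap | None]:
    """Load the dictionary file family with cross-file consistency checks.

    File 3 term IDs must be a subset of File 1's; File 3 concept IDs a
    subset of File 2a's; Files 2a and 2b must agree on the concept→CUI map
    (which is one-to-one).  Dangling IDs raise a validation error listing
    the offenders.
    """
    entries: list[tuple[str, int]] = []
    for lineno, (tid_s, string) in _read_tsv(term_file, 2):
        try:
            entries.append((string, int(tid_s)))
        except ValueError:
            raise ParseError(term_file, lineno, f"non-integer term id {tid_s!r}") from None

    stop_words: frozenset[str] = frozenset()
    if stop_word_file is not None:
        with open(stop_word_file, encoding="utf-8") as fh:
            stop_words = frozenset(w.strip().lower() for w in fh if w.strip())

    lexicon, _ = build_lexicon(entries, stop_words=stop_words, min_length=min_term_length)

    concept_map = None
    if concept_string_file is not None or concept_cui_file is not None:
        concept_to_string: dict[int, str] = {}
        cui_a: dict[int, str] = {}
        if concept_string_file is not None:
            for lineno, (cid_s, string, cui) in _read_tsv(concept_string_file, 3):
                cid = int(cid_s)
                concept_to_string[cid] = string
                cui_a[cid] = cui
        cui_b: dict[int, str] = {}
        if concept_cui_file is not None:
            for lineno, (cid_s, cui) in _read_tsv(concept_cui_file, 2):
                cui_b[int(cid_s)] = cui
        if cui_a and cui_b:
            disagree = {c for c in cui_a.keys() & cui_b.keys() if cui_a[c] != cui_b[c]}
            if disagree:
                raise ValueError(
                    f"concept->CUI disagreement between 2a and 2b for: {sorted(disagree)}"
                )
        concept_to_cui = {**cui_b, **cui_a}

        term_to_concepts: dict[int, frozenset[int]] = {}
        if term_concept_file is not None:
            mapping: dict[int, set[int]] = {}
            for lineno, (tid_s, cid_s) in _read_tsv(term_concept_file, 2):
                mapping.setdefault(int(tid_s), set()).add(int(cid_s))
            known_tids = set(lexicon.terms.values()) | {tid for _, tid in entries}
            dangling_t = sorted(set(mapping) - known_tids)
            if dangling_t:
                raise ValueError(f"term->concept file references unknown term IDs: {dangling_t}")
            dangling_c = sorted(
                {c for cs in mapping.values() for c in cs} - set(concept_to_cui)
            )
            if dangling_c:
                raise ValueError(
                    f"term->concept file references unknown concept IDs: {dangling_c}"
                )
            term_to_concepts = {t: frozenset(cs) for t, cs in mapping.items()}
        concept_map = ConceptMap(
            term_to_concepts=term_to_concepts,
            concept_to_cui=concept_to_cui,
            concept_to_string=concept_to_string,
        )
    return lexicon, concept_map


def decode_counts(count_file, mapping: dict[int, str]) -> Iterator[tuple]:
    """Decode a co-frequency or singleton file through an ID→string map.

    Yields ``(string_x, string_y, count)`` or ``(string, count)`` rows,
    preserving file order.  An ID missing from the map is an error — never
    a silent skip.
    """
    with open(count_file, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ParseError(count_file, lineno, f"expected 2 or 3 columns, got {len(parts)}")
            try:
                ints = [int(p) for p in parts]
            except ValueError:
                raise ParseError(count_file, lineno, f"non-integer field in {parts!r}") from None
            ids, count = ints[:-1], ints[-1]
            for i in ids:
                if i not in mapping:
                    raise KeyError(f"{count_file}:{lineno}: unknown ID {i}")
            yield tuple(mapping[i] for i in ids) + (count,)


# ---------------------------------------------------------------------------
# Export manifest

MODES = (AggregationMode.PER_BIN, AggregationMode.PER_PATIENT)
LEVELS = ("term", "concept")


def cofrequency_filename(level: str, mode: AggregationMode, width: float) -> str:
    return f"cofreq_{level}_{mode.value}_{width_token(width)}.tsv"


def singleton_filename(level: str, mode: AggregationMode, width: float | None) -> str:
    if mode is AggregationMode.PER_PATIENT:
        return f"singletons_{level}_per-patient.tsv"
    return f"singletons_{level}_per-bin_{width_token(width)}.tsv"


def build_manifest(
    widths: tuple[float, ...] = CANONICAL_WIDTHS,
    levels: tuple[str, ...] = LEVELS,
    modes: tuple[AggregationMode, ...] = MODES,
) -> dict[str, list[str]]:
    """Filename manifest for an export over the given widths/levels/modes."""
    cofreq = [
        cofrequency_filename(level, mode, w)
        for level in levels
        for mode in modes
        for w in widths
    ]
    singles = [
        singleton_filename(level, AggregationMode.PER_BIN, w)
        for level in levels
        for w in widths
    ]
    if AggregationMode.PER_PATIENT in modes:
        singles += [
            singleton_filename(level, AggregationMode.PER_PATIENT, None)
            for level in levels
        ]
    return {"cofrequency": cofreq, "singleton": singles}


def check_complete_manifest(manifest: dict[str, list[str]]) -> None:
    """A full export has exactly 28 co-frequency and 16 singleton files."""
    n_co, n_s = len(manifest["cofrequency"]), len(manifest["singleton"])
    if n_co != 28 or n_s != 16:
        raise ValueError(
            f"incomplete export manifest: {n_co} co-frequency files (want 28), "
            f"{n_s} singleton files (want 16)"
        )
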