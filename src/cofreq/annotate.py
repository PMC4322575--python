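"""Dictionary-based term recognition, negation/section flagging, and
term→concept mapping.

The recogniser is a deterministic maximal-munch matcher: the note is
lowercased and tokenised on non-word boundaries, and at each position the
longest dictionary n-gram wins; matches never overlap.  Suppression rules
(stop words, first/surname homonyms, strings shorter than four characters,
which tend to be ambiguous abbreviations) are applied when the lexicon is
built, so nothing downstream ever sees a suppressed term.

Negation is a trigger-window approximation of NegEx: a mention is flagged
negated when a pre-trigger ends within a fixed token window before it
("no evidence of pneumonia") or a post-trigger starts within the window
after it ("myocardial infarction was ruled out").  History and family
history are flagged by section markers: a mention carries the flag when it
falls after a matching marker and before the next section marker of any
kind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")

DEFAULT_MIN_TERM_LENGTH = 4
DEFAULT_NEGATION_WINDOW = 6

SEMANTIC_GROUPS = ("drug", "disease", "device", "procedure", "other")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Lowercased word tokens with character spans."""
    return [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def normalize_term(s: str) -> tuple[str, ...]:
    """Normalise a dictionary string to its token tuple (lowercase, punctuation
    stripped at token boundaries, whitespace collapsed)."""
    return tuple(t for t, _, _ in tokenize(s))


@dataclass(frozen=True)
class Lexicon:
    """Term dictionary after suppression.

    ``terms`` maps the original (retained) term string to its integer ID;
    ``index`` maps normalised token tuples to IDs and drives matching.
    """

    terms: dict[str, int]
    index: dict[tuple[str, ...], int]
    stop_words: frozenset[str] = frozenset()
    name_homonyms: frozenset[str] = frozenset()
    min_term_length: int = DEFAULT_MIN_TERM_LENGTH

    @property
    def max_token_length(self) -> int:
        return max((len(k) for k in self.index), default=0)

    def id_to_string(self) -> dict[int, str]:
        return {tid: s for s, tid in self.terms.items()}


@dataclass(frozen=True)
class TermMention:
    """A recognised term occurrence in one note."""

    term_id: int
    start: int
    end: int
    negated: bool = False
    history: bool = False
    family_history: bool = False


@dataclass(frozen=True)
class ConceptMention:
    """A term mention resolved to a normalised clinical concept."""

    concept_id: int
    start: int
    end: int
    negated: bool = False
    history: bool = False
    family_history: bool = False


@dataclass(frozen=True)
class ConceptMap:
    """Term→concept (many-to-many) and concept→CUI (one-to-one) mappings.

    ``suppressed_pairs`` removes specific ambiguous interpretations, e.g.
    'clip' as the peptide drug rather than the device.  ``ingredient_map``
    normalises drug concepts to their ingredient concepts.
    """

    term_to_concepts: dict[int, frozenset[int]]
    concept_to_cui: dict[int, str]
    concept_to_string: dict[int, str] = field(default_factory=dict)
    concept_group: dict[int, str] = field(default_factory=dict)
    suppressed_pairs: frozenset[tuple[int, int]] = frozenset()
    ingredient_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cuis: dict[str, int] = {}
        for cid, cui in self.concept_to_cui.items():
            if cui in cuis and cuis[cui] != cid:
                raise ValueError(
                    f"concept->CUI must be one-to-one: CUI {cui!r} maps to "
                    f"concepts {cuis[cui]} and {cid}"
                )
            cuis[cui] = cid
        for tid, cid in self.suppressed_pairs:
            if cid not in self.term_to_concepts.get(tid, frozenset()):
                raise ValueError(
                    f"suppressed pair ({tid}, {cid}) not present in the "
                    f"term->concept map"
                )


def build_lexicon(
    raw_entries: list[tuple[str, int]],
    stop_words: frozenset[str] | set[str] = frozenset(),
    name_homonyms: frozenset[str] | set[str] = frozenset(),
    min_length: int = DEFAULT_MIN_TERM_LENGTH,
) -> tuple[Lexicon, dict[str, list[str]]]:
    """Build a lexicon, dropping entries that fail any suppression rule.

    Returns the lexicon and a report mapping drop reason (``stop_word``,
    ``name_homonym``, ``too_short``) to the dropped strings.
    """
    if not raw_entries:
        raise ValueError("raw_entries must be non-empty")
    stop = {w.strip().lower() for w in stop_words}
    names = {w.strip().lower() for w in name_homonyms}
    report: dict[str, list[str]] = {"stop_word": [], "name_homonym": [], "too_short": []}
    terms: dict[str, int] = {}
    index: dict[tuple[str, ...], int] = {}
    seen_ids: dict[int, str] = {}
    for raw, tid in raw_entries:
        key = raw.strip().lower()
        if key in stop:
            report["stop_word"].append(raw)
            continue
        if key in names:
            report["name_homonym"].append(raw)
            continue
        if len(key) < min_length:
            report["too_short"].append(raw)
            continue
        norm = normalize_term(raw)
        if not norm:
            report["too_short"].append(raw)
            continue
        if norm in index and index[norm] != tid:
            raise ValueError(
                f"duplicate term string {raw!r} with conflicting IDs "
                f"{index[norm]} and {tid}"
            )
        if tid in seen_ids and normalize_term(seen_ids[tid]) != norm:
            raise ValueError(f"term ID {tid} assigned to two distinct strings")
        terms[raw] = tid
        index[norm] = tid
        seen_ids[tid] = raw
    lex = Lexicon(
        terms=terms,
        index=index,
        stop_words=frozenset(stop),
        name_homonyms=frozenset(names),
        min_term_length=min_length,
    )
    return lex, report


def annotate_note(text: str, lexicon: Lexicon) -> list[TermMention]:
    """Find dictionary term mentions in a note (flags unset).

    Case-insensitive, longest-match-wins, leftmost, non-overlapping over
    the tokenised text; deterministic and independent of lexicon insertion
    order.
    """
    tokens = tokenize(text)
    if not tokens or not lexicon.index:
        return []
    max_len = lexicon.max_token_length
    mentions: list[TermMention] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 0, -1):
            key = tuple(t for t, _, _ in tokens[i : i + length])
            tid = lexicon.index.get(key)
            if tid is not None:
                mentions.append(
                    TermMention(term_id=tid, start=tokens[i][1], end=tokens[i + length - 1][2])
                )
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def _load_word_list(name: str) -> tuple[str, ...]:
    text = resources.files("cofreq.data").joinpath(name).read_text(encoding="utf-8")
    return tuple(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def default_negation_pre_triggers() -> tuple[str, ...]:
    return _load_word_list("negation_pre_triggers.txt")


def default_negation_post_triggers() -> tuple[str, ...]:
    return _load_word_list("negation_post_triggers.txt")


def default_history_markers() -> tuple[str, ...]:
    return _load_word_list("history_markers.txt")


def default_family_history_markers() -> tuple[str, ...]:
    return _load_word_list("family_history_markers.txt")


def _find_phrase_spans(
    tokens: list[tuple[str, int, int]], phrases: tuple[str, ...]
) -> list[tuple[int, int]]:
    """Token-index spans [start, end) of every phrase occurrence."""
    norms = {normalize_term(p) for p in phrases if normalize_term(p)}
    if not norms:
        return []
    max_len = max(len(p) for p in norms)
    spans = []
    for i in range(len(tokens)):
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            if tuple(t for t, _, _ in tokens[i : i + length]) in norms:
                spans.append((i, i + length))
                break
    return spans


def flag_mentions(
    text: str,
    mentions: list[TermMention],
    negation_pre_triggers: tuple[str, ...] | None = None,
    negation_post_triggers: tuple[str, ...] | None = None,
    history_markers: tuple[str, ...] | None = None,
    family_history_markers: tuple[str, ...] | None = None,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> list[TermMention]:
    """Set negation / history / family-history flags on mentions.

    Trigger and marker lists default to the data files shipped with the
    package.  ``window`` is the token distance within which a negation
    trigger acts.
    """
    if negation_pre_triggers is None:
        negation_pre_triggers = default_negation_pre_triggers()
    if negation_post_triggers is None:
        negation_post_triggers = default_negation_post_triggers()
    if history_markers is None:
        history_markers = default_history_markers()
    if family_history_markers is None:
        family_history_markers = default_family_history_markers()

    tokens = tokenize(text)
    # char offset -> token index, for locating mention spans
    starts = [s for _, s, _ in tokens]
    ends = [e for _, _, e in tokens]

    def token_range(m: TermMention) -> tuple[int, int]:
        first = next(i for i, s in enumerate(starts) if s >= m.start)
        last = max(i for i, e in enumerate(ends) if e <= m.end)
        return first, last

    pre_spans = _find_phrase_spans(tokens, negation_pre_triggers)
    post_spans = _find_phrase_spans(tokens, negation_post_triggers)
    hist_spans = _find_phrase_spans(tokens, history_markers)
    fam_spans = _find_phrase_spans(tokens, family_history_markers)
    # family markers subsume plain history markers ("family history" contains
    # "history"); drop history-marker hits nested inside a family-marker span
    hist_spans = [
        (a, b)
        for a, b in hist_spans
        if not any(fa <= a and b <= fb for fa, fb in fam_spans)
    ]
    section_starts = sorted(a for a, _ in hist_spans + fam_spans)

    def in_section(first: int, marker_spans: list[tuple[int, int]]) -> bool:
        for a, b in marker_spans:
            if b <= first and not any(a < s <= first for s in section_starts):
                return True
        return False

    _TERMINATORS = ".;:?!"

    def clear_path(char_a: int, char_b: int) -> bool:
        """Negation scope never crosses sentence-ending punctuation."""
        return not any(ch in _TERMINATORS for ch in text[char_a:char_b])

    out: list[TermMention] = []
    for m in mentions:
        first, last = token_range(m)
        negated = any(
            0 <= first - b < window and clear_path(tokens[b - 1][2], m.start)
            for _, b in pre_spans
        ) or any(
            0 <= a - last - 1 < window and clear_path(m.end, tokens[a][1])
            for a, _ in post_spans
        )
        out.append(
            replace(
                m,
                negated=negated,
                history=in_section(first, hist_spans),
                family_history=in_section(first, fam_spans),
            )
        )
    return out


def map_to_concepts(
    mentions: list[TermMention],
    concept_map: ConceptMap,
    level: str = "concept",
    restrict_to_groups: set[str] | None = None,
) -> list[ConceptMention] | list[TermMention]:
    """Resolve term mentions to concept mentions.

    Suppressed (term, concept) interpretations are removed first.  When
    ``restrict_to_groups`` is given, a term survives only if all of its
    remaining concepts fall in those semantic groups and the mapping is
    unambiguous (exactly one concept).  Drug concepts are replaced by their
    ingredient concepts.  Terms with no remaining mapping are dropped from
    concept-level output.  At ``level="term"`` mentions pass through
    unchanged.
    """
    if level == "term":
        return list(mentions)
    if level != "concept":
        raise ValueError(f"level must be 'term' or 'concept', got {level!r}")
    out: list[ConceptMention] = []
    for m in mentions:
        concepts = set(concept_map.term_to_concepts.get(m.term_id, frozenset()))
        concepts -= {c for t, c in concept_map.suppressed_pairs if t == m.term_id}
        if not concepts:
            continue
        if restrict_to_groups is not None:
            groups = {concept_map.concept_group.get(c, "other") for c in concepts}
            if not groups <= set(restrict_to_groups) or len(concepts) != 1:
                continue
        for cid in sorted(concepts):
            cid = concept_map.ingredient_map.get(cid, cid)
            if cid not in concept_map.concept_to_cui:
                raise ValueError(f"concept {cid} has no CUI")
            out.append(
                ConceptMention(
                    concept_id=cid,
                    start=m.start,
                    end=m.end,
                    negated=m.negated,
                    history=m.history,
                    family_history=m.family_history,
                )
            )
    return out


def mentions_to_id_set(
    mentions,
    include_negated: bool = False,
    include_history: bool = True,
    include_family_history: bool = False,
) -> frozenset[int]:
    """Collapse mentions to the ID set counted for a note.

    Default policy excludes negated and family-history mentions and keeps
    history mentions; all three are configurable because the original
    counting policy is not documented.
    """
    ids = set()
    for m in mentions:
        if m.negated and not include_negated:
            continue
        if m.family_history and not include_family_history:
            continue
        if m.history and not m.family_history and not include_history:
            continue
        ids.add(m.term_id if isinstance(m, TermMention) else m.concept_id)
    return frozenset(ids)
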