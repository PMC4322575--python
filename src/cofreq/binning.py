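"""Temporal binning of longitudinal notes.

Each patient's notes are hashed into temporal bins of width ``w`` days with
a per-patient random offset ``r`` drawn uniformly on ``[0, w]``::

    bin(w, r, t) = floor((t + r) / w)

where ``t`` is the note's time in days since the patient's first note.  The
offset decouples bin boundaries from any global timestamp recording bias
(e.g. a weekend effect).  A bin covers ``t + r`` in ``[k*w, (k+1)*w)``, so
two notes more than ``w`` days apart can never share a bin.  The special
width ``inf`` collapses each patient's entire record into a single bin.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

INFINITY = math.inf

#: Bin widths (days) used for a complete export.
CANONICAL_WIDTHS: tuple[float, ...] = (1.0, 7.0, 30.0, 90.0, 180.0, 365.0, INFINITY)


def parse_width(token: str | float | int) -> float:
    """Parse a bin width; the token ``"inf"`` (any case) means infinity."""
    if isinstance(token, str):
        if token.strip().lower() in {"inf", "infinity", "∞"}:
            return INFINITY
        token = float(token)
    w = float(token)
    if not (w > 0):
        raise ValueError(f"bin width must be positive or inf, got {token!r}")
    return w


def width_token(w: float) -> str:
    """Canonical filename token for a width: ``"7"``, ``"365"`` or ``"inf"``."""
    if math.isinf(w):
        return "inf"
    return str(int(w)) if float(w).is_integer() else str(w)


@dataclass(frozen=True)
class NoteRecord:
    """One timestamped clinical note for one patient.

    ``timestamp`` is in fractional days on an absolute scale.  ``term_ids``
    is the post-annotation term-ID set; it is ``None`` for raw text notes.
    """

    patient_id: str
    timestamp: float
    text: str = ""
    term_ids: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.timestamp):
            raise ValueError(f"note timestamp must be finite, got {self.timestamp}")


@dataclass(frozen=True)
class AnnotatedBin:
    """A temporal bin: the union of term IDs over its member notes."""

    patient_id: str
    bin_index: int
    term_ids: frozenset[int]
    n_notes: int
    width: float = INFINITY


@dataclass(frozen=True)
class OffsetAssignment:
    """Per-patient random offsets ``r`` in ``[0, w]``, reproducible from seed."""

    width: float
    seed: int
    offsets: dict[str, float] = field(default_factory=dict)


def filter_patients(
    notes: list[NoteRecord],
    min_notes: int = 10,
    min_span_days: float = 365.0,
) -> set[str]:
    """Return IDs of patients with at least ``min_notes`` notes spanning at
    least ``min_span_days`` days (both bounds inclusive)."""
    if not notes:
        raise ValueError("filter_patients requires a non-empty note list")
    first: dict[str, float] = {}
    last: dict[str, float] = {}
    count: dict[str, int] = {}
    for note in notes:
        p = note.patient_id
        count[p] = count.get(p, 0) + 1
        if p not in first or note.timestamp < first[p]:
            first[p] = note.timestamp
        if p not in last or note.timestamp > last[p]:
            last[p] = note.timestamp
    return {
        p
        for p in count
        if count[p] >= min_notes and (last[p] - first[p]) >= min_span_days
    }


def assign_bin(w: float, r: float, t: float) -> int:
    """Hash a note at ``t`` days since the patient's first note into a bin.

    Returns ``floor((t + r) / w)``.  ``w`` must be finite here; infinite
    widths are handled by :func:`build_bins` as a single bin per patient.
    """
    if t < 0:
        raise ValueError(f"t is the delta from the first note and must be >= 0, got {t}")
    if not (0 <= r <= w):
        raise ValueError(f"offset r must satisfy 0 <= r <= w, got r={r}, w={w}")
    if math.isinf(w):
        raise ValueError("assign_bin requires a finite width")
    return int(math.floor((t + r) / w))


def patient_offset(seed: int, patient_id: str, width: float) -> float:
    """Draw the offset r ~ U[0, w] for one (patient, width) pair.

    A keyed counter-based scheme: the generator is seeded from a digest of
    (seed, width, patient_id), so offsets are reproducible, independent
    across patients, and redrawn per width.
    """
    if math.isinf(width):
        return 0.0
    key = f"{seed}|{width_token(width)}|{patient_id}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return float(rng.uniform(0.0, width))


def build_bins(
    notes: list[NoteRecord],
    width: float,
    seed: int = 0,
) -> tuple[list[AnnotatedBin], OffsetAssignment]:
    """Hash annotated notes into temporal bins.

    ``t0`` is each patient's earliest timestamp; one offset is drawn per
    patient per width.  Only non-empty bins are materialised; a bin's term
    set is the union over its member notes ("splicing").  ``width = inf``
    yields exactly one bin per patient covering the whole record.
    """
    per_patient: dict[str, list[NoteRecord]] = {}
    for note in notes:
        if note.term_ids is None:
            raise ValueError(
                f"build_bins requires annotated notes; note for patient "
                f"{note.patient_id!r} has no term_ids"
            )
        per_patient.setdefault(note.patient_id, []).append(note)

    bins: list[AnnotatedBin] = []
    offsets: dict[str, float] = {}
    for patient_id in sorted(per_patient):
        pnotes = per_patient[patient_id]
        if not pnotes:  # defensive; grouping above cannot produce this
            warnings.warn(f"patient {patient_id!r} has no notes; skipped")
            continue
        r = patient_offset(seed, patient_id, width)
        offsets[patient_id] = r
        t0 = min(n.timestamp for n in pnotes)
        grouped: dict[int, tuple[set[int], int]] = {}
        for n in pnotes:
            idx = 0 if math.isinf(width) else assign_bin(width, r, n.timestamp - t0)
            if idx not in grouped:
                grouped[idx] = (set(), 0)
            terms, cnt = grouped[idx]
            terms.update(n.term_ids)  # type: ignore[arg-type]
            grouped[idx] = (terms, cnt + 1)
        for idx in sorted(grouped):
            terms, cnt = grouped[idx]
            bins.append(
                AnnotatedBin(
                    patient_id=patient_id,
                    bin_index=idx,
                    term_ids=frozenset(terms),
                    n_notes=cnt,
                    width=width,
                )
            )
    return bins, OffsetAssignment(width=width, seed=seed, offsets=offsets)
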