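"""Singleton and pairwise co-occurrence counting over temporal bins.

Two aggregation modes are supported.  Under per-bin aggregation every bin
containing an entity (or a pair) contributes one count, so a patient may
contribute many.  Under per-patient aggregation a patient contributes at
most one count per entity or pair, no matter how many of their bins
qualify.  At infinite bin width the two modes coincide because each bin is
an entire patient record.

Within-bin multiplicity is ignored (a bin's content is a set); self-pairs
are excluded from the pair matrix — f(X,X) is definitionally f(X) under
set semantics and lives with the singletons.
"""

from __future__ import annotations

import enum
import itertools
import math
import multiprocessing
from collections import Counter
from dataclasses import dataclass, field, replace

from .binning import AnnotatedBin


class AggregationMode(enum.Enum):
    PER_BIN = "per-bin"
    PER_PATIENT = "per-patient"

    @classmethod
    def parse(cls, token: "str | AggregationMode") -> "AggregationMode":
        if isinstance(token, AggregationMode):
            return token
        t = token.strip().lower().replace("_", "-")
        for m in cls:
            if m.value == t:
                return m
        raise ValueError(f"unknown aggregation mode {token!r}")


@dataclass(frozen=True)
class SingletonCounts:
    """f(X) for every entity, with the universe size N.

    N is the number of bins (per-bin mode, at this width) or the number of
    patients (per-patient mode).  Per-patient counts are independent of the
    bin width.
    """

    counts: dict[int, int] = field(default_factory=dict)
    mode: AggregationMode = AggregationMode.PER_BIN
    width: float | None = None
    level: str = "term"
    n: int = 0


@dataclass(frozen=True)
class CoFrequencyMatrix:
    """Sparse symmetric pair counts f(X,Y), keyed (min_id, max_id)."""

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    mode: AggregationMode = AggregationMode.PER_BIN
    width: float | None = None
    level: str = "term"
    n: int = 0


def _check_single_width(bins: list[AnnotatedBin]) -> float | None:
    widths = {b.width for b in bins}
    if len(widths) > 1:
        raise ValueError(f"bins built at mixed widths: {sorted(widths)}")
    return widths.pop() if widths else None


def _universe_size(bins: list[AnnotatedBin], mode: AggregationMode) -> int:
    if mode is AggregationMode.PER_BIN:
        return len(bins)
    return len({b.patient_id for b in bins})


def count_singletons(
    bins: list[AnnotatedBin],
    mode: AggregationMode | str,
    level: str = "term",
) -> SingletonCounts:
    """Count, per ID, the number of bins (or patients) containing it."""
    mode = AggregationMode.parse(mode)
    width = _check_single_width(bins)
    counter: Counter[int] = Counter()
    if mode is AggregationMode.PER_BIN:
        for b in bins:
            counter.update(b.term_ids)
    else:
        seen: dict[str, set[int]] = {}
        for b in bins:
            seen.setdefault(b.patient_id, set()).update(b.term_ids)
        for ids in seen.values():
            counter.update(ids)
    return SingletonCounts(
        counts=dict(counter),
        mode=mode,
        width=width,
        level=level,
        n=_universe_size(bins, mode),
    )


def _pairs_of(ids: frozenset[int]):
    return itertools.combinations(sorted(ids), 2)


def _count_patient_group(
    args: tuple[list[AnnotatedBin], AggregationMode],
) -> Counter:
    """Count one shard of whole patients; merge algebra is plain summation
    because no patient is split across shards."""
    bins, mode = args
    counter: Counter[tuple[int, int]] = Counter()
    if mode is AggregationMode.PER_BIN:
        for b in bins:
            counter.update(_pairs_of(b.term_ids))
    else:
        per_patient: dict[str, set[tuple[int, int]]] = {}
        for b in bins:
            per_patient.setdefault(b.patient_id, set()).update(_pairs_of(b.term_ids))
        for pairs in per_patient.values():
            counter.update(pairs)
    return counter


def count_cofrequencies(
    bins: list[AnnotatedBin],
    mode: AggregationMode | str,
    n_workers: int = 1,
    level: str = "term",
) -> CoFrequencyMatrix:
    """Pairwise co-occurrence counts; result is independent of ``n_workers``
    and of bin processing order.

    Bins are sharded across workers by whole patients, each worker emits a
    partial sparse map, and partials are reduced by summation (valid in both
    modes because the per-patient union happens inside a single shard).
    """
    mode = AggregationMode.parse(mode)
    width = _check_single_width(bins)
    n = _universe_size(bins, mode)

    if n_workers <= 1 or len(bins) < 2 * n_workers:
        total = _count_patient_group((bins, mode))
    else:
        patients = sorted({b.patient_id for b in bins})
        shards: list[list[AnnotatedBin]] = [[] for _ in range(n_workers)]
        shard_of = {p: i % n_workers for i, p in enumerate(patients)}
        for b in bins:
            shards[shard_of[b.patient_id]].append(b)
        ctx = multiprocessing.get_context("fork")
        with ctx.Pool(n_workers) as pool:
            partials = pool.map(
                _count_patient_group, [(shard, mode) for shard in shards if shard]
            )
        total = Counter()
        for part in partials:
            total.update(part)

    return CoFrequencyMatrix(
        counts=dict(total), mode=mode, width=width, level=level, n=n
    )


def reference_count(
    bins: list[AnnotatedBin],
    mode: AggregationMode | str,
    level: str = "term",
) -> CoFrequencyMatrix:
    """Single-threaded, order-obvious double-loop counter.

    Semantically identical to :func:`count_cofrequencies` but written as the
    most naive loop possible, with no sharding and no shared helpers for the
    inner pair enumeration; exists solely as an independent oracle.
    """
    mode = AggregationMode.parse(mode)
    width = _check_single_width(bins)
    counts: dict[tuple[int, int], int] = {}
    if mode is AggregationMode.PER_BIN:
        for b in bins:
            ids = sorted(b.term_ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    key = (ids[i], ids[j])
                    counts[key] = counts.get(key, 0) + 1
    else:
        patient_pairs: dict[str, set[tuple[int, int]]] = {}
        for b in bins:
            ids = sorted(b.term_ids)
            bucket = patient_pairs.setdefault(b.patient_id, set())
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    bucket.add((ids[i], ids[j]))
        for bucket in patient_pairs.values():
            for key in bucket:
                counts[key] = counts.get(key, 0) + 1
    return CoFrequencyMatrix(
        counts=counts, mode=mode, width=width, level=level,
        n=_universe_size(bins, mode),
    )


def apply_count_threshold(
    obj: SingletonCounts | CoFrequencyMatrix, threshold: int = 100
):
    """Return a copy with every row of count <= threshold removed.

    Mirrors the published-file filter ("counts of size 100 or fewer"); the
    in-memory counts used for statistics are left exact — apply this at
    serialization time.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    kept = {k: v for k, v in obj.counts.items() if v > threshold}
    return replace(obj, counts=kept)


def pair_enumeration_cost(n_bins: int, mean_terms_per_bin: int) -> int:
    """Estimated pair evaluations for a counting run: n * m**2.

    Counting is O(n*m^2) in the number of bins n and the mean per-bin term
    count m; this estimate drives progress reporting and planning.
    """
    if n_bins < 0 or mean_terms_per_bin < 0:
        raise ValueError("inputs must be non-negative")
    return int(n_bins) * int(mean_terms_per_bin) ** 2
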