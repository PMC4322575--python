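"""End-to-end orchestration: annotate → bin → count → export.

Produces the full data-record file family (28 co-frequency + 16 singleton
files when both levels and all seven widths are requested) plus a JSON
manifest recording the seed, an offsets digest, and per-width summary
statistics (number of bins, mean notes/terms/concepts per bin — the usual
corpus summary schema).

All outputs are written atomically (temp file + rename), so a failed run
never leaves truncated files behind.  A re-run with the same inputs and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import formats
from .annotate import (
    ConceptMap,
    Lexicon,
    annotate_note,
    flag_mentions,
    map_to_concepts,
    mentions_to_id_set,
)
from .binning import (
    CANONICAL_WIDTHS,
    NoteRecord,
    build_bins,
    filter_patients,
    width_token,
)
from .counting import (
    AggregationMode,
    count_cofrequencies,
    count_singletons,
    pair_enumeration_cost,
)

log = logging.getLogger("cofreq.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str = "export"
    widths: tuple[float, ...] = CANONICAL_WIDTHS
    modes: tuple[AggregationMode, ...] = (
        AggregationMode.PER_BIN,
        AggregationMode.PER_PATIENT,
    )
    levels: tuple[str, ...] = ("term", "concept")
    threshold: int = 100
    include_negated: bool = False
    include_history: bool = True
    include_family_history: bool = False
    min_notes: int = 10
    min_span_days: float = 365.0
    seed: int = 0
    workers: int = 1
    apply_flags: bool = True

    def __post_init__(self) -> None:
        if not set(self.widths) <= set(CANONICAL_WIDTHS):
            raise ValueError(
                f"widths must be a subset of {CANONICAL_WIDTHS}, got {self.widths}"
            )
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def annotate_corpus(
    notes: list[NoteRecord],
    lexicon: Lexicon,
    concept_map: ConceptMap | None,
    config: PipelineConfig,
) -> dict[str, list[NoteRecord]]:
    """Annotate raw notes; returns per-level lists of notes carrying ID sets."""
    out: dict[str, list[NoteRecord]] = {level: [] for level in config.levels}
    for note in notes:
        mentions = annotate_note(note.text, lexicon)
        if config.apply_flags:
            mentions = flag_mentions(note.text, mentions)
        for level in config.levels:
            if level == "concept":
                if concept_map is None:
                    raise ValueError("concept-level export requires a concept map")
                level_mentions = map_to_concepts(mentions, concept_map, level="concept")
            else:
                level_mentions = mentions
            ids = mentions_to_id_set(
                level_mentions,
                include_negated=config.include_negated,
                include_history=config.include_history,
                include_family_history=config.include_family_history,
            )
            out[level].append(
                NoteRecord(
                    patient_id=note.patient_id,
                    timestamp=note.timestamp,
                    text="",
                    term_ids=ids,
                )
            )
    return out


def run_pipeline(
    notes: list[NoteRecord],
    lexicon: Lexicon,
    config: PipelineConfig,
    concept_map: ConceptMap | None = None,
) -> dict:
    """Run the full pipeline over raw notes and write the export.

    Returns the manifest: filenames per family, seed, an offsets digest and
    the per-width summary table (as records).
    """
    t_start = time.perf_counter()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    eligible = (
        filter_patients(notes, config.min_notes, config.min_span_days)
        if config.min_notes > 0
        else {n.patient_id for n in notes}
    )
    kept = [n for n in notes if n.patient_id in eligible]
    log.info(
        "eligibility: %d/%d patients, %d/%d notes retained",
        len(eligible),
        len({n.patient_id for n in notes}),
        len(kept),
        len(notes),
    )

    annotated = annotate_corpus(kept, lexicon, concept_map, config)
    log.info("annotation done in %.2fs", time.perf_counter() - t_start)

    manifest_files = formats.build_manifest(config.widths, config.levels, config.modes)
    written: list[str] = []
    summary_rows = []
    offset_digest = hashlib.sha256()

    for width in config.widths:
        row = {"width": width_token(width)}
        for level in config.levels:
            t_w = time.perf_counter()
            bins, offsets = build_bins(annotated[level], width, seed=config.seed)
            for pid in sorted(offsets.offsets):
                offset_digest.update(
                    f"{width_token(width)}|{level}|{pid}|{offsets.offsets[pid]:.12g}\n".encode()
                )
            n_bins = len(bins)
            mean_terms = (
                sum(len(b.term_ids) for b in bins) / n_bins if n_bins else 0.0
            )
            if level == config.levels[0]:
                row["n_bins"] = n_bins
                row["notes_per_bin"] = (
                    sum(b.n_notes for b in bins) / n_bins if n_bins else 0.0
                )
            row[f"{level}s_per_bin"] = mean_terms
            log.info(
                "width=%s level=%s: %d bins, ~%d pair evaluations",
                width_token(width),
                level,
                n_bins,
                pair_enumeration_cost(n_bins, int(mean_terms) or 1),
            )
            for mode in config.modes:
                matrix = count_cofrequencies(
                    bins, mode, n_workers=config.workers, level=level
                )
                name = formats.cofrequency_filename(level, mode, width)
                formats.write_cofrequency_file(
                    matrix, out_dir / name, threshold=config.threshold
                )
                written.append(name)
                if mode is AggregationMode.PER_BIN:
                    singles = count_singletons(bins, mode, level=level)
                    name = formats.singleton_filename(level, mode, width)
                    formats.write_singleton_file(
                        singles, out_dir / name, threshold=config.threshold
                    )
                    written.append(name)
            log.info(
                "width=%s level=%s counted in %.2fs",
                width_token(width),
                level,
                time.perf_counter() - t_w,
            )
        summary_rows.append(row)

    # per-patient singleton counts are width-independent: write once per
    # level, from the widest requested bin
    if AggregationMode.PER_PATIENT in config.modes:
        ref_width = (
            math.inf if math.inf in config.widths else max(config.widths)
        )
        for level in config.levels:
            bins, _ = build_bins(annotated[level], ref_width, seed=config.seed)
            singles = count_singletons(bins, AggregationMode.PER_PATIENT, level=level)
            name = formats.singleton_filename(level, AggregationMode.PER_PATIENT, None)
            formats.write_singleton_file(
                singles, out_dir / name, threshold=config.threshold
            )
            written.append(name)

    summary = pd.DataFrame(summary_rows)
    manifest = {
        "seed": config.seed,
        "threshold": config.threshold,
        "widths": [width_token(w) for w in config.widths],
        "modes": [m.value for m in config.modes],
        "levels": list(config.levels),
        "n_patients": len(eligible),
        "n_notes": len(kept),
        "offsets_sha256": offset_digest.hexdigest(),
        "files": manifest_files,
        "written": sorted(written),
        "summary": summary.to_dict(orient="records"),
        "elapsed_seconds": round(time.perf_counter() - t_start, 3),
    }
    formats._atomic_write(
        out_dir / "manifest.json", json.dumps(manifest, indent=2) + "\n"
    )
    return manifest
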