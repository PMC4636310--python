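"""Homolog acceptance criteria for CAZyme BLAST hits, best-hit selection
and family tagging.

A hit against the CAZyme protein database is accepted only when all three
criteria hold:

* E-value strictly below ``max_evalue`` (default 1e-05);
* bit score per alignment column strictly above ``min_bits_per_col``
  (default 1.0);
* alignment coverage at least ``min_coverage`` (default 0.75, inclusive).

Coverage defaults to the query basis with a x3 nucleotide-to-amino-acid
correction (``3 * alignment_length / query_length``) because the queries
are nucleotide contigs aligned against protein subjects; the subject basis
(``alignment_length / subject_length``) is available for pipelines whose
queries are called genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import BlastHit, SubjectAnnotation, validate_family_label

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class DetectionCriteria:
    """Thresholds of the three-part homolog acceptance rule."""

    max_evalue: float = 1e-05
    min_bits_per_col: float = 1.0
    min_coverage: float = 0.75
    coverage_basis: str = "query"  # "query" (x3 nt->aa) or "subject"

    def __post_init__(self) -> None:
        if self.max_evalue <= 0 or self.min_bits_per_col <= 0 or self.min_coverage <= 0:
            raise ValueError("all detection thresholds must be positive")
        if self.coverage_basis not in ("query", "subject"):
            raise ValueError(f"unknown coverage basis {self.coverage_basis!r}")


@dataclass(frozen=True, slots=True)
class FilterFlags:
    """Per-criterion outcome for one hit; `passed` is their conjunction."""

    evalue_ok: bool
    bits_per_col_ok: bool
    coverage_ok: bool

    @property
    def passed(self) -> bool:
        return self.evalue_ok and self.bits_per_col_ok and self.coverage_ok


@dataclass(slots=True)
class FamilyCounts:
    """Accepted-hit counts per CAZyme family for one sample."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_hits(self) -> int:
        return sum(self.counts.values())


def coverage_of(hit: BlastHit, criteria: DetectionCriteria) -> float:
    """Alignment coverage of a hit under the chosen basis."""
    if criteria.coverage_basis == "query":
        if hit.query_length is None:
            raise ValueError(
                f"hit {hit.query_id!r}->{hit.subject_id!r} lacks query_length "
                "required for query-basis coverage"
            )
        return 3.0 * hit.alignment_length / hit.query_length
    if hit.subject_length is None:
        raise ValueError(
            f"hit {hit.query_id!r}->{hit.subject_id!r} lacks subject_length "
            "required for subject-basis coverage"
        )
    return hit.alignment_length / hit.subject_length


def apply_filters(
    hits: Iterable[BlastHit],
    criteria: DetectionCriteria = DetectionCriteria(),
) -> list[tuple[BlastHit, FilterFlags]]:
    """Evaluate every hit against the acceptance criteria.

    Returns ``(hit, flags)`` pairs in input order; ``flags.passed`` is the
    conjunction of the three independent per-criterion flags.
    """
    out = []
    for hit in hits:
        flags = FilterFlags(
            evalue_ok=hit.evalue < criteria.max_evalue,
            bits_per_col_ok=hit.bit_score / hit.alignment_length > criteria.min_bits_per_col,
            coverage_ok=coverage_of(hit, criteria) >= criteria.min_coverage,
        )
        out.append((hit, flags))
    return out


def passing_hits(
    hits: Iterable[BlastHit],
    criteria: DetectionCriteria = DetectionCriteria(),
) -> list[BlastHit]:
    """Hits that satisfy all three acceptance criteria, in input order."""
    return [h for h, f in apply_filters(hits, criteria) if f.passed]


def select_best_hits(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Keep the single best-scoring alignment per query.

    Best = maximum bit score; ties broken by lower E-value, then by
    lexicographically smallest subject_id, so selection is deterministic.
    Output is ordered by first appearance of each query.
    """
    best: dict[str, BlastHit] = {}
    order: list[str] = []
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            order.append(hit.query_id)
            continue
        key = (-hit.bit_score, hit.evalue, hit.subject_id)
        cur_key = (-cur.bit_score, cur.evalue, cur.subject_id)
        if key < cur_key:
            best[hit.query_id] = hit
    return [best[q] for q in order]


def tag_families(
    best_hits: Iterable[BlastHit],
    annotations: Mapping[str, SubjectAnnotation],
    sample_id: str = "",
) -> FamilyCounts:
    """Tag accepted hits to CAZyme families and collate counts.

    Every subject must be present in the annotation map (unmapped subjects
    raise, listing the offenders).  Annotation maps built through
    :func:`~cazyprofiler.io_formats.read_annotation_map` cannot contain
    CBM/AA subjects; family labels are re-validated here regardless and
    excluded hits are counted in the log.
    """
    counts: Counter[str] = Counter()
    unmapped: list[str] = []
    excluded = 0
    for hit in best_hits:
        ann = annotations.get(hit.subject_id)
        if ann is None:
            unmapped.append(hit.subject_id)
            continue
        try:
            validate_family_label(ann.family)
        except ValueError:
            excluded += 1
            continue
        counts[ann.family] += 1
    if unmapped:
        raise KeyError(
            f"{len(unmapped)} hit(s) to subjects absent from the annotation "
            f"map: {sorted(set(unmapped))[:10]}"
        )
    if excluded:
        logger.info("excluded %d hit(s) to non-catalytic (CBM/AA) subjects", excluded)
    return FamilyCounts(sample_id=sample_id, counts=dict(sorted(counts.items())))


def detect_sample(
    hits: Sequence[BlastHit],
    annotations: Mapping[str, SubjectAnnotation],
    criteria: DetectionCriteria = DetectionCriteria(),
    sample_id: str = "",
    count_mode: str = "best",
) -> FamilyCounts:
    """Full per-sample detection: filter, (optionally) best-hit, tag.

    ``count_mode="best"`` counts one hit per query (default);
    ``"all"`` counts every passing alignment.
    """
    if count_mode not in ("best", "all"):
        raise ValueError(f"unknown count mode {count_mode!r}")
    kept = passing_hits(hits, criteria)
    if count_mode == "best":
        kept = select_best_hits(kept)
    return tag_families(kept, annotations, sample_id=sample_id)
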