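"""Tiered taxonomic attribution of CAZyme hits and enrichment indices.

A best hit inherits taxonomy from its database subject at a rank that
depends on the alignment percent identity — high-identity hits can be
trusted to genus, low-identity ones only to phylum:

* identity >  85        -> genus
* 70 < identity <= 85   -> family
* 55 < identity <= 70   -> class
* 40 <= identity <= 55  -> phylum
* identity < 40         -> unassigned

The enrichment index of a taxon compares its share among CAZyme-attributed
hits with its share in the whole metagenome: log10 of the fold enrichment,
so 0 means no enrichment and +1 a ten-fold over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import benjamini_hochberg
from .io_formats import BlastHit, SubjectAnnotation, LINEAGE_RANKS

UNASSIGNED = "unassigned"

#: Floor reported for log10(0) enrichment (taxon absent from CAZyme hits).
ENRICHMENT_FLOOR = -12.0


@dataclass(frozen=True)
class Tier:
    rank: str           # lineage rank, or "unassigned"
    lower: float        # identity bound, exclusive unless lower_inclusive
    upper: float        # identity bound, inclusive unless not upper_inclusive
    lower_inclusive: bool = False
    upper_inclusive: bool = True

    def contains(self, identity: float) -> bool:
        above = identity >= self.lower if self.lower_inclusive else identity > self.lower
        below = identity <= self.upper if self.upper_inclusive else identity < self.upper
        return above and below


@dataclass(frozen=True)
class TierRules:
    """Ordered identity tiers; together they cover [0, 100] exactly once.

    Boundary identities fall to the lower-resolution tier: only the genus
    tier is strict (> 85), while 40 itself still maps to phylum.
    """

    tiers: tuple[Tier, ...] = (
        Tier("genus", 85.0, 100.0),
        Tier("family", 70.0, 85.0),
        Tier("class", 55.0, 70.0),
        Tier("phylum", 40.0, 55.0, lower_inclusive=True),
        Tier(UNASSIGNED, 0.0, 40.0, lower_inclusive=True, upper_inclusive=False),
    )

    def rank_for(self, identity: float) -> str:
        if not 0.0 <= identity <= 100.0:
            raise ValueError(f"percent identity outside [0, 100]: {identity}")
        for t in self.tiers:
            if t.contains(identity):
                return t.rank
        raise AssertionError("tiers must cover [0, 100]")  # pragma: no cover


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    family: str
    rank: str            # "genus"/"family"/"class"/"phylum"/"unassigned"
    taxon: str           # taxon label, or "unassigned"


def assign_taxon(
    hit: BlastHit,
    annotation: SubjectAnnotation,
    rules: TierRules = TierRules(),
) -> TaxonAssignment:
    """Resolve one accepted best hit to (rank, taxon).

    The rank comes from the identity tier; the label is the subject's
    lineage entry at that rank.  An ``unknown`` lineage entry propagates
    to unassigned.
    """
    rank = rules.rank_for(hit.percent_identity)
    if rank == UNASSIGNED:
        return TaxonAssignment(hit.query_id, annotation.family, UNASSIGNED, UNASSIGNED)
    taxon = annotation.lineage_at(rank)
    if not taxon or taxon.lower() == "unknown":
        return TaxonAssignment(hit.query_id, annotation.family, UNASSIGNED, UNASSIGNED)
    return TaxonAssignment(hit.query_id, annotation.family, rank, taxon)


def assign_all(
    hits,
    annotations,
    rules: TierRules = TierRules(),
) -> list[TaxonAssignment]:
    return [assign_taxon(h, annotations[h.subject_id], rules) for h in hits]


@dataclass
class TaxonComposition:
    """Taxon proportions per rank over a group of assignments."""

    proportions: dict[str, pd.Series]   # rank -> taxon proportions (sum 1)
    unassigned: int
    n_assigned: dict[str, int]

    def at(self, rank: str) -> pd.Series:
        return self.proportions.get(rank, pd.Series(dtype=float))


def taxon_composition(assignments) -> TaxonComposition:
    """Proportions of taxa at each rank, unassigned hits tracked apart."""
    by_rank: dict[str, dict[str, int]] = {r: {} for r in LINEAGE_RANKS}
    unassigned = 0
    for a in assignments:
        if a.rank == UNASSIGNED:
            unassigned += 1
            continue
        by_rank[a.rank][a.taxon] = by_rank[a.rank].get(a.taxon, 0) + 1
    props = {}
    counts = {}
    for rank, tab in by_rank.items():
        if not tab:
            continue
        s = pd.Series(tab, dtype=float).sort_index()
        counts[rank] = int(s.sum())
        props[rank] = s / s.sum()
    return TaxonComposition(proportions=props, unassigned=unassigned,
                            n_assigned=counts)


@dataclass(frozen=True)
class EnrichmentRecord:
    taxon: str
    rank: str
    proportion_in_cazymes: float
    proportion_in_metagenome: float
    fold_enrichment: float
    enrichment_index: float
    floored: bool = False


def enrichment_index(
    p_caz: float, p_meta: float, taxon: str = "", rank: str = ""
) -> EnrichmentRecord:
    """log10 fold enrichment of a taxon among CAZyme hits vs the whole
    metagenome.  ``p_meta`` must be positive; ``p_caz = 0`` yields a
    flagged floor value instead of -infinity."""
    if p_meta <= 0:
        raise ValueError("metagenome proportion must be positive")
    if p_caz < 0:
        raise ValueError("CAZyme proportion must be non-negative")
    fold = p_caz / p_meta
    if p_caz == 0:
        return EnrichmentRecord(taxon, rank, p_caz, p_meta, 0.0,
                                ENRICHMENT_FLOOR, floored=True)
    return EnrichmentRecord(taxon, rank, p_caz, p_meta, fold, float(np.log10(fold)))


def enrichment_table(
    caz_props: pd.Series, meta_props: pd.Series, rank: str = "genus"
) -> pd.DataFrame:
    """Enrichment indices for every taxon with a nonzero metagenome share."""
    rows = []
    for taxon, pm in meta_props.items():
        if pm <= 0:
            continue
        rec = enrichment_index(float(caz_props.get(taxon, 0.0)), float(pm),
                               taxon=str(taxon), rank=rank)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CAZotype driver taxa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriverRecord:
    taxon: str
    cazotype: int
    mean_in: float
    mean_out: float
    ratio: float
    p_value: float
    p_adjusted: float
    is_driver: bool


def cazotype_drivers(
    compositions: pd.DataFrame,
    labels: pd.Series,
    min_contribution: float = 0.001,
    alpha: float = 0.05,
    min_ratio: float = 1.5,
) -> list[DriverRecord]:
    """Taxa driving each CAZotype.

    ``compositions`` is a samples x taxa table of per-sample taxon shares
    of the CAZyme repertoire.  Within each CAZotype, taxa contributing
    more than ``min_contribution`` (0.1%) of the pooled repertoire are
    tested one-sided (Welch, in-group greater) against all other samples,
    with BH adjustment across the tests performed and the same fold-ratio
    gate as marker detection.
    """
    labels = labels.reindex(compositions.index)
    lvls = sorted(labels.unique())
    for lvl in lvls:
        if (labels == lvl).sum() < 3:
            raise ValueError(f"cazotype {lvl!r} has fewer than 3 samples")
    raw = []
    for lvl in lvls:
        mask = (labels == lvl).to_numpy()
        pooled = compositions.loc[mask].mean(axis=0)
        pooled = pooled / pooled.sum() if pooled.sum() > 0 else pooled
        candidates = pooled.index[pooled > min_contribution]
        for taxon in candidates:
            a = compositions.loc[mask, taxon].to_numpy(dtype=float)
            b = compositions.loc[~mask, taxon].to_numpy(dtype=float)
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                continue
            t = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            raw.append((str(taxon), int(lvl), float(a.mean()), float(b.mean()),
                        float(t.pvalue)))
    if not raw:
        return []
    adj = benjamini_hochberg([r[4] for r in raw])
    out = []
    for (taxon, lvl, mi, mo, p), pa in zip(raw, adj):
        ratio = np.inf if mo == 0 else mi / mo
        out.append(DriverRecord(
            taxon=taxon, cazotype=lvl, mean_in=mi, mean_out=mo,
            ratio=float(ratio), p_value=p, p_adjusted=float(pa),
            is_driver=bool(pa < alpha and ratio > min_ratio),
        ))
    return out


def drivers_frame(records: list[DriverRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
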