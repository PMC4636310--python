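"""Abundance profiles: per-Mbp normalization, overall abundance and
diversity, core families, and the two-stage normalization used for
community typing.

The abundance unit throughout is accepted BLAST hits per million base
pairs of metagenome (hits/Mbp), which evens out differences in sequencing
depth between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .detection import FamilyCounts
from .io_formats import SampleRecord, metadata_frame


@dataclass
class AbundanceProfile:
    """Samples x families hit counts with metadata; rates are derived.

    ``counts`` holds raw accepted-hit counts (needed by the diversity
    exclusion rule); ``rates`` divides by metagenome size to give hits/Mbp.
    Family columns are sorted; missing families are explicit zeros.
    """

    counts: pd.DataFrame           # samples x families, integer hit counts
    metadata: pd.DataFrame         # indexed by sample_id; has metagenome_size_bp

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            missing = self.counts.index.difference(self.metadata.index).tolist()
            if missing:
                raise KeyError(f"samples without metadata: {missing}")
            self.metadata = self.metadata.loc[self.counts.index]

    @property
    def rates(self) -> pd.DataFrame:
        """Abundance in hits per Mbp: count * 1e6 / metagenome_size_bp."""
        sizes = self.metadata["metagenome_size_bp"].astype(float)
        return self.counts.mul(1e6 / sizes, axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)


def build_abundance_matrix(
    counts: Iterable[FamilyCounts],
    metadata: Sequence[SampleRecord] | pd.DataFrame,
) -> AbundanceProfile:
    """Assemble per-sample family counts into an abundance profile.

    The family axis is the sorted union over samples; families absent in a
    sample get zero.  Every sample must have a metadata record.
    """
    counts = list(counts)
    if not isinstance(metadata, pd.DataFrame):
        metadata = metadata_frame(metadata)
    order = [fc.sample_id for fc in counts]
    if len(set(order)) != len(order):
        raise ValueError("duplicate sample_id in counts")
    rows = {fc.sample_id: fc.counts for fc in counts}
    mat = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    mat = mat.reindex(index=order, columns=sorted(mat.columns))
    mat.index.name = "sample_id"
    missing = mat.index.difference(metadata.index).tolist()
    if missing:
        raise KeyError(f"no metadata for sample(s): {missing}")
    return AbundanceProfile(counts=mat, metadata=metadata.loc[mat.index])


def overall_abundance(profile: AbundanceProfile) -> pd.Series:
    """Cumulated hits/Mbp per sample (row sum of the rate matrix)."""
    return profile.rates.sum(axis=1)


def diversity(profile: AbundanceProfile, min_frac: float = 1e-4) -> pd.Series:
    """Number of CAZyme families with a non-negligible hit count per sample.

    A family is not counted when its raw hit count is less than
    ``min_frac`` (default 0.01%) of the sample's total hits; a count equal
    to the threshold is retained (only "less than" is excluded).
    """
    totals = profile.counts.sum(axis=1)
    thresh = totals.astype(float) * min_frac
    kept = profile.counts.ge(thresh, axis=0) & (profile.counts > 0)
    return kept.sum(axis=1)


def retained_counts(sample_counts: pd.Series, min_frac: float = 1e-4) -> pd.Series:
    """One sample's counts restricted to families passing the diversity
    exclusion (count >= min_frac * total, count > 0)."""
    total = float(sample_counts.sum())
    keep = (sample_counts >= min_frac * total) & (sample_counts > 0)
    return sample_counts[keep]


def core_families(profile: AbundanceProfile, prevalence: float = 0.85) -> list[str]:
    """Families present (>= 1 accepted hit) in at least ``prevalence`` of
    samples — the "core" CAZyme repertoire."""
    n = len(profile.samples)
    presences = (profile.counts > 0).sum(axis=0)
    return [f for f in profile.families if presences[f] >= prevalence * n]


@dataclass
class NormalizedProfile:
    """Range-scaled Z-score matrix in [0, 1] with the scaling parameters."""

    matrix: pd.DataFrame        # samples x retained families, values in [0,1]
    family_mean: pd.Series
    family_sd: pd.Series


def normalize_for_typing(
    profile: AbundanceProfile | pd.DataFrame,
    sparse_prevalence: float = 0.5,
) -> NormalizedProfile:
    """Two-stage normalization for typing/ordination.

    Families present in fewer than ``sparse_prevalence`` of samples are
    dropped as sparse; each remaining family column is converted to
    Z-scores ((x - mean) / sd, sample sd) and then range-scaled to [0, 1]
    ((z - min) / (max - min)).  A constant column maps to 0.5 everywhere.
    """
    rates = profile.rates if isinstance(profile, AbundanceProfile) else profile
    if len(rates) < 2:
        raise ValueError("need at least 2 samples to normalize")
    n = len(rates)
    keep = (rates > 0).sum(axis=0) >= sparse_prevalence * n
    x = rates.loc[:, keep]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    safe_sd = sd.replace(0.0, 1.0)
    z = (x - mean) / safe_sd
    span = z.max(axis=0) - z.min(axis=0)
    scaled = (z - z.min(axis=0)).div(span.replace(0.0, 1.0), axis=1)
    constant = span == 0.0
    if constant.any():
        scaled.loc[:, constant] = 0.5
    return NormalizedProfile(matrix=scaled, family_mean=mean, family_sd=sd)


def relative_abundance(profile: AbundanceProfile | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative family profile (rows sum to 1)."""
    rates = profile.rates if isinstance(profile, AbundanceProfile) else profile
    totals = rates.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"sample(s) with all-zero profile: {bad}")
    return rates.div(totals, axis=0)


def profile_summary(profile: AbundanceProfile, min_frac: float = 1e-4) -> pd.DataFrame:
    """Per-sample overall abundance (hits/Mbp) and diversity table."""
    return pd.DataFrame(
        {
            "total_hits": profile.counts.sum(axis=1),
            "overall_abundance": overall_abundance(profile),
            "diversity": diversity(profile, min_frac=min_frac),
        }
    )
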