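"""Synthetic gut-metagenome cohorts with planted ground truth.

The generator emulates the statistical structure the pipeline is built to
recover, without any sequence simulation: hit-level BLAST-tabular records
whose filter attributes (E-value, bits per column, coverage) are drawn to
pass each acceptance criterion except with a configured failure rate;
cluster-structured family abundance profiles (planted CAZotypes drawn
from cazotype-specific Dirichlet centers); families with planted linear
BMI effects; infant samples whose abundance concentrates onto a few
families (high-Gini structure); family-to-genus attribution mixtures; and
whole-metagenome taxon profiles for enrichment denominators.

Cohort structure: every infant belongs to the last planted CAZotype (whose
members carry >= 90% of their abundance on a handful of families, the way
infant microbiomes concentrate on milk-adapted taxa); non-infant samples
are spread uniformly over the remaining CAZotypes, each defined by a
disjoint set of signature families boosted by ``cluster_separation``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    SampleRecord,
    SubjectAnnotation,
    metadata_frame,
    write_annotation_map,
    write_matrix,
    write_sample_metadata,
)
from .profiles import AbundanceProfile

#: Reference lineages (phylum, class, family, genus) used for subjects.
GENUS_LINEAGES: dict[str, tuple[str, str, str, str]] = {
    "Bacteroides": ("Bacteroidetes", "Bacteroidia", "Bacteroidaceae", "Bacteroides"),
    "Prevotella": ("Bacteroidetes", "Bacteroidia", "Prevotellaceae", "Prevotella"),
    "Ruminococcus": ("Firmicutes", "Clostridia", "Oscillospiraceae", "Ruminococcus"),
    "Eubacterium": ("Firmicutes", "Clostridia", "Eubacteriaceae", "Eubacterium"),
    "Roseburia": ("Firmicutes", "Clostridia", "Lachnospiraceae", "Roseburia"),
    "Lactobacillus": ("Firmicutes", "Bacilli", "Lactobacillaceae", "Lactobacillus"),
    "Bifidobacterium": ("Actinobacteria", "Actinomycetia", "Bifidobacteriaceae", "Bifidobacterium"),
    "Escherichia": ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriaceae", "Escherichia"),
}

#: Genus driving each planted CAZotype's signature families, in cluster order.
CLUSTER_DRIVER_GENERA = ["Bacteroides", "Ruminococcus", "Lactobacillus",
                         "Prevotella", "Eubacterium", "Bifidobacterium"]

#: Identity bands (sampled uniformly within) per taxonomy tier, kept clear
#: of the tier boundaries so rounding cannot move a hit across tiers.
IDENTITY_BANDS = {
    "genus": (85.5, 99.5),
    "family": (70.5, 84.5),
    "class": (55.5, 69.5),
    "phylum": (40.5, 54.5),
    "unassigned": (20.0, 39.5),
}

DEFAULT_TIER_PROBS = {"genus": 0.55, "family": 0.20, "class": 0.15,
                      "phylum": 0.08, "unassigned": 0.02}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 200
    n_families: int = 60
    n_cazotypes: int = 3
    n_signature_families: int = 6
    dirichlet_concentration_within: float = 500.0
    cluster_separation: float = 4.0
    bmi_marker_families: list[str] | None = None   # None -> pick n_bmi_families
    n_bmi_families: int = 5
    bmi_slope: float = 0.15          # hits/Mbp per BMI unit
    noise_sd: float = 0.5            # hits/Mbp, Gaussian on planted families
    infant_fraction: float = 0.15
    child_fraction: float = 0.05
    infant_concentration_families: int = 4
    infant_concentration_share: float = 0.92
    filter_fail_rates: dict = field(default_factory=lambda: {
        "evalue": 0.05, "bitscore_ratio": 0.05, "coverage": 0.10})
    tier_probs: dict = field(default_factory=lambda: dict(DEFAULT_TIER_PROBS))
    taxon_mixture: dict | None = None   # family -> {genus: prob}; None -> built
    dominant_genus_weight: float = 0.8
    mean_hits_per_mbp: float = 150.0
    metagenome_size_range_bp: tuple[int, int] = (20_000_000, 100_000_000)
    geography_bias: float = 0.7      # P(sample takes its cluster's geography)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("infant_fraction", "child_fraction", "geography_bias",
                     "infant_concentration_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for k, v in self.filter_fail_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"filter fail rate {k}={v} outside [0, 1]")
        if self.n_cazotypes > self.n_samples:
            raise ValueError("n_cazotypes cannot exceed n_samples")
        if self.mean_hits_per_mbp <= 0:
            raise ValueError("mean_hits_per_mbp must be positive "
                             "(an all-zero hit rate generates nothing)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "metagenome_size_range_bp" in raw:
            raw["metagenome_size_range_bp"] = tuple(raw["metagenome_size_range_bp"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["metagenome_size_range_bp"] = list(self.metagenome_size_range_bp)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    cazotype_of_sample: pd.Series            # sample -> 1..k
    true_family_rates: pd.DataFrame          # samples x families, hits/Mbp
    planted_bmi_families: set[str]
    signature_families: dict[int, list[str]] # cazotype -> signature family list
    driver_genus: dict[int, str]             # cazotype -> planted driver genus
    hit_tables: dict[str, pd.DataFrame] | None = None  # per-hit flags & taxa


def family_labels(n: int) -> list[str]:
    """n CAZyme family labels cycling through the catalytic classes."""
    classes = ["GH", "GT", "PL", "CE"]
    return [f"{classes[i % 4]}{i // 4 + 1}" for i in range(n)]


def _build_taxon_mixture(cfg: SimulationConfig, families: list[str],
                         signature: dict[int, list[str]]) -> dict[str, dict[str, float]]:
    genera = list(GENUS_LINEAGES)
    fam_to_driver: dict[str, str] = {}
    for c, fams in signature.items():
        for f in fams:
            fam_to_driver[f] = CLUSTER_DRIVER_GENERA[(c - 1) % len(CLUSTER_DRIVER_GENERA)]
    mixture = {}
    for i, fam in enumerate(families):
        dom = fam_to_driver.get(fam, genera[i % len(genera)])
        others = [g for g in genera if g != dom]
        w_rest = (1.0 - cfg.dominant_genus_weight) / len(others)
        mixture[fam] = {dom: cfg.dominant_genus_weight, **{g: w_rest for g in others}}
    return mixture


def _simulate_truth(cfg: SimulationConfig, rng: np.random.Generator):
    families = family_labels(cfg.n_families)
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    k = cfg.n_cazotypes

    # disjoint signature family sets, one per cazotype
    n_sig = min(cfg.n_signature_families, cfg.n_families // max(k, 1))
    sig_pool = rng.permutation(cfg.n_families)[: n_sig * k]
    signature = {c + 1: sorted(families[j] for j in sig_pool[c * n_sig:(c + 1) * n_sig])
                 for c in range(k)}

    # age structure; every infant belongs to the last cazotype
    n = cfg.n_samples
    groups = np.array(["adult"] * n, dtype=object)
    n_inf = int(round(cfg.infant_fraction * n))
    n_child = int(round(cfg.child_fraction * n))
    idx = rng.permutation(n)
    groups[idx[:n_inf]] = "infant"
    groups[idx[n_inf:n_inf + n_child]] = "child"
    ages = np.empty(n)
    ages[groups == "infant"] = rng.uniform(0.2, 2.5, (groups == "infant").sum())
    ages[groups == "child"] = rng.uniform(3.0, 12.0, (groups == "child").sum())
    ages[groups == "adult"] = rng.uniform(18.0, 70.0, (groups == "adult").sum())

    caz = np.empty(n, dtype=int)
    infant_mask = groups == "infant"
    adult_clusters = list(range(1, k)) if (infant_mask.any() and k > 1) else list(range(1, k + 1))
    caz[infant_mask] = k
    caz[~infant_mask] = rng.choice(adult_clusters, size=(~infant_mask).sum())

    # BMI: adults only; infants/children carry no BMI
    bmi = np.full(n, np.nan)
    adult_mask = groups == "adult"
    bmi[adult_mask] = np.clip(rng.normal(25.0, 4.0, adult_mask.sum()), 15.0, 45.0)

    sizes = rng.integers(cfg.metagenome_size_range_bp[0],
                         cfg.metagenome_size_range_bp[1] + 1, size=n)

    # cluster centers: unit weights, signatures boosted by the separation
    centers = np.ones((k, cfg.n_families))
    fam_index = {f: j for j, f in enumerate(families)}
    for c in range(1, k + 1):
        for f in signature[c]:
            centers[c - 1, fam_index[f]] *= cfg.cluster_separation
    centers /= centers.sum(axis=1, keepdims=True)

    shares = np.empty((n, cfg.n_families))
    for i in range(n):
        alpha = centers[caz[i] - 1] * cfg.dirichlet_concentration_within
        shares[i] = rng.dirichlet(alpha)

    # Infant concentration: the first few signature families of the infant
    # cazotype grow until they carry >= the configured share of the
    # sample's total abundance.  The growth is additive — the remaining
    # families keep their cluster-level rates — so infant repertoires are
    # both concentrated (high Gini) and high in overall abundance, and no
    # other family's rate is perturbed by the concentration.
    conc = [fam_index[f] for f in
            signature[k][: cfg.infant_concentration_families]] if k >= 1 else []
    totals = np.full(n, cfg.mean_hits_per_mbp)
    s = cfg.infant_concentration_share
    for i in np.flatnonzero(infant_mask):
        p = shares[i].copy()
        in_conc = p[conc].sum()
        if in_conc <= 0:
            p[conc] = 1.0 / len(conc)
            in_conc = p[conc].sum()
        scale_in = s / in_conc
        scale_out = (1 - s) / (1 - in_conc) if in_conc < 1 else 0.0
        q = p * scale_out
        q[conc] = p[conc] * scale_in
        shares[i] = q / q.sum()
        # total chosen so non-concentrated families keep their old rates
        totals[i] = cfg.mean_hits_per_mbp * (1.0 - in_conc) / (1.0 - s)

    rates = shares * totals[:, None]

    # planted BMI effect (adults with BMI; truncated at zero)
    if cfg.bmi_marker_families is None:
        non_sig = [f for f in families
                   if all(f not in signature[c] for c in signature)]
        bmi_fams = sorted(rng.choice(non_sig, size=min(cfg.n_bmi_families,
                                                       len(non_sig)),
                                     replace=False).tolist())
    else:
        bmi_fams = list(cfg.bmi_marker_families)
    if bmi_fams and adult_mask.any():
        center = np.nanmean(bmi)
        has_bmi = ~np.isnan(bmi)
        for f in bmi_fams:
            j = fam_index[f]
            # effect (and its noise) only where the covariate exists, so
            # BMI-less samples keep their planted cluster structure intact
            eff = np.where(has_bmi, cfg.bmi_slope * (bmi - center), 0.0)
            eff = eff + np.where(has_bmi, rng.normal(0.0, cfg.noise_sd, n), 0.0)
            rates[:, j] = np.maximum(rates[:, j] + eff, 0.0)

    # geographies biased toward the sample's cazotype
    geo_names = [f"geo{c}" for c in range(1, k + 1)]
    geos = np.empty(n, dtype=object)
    for i in range(n):
        if rng.uniform() < cfg.geography_bias:
            geos[i] = geo_names[caz[i] - 1]
        else:
            geos[i] = geo_names[rng.integers(k)]
    cohort_of_geo = {g: ["Asian", "American", "European",
                         "SouthAmerica-Africa", "other"][i % 5]
                     for i, g in enumerate(geo_names)}

    meta = [SampleRecord(
        sample_id=samples[i],
        metagenome_size_bp=int(sizes[i]),
        geography=str(geos[i]),
        cohort=cohort_of_geo[geos[i]],
        age_years=float(round(ages[i], 2)),
        bmi=None if np.isnan(bmi[i]) else float(round(bmi[i], 2)),
        age_group=str(groups[i]),
    ) for i in range(n)]

    truth = GroundTruth(
        cazotype_of_sample=pd.Series(caz, index=pd.Index(samples, name="sample_id"),
                                     name="cazotype"),
        true_family_rates=pd.DataFrame(rates, index=samples, columns=families),
        planted_bmi_families=set(bmi_fams),
        signature_families=signature,
        driver_genus={c: CLUSTER_DRIVER_GENERA[(c - 1) % len(CLUSTER_DRIVER_GENERA)]
                      for c in range(1, k + 1)},
    )
    return families, samples, meta, truth


def simulate_profile(cfg: SimulationConfig) -> tuple[AbundanceProfile, GroundTruth]:
    """Counts-level cohort: Poisson family counts thinned by the filter
    pass probability, skipping hit-level records.

    Equivalent in distribution to running detection on
    :func:`generate_cohort` output, and much faster for large cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    families, samples, meta, truth = _simulate_truth(cfg, rng)
    sizes = np.array([m.metagenome_size_bp for m in meta], dtype=float)
    lam = truth.true_family_rates.to_numpy() * (sizes[:, None] / 1e6)
    counts = rng.poisson(lam)
    q = float(np.prod([1.0 - v for v in cfg.filter_fail_rates.values()]))
    accepted = rng.binomial(counts, q)
    profile = AbundanceProfile(
        counts=pd.DataFrame(accepted, index=pd.Index(samples, name="sample_id"),
                            columns=families),
        metadata=metadata_frame(meta),
    )
    return profile, truth


def build_annotations(cfg: SimulationConfig, families: list[str],
                      mixture: dict[str, dict[str, float]]) -> dict[str, SubjectAnnotation]:
    """One database subject per (family, genus) pair in the mixture."""
    out = {}
    for fam in families:
        for genus in sorted(mixture[fam]):
            sid = f"{fam}|{genus}"
            out[sid] = SubjectAnnotation(subject_id=sid, family=fam,
                                         lineage=GENUS_LINEAGES[genus])
    return out


def _simulate_hits(cfg: SimulationConfig, rng: np.random.Generator,
                   sample_id: str, counts: np.ndarray, families: list[str],
                   mixture) -> pd.DataFrame:
    """Hit-level attributes for one sample (one query per hit)."""
    fam_of_hit = np.repeat(np.arange(len(families)), counts)
    m = fam_of_hit.size
    fr = cfg.filter_fail_rates
    fail_e = rng.uniform(size=m) < fr.get("evalue", 0.0)
    fail_b = rng.uniform(size=m) < fr.get("bitscore_ratio", 0.0)
    fail_c = rng.uniform(size=m) < fr.get("coverage", 0.0)

    evalue = np.where(fail_e, 10.0 ** -rng.uniform(0.0, 5.0, m),
                      10.0 ** -rng.uniform(6.0, 50.0, m))
    alnlen = rng.integers(100, 400, size=m)
    ratio = np.where(fail_b, rng.uniform(0.3, 0.995, m), rng.uniform(1.05, 2.5, m))
    bits = ratio * alnlen
    cov = np.where(fail_c, rng.uniform(0.30, 0.74, m), rng.uniform(0.76, 1.0, m))
    qlen = np.rint(3.0 * alnlen / cov).astype(int)

    tiers = list(cfg.tier_probs)
    probs = np.array([cfg.tier_probs[t] for t in tiers], dtype=float)
    probs /= probs.sum()
    tier_of_hit = rng.choice(len(tiers), size=m, p=probs)
    lo = np.array([IDENTITY_BANDS[t][0] for t in tiers])
    hi = np.array([IDENTITY_BANDS[t][1] for t in tiers])
    identity = rng.uniform(lo[tier_of_hit], hi[tier_of_hit])

    genus = np.empty(m, dtype=object)
    for j in np.unique(fam_of_hit):
        mix = mixture[families[j]]
        gs = sorted(mix)
        p = np.array([mix[g] for g in gs])
        sel = fam_of_hit == j
        genus[sel] = np.array(gs, dtype=object)[rng.choice(len(gs), sel.sum(), p=p / p.sum())]

    fam_names = np.array(families, dtype=object)[fam_of_hit]
    return pd.DataFrame({
        "query_id": [f"{sample_id}_c{i}" for i in range(m)],
        "family": fam_names,
        "subject_id": [f"{f}|{g}" for f, g in zip(fam_names, genus)],
        "identity": np.round(identity, 2),
        "alignment_length": alnlen,
        "evalue": evalue,
        "bit_score": np.round(bits, 2),
        "query_length": qlen,
        "subject_length": alnlen,
        "genus": genus,
        "evalue_ok": ~fail_e,
        "bits_ok": ~fail_b,
        "coverage_ok": ~fail_c,
        "passes": ~(fail_e | fail_b | fail_c),
    })


def _write_blast_table(df: pd.DataFrame, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for r in df.itertuples(index=False):
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.identity:.2f}\t"
                f"{r.alignment_length}\t0\t0\t1\t{r.query_length}\t1\t"
                f"{r.alignment_length}\t{r.evalue:.6g}\t{r.bit_score:.6g}\t"
                f"{r.query_length}\t{r.subject_length}\n"
            )


def metagenome_taxon_profile(truth: GroundTruth, mixture, families,
                             background: float = 0.2) -> pd.DataFrame:
    """Per-sample whole-metagenome genus proportions.

    A mixture of the genus profile implied by the sample's CAZyme family
    rates (weight 1 - background) and a uniform community background, so
    CAZyme-affiliated taxa are genuinely enriched relative to it.
    """
    genera = sorted(GENUS_LINEAGES)
    mix_mat = np.array([[mixture[f].get(g, 0.0) for g in genera] for f in families])
    shares = truth.true_family_rates.to_numpy()
    shares = shares / shares.sum(axis=1, keepdims=True)
    implied = shares @ mix_mat
    uniform = np.full(len(genera), 1.0 / len(genera))
    prof = (1.0 - background) * implied + background * uniform
    return pd.DataFrame(prof, index=truth.true_family_rates.index, columns=genera)


def generate_cohort(cfg: SimulationConfig, outdir: str | Path) -> tuple[dict, GroundTruth]:
    """Write a full synthetic cohort to disk and return its ground truth.

    Files: ``blast/<sample>.tsv`` (14-column BLAST tabular per sample),
    ``annotations.tsv``, ``metadata.tsv``, ``metagenome_taxa.tsv``,
    ``truth/`` (planted cazotypes, rates, BMI families) and
    ``config.yaml``.  Same config and seed give byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "blast").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    families, samples, meta, truth = _simulate_truth(cfg, rng)
    mixture = cfg.taxon_mixture or _build_taxon_mixture(cfg, families,
                                                        truth.signature_families)
    for fam, mix in mixture.items():
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon mixture for {fam} sums to {total}, not 1")

    sizes = np.array([m.metagenome_size_bp for m in meta], dtype=float)
    lam = truth.true_family_rates.to_numpy() * (sizes[:, None] / 1e6)
    counts = rng.poisson(lam)

    paths = {"blast": {}, "outdir": str(outdir)}
    hit_tables = {}
    for i, sid in enumerate(samples):
        table = _simulate_hits(cfg, rng, sid, counts[i], families, mixture)
        p = outdir / "blast" / f"{sid}.tsv"
        _write_blast_table(table, p)
        paths["blast"][sid] = str(p)
        hit_tables[sid] = table
    truth.hit_tables = hit_tables

    annotations = build_annotations(cfg, families, mixture)
    write_annotation_map(annotations, outdir / "annotations.tsv")
    write_sample_metadata(meta, outdir / "metadata.tsv")
    taxa = metagenome_taxon_profile(truth, mixture, families)
    write_matrix(taxa, outdir / "metagenome_taxa.tsv")
    cfg.to_yaml(outdir / "config.yaml")

    truth.cazotype_of_sample.to_frame().to_csv(outdir / "truth" / "cazotypes.tsv",
                                               sep="\t")
    write_matrix(truth.true_family_rates, outdir / "truth" / "true_rates.tsv")
    with (outdir / "truth" / "planted.json").open("w", encoding="utf-8") as fh:
        json.dump({
            "planted_bmi_families": sorted(truth.planted_bmi_families),
            "signature_families": {str(k): v for k, v in
                                   truth.signature_families.items()},
            "driver_genus": {str(k): v for k, v in truth.driver_genus.items()},
        }, fh, indent=2, sort_keys=True)
    paths.update({
        "annotations": str(outdir / "annotations.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "metagenome_taxa": str(outdir / "metagenome_taxa.tsv"),
    })
    return paths, truth


# ---------------------------------------------------------------------------
# Worked example: a tiny hand-checkable cohort
# ---------------------------------------------------------------------------

#: Lineages used by the worked example, one genus per family.
_FIXTURE_FAMILIES = ["GH13", "GH2", "GT2", "PL1", "CE1", "GH95"]
_FIXTURE_GENUS = {
    "GH13": "Bacteroides", "GH2": "Prevotella", "GT2": "Ruminococcus",
    "PL1": "Lactobacillus", "CE1": "Bifidobacterium", "GH95": "Escherichia",
}
#: Identity given to every accepted hit of a family (exercises every tier).
_FIXTURE_IDENTITY = {"GH13": 92.0, "GH2": 80.0, "GT2": 60.0, "PL1": 50.0,
                     "CE1": 30.0, "GH95": 90.0}


def _fixture_row(qid, fam, identity, alnlen, evalue, bits, qlen):
    sid = f"{fam}|{_FIXTURE_GENUS[fam]}"
    return (f"{qid}\t{sid}\t{identity:.2f}\t{alnlen}\t0\t0\t1\t{qlen}\t1\t"
            f"{alnlen}\t{evalue:.6g}\t{bits:.6g}\t{qlen}\t{alnlen}\n")


def worked_example_fixture(outdir: str | Path) -> dict:
    """Tiny 4-sample, 6-family cohort with hand-computed expectations.

    * sampleA: 250 accepted hits over a 50 Mbp metagenome -> overall
      abundance 5.0 hits/Mbp; includes one hit failing exactly one
      criterion each, plus a coverage == 0.75 boundary hit that passes.
    * sampleB: 1 Mbp; counts (5,5,5,5,0,0) -> abundance vector with
      Gini 1/3 over all six families, 0 over the four retained ones.
    * sampleC: 10,000 hits split (9000, 999, 1) -> diversity 3 at the
      0.01% exclusion (the single-hit family sits exactly on the
      threshold and is retained).
    * sampleD: 10 Mbp; counts (10,20,30,40) -> abundances (1,2,3,4)
      with Gini 0.25.

    Returns a dict of file paths and the expected values.
    """
    outdir = Path(outdir)
    (outdir / "blast").mkdir(parents=True, exist_ok=True)

    def accepted(qid, fam, alnlen=200, qlen=None):
        qlen = qlen if qlen is not None else 750  # coverage 0.8
        return _fixture_row(qid, fam, _FIXTURE_IDENTITY[fam], alnlen,
                            1e-30, 1.5 * alnlen, qlen)

    # sampleA: accepted 100 GH13 + 80 GH2 + 40 GT2 + 20 PL1 + 10 CE1 = 250
    rows = []
    a_counts = {"GH13": 100, "GH2": 80, "GT2": 40, "PL1": 20, "CE1": 10}
    q = 0
    for fam, k in a_counts.items():
        for _ in range(k):
            rows.append(accepted(f"A_c{q}", fam))
            q += 1
    # boundary pass: replace the last accepted hit's coverage with exactly
    # 0.75 (alignment 100 cols, query 400 nt -> 3*100/400)
    rows[-1] = _fixture_row(f"A_c{q - 1}", "CE1", _FIXTURE_IDENTITY["CE1"],
                            100, 1e-30, 150.0, 400)
    # three rejected hits, each failing exactly one criterion
    rows.append(_fixture_row(f"A_c{q}", "GH13", 92.0, 200, 1e-05, 300.0, 750))
    rows.append(_fixture_row(f"A_c{q + 1}", "GH13", 92.0, 100, 1e-30, 100.0, 400))
    rows.append(_fixture_row(f"A_c{q + 2}", "GH13", 92.0, 100, 1e-30, 150.0, 500))
    (outdir / "blast" / "sampleA.tsv").write_text("".join(rows), encoding="utf-8")

    def write_counts(sample, counts, path):
        rows = []
        q = 0
        for fam, k in counts.items():
            for _ in range(k):
                rows.append(accepted(f"{sample}_c{q}", fam))
                q += 1
        path.write_text("".join(rows), encoding="utf-8")

    write_counts("B", {"GH13": 5, "GH2": 5, "GT2": 5, "PL1": 5},
                 outdir / "blast" / "sampleB.tsv")
    write_counts("C", {"GH13": 9000, "GH2": 999, "GT2": 1},
                 outdir / "blast" / "sampleC.tsv")
    write_counts("D", {"GH13": 10, "GH2": 20, "GT2": 30, "PL1": 40},
                 outdir / "blast" / "sampleD.tsv")

    anns = [SubjectAnnotation(subject_id=f"{fam}|{g}", family=fam,
                              lineage=GENUS_LINEAGES[g])
            for fam, g in _FIXTURE_GENUS.items()]
    write_annotation_map(anns, outdir / "annotations.tsv")
    meta = [
        SampleRecord("sampleA", 50_000_000, "geoA", "European", 35.0, 24.0, "adult"),
        SampleRecord("sampleB", 1_000_000, "geoA", "European", 1.0, None, "infant"),
        SampleRecord("sampleC", 100_000_000, "geoB", "Asian", 40.0, 27.0, "adult"),
        SampleRecord("sampleD", 10_000_000, "geoB", "Asian", 55.0, 30.0, "adult"),
    ]
    write_sample_metadata(meta, outdir / "metadata.tsv")

    return {
        "outdir": str(outdir),
        "blast": {s: str(outdir / "blast" / f"{s}.tsv")
                  for s in ("sampleA", "sampleB", "sampleC", "sampleD")},
        "annotations": str(outdir / "annotations.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "expected": {
            "sampleA_counts": a_counts,
            "sampleA_total_accepted": 250,
            "sampleA_overall_abundance": 5.0,
            "sampleA_rejected": 3,
            "sampleB_abundances": [5.0, 5.0, 5.0, 5.0, 0.0, 0.0],
            "sampleB_gini_all6": 1.0 / 3.0,
            "sampleB_gini_retained": 0.0,
            "sampleC_diversity": 3,
            "sampleD_abundances": [1.0, 2.0, 3.0, 4.0],
            "sampleD_gini": 0.25,
            "sampleA_genus_composition": {"Bacteroides": 1.0},
        },
    }
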