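"""End-to-end orchestration: simulate (optional) -> detect -> profile ->
gini -> associate -> cazotype -> taxonomy, with a manifest recording every
parameter and seed.

All stage outputs are plain TSV/JSON and are identical to what the stage
functions produce when run individually on the same inputs; the pipeline
holds no hidden state, so two runs with the same config and master seed
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    correlate_families,
    prevalence_filter,
    significant_families,
    summed_marker_correlation,
)
from .cazotypes import (
    bca_ordination,
    cazotype_preference_table,
    cluster_and_select_k,
    detect_markers,
    markers_frame,
    sample_distance,
)
from .detection import DetectionCriteria, detect_sample
from .gini import fit_gini_age, sample_gini
from .io_formats import (
    metadata_frame,
    read_annotation_map,
    read_blast_tab,
    read_matrix,
    read_sample_metadata,
    write_matrix,
)
from .profiles import (
    AbundanceProfile,
    build_abundance_matrix,
    core_families,
    normalize_for_typing,
    profile_summary,
)
from .synthetic import SimulationConfig, generate_cohort
from .taxonomy import (
    TierRules,
    assign_all,
    cazotype_drivers,
    drivers_frame,
    enrichment_table,
    taxon_composition,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Single configuration for a full run.

    When ``simulate`` is set, inputs are generated under
    ``outdir/inputs`` from the embedded simulation config; otherwise
    ``blast_dir``, ``annotations``, ``metadata`` (and optionally
    ``metagenome_taxa``) must point at existing files.
    """

    outdir: str = "cazyprofiler_run"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    blast_dir: str | None = None
    annotations: str | None = None
    metadata: str | None = None
    metagenome_taxa: str | None = None
    criteria: DetectionCriteria = field(default_factory=DetectionCriteria)
    count_mode: str = "best"
    core_prevalence: float = 0.85
    diversity_min_frac: float = 1e-4
    sparse_prevalence: float = 0.5
    assoc_covariate: str = "bmi"
    assoc_min_prev: float = 0.5
    assoc_adjust: str = "bh"
    assoc_rank_transform: bool = True
    window: int | None = None
    window_step: int = 1
    distance: str = "jsd"
    k_min: int = 2
    k_max: int = 6
    marker_alpha: float = 0.05
    marker_min_ratio: float = 1.5
    driver_min_contribution: float = 0.001
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            if "metagenome_size_range_bp" in sim:
                sim["metagenome_size_range_bp"] = tuple(sim["metagenome_size_range_bp"])
            raw["simulation"] = SimulationConfig(**sim)
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = DetectionCriteria(**raw["criteria"])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle of paths and key objects."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"outdir": str(out)}

    # ----- inputs ---------------------------------------------------------
    if config.simulate:
        sim = config.simulation
        sim.seed = config.seed if sim.seed == 0 else sim.seed
        paths, truth = generate_cohort(sim, out / "inputs")
        blast_dir = out / "inputs" / "blast"
        ann_path = out / "inputs" / "annotations.tsv"
        meta_path = out / "inputs" / "metadata.tsv"
        taxa_path = out / "inputs" / "metagenome_taxa.tsv"
        results["truth"] = truth
    else:
        for name in ("blast_dir", "annotations", "metadata"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise PipelineError(f"stage 'inputs' failed: missing {name} ({p})")
        blast_dir = Path(config.blast_dir)
        ann_path = Path(config.annotations)
        meta_path = Path(config.metadata)
        taxa_path = (Path(config.metagenome_taxa)
                     if config.metagenome_taxa else None)

    # ----- detection ------------------------------------------------------
    @_stage("detect")
    def _detect():
        annotations = read_annotation_map(ann_path)
        meta_records = read_sample_metadata(meta_path)
        counts, kept_hits = [], {}
        for rec in meta_records:
            bpath = blast_dir / f"{rec.sample_id}.tsv"
            if not bpath.exists():
                raise PipelineError(
                    f"stage 'detect' failed: no BLAST table for sample "
                    f"{rec.sample_id!r} at {bpath}")
            hits = read_blast_tab(bpath, has_lengths=True)
            fc = detect_sample(hits, annotations, config.criteria,
                               sample_id=rec.sample_id,
                               count_mode=config.count_mode)
            counts.append(fc)
            from .detection import passing_hits, select_best_hits
            kept = passing_hits(hits, config.criteria)
            if config.count_mode == "best":
                kept = select_best_hits(kept)
            kept_hits[rec.sample_id] = kept
        return annotations, meta_records, counts, kept_hits

    annotations, meta_records, counts, kept_hits = _detect()

    # ----- profiles -------------------------------------------------------
    @_stage("profile")
    def _profile():
        profile = build_abundance_matrix(counts, meta_records)
        write_matrix(profile.rates, out / "abundance.tsv")
        summary = profile_summary(profile, min_frac=config.diversity_min_frac)
        summary.to_csv(out / "summary.tsv", sep="\t", float_format="%.12g")
        core = core_families(profile, prevalence=config.core_prevalence)
        (out / "core_families.txt").write_text("\n".join(core) + "\n",
                                               encoding="utf-8")
        return profile, summary, core

    profile, summary, core = _profile()
    results.update(profile=profile, summary=summary, core_families=core)

    # ----- gini -----------------------------------------------------------
    @_stage("gini")
    def _gini():
        g = sample_gini(profile, min_frac=config.diversity_min_frac)
        meta = metadata_frame(meta_records)
        gdf = g.to_frame()
        gdf["age_years"] = meta["age_years"]
        gdf.to_csv(out / "gini.tsv", sep="\t", float_format="%.12g")
        fit = None
        ages = meta["age_years"]
        ok = ages.notna() & (ages > 0)
        if ok.sum() >= 3:
            fit = fit_gini_age(g[ok].to_numpy(), ages[ok].to_numpy())
        return g, fit

    ginis, age_fit = _gini()
    results.update(gini=ginis, gini_age_fit=age_fit)

    # ----- association ----------------------------------------------------
    @_stage("associate")
    def _associate():
        meta = metadata_frame(meta_records)
        cov = meta[config.assoc_covariate]
        rates = prevalence_filter(profile.rates, min_prev=config.assoc_min_prev,
                                  covariate=cov)
        if rates.shape[1] == 0 or cov.notna().sum() < 3:
            return None, None, None
        records = correlate_families(rates, cov,
                                     rank_transform=config.assoc_rank_transform,
                                     adjust=config.assoc_adjust)
        table = pd.DataFrame([r.__dict__ for r in records])
        table.to_csv(out / "association.tsv", sep="\t", index=False,
                     float_format="%.12g")
        sig = [f for f in significant_families(records, alpha=0.05)
               if next(r for r in records if r.family == f).r > 0]
        win = None
        if sig:
            win = summed_marker_correlation(rates, sig, cov,
                                            window=config.window,
                                            step=config.window_step)
        return records, sig, win

    assoc_records, assoc_sig, assoc_window = _associate()
    results.update(association=assoc_records, associated_families=assoc_sig,
                   window_correlation=assoc_window)

    # ----- cazotypes ------------------------------------------------------
    @_stage("cazotype")
    def _cazotype():
        if config.distance == "jsd":
            dist = sample_distance(profile, metric="jsd")
            ord_matrix = normalize_for_typing(
                profile, sparse_prevalence=config.sparse_prevalence).matrix
        else:
            ord_matrix = normalize_for_typing(
                profile, sparse_prevalence=config.sparse_prevalence).matrix
            dist = sample_distance(ord_matrix, metric="euclidean")
        n = len(dist)
        k_hi = min(config.k_max, n - 1)
        model = cluster_and_select_k(dist, range(config.k_min, k_hi + 1))
        coords, cents = bca_ordination(ord_matrix, model.labels)
        model.bca_coordinates, model.class_centroids = coords, cents
        markers = detect_markers(profile.rates, model.labels,
                                 alpha=config.marker_alpha,
                                 min_ratio=config.marker_min_ratio)
        meta = metadata_frame(meta_records)
        pref = cazotype_preference_table(model.labels, meta["geography"])

        model.labels.to_frame().to_csv(out / "cazotypes.tsv", sep="\t")
        coords.to_csv(out / "bca_coords.tsv", sep="\t", float_format="%.12g")
        markers_frame(markers).to_csv(out / "markers.tsv", sep="\t",
                                      index=False, float_format="%.12g")
        pref.to_csv(out / "cazotype_preference.tsv", sep="\t",
                    float_format="%.12g")
        with (out / "cazotype_model.json").open("w", encoding="utf-8") as fh:
            json.dump({
                "k": model.k,
                "medoids": model.medoids,
                "ch_index_by_k": {str(k): v for k, v in
                                  sorted(model.ch_index_by_k.items())},
                "silhouette_by_k": {str(k): None if np.isnan(v) else v
                                    for k, v in
                                    sorted(model.silhouette_by_k.items())},
                "labels": {s: int(c) for s, c in model.labels.items()},
            }, fh, indent=2, sort_keys=True)
        return model, markers, pref

    model, markers, preference = _cazotype()
    results.update(cazotype_model=model, markers=markers,
                   preference_table=preference)

    # ----- taxonomy -------------------------------------------------------
    @_stage("taxonomy")
    def _taxonomy():
        rules = TierRules()
        comp_rows = {}
        for sid, hits in kept_hits.items():
            assigns = assign_all(hits, annotations, rules)
            comp = taxon_composition(assigns)
            comp_rows[sid] = comp.at("genus")
        genus_comp = pd.DataFrame(comp_rows).T.fillna(0.0)
        genus_comp.index.name = "sample_id"
        genus_comp = genus_comp.reindex(sorted(genus_comp.columns), axis=1)
        write_matrix(genus_comp, out / "genus_composition.tsv")

        enrich = None
        if taxa_path is not None and Path(taxa_path).exists():
            meta_taxa = read_matrix(taxa_path)
            pooled_caz = genus_comp.mean(axis=0)
            pooled_caz = pooled_caz / pooled_caz.sum() if pooled_caz.sum() else pooled_caz
            pooled_meta = meta_taxa.mean(axis=0)
            pooled_meta = pooled_meta / pooled_meta.sum()
            enrich = enrichment_table(pooled_caz, pooled_meta, rank="genus")
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.12g")

        drivers = cazotype_drivers(genus_comp, model.labels,
                                   min_contribution=config.driver_min_contribution,
                                   alpha=config.marker_alpha,
                                   min_ratio=config.marker_min_ratio)
        drivers_frame(drivers).to_csv(out / "drivers.tsv", sep="\t",
                                      index=False, float_format="%.12g")
        return genus_comp, enrich, drivers

    genus_comp, enrichment, drivers = _taxonomy()
    results.update(genus_composition=genus_comp, enrichment=enrichment,
                   drivers=drivers)

    # ----- manifest -------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "criteria": asdict(config.criteria),
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("criteria", "simulation", "outdir", "blast_dir",
                         "annotations", "metadata", "metagenome_taxa")
        },
        "simulation": (asdict(config.simulation) if config.simulate else None),
        "selected_k": model.k,
        "n_samples": len(profile.samples),
        "n_families_detected": len(profile.families),
        "n_core_families": len(core),
    }
    if manifest["simulation"] is not None:
        manifest["simulation"]["metagenome_size_range_bp"] = list(
            manifest["simulation"]["metagenome_size_range_bp"])
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
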