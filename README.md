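# cazyprofiler

Profiling of carbohydrate-active enzymes (CAZymes) in human gut
metagenomes, from raw BLAST-tabular homology searches to community types.

Gut bacteria digest the complex carbohydrates our own enzymes cannot, and
the repertoire of CAZyme families (glycoside hydrolases GH, glycosyl
transferases GT, polysaccharide lyases PL, carbohydrate esterases CE) a
microbiome carries is a functional fingerprint of its host's diet, age and
geography. `cazyprofiler` implements the full analysis chain used to read
that fingerprint out of shotgun metagenome assemblies that were searched
(BLASTx) against a CAZy-style annotated protein database:

1. **Detection** — accept a hit only if E < 1e-05, bit-score per alignment
   column > 1.0 and alignment coverage ≥ 75% (query basis with a ×3
   nucleotide→amino-acid correction, or subject basis); keep the best
   scoring alignment per query; tag hits to CAZyme families (CBM/AA
   excluded).
2. **Profiles** — abundance of family *f* in sample *s* is
   `count[s,f] × 1e6 / metagenome_size_bp[s]` (hits/Mbp); per-sample
   overall abundance and diversity (families below 0.01 % of total hits
   ignored); core families present in ≥ 85 % of samples; two-stage
   normalization for typing (Z-score per family, then range-scaling to
   [0, 1]).
3. **Functional rarefaction** — per-sample Gini coefficient
   `G = Σᵢⱼ|xᵢ−xⱼ| / (2n²µ)` from the Lorenz curve of family abundances
   (0 = all families contribute equally, →1 = a handful dominate), plus an
   OLS fit of `G = a + b·ln(age)`.
4. **Covariate association** — prevalence-filtered, rank-transformed
   Pearson correlation of each family with age/BMI, BH (or Bonferroni)
   adjusted; a sliding-window summed-abundance statistic for a marker set;
   ANOVA + Tukey HSD group comparisons.
5. **CAZotypes** — community typing à la enterotypes: root
   Jensen–Shannon divergence between relative profiles, partitioning
   around medoids, Calinski–Harabasz selection of k, between-class
   analysis (PCA of class centers of gravity) for ordination, and
   CAZotype marker families by one-sided Welch t-tests with BH < 0.05 and
   fold-ratio > 1.5.
6. **Taxonomy** — tiered attribution of each hit by percent identity
   (> 85 → genus, 70–85 → family, 55–70 → class, 40–55 → phylum, < 40
   unassigned), per-group taxon compositions, `log10` enrichment indices
   against whole-metagenome taxon profiles, and CAZotype driver taxa.

A synthetic-cohort generator (`cazyprofiler.synthetic`) plants all of this
structure — CAZotype clusters, BMI-correlated families, infant
concentration, filter-failure rates, family→genus mixtures — with full
ground truth, so every stage is testable without downloading metagenomes.

## Worked example

Run the whole pipeline on a simulated 60-sample cohort:

```bash
$ cat demo_cfg.yaml
simulation:
  n_samples: 60
  n_families: 30
  mean_hits_per_mbp: 80.0
  metagenome_size_range_bp: [5000000, 20000000]

$ cazyprofiler run-all --config demo_cfg.yaml --seed 1 --out demo
run complete: 60 samples, 30 families, 30 core, k = 3
```

Three CAZotypes were found (`k = 3`), and with only 30 families in play
all of them are core (present in ≥ 85 % of samples). Stage outputs land
in `demo/`: `abundance.tsv` (hits/Mbp matrix), `summary.tsv`, `gini.tsv`,
`association.tsv`, `cazotypes.tsv`, `markers.tsv`, `bca_coords.tsv`,
`enrichment.tsv`, `drivers.tsv` and a `manifest.json` recording every
parameter and seed. The stages are also individual subcommands:

```bash
$ cazyprofiler detect --blast demo/inputs/blast --annot demo/inputs/annotations.tsv \
      --meta demo/inputs/metadata.tsv --out counts.tsv
rejected by evalue: 6342
rejected by bits_per_col: 6504
rejected by coverage: 12834

$ cazyprofiler gini --counts counts.tsv --meta demo/inputs/metadata.tsv \
      --fit-age --out gini.tsv
G = 0.7759 + -0.1026 ln(age), r^2 = 0.794 (n = 60)

$ cazyprofiler associate --abundance demo/abundance.tsv \
      --meta demo/inputs/metadata.tsv --covariate bmi --out assoc.tsv
5 positively associated families at adjusted p < 0.05
summed-marker windowed r^2 = 0.928 (window 5, step 1)
```

The Gini fit shows the planted age structure: infant repertoires are
concentrated on a few milk-adapted families (G near 0.9), adults spread
across many (G ≈ 0.35), giving the negative logarithmic trend. The five
recovered BMI families are exactly the planted ones, and the head of
`markers.tsv` shows a CAZotype-2 marker (4.5-fold enriched, BH-adjusted
p ≈ 5e-15):

```
family  cazotype  mean_in  mean_out  ratio   p_adjusted    is_marker
CE1     1         1.247    4.251     0.293   1.000         False
CE1     2         5.386    1.208     4.457   4.79e-15      True
CE1     3         1.098    3.276     0.335   1.000         False
```

## Scope

The pipeline consumes BLAST tabular output; it does not run BLASTx,
CD-HIT pre-clustering, or metagenome assembly, and does not ship any real
metagenome data. See `docs/methods.md` for the statistical model, the
generator's assumptions and known limitations.
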