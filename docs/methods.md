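# Methods

This note documents the statistical procedures implemented in
`cazyprofiler`, the choices made where a procedure admits more than one
reasonable reading, and what the synthetic cohorts do and do not emulate.

## Homolog detection

A BLAST-tabular hit of a contig against the annotated CAZyme protein
database is accepted when all three criteria hold:

* E-value strictly below 1e-05;
* bit score per alignment column strictly above 1.0;
* alignment coverage of at least 75 % (inclusive).

Coverage is ambiguous for whole-contig queries: a long contig can carry a
perfect CAZyme gene yet cover only a sliver of itself. The default
therefore computes coverage on the query basis with a ×3
nucleotide→amino-acid correction, `3·alignment_length / query_length`,
which equals the intended "fraction of the encoded protein aligned" when
queries are gene-length; `coverage_basis="subject"` switches to
`alignment_length / subject_length`. Both are exposed rather than hiding
the ambiguity.

One best hit is kept per query: maximal bit score, ties broken by lower
E-value and then lexicographically smallest subject id, so selection is
deterministic. Counting all passing hits instead is available
(`count_mode="all"`). Hits to non-catalytic classes (CBM, AA) are
excluded; the annotation reader refuses them outright.

## Abundance, diversity, core and normalization

Abundance of family *f* in sample *s* is `count × 1e6 / size_bp`
(hits/Mbp), which removes sequencing-depth differences. Overall abundance
is the row sum. Diversity counts families whose raw hit count is **not
less than** 0.01 % of the sample's total hits — a family exactly at the
threshold is retained, and the exclusion applies to diversity (and the
per-sample Gini universe) only, not to presence/absence filters. Core
families have ≥ 1 accepted hit in at least 85 % of samples.

For typing/ordination the abundance matrix is normalized in two stages:
families present in under half the samples are dropped as sparse, each
remaining column is converted to Z-scores (sample standard deviation,
n−1) and range-scaled to [0, 1]. A constant column would divide by zero;
it maps to 0.5 everywhere, preserving the matrix shape deterministically.

## Gini functional rarefaction

For a non-negative abundance vector sorted ascending, the Lorenz curve
plots cumulative family fraction against cumulative abundance fraction;
the Gini coefficient is one minus twice the trapezoidal area under it,
which for discrete data equals the normalized mean absolute difference
`Σᵢⱼ|xᵢ−xⱼ| / (2n²µ)`. The implementation is tested against that pairwise
oracle (|Δ| < 1e-10 over random vectors), for scale invariance, and for
the Pigou–Dalton property (a rich-to-poor transfer never increases G).
The per-sample statistic uses the sample's own retained family set after
the 0.01 % exclusion; zero-abundance families inside a supplied vector
are legitimate members of n (they carry maximal inequality), but an
all-zero vector is an error. The age trend is ordinary least squares of
G on ln(age), ages strictly positive.

## Covariate association

Families present in at least half of the covariate-complete samples are
ranked within family across samples and correlated with the raw covariate
through a linear regression (Pearson r on ranks, a Spearman-style
statistic; `rank_transform=False` gives raw Pearson). P-values are
two-sided regression p, adjusted by Benjamini–Hochberg step-up across the
tested families; Bonferroni is available since both conventions circulate
for this analysis. Zero-variance families are flagged degenerate and do
not count toward the adjustment.

The summed-marker statistic sorts covariate-complete samples by the
covariate, slides a window of `⌈n/10⌉` samples (step 1) across them, and
reports the squared Pearson correlation of (window mean covariate, window
mean summed abundance). Window and step are configurable because no
canonical values exist for this smoother; window 1 reduces exactly to the
plain correlation, and windowing can only be interpreted as noise
averaging, not as extra evidence — the per-sample correlation should be
reported alongside.

Group comparisons (abundance/diversity/Gini across age or geography
cohorts) use one-way ANOVA with Tukey HSD post-hoc; when several response
variables are tested the ANOVA p-values are BH-adjusted across variables.
Zero within-group variance everywhere is flagged degenerate rather than
producing an infinite F.

## CAZotype discovery

The distance between two samples is the square root of the Jensen–Shannon
divergence (base-2 logs, so the maximum is 1) between their relative
family profiles, with zeros replaced by a 1e-9 pseudo-probability and
renormalized. Root-JSD is a metric, verified by a triangle-inequality
property test. Clustering on the range-scaled Z-score matrix with
Euclidean distance is available as an alternative
(`distance="euclidean"`), since the normalization chain and the
JSD-based typing tradition pull in different directions; JSD on relative
abundances is the default.

Partitioning around medoids is implemented with a deterministic greedy
BUILD phase and best-single-swap iterations, so results are reproducible
without a random seed. The number of clusters is chosen over k = 2..6 by
the Calinski–Harabasz pseudo-F, computed directly from the distance
matrix via the identity `W_c = Σ_{i,j∈c} d²ᵢⱼ / (2n_c)` (exact for
Euclidean-embeddable distances); silhouette widths are reported
alongside but do not drive selection. Ties go to the smaller k.

Between-class analysis eigendecomposes the size-weighted covariance of
the class mean profiles around the grand mean and projects samples and
class centroids onto the top two axes; with k classes only k−1 axes are
informative, and axis signs are fixed by making the largest-magnitude
loading positive.

Marker families: per family × CAZotype, a one-sided Welch t-test
(in-group greater than all other samples pooled), BH adjustment across
all tests performed, and a call requiring adjusted p < 0.05 **and**
in/out mean ratio > 1.5. The ratio gate is what keeps statistically
significant but biologically negligible differences out.

## Taxonomy

Percent identity of the best hit decides how deep an attribution can
honestly go: > 85 genus, 70–85 family, 55–70 class, 40–55 phylum. The
boundaries fall to the lower-resolution tier (only the genus tier is
written strictly), 40 itself still maps to phylum, and below 40 the hit
is unassigned — the conservative reading of the printed intervals.
Unknown lineage entries propagate to unassigned. Tier totality and
uniqueness are checked exhaustively on a 0.1-step identity grid.

The enrichment index of a taxon is `log10(p_caz / p_meta)` — its share
among CAZyme-attributed hits over its share in the whole metagenome. The
whole-metagenome profile is an explicit input (any profiler can supply
it); `p_caz = 0` yields a flagged floor value rather than −∞, `p_meta = 0`
is an error. CAZotype driver taxa re-use the marker machinery on
per-sample taxon compositions, after discarding taxa contributing ≤ 0.1 %
of the CAZotype's pooled repertoire.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline must
recover, at the hit-record level — no sequences are simulated, because
the analysis consumes tabular hits only.

Defaults (the study conditions of the test suite): 200 samples, 60
families, 3 CAZotypes, metagenome sizes uniform in 20–100 Mbp, 150
accepted hits/Mbp expected per adult sample. Each CAZotype has 6 disjoint
signature families whose center weight is boosted 4-fold
(`cluster_separation`); per-sample family shares are Dirichlet draws
around the center with total concentration 500
(`dirichlet_concentration_within`). These two values put the cohort in a
distinct-cluster regime — within-cluster spread clearly below
between-cluster distance — which is the community-type structure the
generator exists to emulate; at weak separation the k-selection is
expected to collapse below the planted k, and a test asserts exactly
that.

Age structure: 15 % infants (0.2–2.5 y), 5 % children (3–12 y), the rest
adults (18–70 y). Every infant belongs to the last CAZotype, whose first
4 signature families grow **additively** until they carry ≥ 92 % of the
infant's total abundance — the non-concentrated families keep their
cluster-level rates, so infant samples are simultaneously concentrated
(Gini ≈ 0.9 against ≈ 0.35 for adults) and high in overall abundance.
The additive construction is deliberate: a mass-preserving reallocation
would depress every other family in infants and thereby make *all*
generic families genuinely ~1.3–1.5-fold enriched in the adult CAZotypes
relative to the pooled out-group, blurring the planted marker ground
truth; with the additive variant the signature families are exactly the
truly enriched set.

BMI: adults draw BMI ~ N(25, 4²) clipped to [15, 45]; infants and
children have none. Five non-signature families receive
`0.15 hits/Mbp per BMI unit` times the centered BMI plus N(0, 0.5²)
noise, truncated at zero, only where BMI exists.

Hits: family counts are Poisson(rate × size/1e6); each hit independently
fails the E-value, bits-per-column and coverage criteria with rates
5 %/5 %/10 %, its attributes drawn inside the corresponding pass/fail
band with a safety gap around each threshold so that integer rounding of
lengths can never flip a label. Identities are drawn from tier bands
(55 % genus-grade, 20 % family, 15 % class, 8 % phylum, 2 % unassigned),
and each hit's source genus comes from its family's mixture — dominant
genus weight 0.8, with the signature families of each CAZotype pointing
at that CAZotype's driver genus (Bacteroides, Ruminococcus,
Lactobacillus, …). Whole-metagenome taxon profiles mix the
CAZyme-implied genus profile (80 %) with a uniform background (20 %).
One query per hit is emitted, so best-hit selection is the identity on
synthetic data; multi-hit queries are exercised by hand-built fixtures
instead.

What the generator does **not** emulate: realistic BLAST score
distributions (attributes are placed in threshold bands, nothing more),
compositional coupling between families, overlapping or gradient
community structure, sequencing error, or strain-level taxonomy. Tests
passing on these cohorts show the statistical machinery is correct and
calibrated under its stated model — not that the biological conclusions
transfer to any particular real cohort.

## Numerical and degenerate-input conventions

* Writers emit 12 significant digits; read–write round-trips are exact to
  that precision, and two runs with the same master seed are
  byte-identical (paths excluded from the manifest).
* All-zero abundance vectors: error for Gini and JSD (no Lorenz curve, no
  distribution); explicit zeros inside otherwise positive vectors are
  fine.
* Constant normalized columns → 0.5; zero-variance families in
  association → flagged, excluded from multiplicity counts; zero variance
  in both Welch groups → test skipped and logged.
* Ties: best-hit (bit score, then E-value, then subject id), PAM (lowest
  index), k selection (smaller k).
* The BCA second axis is zero-padded when the feature space or class
  count leaves fewer than two informative axes.

## Limitations

Per-query best-hit selection ignores multi-gene contigs (a contig
carrying two CAZymes contributes one hit); ORF calling is out of scope.
The enrichment denominator is trusted input, not computed from reads.
The published headline numbers of this analysis family (counts of
detected/core families on real cohorts, specific marker counts, the
real-data BMI signature R²) depend on hundreds of downloaded metagenomes
and a specific database version and are deliberately not targets of this
package's test suite; the suite asserts the properties of the method
instead.
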