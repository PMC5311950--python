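# Methods

## Scoring model

Each individual is fingerprinted with two digests, EcoRI/HpaII ("HPA")
and EcoRI/MspI ("MSP"). Both isoschizomers cut unmethylated CCGG; HpaII
is blocked by methylation of the internal cytosine, MspI by full or
hemimethylation of the external cytosine, and both are blocked when the
site is hypermethylated or mutated away. The pair of 0/1 band calls at a
locus therefore maps totally onto four states: (1,1) → Type I
(unmethylated), (0,1) → Type II (internal-C methylation), (1,0) →
Type III (external-C / hemimethylation), (0,0) → Type IV. Type IV
confounds hypermethylation with restriction-site mutation, so it never
contributes to methylation quantities; under the default policy it is
missing data in MSL analyses (configurable to "unmethylated" for
sensitivity analysis).

A locus is **methylation-susceptible (MSL)** when its discordance — the
proportion of Type II + III calls across all individuals, Type IV rows
included in the denominator — strictly exceeds the error-rate threshold
(ERT). The strict comparison means ERT = 0 makes every locus with at
least one discordant call MSL, and an ERT at the maximum observed
discordance leaves none. Default ERT 0.05: two-enzyme AFLP scoring
error is typically a few percent, and 5% separates sporadic mis-calls
from repeatable methylation polymorphism. All other loci are
**non-methylated (NML)**; their band variation is read as genetic.
Band presence at an NML locus defaults to "not Type IV": sub-threshold
discordance is treated as noise, so a cut by either enzyme shows the
restriction site exists (configurable to Type I only).

Only polymorphic loci — both binary states observed at least twice
among non-missing entries — enter diversity and differentiation
analyses; the MSL/NML totals are reported before this filter, the
analysed counts after it.

The global methylation level is (Type II + III) / (Type I + II + III)
over the MSL partition. Population summaries report both the
pooled-count proportion and the mean of per-individual proportions;
the two differ whenever individuals have unequal numbers of scorable
(non-Type-IV) loci, so they are kept distinct in every output.

## Diversity and group comparisons

Per-locus Shannon diversity uses natural logarithms (so a binary locus
is bounded by ln 2 ≈ 0.693) with frequencies over non-missing entries;
the log base is configurable. The MSL and NML per-locus vectors are
compared with the two-sided Wilcoxon rank-sum test, normal
approximation with tie correction and continuity correction; the W
statistic is the rank sum of the first sample minus its minimum,
matching R's `wilcox.test`. Loci are the observations in this
comparison.

The group battery on per-individual methylation levels runs classic
one-way ANOVA and checks its residuals with Shapiro-Wilk; when the
check rejects at 0.05 or is uninterpretable (statistic outside [0,1] or
p not computable) the Welch F for unequal variances replaces ANOVA.
Medians are compared with Kruskal-Wallis (both raw H and tie-corrected
Hc are reported). Post-hoc: Tukey-Kramer on means, with
Q = |m̄_i − m̄_j| / √(MS_w/2 · (1/n_i + 1/n_j)) and p from the
studentized-range distribution (Q and p are reported as two separate
symmetric tables rather than one mixed triangle), and pairwise
Mann-Whitney on medians. Outlier exclusion is never automatic: callers
pass explicit individual IDs, which are recorded in the report. No
multiple-testing correction is applied across the battery.

## Differentiation

Distances between individuals are squared Euclidean on the binary
vectors — the mismatch count for dominant markers — computed over
pairwise-complete loci and rescaled by L / (#compared loci) when
missing MSL entries (Type IV) reduce the comparison set
(complete-case deletion is available as an option). This is the
standard substrate for dominant-marker AMOVA.

AMOVA decomposes the pairwise squared distances: SS_total =
Σ_{i<j} d²_ij / N, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g, SS_among =
SS_total − SS_within; σ²_w = SS_within / (N − K) and σ²_a = (MS_among −
σ²_w) / n₀ with the unequal-size coefficient n₀ = (N − Σ n_g²/N)/(K−1).
ɸ_ST = σ²_a / (σ²_a + σ²_w); negative estimates are reported as
computed, never truncated. Significance permutes individuals among
populations with group sizes fixed; the Monte Carlo p uses the +1/+1
convention (observed arrangement included) so p > 0 always, and an
exact mode enumerates all distinct assignments when that is feasible.
Default 10,000 permutations (p resolvable to 10⁻⁴); a seed is mandatory
whenever permutations are run. Pairwise ɸ_ST applies the same two-group
machinery to each population pair, with per-pair permutation streams
spawned deterministically from the master seed. "AFLP mode" concatenates
the HPA and MSP profiles into a 2L-column presence/absence fingerprint
(per-column polymorphism filter) and runs the same AMOVA — an all-loci
second measure of genetic differentiation.

PCoA Gower-centres −½ D² (the stored distances are already squared),
eigendecomposes the centred matrix, keeps positive-eigenvalue axes
scaled by √λ, and reports percent variance over the positive spectrum.
Negative eigenvalues — expected when missing-data rescaling makes the
matrix slightly non-Euclidean — are reported, not silently dropped.
The implementation is cross-checked against scikit-bio's ordination in
the test suite.

## Synthetic data generator

The generator emulates the structure of real two-enzyme MSAP surveys:
K populations of n_k individuals over L loci, a fraction `msl_fraction`
(default 0.53, a typical MSL share of anonymous CCGG loci) of which are
methylation-susceptible. For each MSL locus and population a
methylation probability is drawn from Beta(μ_k·c, (1−μ_k)·c)
(concentration c = 10) so per-locus diversity varies as in real data;
each individual is methylated with that probability, split uniformly
between Type II and Type III (the data never resolve their relative
frequencies mechanistically), else Type I; Type IV replaces the latent
state at `type_iv_extra_rate` (default 0.25 — real MSAP profiles show
Type IV as the most frequent state). NML loci draw an ancestral band
frequency from Uniform(0.1, 0.9) (range configurable, e.g. near
fixation to emulate low genetic diversity) and population frequencies
from the F-model Beta(p(1−F)/F, (1−p)(1−F)/F), making realized ɸ_ST
tunable through F and exactly exchangeable at F = 0. Latent states are
rendered to band pairs through the truth table, and scoring errors flip
band bits independently at `scoring_error_rate`. All draws come from
one seeded generator: identical seeds give byte-identical datasets.

What the generator does **not** emulate: linkage among loci,
comigration of non-homologous fragments into one bin, instrument-level
intensity noise (errors are symmetric bit flips), within-population
family structure, and any mechanistic link between environment and
methylation. Passing tests therefore demonstrate that the estimators
recover the statistical structure they target — not that real surveys
are free of those artefacts.

`calibrate_phist` maps the divergence parameter to realized NML ɸ_ST by
running the full simulate → score → classify → AMOVA chain per
replicate, so the curve includes scoring error and the polymorphism
filter. `null_rejection_rate` measures the empirical size of the
permutation test under the exchangeable null.

## Numerical and design choices

- Peak binning is greedy left-to-right 1-D clustering of the pooled,
  sorted peak sizes: a new locus starts when a peak lies more than
  `bin_width` (default 1.5 bp) above the first member of the running
  cluster. This is deterministic and invariant to input order of peaks
  and individuals (individuals are sorted lexicographically). The
  height-ratio filter (default 1.8) removes peaks above that multiple
  of the **locus median** height after binning; the median is the
  reference because it is robust and at least the median peak always
  survives. Multiple surviving peaks of one individual in one bin
  collapse to presence.
- Strict ERT comparison (`>`), discordance denominator = all
  individuals including Type IV rows: the literal "proportion across
  all samples" reading; both documented above.
- The band-matrix CSV reader accepts only the row-per-individual×enzyme
  layout and fails loudly (naming the offending row or cell) on
  anything else, including transposed files.
- Tie-break and degenerate inputs: all-tied Wilcoxon samples return
  p = 1 with a warning; all-missing Shannon loci are excluded with a
  warning; singleton populations are errors in AMOVA and dropped with a
  warning from post-hoc tables; an all-zero distance matrix is a
  degenerate-input error in PCoA.
- Pipeline permutation seeds for the MSL, NML and AFLP analyses are
  spawned from the master seed via independent seed sequences, so the
  three tests are decoupled but jointly reproducible; reruns with the
  same inputs and seed produce byte-identical TSVs.

## Problem sizes in the shipped experiments

The packaged experiments use sizes chosen to estimate each quantity to
comfortably better precision than the bands being checked: AMOVA oracle
equivalence on 100 random instances with N ≤ 8 at 10⁻¹⁰ tolerance plus
exhaustive enumeration of permutation nulls; null calibration with 600
replicates of two 15-individual populations over 100 loci at 199
permutations (binomial SE ≈ 0.009 on a 0.05 target); divergence
monotonicity over F ∈ {0, 0.05, 0.1, 0.2} with 40 replicates per point;
parameter recovery of the 55%-vs-67% contrast over 100 seeds at K = 2,
n_k = 30, L = 380; and a full-pipeline run at the survey scale of
82 individuals × 380 loci × 3 populations.

## Known limitations

- Type II/III must not be over-interpreted as CG vs CHG methylation;
  nested differentially-methylated internal sites produce the same
  patterns. The toolkit reports the states and their pooled
  methylated/unmethylated summary only.
- MSL/NML classification with few individuals is noisy: with n = 20,
  one discordant call (0.05) sits exactly at the default threshold.
- The AMOVA here is single-level (populations / individuals); no
  hierarchical strata, no sequence-based distances.
- Pairwise-complete distance rescaling can make D² slightly
  non-Euclidean; PCoA reports the resulting negative eigenvalues and
  AMOVA is unaffected (it uses the squared distances directly).
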