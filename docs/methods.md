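# Methods

This note documents the models, numerical choices and limitations behind
`labyprot`.  The pipeline analyses a zoospore-to-vegetative-cell settlement
time course: five timepoints (0, 2, 4, 6, 8 hours post-settlement), three
biological replicates each, with per-sample reporter-ion intensities per
protein.  Replicates are treated as batches, since each replicate's five
channels were labeled and fractionated together.

## Normalization

**Calibration.**  Each sample is scaled by a median-of-ratios factor
against a reference profile (the per-protein geometric mean over samples,
computed on proteins quantified everywhere).  This removes per-sample
loading/labeling differences without assuming any protein is constant.

**Generalized log (glog).**  Calibrated intensities pass through
y = log2((x + √(x² + c²))/2), which equals log2(x) for x ≫ c and stays
finite and nearly linear near zero, so replicate variance stops depending
on intensity when additive noise dominates at the bottom of the range.
The offset c is the 5th percentile of the calibrated intensities
(`GlogNormalizer(offset_quantile=0.05)`).  This quantile heuristic
stabilizes variance when the additive noise floor sits near the low end of
the intensity distribution, which is the regime reporter-ion data occupy;
it is not a maximum-likelihood VSN fit, and if the additive/multiplicative
noise ratio is far from the low quantile the bottom decile remains
under-stabilized.  The test suite quantifies this with a simulation
oracle: under matched noise (multiplicative sd 0.15, additive sd 900 on
baselines 2^12–2^24) the replicate-difference sd varies by < 25% across
intensity deciles after glog, versus > 50% on a raw log scale.

**Missing values.**  Raw intensities of 0 (the MaxQuant convention for an
unquantified channel) or empty cells are missing; the sentinel is
configurable.  No imputation is performed: a contrast needs at least 2
quantified replicates on each side or its statistic is set missing with a
reason code.

## Batch correction

A two-way empirical-Bayes decomposition in the ComBat family, protecting
the timepoint structure: per-protein timepoint means are fitted and set
aside; residuals are standardized by their pooled scale; per-(batch,
protein) location and scale parameters are estimated, shrunk toward
batch-level priors, removed; the timepoint means are restored.

One deliberate departure from the common moment estimates: the prior
variance τ²_b of the batch locations is the across-protein spread of the
observed per-protein batch means **minus their average sampling variance**
(and analogously the scale parameters shrink fully to the batch mean when
their spread does not exceed the chi-square sampling spread).  When a batch
shift is shared by all proteins — the generative situation for
replicate-level labeling offsets — the raw moments are dominated by
sampling noise, and removing per-protein batch means estimated from 5
samples silently eats ~20% of the residual degrees of freedom, inflating
every downstream t-statistic.  With the sampling-corrected moments the
correction collapses to exact batch-mean removal in that regime, and the
all-null type-I error of the full pipeline stays at the nominal level
(measured 0.050–0.056 at the 0.05 point over seeds).  When batch effects
genuinely differ across proteins the spread exceeds its sampling floor and
the standard per-protein EB iteration takes over.  A batch nested entirely
within one timepoint is refused as confounded.

## Moderated differential abundance

Per protein, ordinary least squares on timepoint means (equivalent to a
group-means linear model); residual variance s²_g with d_g = n_obs −
n_groups df.  The shrinkage prior (d₀, s₀²) comes from moment-matching
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of Var(e) over the mean
chi-square log-variance ψ′(d_g/2) determines ψ′(d₀/2), inverted by Newton
iteration (tolerance 1e-8 relative); the mean determines s₀².  If the
observed spread does not exceed the sampling spread — e.g. all s²_g equal —
d₀ is the +∞ sentinel and every posterior variance equals s₀².  The
posterior s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g); moderated
t = log2FC/(s̃_g √(1/n_k + 1/n_0)) with d₀ + d_g df.  On a frozen
heteroskedastic fixture the implementation reproduces Bioconductor limma's
`eBayes` hyperparameters and statistics to ~1e-7 (values frozen in the test
suite).

**Calls.**  Significant means BH-adjusted p < α = 0.1 AND fold change
outside [1/1.0001, 1.0001] (|log2FC| > log2(1.0001) ≈ 1.44e-4 on the glog
scale, where glog ≈ log2 at quantified intensities).  Two open choices are
resolved as defaults with switches: α applies to the **adjusted** p (the
convention of the DEP workflow this pipeline mirrors; `--raw-p` switches),
and BH runs **within each contrast** as four separate families
(`pool_contrasts` pools them).  Correspondingly, the null false-discovery
guarantee is per family; on a global null the chance that *any* of four
families rejects is roughly four times the per-family level, so the
pipeline's calibration checks measure the FDP at the family level.

## Clustering and PCA

Profiles of the significant proteins are mean-centered per protein
("log2-centered"), z-scored, and clustered by restarted Lloyd k-means
(k = 4, 25 random initializations, best total distance kept, deterministic
given the seed).  For z-scored rows the Pearson distance 1 − r equals
squared Euclidean distance / 2p, so the Euclidean Lloyd step minimizes
total Pearson distance; an emptied cluster is re-seeded at the point
farthest from its centroid.  Constant profiles carry no correlation signal
and are excluded with a reason code; proteins with missing cells are
likewise not clustered.

Because k-means labels are arbitrary, fitted clusters are renamed by a
fixed convention — descending centroid value at the reference timepoint,
ties broken by earlier centroid maximum — which reproduces the settlement
semantics: C1 and C2 zoospore-high (C1 dropping fastest), C3 late-rising,
C4 rising from T2.  PCA of samples runs on the complete-row normalized
matrix (proteins as variables, centered), via SVD; variance fractions are
the normalized squared singular values.

## Enrichment

Each (term, foreground) cell is tested with exact hypergeometric tails
P(X ≥ k) and P(X ≤ k) against the detected-protein background — the
background is what was measured, not the whole predicted proteome.  Both
tails are reported and BH-corrected as two separate families at 5% FDR, so
over- and under-representation flags do not compete for the same budget.
GO maps are tested with the same plain machinery; DAG-aware decorrelation
(weight01-style) is out of scope.

## Proteome merge

Best hit per query maximizes bitscore, ties broken by lower e-value, higher
percent identity, then lexicographic subject id; reciprocal best hits are
mutual bests.  The non-redundant set keeps one entry per RBH pair (keyed by
the first annotation's id, the partner kept as alias) plus all unpaired
ids.  An unpaired entry that is the best hit of ≥ 2 unpaired queries from
the other annotation is a many-to-one conflict: it is dropped with a logged
reason, as a deterministic, auditable reading of "remove ambiguous or
redundant assignments"; the rule can be switched off.  Detection maps onto
the merged set by union over pair members.

## Lineage-restriction screen

Top-5 hits per query are retained by (e-value ↑, percent identity ↓,
bitscore ↓, subject id ↑).  Queries partition into four groups: no
stramenopile hits (`aurli_only`); hits only to *H. fermentalgiana*
(`laby_only`); hits only to other stramenopiles, or ≥ 5 retained other-hits
all scoring strictly above the best Hondaea hit
(`stramenopile_not_hondaea`); otherwise `both`.  A query whose retained
hits are all other-stramenopile but fewer than five is assigned
`stramenopile_not_hondaea` — it demonstrably has non-laby homologs and no
laby ones — keeping the partition total.  For `both` queries the deltas
best-Hondaea − best-other are computed for bitscore, −log10 e-value and
percent identity ("best" = highest bitscore, ties by lowest e-value), and
the bitscore delta is binned by empirical percentile (0–85, 85–90, 90–95,
95–97.5, 97.5–100) using maximum tie rank, so a query at the maximum —
including a single-delta population — lands in the top bin; an all-equal
delta population is degenerate and triggers a warning.

The orthogroup route passes a protein iff its orthogroup (1) spans ≥ 2
Labyrinthulomycota genomes, (2) ≤ 1 non-Labyrinthulomycota genome, (3) the
protein is significantly upregulated at T4, T6 or T8, and (4) the
orthogroup has ≥ 1 *H. fermentalgiana* copy.  Note (1) and (4) are not
independent: failing (1) with the protein's own genome present forces
failing (4), since Hondaea is itself a laby genome.  A separate
conservation flag (orthogroup in ≥ 3 of the 5 laby genomes) is
annotation-only and does not gate candidacy.

Candidates are the union of the two routes, restricted to proteins
upregulated at the configured post-settlement timepoints.  BLAST-route
candidacy defaults to `laby_only` plus `both` in the top (≥ 97.5%) bin —
the most conservative reading of "Hondaea-like" — and is a configuration
knob, as is the exclusion of `aurli_only` orphans (no identifiable laby
homolog at all).

## Synthetic data

The generator defines the study conditions.  Log2 intensity = baseline
(uniform on 11.8–24.4, the observed reporter-intensity range) + planted
temporal effect + replicate batch offset (N(0, 0.3²)) + noise
(N(0, 0.25²)), exponentiated and rounded to integer intensity units ≥ 1;
cells go missing at random (2% by default).  Four archetypes plant effects
in multiples of 1.0 log2 unit at (T2, T4, T6, T8): C1 = (−1,−1,−1,−1),
C2 = (−⅓,−⅔,−1,−1), C3 = (0,0,1,1), C4 = (1,1,1,1); fractions
(2.4%, 4.7%, 4.2%, 5.2%) mirror the relative sizes of the published
settlement clusters.  Planted sensitivity is evaluated on (protein,
timepoint) pairs carrying the full effect size; C2's graded early effects
are real but below what three replicates can reliably detect, and are not
counted against the engine.

Lineage structure: planted candidates (default 12) are laby-restricted and
drawn from the upregulated archetypes; orphans get no hits and no
orthogroup; broadly conserved proteins hit both taxon classes, with the
bitscore delta drawn high for background proteins and low (≤ −30 bits) for
upregulated decoys, so decoys are never Hondaea-like even under 5-bit
scoring noise.  Orthogroups are built so every planted candidate satisfies
the structural screen conditions and negative controls violate exactly one
condition each where that is logically possible (a cond-1-only violation is
not, see above).  One annotation term is enriched in a chosen archetype at
a configured odds ratio (default 8); the rest are uniform.  Every generator
draws from its own named RNG stream derived from the single seed, so adding
one generator never perturbs another's output.

What the generator does **not** emulate: peptide-level structure and
shared-peptide ambiguity, intensity-dependent (left-censored) missingness,
correlated protein co-regulation, realistic sequence content, or
phylogenetic correlation among hit scores.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every pathology of real MS data.

## Problem sizes and numerics

Default analyses use 2,000–5,000 proteins; calibration checks use an
all-null 5,000-protein course and 20 seeds; hyperparameter recovery uses
2,000 proteins; merge oracles use ≤ 50 ids per side over 100 fixtures;
hypergeometric exactness is enumerated for every population N ≤ 60.  These
sizes give stable estimates in about a minute of CPU.  Numerical
tolerances: trigamma inversion 1e-8 relative; batch-corrector EB iteration
1e-6 with a 100-iteration cap; Lloyd convergence 1e-9 on the objective;
residual scales at or below 1e-8 × the data magnitude are treated as
degenerate (noise-free data) rather than standardized.  All TSV output is
written with fixed float formats so identical seeds reproduce byte-identical
files.

## Known limitations

* The glog offset heuristic under-stabilizes when additive noise is much
  larger than the low-intensity quantile (see Normalization).
* The ambiguity rule in the merge is a documented, deterministic stand-in
  for an unspecified redundancy filter; other reasonable rules exist.
* The screen's quantile binning is relative to the analysed cohort: the
  top bin always contains ~2.5% of `both`-group queries, so "Hondaea-like"
  is a cohort-relative statement, and on a degenerate all-equal delta
  population every query is top-binned (warned).
* BH control is per contrast family; pooled control across the four
  contrasts is available but changes the guarantee.
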