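# Methods

This note documents the statistical procedures `fastkit` implements, the
assumptions and defaults behind them, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Recovery statistics

All recovery quantities are computed from **un-rarefied** counts: detection
("count > 0") is the object of interest, and rarefaction would discard
exactly the rare observations the statistic is about. Distance and
diversity analyses, by contrast, are depth-sensitive and use counts
rarefied to a common depth. The pipeline enforces this split and records it
in the run log.

For one subject, a comparison has a reference sample and a query group
(S1 vs S2: single query; S2 vs mouse: the subject's mice). Taxa enter a
comparison only if they reach relative abundance ≥ τ (default 0.001) in at
least one sample of the comparison group; the threshold is inclusive
("at least 0.1%"), and for mouse comparisons the group is S2 plus all
mice, so a taxon that blooms in mice is counted even if rare in the
inoculum. "Detected" means a raw count above zero — no second threshold is
applied on the query side, which matches the observation that taxa lost
between aliquots sit just above the inclusion bound (0.1–0.3%).

Two pooling policies are reported for mouse comparisons. `any_mouse`
(default): a taxon is recovered if any of the subject's mice carries it —
the natural reading of a comparison group that includes all mice.
`per_mouse_mean`: the statistic is computed per mouse and averaged, which
is the right denominator if one wants per-animal engraftment rates. Venn
partitions always use the detection union across mice (one diagram per
subject, not per animal). Summaries aggregate per subject first and report
mean ± SE (sample SD / √n) across subjects; pooling all mice instead is
available by summarizing the per-subject frame differently, but subjects —
not cage-mates — are the independent units.

Abundance captured uses all taxa present in the reference, with no τ
filter, so it answers "how much of the community's mass survives" rather
than "how many of its members".

Degenerate cases: a comparison whose reference detects no included taxon is
flagged undefined and excluded from summaries; an all-zero sample stays
all-zero in the proportion table (with a warning) rather than producing
NaNs.

## Alpha and beta diversity

Shannon diversity uses natural log, matching the mothur convention of the
upstream 16S pipelines this package sits behind. Good's coverage is
1 − singletons/reads. Rarefaction is a single multivariate-hypergeometric
draw (subsampling without replacement) per sample, deterministic given the
seed; samples below depth are dropped, not scaled. Averaging over repeated
draws is deliberately not the default — the single-draw contract matches
"rarefied to N sequences" semantics — but can be had by calling `rarefy`
with several seeds.

Bray-Curtis is Σ|x−y| / Σ(x+y) on counts. Jaccard is the binary
presence/absence distance (the unweighted counterpart to Bray-Curtis in
the four-metric panel); the abundance-based Ružička variant is available
behind a flag. UniFrac is computed from a branch × feature incidence
matrix built in one postorder traversal; unweighted UniFrac is unique
branch length over observed branch length, weighted UniFrac is
Σ l_b |p_b(x) − p_b(y)| with the normalized variant (divide by
Σ l_b (p_b(x)+p_b(y))) as default so values are comparable across pairs.
Which weighted variant the original R/phyloseq analyses used is generally
not recoverable from publications; both are provided. Full matrices are
assembled with dense linear algebra over the same incidence matrix, and
the per-pair functions are checked against brute-force per-branch
enumeration in the test suite.

The phylogeny is an input: build one however your pipeline does (e.g.
FastTree on aligned representative sequences) and supply it as newick. The
simulator generates a random tree because UniFrac's correctness does not
depend on the tree being biologically meaningful.

## Hypothesis tests

PERMANOVA uses Anderson's pseudo-F on squared distances:
SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
F = (SS_among/(k−1)) / (SS_within/(n−k)). The p-value comes from random
relabelings with the plus-one correction (1 + #{F* ≥ F}) / (1 + P), so it
is never zero and has resolution 1/(P+1); P defaults to 999. With strata,
labels permute only within each stratum — the pipeline uses subject strata
when testing S1-vs-S2, so the test asks "do roles differ given subjects?"
rather than mixing the (huge) between-subject variation into the null.
Ties in the permuted statistic are counted as exceedances (F* ≥ F − 1e−12).
Pairwise PERMANOVA applies Bonferroni (p·n_pairs, capped at 1). Note the
permutation floor: two groups of size 3 admit only 10 distinct splits, so
p cannot fall below 0.1 regardless of separation.

Kruskal-Wallis (midranks, tie-corrected, chi-square reference) is used for
the DONOR/OTHER comparison, where group sizes are very unequal (each mouse
contributes 2 DONOR distances and 14 OTHER distances in the default
design). All-identical inputs return H = 0, p = 1. The serum regression is
ordinary least squares of choline on TMAO with the slope F-test. A paired
Wilcoxon signed-rank test on per-subject S1/S2 Shannon values stands in
for a subject-random-effect mixed model; it is labeled as such in the
output and is the package's own choice of a simpler, assumption-light
substitute.

## The synthetic study generator

The generator emulates the *structure* the analysis assumes, with defaults
fixed at the emulated study's design: 8 subjects, 2 aliquots + 3 mice per
subject, 800 OTUs, 60,000 reads per sample (the real study's mean depth,
order of magnitude), log-normal(σ = 2) abundances, per-subject presence
masks (prevalence 0.7) so subjects differ strongly while aliquots are
near-identical, and retention 0.785 on engraftment.

- **Aliquots** are independent multinomial resamples of the donor: the only
  source of S1/S2 disagreement is sequencing depth, which reproduces the
  observed regime where only taxa near the 0.1% bound are lost. A Dirichlet
  overdispersion knob exists for stress testing and is off by default.
- **Engraftment dropout** is a Bernoulli per donor OTU with probability
  logistic in standardized log-abundance (slope 3). The intercept is solved
  per subject (Brent root-finding) so that the mean retention over the taxa
  at or above τ equals `retention_p` exactly — the measured recovery
  statistic averages detection over essentially that set, which makes the
  dial an unbiased, monotone readout of the parameter. The steep slope
  concentrates losses in the 0.1–0.3% band and keeps the two inclusion
  pathways that would otherwise bias the measurement (rare taxa entering
  the comparison only via retained-and-bloomed mouse abundances; boundary
  taxa conditioned on retention) negligible.
- **Retention is drawn once per subject**, not per mouse: cage-mates
  receive the same gavage and exchange microbiota, so whether a taxon
  colonizes at all behaves as a property of the donor-taxon/host pairing.
  Per-mouse independent retention would make union-pooled recovery
  1 − (1−p)³ ≈ 0.99 at p = 0.785, which is not the regime being emulated.
  Per-mouse variation enters through log-normal abundance noise
  (σ = 0.3) and read resampling.
- **Phylum fold changes** (Bacteroidetes ×2, Verrucomicrobia ×2,
  Firmicutes ×0.5, Proteobacteria ×0.5) shift surviving taxa before
  renormalization, reproducing the bloom/contraction pattern seen on
  transplantation into mice. The magnitudes are order-of-magnitude choices;
  only the signs are treated as meaningful, and the tests check them by
  sign test.
- **Phenotypes**: a mouse's TMAO is proportional (scale 100, arbitrary
  concentration units) to the summed abundance of a random 10% of OTUs
  designated TMA producers, and choline falls linearly from a baseline of
  40 units at 0.5 units per TMAO unit, both with Gaussian noise and
  truncation at zero. This yields the inverse TMAO–choline relation with a
  subject-to-subject spread driven by how much producer mass engrafted.

All randomness derives from one root seed through fixed substreams
(documented in `generate_study`), so bundles are pure functions of their
configuration.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: taxonomic structure is synthetic (balanced
nested lineages; real rank-level recovery values depend on the real
taxonomy's shape, so only the OTU-level rate and the coarse-to-fine
monotone ordering are meaningful targets); the phylogeny is random rather
than trait-correlated, so UniFrac results validate the computation, not
phylogenetic signal; dropout is statistical, not mechanistic (no oxygen
sensitivity, diet, or host adaptation); there are no sequencing error or
chimera models; and an entire rare phylum can occasionally be lost because
dropout acts on OTUs — real transplant data showed every included phylum
recovered.

## Numerical choices and problem sizes

Rarefaction, permutation tests and the generator take explicit seeds;
nothing draws from global RNG state. The acceptance script averages 20
replicate synthetic studies at the full default design, which a laptop
completes in seconds; the test suite's property checks use 200–1000 random
8-leaf instances for the distance oracles and 500 replicates for null
calibration of the permutation test, sizes at which binomial/KS bounds are
tight enough to catch calibration errors of a percentage point or two.
Counts are validated as non-negative integers on input; proportion columns
must sum to 1 within 1e−9; distance matrices are symmetrized only against
floating-point asymmetry (averaging with the transpose after vectorized
assembly).

## Known limitations

- Recovery statistics treat detection as binary; they do not model
  detection probability as a function of depth, so comparing studies at
  very different sequencing depths requires care.
- The PERMANOVA permutation scheme (strata choice) changes p-values;
  published p-values from other implementations are reproducible only
  qualitatively unless the scheme is known.
- The SE reported for mouse comparisons uses subjects as the unit; with 8
  subjects the SE itself is noisy.
- `per_mouse_mean` pooling shares the reference set across mice; a fully
  per-animal analysis would also recompute the inclusion set per mouse,
  which the comparison-group definition (S2 plus all mice) deliberately
  does not.
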