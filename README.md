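# fastkit

Quantitative analysis of fecal-aliquot reproducibility and germ-free-mouse
engraftment fidelity for 16S rRNA OTU tables.

When a stool specimen is stored as frozen straw aliquots and later used both
for sequencing and as an oral inoculum for gnotobiotic mice, two questions
decide whether the workflow is trustworthy: do two aliquots of the same
specimen (S1, S2) yield the same community, and how much of the inoculum
community actually engrafts in the recipient mice? `fastkit` answers both
with a reusable, tested pipeline aimed at microbiome researchers running
fecal-transplant or biobanking studies.

## The statistics at its core

For each subject, a comparison pairs a *reference* sample (S1 or S2) with a
*query group* (S2, or the subject's mouse fecal samples). Let `p_f(s)` be
the relative abundance of taxon `f` in sample `s`, computed from
**un-rarefied** counts at a chosen rank (phylum, order, family, genus, or
OTU). With inclusion threshold τ = 0.001 (0.1%):

- **Inclusion set** `I = { f : p_f(s) ≥ τ for at least one sample s in the
  comparison group }` (for mouse comparisons the group is S2 plus all of the
  subject's mice).
- **Taxa recovery** = `100 · |{ f ∈ I : detected in reference and query }| /
  |{ f ∈ I : detected in reference }|`, where "detected" means count > 0;
  a taxon counts as recovered if any of the subject's mice carries it
  (`any_mouse` pooling; a per-mouse average is also reported).
- **Abundance captured** = `100 · Σ { p_f(reference) : f detected in the
  query }` over *all* taxa present in the reference (no threshold).
- **Venn partition** of `I` into reference-only / shared / query-only taxa.

Around these sit the standard community-ecology stack, computed on counts
rarefied to a common depth (default 4500): Shannon diversity, Good's
coverage, Bray-Curtis, binary Jaccard, unweighted and weighted UniFrac,
PERMANOVA (Anderson's pseudo-F, optionally with within-subject strata),
Kruskal-Wallis on DONOR-vs-OTHER mouse-to-human distances, and an OLS
regression of serum choline on TMAO for choline-metabolism phenotyping.

A synthetic-study generator (`fastkit.simulate`) emulates the full design —
8 subjects × (2 aliquots + 3 mice), heavy-tailed log-normal communities,
multinomial aliquot resampling, abundance-dependent engraftment dropout
calibrated to a retention parameter, phylum-level blooms/contractions, and
an inverse TMAO–choline phenotype — so every stage is testable without
sequencing data.

## Worked example

```python
from fastkit import EngraftmentRecovery, SyntheticConfig, generate_study

bundle = generate_study(SyntheticConfig(rng_seed=1))   # 8 subjects, 40 samples
results = EngraftmentRecovery(bundle.table, bundle.taxonomy, bundle.manifest).fit()
print(results.summary())
```

```
Taxa recovery under the 0.1% inclusion rule
==========================================================================
comparison    pooling         rank          recovery %     abundance %   n
--------------------------------------------------------------------------
S1_vs_S2      single          phylum       100.0 ± 0.0     100.0 ± 0.0   8
S2_vs_mouse   any_mouse       phylum        97.9 ± 2.1      99.9 ± 0.1   8
...
S1_vs_S2      single          OTU          100.0 ± 0.0      99.9 ± 0.0   8
S2_vs_mouse   any_mouse       OTU           77.6 ± 1.1      86.2 ± 0.6   8
==========================================================================
```

Reading the OTU rows: the two aliquots of each donor recover each other's
taxa essentially completely (100%, with recovered taxa covering 99.9% of
the reference community), while the mice retain 77.6 ± 1.1% of the
inoculum's OTUs — the engraftment bottleneck the method quantifies. Values
are means ± standard error across the 8 subjects.

The same analysis runs from the shell on TSV/newick inputs:

```sh
fast-kit simulate --seed 1 --outdir study/
fast-kit run --table study/counts.tsv --taxonomy study/taxonomy.tsv \
    --tree study/tree.nwk --manifest study/manifest.tsv \
    --metabolites study/metabolites.tsv --outdir report/
```

which writes per-subject recovery tables, four beta-diversity matrices,
PERMANOVA / Kruskal-Wallis / regression statistics and a seeded run log.

## Layout

- `src/fastkit/io.py` — validated readers/writers (count table, taxonomy,
  newick tree, manifest, metabolites, distance matrices)
- `src/fastkit/community.py` — relative abundance, rank aggregation,
  rarefaction, Shannon, Good's coverage
- `src/fastkit/beta.py` — Bray-Curtis, Jaccard, UniFrac, distance matrices
- `src/fastkit/recovery.py` — the recovery statistics and the
  `EngraftmentRecovery` model / `RecoveryResults` pair
- `src/fastkit/inference.py` — PERMANOVA (with strata), pairwise PERMANOVA,
  Kruskal-Wallis, OLS
- `src/fastkit/simulate.py` — the synthetic study generator
- `src/fastkit/pipeline.py`, `src/fastkit/cli.py` — orchestration and the
  `fast-kit` command

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
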