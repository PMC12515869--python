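# lactylome

Desk-scale analysis pipeline for lysine-lactylation (Kla) profiling — the
kind of label-free PTM omics experiment that compares modification levels
between two tissue states (e.g. healthy vs infarcted mouse heart) at the
resolution of individual lysine sites.

The central statistical problem: an observed modification-site intensity
confounds two signals, how much of the *protein* is present and how much of
it is *modified*. The pipeline therefore quantifies each site relative to
its parent protein before testing:

1. **Normalize** — per-sample intensities are rescaled so column medians
   agree (loading correction); the site table borrows the factors derived
   from the global proteome, which is robust when modification changes are
   one-directional.
2. **Center** — every feature row is divided by the mean of its present
   values, giving unitless relative quantifications `r_ij` with row mean 1.
3. **Correct** — each site's relative value is divided by its parent
   protein's: `c_ij = r_ij^site / r_ij^protein`, cancelling protein
   expression so that changes reflect modification stoichiometry.
4. **Test** — per site, the fold change is the ratio of group means on the
   linear scale, `FC = mean(case) / mean(control)`; inference runs on log2
   values through an assumption gate (Shapiro–Wilk normality per group,
   Brown–Forsythe variance homogeneity) choosing Student's vs Welch's
   t-test; p-values are Benjamini–Hochberg adjusted; a site is called
   changed when `FC > 1.5` or `FC < 1/1.5` with raw `p < 0.05`.

Around that core the package provides, as separate modules with plain
functions:

* `simulate` — a synthetic-data generator reproducing the structure of such
  experiments (3 vs 3 design, ~44% singly-modified proteins, heavy-tailed
  sites-per-protein counts, log-normal intensities, per-sample scaling,
  spiked fold changes, missing values) with ground-truth spike tables;
* `catalog` — sites-per-protein histograms, single-site fraction, flanking
  windows, Venn overlap of modification vs protein-content changes,
  compartment tallies;
* `motif` — positional residue frequencies around modified lysines and a
  greedy motif-x-style binomial motif search against a proteome background;
* `network` — MCODE molecular-complex detection (k-core vertex weighting,
  seeded expansion, density × size scoring) on PPI edge lists;
* `enrich` — hypergeometric over-representation analysis and preranked GSEA
  with a gene-label permutation null.

## Worked example

```python
import lactylome as lm

proteome = lm.generate_proteome(400, 400, seed=3)
design = lm.SyntheticDesign(seed=3)            # 3 vs 3, spiked FC 2.0
catalog = lm.generate_lactylome(proteome, design)
sites, proteins, truth = lm.generate_intensities(catalog, design)

model = lm.DifferentialModel.from_raw_tables(
    sites, proteins, catalog.site_protein_map(), design.group_design())
results = model.fit()
print(results.summary())
print(f"single-site fraction: {lm.fraction_single_site(catalog):.2f}%")
```

prints

```
Two-group differential modification analysis
============================================
features: 872  (untestable: 41)
groups:   3 control vs 3 case
call window: fc > 1.5 or fc < 0.6667, p < 0.05 (gate alpha 0.05)
up:   75
down: 0
ns:   756
tests used: student=697, welch=134, untestable=41

single-site fraction: 43.98%
```

The 872 sites carry 10% up-spikes at true FC 2.0; 75 are called up (the
spiked ones recovered at ~80% sensitivity, near-zero false discovery), none
down, 41 sites have too few present values to test. `results.table` holds
the per-site `fc, log2fc, p, q, test_used, call` columns,
`results.plot_volcano()` draws the volcano plot, and
`results.changed_proteins()` maps calls back to parent proteins.

The same chain is scriptable from the shell:

```bash
lactylome run --outdir myrun --seed 3      # full simulate→…→enrich chain
lactylome simulate --outdir data --seed 3  # individual stages
lactylome quantify --sites data/site_intensities.tsv \
    --proteins data/protein_intensities.tsv \
    --map data/sites.tsv --design data/design.tsv --out corrected.tsv
```

All files are plain TSV/FASTA/GMT with `#` metadata headers; identical
config + seed reproduces identical bytes.

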