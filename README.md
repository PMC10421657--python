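# ighrep

Downstream analysis of B-cell receptor (immunoglobulin heavy chain, IGH)
repertoires from clonotype tables, built for cohort studies that compare
disease groups and geographic regions — the motivating design is an
endemic autoimmune skin disease (pemphigus foliaceus) with five groups:
non-treated patients, treated patients, patients in remission, healthy
controls from the endemic region, and healthy controls from a non-endemic
region, each profiled for IGHM and IGHG.

The pipeline starts where upstream processing (UMI consensus, V(D)J
annotation, clonotype calling) ends: a clonotype table in AIRR
Rearrangement TSV format plus a sample→group metadata table. It provides:

- **Clonal expansion spectra** — clonotypes binned by within-sample
  frequency *f*: low (*f* < 0.1 %), medium (0.1 % ≤ *f* ≤ 1 %),
  hyperexpanded (*f* > 1 %); bin proportions compared between groups with
  the Wilcoxon rank-sum test.
- **Alpha diversity** — Shannon entropy H = −Σᵢ fᵢ ln fᵢ and Faith's
  phylogenetic diversity (root-inclusive branch length of the subtree
  spanning a sample's CDR3 sequences) on a neighbor-joining tree built
  from normalized unit-cost alignment distances between CDR3 amino-acid
  sequences. Externally inferred newick trees can be supplied instead.
- **Beta diversity** — normalized weighted UniFrac between samples mapped
  onto a pooled per-isotype tree (IGHG restricted to clonotypes with
  frequency > 0.001; IGHM uses all), embedded by classical PCoA and tested
  with one-way PERMANOVA (Anderson's pseudo-F, label permutation, 99,999
  permutations by default, exhaustive enumeration when feasible).
- **Gene-segment usage** — per-sample IGHV/IGHJ/IGHC usage frequencies
  over unique clonotypes, per-segment Wilcoxon tests between disease
  statuses with Benjamini–Hochberg adjusted p-values alongside, and PCA on
  the differentially used segments.
- **CDR3 features** — length histograms with Shapiro–Wilk normality
  testing (integer lengths are dithered by ±0.5 so the test sees the
  underlying distribution, not the rounding), two-sample
  Kolmogorov–Smirnov comparisons, and per-clonotype chemistry (GRAVY,
  net charge at pH 7, aromatic fraction, aliphatic index).
- **Clonal similarity networks** — nodes are (sample, CDR3) pairs, edges
  connect equal-length sequences at Hamming distance ≤ 2; connected
  components spanning ≥ 4 distinct patients are reported with consensus
  sequences and position-frequency matrices.
- **Synthetic cohorts** — a first-class generator that emulates the study
  design (group sizes 5/5/6/6/4, endemic clonotype richness about one
  tenth of non-endemic, Dirichlet clonal-expansion skew, directional IGHV
  usage shifts in active disease, patient long-CDR3 tails, and planted
  near-identical CDR3 clusters) so every stage is testable end to end.

## Worked example

```python
import ighrep as ir

cohort = ir.simulate_cohort(ir.SyntheticConfig(seed=2).scaled_richness(15 / 1224))

dm, tree = ir.beta_diversity(cohort, "IGHG", min_frequency=0.001)
grouping = {sid: ("endemic" if not sid.startswith("NE") else "nonendemic")
            for sid in dm.labels}
res = ir.permanova(dm, grouping, n_permutations=99999, seed=2)
print(res.pseudo_f, res.p_value, res.method)
```

prints

```
1.2496730890110477 0.00013377926421404682 exhaustive
```

the pseudo-F for the endemic vs non-endemic contrast with p = 2/14,950 —
only one other labeling of the 26 samples matches the observed region
split: the two regions' repertoires are phylogenetically distinct, as
planted by the generator. Running `python examples/05_networks.py`
recovers the planted CDR3 family:

```
network: 8045 nodes, 16 edges
components spanning >= 4 patients: 1
  6 nodes, samples ['NT1', 'NT2', 'NT3', 'NT4', 'TR1'], patient_exclusive, consensus CARDYGGNSYAWFDW
```

The `examples/` directory holds one short script per capability; the
`ighrep` command-line tool (`ighrep simulate`, `ighrep run`, per-stage
subcommands) wraps the same functions for shell use.

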