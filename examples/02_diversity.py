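"""Alpha and beta diversity over CDR3 sequences.

Computes Shannon entropy and Faith's phylogenetic diversity per sample on
a pooled neighbor-joining tree, then weighted-UniFrac beta diversity with
PERMANOVA on the endemic vs non-endemic contrast.
"""

import ighrep as ir

cohort = ir.simulate_cohort(ir.SyntheticConfig(seed=2).scaled_richness(15 / 1224))

alpha = ir.alpha_diversity(cohort, "IGHM")
summary = alpha.pivot_table(index="group", columns="metric", values="value")
print("mean alpha diversity per group (IGHM):")
print(summary.round(2).to_string())
print("\nHigher Shannon (nats) and Faith's PD (branch-length units) for the "
      "non-endemic controls reflect their ~10x larger clonotype richness.")

dm, tree = ir.beta_diversity(cohort, "IGHG", min_frequency=0.001)
grouping = {sid: ("endemic" if not sid.startswith("NE") else "nonendemic")
            for sid in dm.labels}
res = ir.permanova(dm, grouping, n_permutations=99999, seed=2)
print(f"\nPERMANOVA (IGHG, frequency > 0.001): pseudo-F = {res.pseudo_f:.2f}, "
      f"p = {res.p_value:.2e} ({res.method}, {res.n_permutations} labelings)")

coords = ir.pcoa(dm, n_axes=2)
print(f"PCoA axis 1 explains {coords.proportion_explained[0]:.0%} of the "
      "positive-eigenvalue variance (UniFrac distances are high-dimensional "
      "here; the PERMANOVA above is the formal test of the region contrast).")
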