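"""Call deficiency-responsive genes with the NB Wald test.

The S0_R/CK_R contrast compares sulfate-deprived roots against control.
A gene is a DEG at |fold change| >= 2, p < 0.05 and BH FDR < 0.01.
"""

from splitrootseq import ContrastSpec, SimulationDesign, call_degs, run_contrast, simulate_counts

design = SimulationDesign(n_genes=4000, effect_log2fc=3.0, dispersion=0.1,
                          base_mean_log_range=(2.0, 3.5), seed=7, shoot_fraction=0.0)
cm, truth = simulate_counts(design)

spec = ContrastSpec.parse("S0_R/CK_R")
table = run_contrast(cm, spec)
up, down = call_degs(table, spec)

print(f"contrast {spec.name}: {len(up)} up, {len(down)} down "
      f"of {int(table['detected'].sum())} detected genes")
planted_up = set(truth.loc[truth["direction"] == "up", "gene_id"])
print(f"planted up-regulated genes recovered: "
      f"{len(planted_up & up.genes)}/{len(planted_up)}")

print("\nstrongest up-calls (log2fc ~ 3 = the planted effect):")
print(table[table["status"] == "up"].nsmallest(3, "p")[
    ["mean_a", "mean_b", "log2fc", "p", "fdr"]].round(4).to_string())
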