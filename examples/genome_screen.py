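"""Screen a simulated 100-gene study for joint SNV-set / expression association.

Simulates 142 samples with 3 causal genes among 100, adjusts the phenotype
for the age- and sex-like covariates, runs all three test modes per gene,
applies Benjamini-Hochberg FDR per mode, and prints the top of the results
table (the screen's output columns mirror a per-gene association report:
region coordinates, per-mode p- and q-values, and the SNV count).
"""

import numpy as np

from wustat import PhenotypeTable, qq_table, screen
from wustat.engine import records_to_frame
from wustat.simulate import SimConfig, simulate_study

cfg = SimConfig(n=142, n_genes=100, n_causal=3, snvs_per_gene=(115, 411),
                beta_g=0.3, beta_t=0.3, gamma=0.6, seed=11)
ds = simulate_study(cfg)

pt = PhenotypeTable(
    sample_ids=ds.sample_ids,
    phenotype=ds.phenotype["quant"].to_numpy(float),
    covariates=ds.phenotype[["age", "sex"]],
    name="quant",
)
records = screen(ds.regions, ds.genotypes, ds.expression, pt)
df = records_to_frame(records).sort_values("P_GT")

print("top 5 of 100 genes by joint-test p-value (3 causal genes planted):")
cols = ["Chr", "BP1", "BP2", "Gene", "P_GT", "P_G", "P_T", "Q_GT", "N_SNV"]
print(df[cols].head(5).to_string(index=False, float_format=lambda x: f"{x:.3g}"))

causal = set(ds.truth.loc[ds.truth.causal, "gene_id"])
top3 = set(df.head(3)["Gene"])
print(f"\nplanted causal genes: {sorted(causal)}")
print(f"top 3 by P_GT:        {sorted(top3)}  (recovered: {len(causal & top3)}/3)")

qq = qq_table(df["P_GT"].to_numpy())
print("\nQQ tail (largest observed -log10 p vs expected under the null):")
print(qq.tail(3).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("observed far above expected at the tail = the planted signals;")
print("the bulk tracking the diagonal = calibrated null behaviour.")
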