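"""Check type-I error calibration of the asymptotic null on all-null data.

Simulates 300 null genes (no genetic or expression effect on the phenotype)
at n = 142 with the rare-variant-heavy MAF spectrum, computes the
asymptotic p-value in each mode, and reports the empirical rejection rate
at alpha = 0.05 plus a Kolmogorov-Smirnov test of p-value uniformity.
"""

import numpy as np
from scipy.stats import kstest

from wustat import ExpressionVector, GenotypeMatrix, rank_phenotype, run_gene_test
from wustat.simulate import SimConfig, simulate_gene

rng = np.random.default_rng(3)
cfg = SimConfig(n=142, snvs_per_gene=(115, 411), seed=3)
n_rep = 300

pvals = {m: [] for m in ("G", "T", "GT")}
for _ in range(n_rep):
    sim = simulate_gene(cfg, causal=False, rng=rng)
    k = sim.dosages.shape[1]
    gm = GenotypeMatrix(sim.dosages, [f"v{j}" for j in range(k)],
                        np.arange(1, k + 1), "1")
    ev = ExpressionVector(t=sim.expression, probe_id="p")
    ranks = rank_phenotype(rng.normal(size=cfg.n))  # null phenotype
    for mode in pvals:
        _, pres = run_gene_test(gm, ev, ranks, mode)
        pvals[mode].append(pres.p)

print(f"{n_rep} all-null genes at n = {cfg.n}:")
for mode, ps in pvals.items():
    ps = np.array(ps)
    rate = np.mean(ps < 0.05)
    ks_p = kstest(ps, "uniform").pvalue
    print(f"  mode {mode:>2}: rejection at alpha=.05 = {rate:.3f}   KS uniformity p = {ks_p:.3f}")
print("rates near 0.05 and non-small KS p-values indicate the chi-square-")
print("mixture null is calibrated; a permutation oracle (see the single-gene")
print("example) certifies it on any specific dataset.")
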