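"""Synthetic genotype / expression / phenotype studies with known truth.

The generator emulates the statistical structure the weighted U test
assumes: a modest unrelated sample (default n = 142), gene regions of
hundreds of mostly rare SNVs (default per-gene SNV counts uniform on
115..411, 80% of SNVs with MAF in (0.001, 0.01)), expression partially
driven by the region's burden score (eQTL strength ``gamma``), and a
phenotype receiving genetic (``beta_g``) and expression (``beta_t``)
effects plus covariates (an age-like and a sex-like variable) and unit
Gaussian noise.  Effects act through the standardized burden score so that
power calibrations align with the statistic under test.  A binary phenotype
is the indicator of the quantitative one exceeding its empirical
(1 - prevalence) quantile.

It deliberately does not model linkage disequilibrium, family structure, or
population stratification (except for a dedicated two-subpopulation helper
used to exercise genotype PCA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .regions import GeneRegion

__all__ = ["SimConfig", "SimDataset", "simulate_gene", "simulate_study",
           "two_population_dosages", "write_vcf"]


@dataclass
class SimConfig:
    n: int = 142
    n_genes: int = 100
    n_causal: int = 5
    snvs_per_gene: tuple[int, int] = (115, 411)
    rare_fraction: float = 0.8
    rare_maf: tuple[float, float] = (0.001, 0.01)
    common_maf: tuple[float, float] = (0.01, 0.5)
    gamma: float = 0.5        # eQTL effect of standardized burden on expression
    beta_g: float = 0.15      # direct genetic effect on the phenotype
    beta_t: float = 0.15      # expression effect on the phenotype
    age_effect: float = 0.05  # per year, phenotype units
    sex_effect: float = 0.5
    prevalence: float = 0.3   # binary phenotype case fraction
    missing_rate: float = 0.0
    flank: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("need n >= 10")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GeneSim:
    dosages: np.ndarray        # n x K minor-allele counts
    maf: np.ndarray            # generating MAFs
    expression: np.ndarray     # per-sample probe value
    burden_std: np.ndarray     # standardized realized burden score
    phenotype_part: np.ndarray # this gene's contribution to the phenotype
    causal: bool


@dataclass
class SimDataset:
    config: SimConfig
    sample_ids: list[str]
    regions: list[GeneRegion]
    genotypes: dict                 # gene_id -> GenotypeMatrix
    expression: pd.DataFrame        # probes x samples
    phenotype: pd.DataFrame         # sample_id, quant, binary, age, sex
    truth: pd.DataFrame             # gene_id, causal, beta_g, beta_t, gamma
    probe_map: pd.DataFrame         # gene_id, probe_id


def _draw_maf(config: SimConfig, rng: np.random.Generator) -> float:
    lo, hi = (config.rare_maf if rng.random() < config.rare_fraction
              else config.common_maf)
    return float(rng.uniform(lo, hi))


def _polymorphic_column(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    # redraw until at least one carrier is realized
    for _ in range(100_000):
        maf = _draw_maf(config, rng)
        col = rng.binomial(2, maf, size=config.n)
        if col.any():
            return col, maf
    raise RuntimeError("could not realize a polymorphic SNV")


def _standardized_burden(dosages: np.ndarray) -> np.ndarray:
    # realized-sample weighted burden, minor-allele coded, standardized
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    v = np.where(flip, 2.0 - dosages, dosages)
    p = np.where(flip, 1.0 - freq, freq)
    w = 1.0 / np.sqrt(p * (1.0 - p))
    a = (v @ w) / (2.0 * w.sum())
    c = a - a.mean()
    sd = c.std(ddof=1)
    return c / sd if sd > 0 else np.zeros_like(c)


def simulate_gene(config: SimConfig, causal: bool, rng: np.random.Generator) -> GeneSim:
    """One gene: binomial dosages, burden-driven expression, phenotype share.

    Dosages are Binomial(2, maf_k) per SNV with maf from the configured
    rare-heavy mixture; columns with no realized carrier are redrawn.
    Expression is gamma * standardized burden + unit Gaussian noise; the
    phenotype contribution is beta_g * standardized burden + beta_t *
    expression.  Null genes (``causal=False``) contribute nothing.
    """
    k = int(rng.integers(config.snvs_per_gene[0], config.snvs_per_gene[1] + 1))
    cols, mafs = zip(*(_polymorphic_column(config, rng) for _ in range(k)))
    dosages = np.column_stack(cols).astype(float)
    burden = _standardized_burden(dosages)
    noise = rng.normal(size=config.n)
    if causal:
        expr = config.gamma * burden + noise
        part = config.beta_g * burden + config.beta_t * expr
    else:
        expr = noise
        part = np.zeros(config.n)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan
    return GeneSim(dosages=dosages, maf=np.array(mafs), expression=expr,
                   burden_std=burden, phenotype_part=part, causal=causal)


def _gene_layout(i: int, k: int, rng: np.random.Generator) -> tuple[str, int, int, np.ndarray]:
    """Deterministic non-overlapping layout on odd-numbered chromosomes."""
    chrom = str(2 * (i // 50) + 1)
    slot = i % 50
    start = 100_000 + slot * 200_000
    length = int(rng.integers(10_000, 50_000))
    end = start + length
    positions = np.sort(rng.choice(np.arange(start, end + 1), size=k, replace=False))
    return chrom, start, end, positions


def simulate_study(config: SimConfig, out_dir: str | Path | None = None) -> SimDataset:
    """A full synthetic study; optionally written in the formats the readers consume.

    The first ``n_causal`` genes (by index, recorded in the truth table)
    carry the configured effects.  With ``out_dir`` set, writes
    genotypes.vcf, expression.tsv, phenotype_quant.csv, phenotype_binary.csv,
    annotation.bed and probe_map.tsv.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    sample_ids = [f"S{i:04d}" for i in range(n)]
    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)

    causal_flags = np.zeros(config.n_genes, dtype=bool)
    causal_flags[: config.n_causal] = True

    regions, genotypes, expr_rows, probe_rows, truth_rows = [], {}, {}, [], []
    y = config.age_effect * (age - 50.0) + config.sex_effect * sex + rng.normal(size=n)
    for i in range(config.n_genes):
        gene_id = f"GENE{i:04d}"
        probe_id = f"PROBE{i:04d}"
        sim = simulate_gene(config, bool(causal_flags[i]), rng)
        chrom, start, end, positions = _gene_layout(i, sim.dosages.shape[1], rng)
        snv_ids = [f"{gene_id}_snv{j}" for j in range(sim.dosages.shape[1])]
        genotypes[gene_id] = GenotypeMatrix(
            dosages=sim.dosages, snv_ids=snv_ids, positions=positions,
            chrom=chrom, sample_ids=sample_ids,
        )
        regions.append(GeneRegion(chrom=chrom, start=start, end=end,
                                  gene_id=gene_id, flank=config.flank,
                                  probe_ids=[probe_id]))
        expr_rows[probe_id] = sim.expression
        probe_rows.append({"gene_id": gene_id, "probe_id": probe_id})
        truth_rows.append({
            "gene_id": gene_id, "causal": sim.causal,
            "beta_g": config.beta_g if sim.causal else 0.0,
            "beta_t": config.beta_t if sim.causal else 0.0,
            "gamma": config.gamma if sim.causal else 0.0,
        })
        y = y + sim.phenotype_part

    cutoff = np.quantile(y, 1.0 - config.prevalence)
    binary = (y > cutoff).astype(int)
    expression = pd.DataFrame(expr_rows, index=sample_ids).T
    expression.index.name = "probe_id"
    phenotype = pd.DataFrame({
        "sample_id": sample_ids, "quant": y, "binary": binary,
        "age": age, "sex": sex,
    })
    ds = SimDataset(
        config=config, sample_ids=sample_ids, regions=regions,
        genotypes=genotypes, expression=expression, phenotype=phenotype,
        truth=pd.DataFrame(truth_rows), probe_map=pd.DataFrame(probe_rows),
    )
    if out_dir is not None:
        _write_study(ds, Path(out_dir))
    return ds


def _write_study(ds: SimDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(out / "genotypes.vcf", ds)
    ds.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
    for name, col in (("quant", "quant"), ("binary", "binary")):
        df = pd.DataFrame({
            "sample_id": ds.phenotype["sample_id"],
            "phenotype": ds.phenotype[col],
            "age": ds.phenotype["age"].round(4),
            "sex": ds.phenotype["sex"].astype(int),
        })
        df.to_csv(out / f"phenotype_{name}.csv", index=False)
    bed = pd.DataFrame({
        "chrom": [r.chrom for r in ds.regions],
        "start": [r.start - 1 for r in ds.regions],  # BED half-open
        "end": [r.end for r in ds.regions],
        "name": [r.gene_id for r in ds.regions],
    })
    bed.to_csv(out / "annotation.bed", sep="\t", header=False, index=False)
    ds.probe_map.to_csv(out / "probe_map.tsv", sep="\t", index=False)
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(path: str | Path, ds: SimDataset) -> None:
    """Minimal VCF 4.2 with GT-only genotypes, sorted by (chrom, pos)."""
    chrom_order = sorted({r.chrom for r in ds.regions}, key=lambda c: (len(c), c))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        for chrom in chrom_order:
            rows = []
            for region in ds.regions:
                if region.chrom != chrom:
                    continue
                gm = ds.genotypes[region.gene_id]
                for j, (pos, sid) in enumerate(zip(gm.positions, gm.snv_ids)):
                    rows.append((int(pos), sid, gm.dosages[:, j]))
            rows.sort(key=lambda r: r[0])
            for pos, sid, dosage in rows:
                gts = "\t".join("./." if np.isnan(d) else _GT[d] for d in dosage)
                fh.write(f"{chrom}\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def toy_filter_study(out_dir: str | Path) -> dict:
    """Deterministic 5-gene, 8-sample toy exercising every screening filter.

    Gene layout (chrom 1, flank 5 kb assumed downstream):

    - GENE_A [10000, 20000]: SNVs at 4999 (outside), 5000 and 25000 (window
      boundaries, included), 12000 (inside), 25001 (outside) -> retained, 3 SNVs
    - GENE_B [40000, 50000]: polymorphic SNV at 45000 but no probe -> dropped
    - GENE_C [70000, 80000]: no SNV in the window -> dropped
    - GENE_D [100000, 110000]: only monomorphic SNVs -> dropped
    - GENE_E [130000, 140000]: 2 polymorphic + 1 monomorphic SNV -> retained, 2 SNVs

    Writes genotypes.vcf, annotation.bed, probe_map.tsv, expression.tsv and
    phenotype_quant.csv; returns the expected retention accounting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = [f"S{i}" for i in range(8)]
    poly = "0/1\t0/0\t0/0\t0/1\t1/1\t0/0\t0/0\t0/1"
    poly2 = "0/0\t0/1\t0/0\t0/0\t0/1\t0/0\t0/1\t0/0"
    mono = "0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0"
    rows = [
        (4999, "a_out_left", poly), (5000, "a_bound_left", poly),
        (12000, "a_inside", poly2), (25000, "a_bound_right", poly),
        (25001, "a_out_right", poly2),
        (45000, "b_poly", poly),
        (100500, "d_mono1", mono), (101500, "d_mono2", mono),
        (130500, "e_poly1", poly), (131500, "e_mono", mono), (132500, "e_poly2", poly2),
    ]
    with open(out / "genotypes.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, sid, gts in rows:
            fh.write(f"1\t{pos}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    genes = [("GENE_A", 10_000, 20_000), ("GENE_B", 40_000, 50_000),
             ("GENE_C", 70_000, 80_000), ("GENE_D", 100_000, 110_000),
             ("GENE_E", 130_000, 140_000)]
    with open(out / "annotation.bed", "w") as fh:
        for gid, start, end in genes:
            fh.write(f"1\t{start - 1}\t{end}\t{gid}\n")
    probed = [g for g, _, _ in genes if g != "GENE_B"]
    pd.DataFrame({"gene_id": probed,
                  "probe_id": [f"PR_{g}" for g in probed]}
                 ).to_csv(out / "probe_map.tsv", sep="\t", index=False)
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.normal(size=(len(probed), 8)).round(4),
                        index=[f"PR_{g}" for g in probed], columns=samples)
    expr.index.name = "probe_id"
    expr.to_csv(out / "expression.tsv", sep="\t")
    pd.DataFrame({"sample_id": samples,
                  "phenotype": rng.normal(size=8).round(4)}
                 ).to_csv(out / "phenotype_quant.csv", index=False)
    return {
        "n_input": 5,
        "retained": {"GENE_A": 3, "GENE_E": 2},
        "dropped_no_probe": ["GENE_B"],
        "dropped_no_snv": ["GENE_C"],
        "dropped_all_monomorphic": ["GENE_D"],
    }


def two_population_dosages(
    n_per_pop: int, k: int, fst_shift: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two subpopulations with divergent allele frequencies, for PCA checks.

    Returns (dosages, population labels).  Each SNV gets a base frequency
    uniform on (0.1, 0.4); the second population's frequency is shifted by
    ``fst_shift`` (clipped to (0.01, 0.99)).
    """
    base = rng.uniform(0.1, 0.4, size=k)
    shifted = np.clip(base + fst_shift * rng.choice((-1.0, 1.0), size=k), 0.01, 0.99)
    g1 = rng.binomial(2, base, size=(n_per_pop, k))
    g2 = rng.binomial(2, shifted, size=(n_per_pop, k))
    labels = np.repeat([0, 1], n_per_pop)
    return np.vstack([g1, g2]).astype(float), labels
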