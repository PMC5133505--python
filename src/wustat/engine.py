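"""Per-gene tests in the three modes, covariate adjustment, FDR, and the screen.

The phenotype (quantitative blood pressure or binary hypertension status) is
residualized on covariates and genotype principal components by ordinary
least squares, the residuals are rank-transformed, and each gene region is
tested in up to three modes: G (genotype similarity only), T (expression
similarity only) and GT (the joint test, the product of both similarities).
Benjamini-Hochberg q-values are computed per mode across the screen.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from . import core, nulldist
from .core import (
    DegeneratePhenotypeError,
    ExpressionVector,
    GenotypeMatrix,
    KernelConfig,
    RankedPhenotype,
)
from .regions import GeneRegion

logger = logging.getLogger("wustat")

MODES = ("G", "T", "GT")

__all__ = [
    "PhenotypeTable",
    "GeneTestRecord",
    "SampleMisalignmentError",
    "residualize_and_rank",
    "genotype_pca",
    "run_gene_test",
    "fdr_adjust",
    "screen",
    "qq_table",
]


class SampleMisalignmentError(ValueError):
    """Raised when inputs disagree on sample identity or order."""


@dataclass
class PhenotypeTable:
    """Phenotype with covariates and optional principal components.

    Covariates (age, sex, medication use, smoking status, ...) and PCs are
    adjusted for by OLS residualization before ranking; binary phenotypes are
    residualized the same way (linear probability residuals) and ranked like
    quantitative ones.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    covariates: pd.DataFrame | None = None
    pcs: np.ndarray | None = None
    name: str = "phenotype"

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.sample_ids)
        if self.phenotype.size != n:
            raise ValueError("phenotype length does not match sample_ids")
        if np.isnan(self.phenotype).any():
            raise ValueError("missing phenotype values must be filtered upstream")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValueError("covariate rows do not match sample_ids")
        if self.pcs is not None:
            self.pcs = np.asarray(self.pcs, dtype=float)
            if self.pcs.shape[0] != n:
                raise ValueError("PC rows do not match sample_ids")


@dataclass
class GeneTestRecord:
    """One output row of the screen, one (region, probe, phenotype) triple."""

    chrom: str
    bp1: int
    bp2: int
    gene_id: str
    probe_id: str
    phenotype: str
    n_snv: int
    p: dict = field(default_factory=dict)   # mode -> p-value (NaN if failed)
    q: dict = field(default_factory=dict)   # mode -> BH-adjusted value
    u: dict = field(default_factory=dict)   # mode -> statistic
    note: str = ""


def residualize_and_rank(pt: PhenotypeTable) -> RankedPhenotype:
    """OLS-residualize the phenotype on intercept + covariates + PCs, then rank.

    With no covariates and no PCs this reduces to ranking the raw phenotype.
    A rank-deficient design (collinear covariates) is an error.
    """
    blocks = [np.ones((len(pt.sample_ids), 1))]
    if pt.covariates is not None and pt.covariates.shape[1] > 0:
        blocks.append(np.asarray(pt.covariates, dtype=float))
    if pt.pcs is not None and pt.pcs.shape[1] > 0:
        blocks.append(pt.pcs)
    design = np.hstack(blocks)
    if design.shape[1] > 1:
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("collinear covariates: design matrix is rank deficient")
        resid = sm.OLS(pt.phenotype, design).fit().resid
    else:
        resid = pt.phenotype
    rp = core.rank_phenotype(resid)
    rp.sample_ids = list(pt.sample_ids)
    return rp


def genotype_pca(dosages: np.ndarray, k: int) -> np.ndarray:
    """Sample scores of the top-k PCs of the standardized dosage matrix.

    Columns are centered and scaled by sqrt(p(1-p)) with p the sample
    allele frequency, then decomposed by SVD.  Deterministic up to sign;
    signs are fixed by making each component's largest-magnitude loading
    positive.  ``k = 0`` returns an empty (n, 0) matrix.
    """
    x = np.asarray(dosages, dtype=float)
    n = x.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples for PCA")
    if k >= n:
        raise ValueError("k must be smaller than the sample count")
    if k == 0:
        return np.empty((n, 0))
    p_hat = x.mean(axis=0) / 2.0
    sd = np.sqrt(p_hat * (1.0 - p_hat))
    keep = sd > 0
    z = (x[:, keep] - 2.0 * p_hat[keep]) / sd[keep]
    u_mat, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(k, s.size)
    scores = u_mat[:, :k] * s[:k]
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


def _check_alignment(*id_lists: Sequence[str] | None) -> None:
    present = [list(ids) for ids in id_lists if ids is not None]
    for ids in present[1:]:
        if ids != present[0]:
            raise SampleMisalignmentError(
                "sample ids differ between inputs; align explicitly, never reorder silently"
            )


def run_gene_test(
    genotypes: GenotypeMatrix | None,
    expression: ExpressionVector | None,
    ranks: RankedPhenotype,
    mode: str,
    config: KernelConfig | None = None,
) -> tuple[core.UStatResult, nulldist.PValueResult]:
    """Test one gene region in one mode and return (U, p).

    Mode GT multiplies both similarity kernels; G fixes the expression
    similarity at 1; T fixes the genotype similarity at 1 (genotypes are
    then ignored entirely).  Sample alignment is verified by id whenever
    ids are attached; mismatches are a hard error.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = config or KernelConfig()
    n = ranks.n
    f = g = None
    if mode in ("G", "GT"):
        if genotypes is None:
            raise ValueError("mode %s needs genotypes" % mode)
        _check_alignment(genotypes.sample_ids, ranks.sample_ids)
        if genotypes.n_samples != n:
            raise SampleMisalignmentError("genotype sample count != phenotype sample count")
        recoded, freqs = core.recode_to_minor(genotypes)
        poly = freqs.maf > 0.0
        if not poly.any():
            raise nulldist.DegenerateTestError("all SNVs monomorphic in the analysis sample")
        recoded = GenotypeMatrix(
            recoded.dosages[:, poly],
            [s for s, m in zip(recoded.snv_ids, poly) if m],
            recoded.positions[poly],
            recoded.chrom,
            recoded.sample_ids,
        )
        freqs = core.AlleleFrequencySet(maf=freqs.maf[poly], flipped=freqs.flipped[poly])
        a = core.burden_scores(recoded, freqs).a
        if config.standardize_burden:
            a = core.standardize(a)
        f = core.gaussian_similarity(a, config)
    if mode in ("T", "GT"):
        if expression is None:
            raise ValueError("mode %s needs expression" % mode)
        _check_alignment(expression.sample_ids, ranks.sample_ids)
        if expression.t.size != n:
            raise SampleMisalignmentError("expression sample count != phenotype sample count")
        t = core.standardize(expression.t) if config.standardize_expression else expression.t
        g = core.gaussian_similarity(t, config)
    h = core.phenotype_kernel(ranks)
    res = core.u_statistic(f, g, h, mode=mode)
    mix = nulldist.mixture_weights(f, g, n)
    pres = nulldist.ustat_pvalue(res.u, mix, n)
    return res, pres


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValueError("p-values must be in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def screen(
    regions: Iterable[GeneRegion],
    genotype_source: Callable[[GeneRegion], GenotypeMatrix] | Mapping[str, GenotypeMatrix],
    expression: pd.DataFrame,
    pt: PhenotypeTable,
    modes: Sequence[str] = MODES,
    config: KernelConfig | None = None,
) -> list[GeneTestRecord]:
    """Run every (region, probe) pair against one phenotype in each mode.

    ``genotype_source`` maps a region to its GenotypeMatrix (a callable or a
    dict keyed by gene_id).  ``expression`` is a probes x samples DataFrame
    whose columns follow the phenotype table's sample order.  Per-region
    failures (degenerate kernels, uncallable regions) are logged and recorded
    with missing p-values; they never abort the screen.  Output order is
    deterministic: (chrom, bp1, gene_id, probe_id).
    """
    config = config or KernelConfig()
    ranks = residualize_and_rank(pt)
    if list(expression.columns) != list(pt.sample_ids):
        raise SampleMisalignmentError("expression columns must follow the phenotype sample order")
    get = genotype_source if callable(genotype_source) else lambda r: genotype_source[r.gene_id]
    ordered = sorted(regions, key=lambda r: (str(r.chrom), r.start, r.gene_id))
    records: list[GeneTestRecord] = []
    for region in ordered:
        try:
            gm = get(region)
        except Exception as exc:  # uncallable region
            logger.warning("region %s: genotype extraction failed: %s", region.gene_id, exc)
            gm = None
        for probe_id in sorted(region.probe_ids):
            rec = GeneTestRecord(
                chrom=str(region.chrom), bp1=region.start, bp2=region.end,
                gene_id=region.gene_id, probe_id=probe_id, phenotype=pt.name,
                n_snv=0 if gm is None else gm.n_snvs,
            )
            if probe_id in expression.index:
                ev = ExpressionVector(
                    t=expression.loc[probe_id].to_numpy(dtype=float),
                    probe_id=probe_id, sample_ids=list(expression.columns),
                )
            else:
                ev = None
            for mode in modes:
                try:
                    ures, pres = run_gene_test(gm, ev, ranks, mode, config)
                    rec.u[mode] = ures.u
                    rec.p[mode] = pres.p
                except SampleMisalignmentError:
                    raise
                except (nulldist.DegenerateTestError, DegeneratePhenotypeError, ValueError) as exc:
                    logger.warning("region %s probe %s mode %s: %s",
                                   region.gene_id, probe_id, mode, exc)
                    rec.u[mode] = np.nan
                    rec.p[mode] = np.nan
                    rec.note = (rec.note + f"{mode}:{exc}; ").strip()
            records.append(rec)
    for mode in modes:
        q = fdr_adjust(np.array([r.p.get(mode, np.nan) for r in records]))
        for r, qv in zip(records, q):
            r.q[mode] = float(qv) if np.isfinite(qv) else np.nan
    return records


def records_to_frame(records: list[GeneTestRecord], modes: Sequence[str] = MODES) -> pd.DataFrame:
    """Table-style results: Chr BP1 BP2 Gene Probe Phenotype P_* Q_* N_SNV."""
    rows = []
    for r in records:
        row = {
            "Chr": r.chrom, "BP1": r.bp1, "BP2": r.bp2, "Gene": r.gene_id,
            "Probe": r.probe_id, "Phenotype": r.phenotype,
        }
        for mode in modes:
            row[f"P_{mode}"] = r.p.get(mode, np.nan)
        for mode in modes:
            row[f"Q_{mode}"] = r.q.get(mode, np.nan)
        row["N_SNV"] = r.n_snv
        rows.append(row)
    return pd.DataFrame(rows)


def qq_table(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot; NaNs are dropped."""
    p = np.asarray(pvalues, dtype=float)
    p = np.sort(p[~np.isnan(p)])
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, nulldist.P_FLOOR, 1.0))
    return pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})


def config_hash(config: KernelConfig, extra: dict | None = None) -> str:
    """Short stable hash of the run configuration, embedded in output headers."""
    payload = {
        "bandwidth_denominator": config.bandwidth_denominator,
        "standardize_expression": config.standardize_expression,
        "standardize_burden": config.standardize_burden,
    }
    if extra:
        payload.update(extra)
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
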