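"""Burden scores, similarity kernels and the weighted U statistic.

A gene region is summarized per sample by a weighted burden score

    a_j = sum_k w_k v_jk / (2 sum_k w_k),   w_k = 1/sqrt(p_k (1 - p_k)),

where ``v_jk`` is the minor-allele dosage (0/1/2) of SNV ``k`` in sample ``j``
and ``p_k`` its minor allele frequency, so rare variants are up-weighted and
``a_j`` lies in [0, 1].  Samples are compared through Gaussian similarity
kernels on the burden score (``f``) and on gene expression (``g``), and
through a phenotype kernel ``h`` built from centered ranks.  The weighted U
statistic is the sum of ``f * g * h`` over ordered sample pairs; with the
unused similarity fixed at 1 the same statistic tests genotype only (G) or
expression only (T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencySet",
    "BurdenScores",
    "ExpressionVector",
    "RankedPhenotype",
    "KernelConfig",
    "UStatResult",
    "UncallableSNVError",
    "DegeneratePhenotypeError",
    "compute_maf",
    "recode_to_minor",
    "snv_weight",
    "burden_scores",
    "gaussian_similarity",
    "standardize",
    "rank_phenotype",
    "phenotype_kernel",
    "u_statistic",
]


class UncallableSNVError(ValueError):
    """Raised for an SNV column with no called genotypes."""


class DegeneratePhenotypeError(ValueError):
    """Raised when the phenotype has zero variance after ranking."""


@dataclass
class GenotypeMatrix:
    """Samples x SNVs minor-allele dosage matrix for one gene region.

    ``dosages`` is a float array with values in {0, 1, 2} and NaN for missing
    genotypes.  Positions are 1-based and strictly increasing.
    """

    dosages: np.ndarray
    snv_ids: list[str]
    positions: np.ndarray
    chrom: str
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, k = self.dosages.shape
        if k < 1:
            raise ValueError("a gene region needs at least one SNV")
        if n < 2:
            raise ValueError("need at least two samples")
        if len(self.snv_ids) != k or len(self.positions) != k:
            raise ValueError("snv_ids/positions length does not match dosages")
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if k > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snvs(self) -> int:
        return self.dosages.shape[1]


@dataclass
class AlleleFrequencySet:
    """Per-SNV minor allele frequencies with recoding flags."""

    maf: np.ndarray
    flipped: np.ndarray

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        self.flipped = np.asarray(self.flipped, dtype=bool)
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("retained SNVs must have 0 < MAF <= 0.5; "
                             "drop monomorphic SNVs upstream")


@dataclass
class BurdenScores:
    """Per-sample weighted burden scores a_j in [0, 1] and SNV weights w_k."""

    a: np.ndarray
    weights: np.ndarray


@dataclass
class ExpressionVector:
    """Per-sample expression for the probe matched to a region."""

    t: np.ndarray
    probe_id: str
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if not np.isfinite(self.t).all():
            raise ValueError(f"non-finite expression values for {self.probe_id}")


@dataclass
class RankedPhenotype:
    """Tie-averaged phenotype ranks with their mean and sample variance."""

    ranks: np.ndarray
    mean: float
    variance: float
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.ranks.size

    def standardized(self) -> np.ndarray:
        """Centered ranks scaled to unit sample variance (sum of squares n-1)."""
        return (self.ranks - self.mean) / np.sqrt(self.variance)


@dataclass
class KernelConfig:
    """Gaussian-kernel settings.

    bandwidth_denominator
        The denominator of the exponent in exp(-d^2 / denom).  ``None`` means
        2N with N the sample count, the published choice.  For burden scores
        in [0, 1] this makes the genotype similarities nearly constant; the
        test remains valid (and, to first order, equivalent to a squared-
        distance kernel) because the null distribution is computed on the
        same scale, but the denominator is exposed for sensitivity analyses.
    standardize_expression
        Scale expression to zero mean / unit variance before the kernel
        (default on: expression units are arbitrary and the shared
        denominator is scale sensitive).
    standardize_burden
        Same for the burden score (default off, as published).
    """

    bandwidth_denominator: float | None = None
    standardize_expression: bool = True
    standardize_burden: bool = False

    def __post_init__(self) -> None:
        if self.bandwidth_denominator is not None and self.bandwidth_denominator <= 0:
            raise ValueError("bandwidth_denominator must be positive")

    def denominator(self, n: int) -> float:
        return 2.0 * n if self.bandwidth_denominator is None else self.bandwidth_denominator


@dataclass
class UStatResult:
    u: float
    mode: Literal["G", "T", "GT"]
    n: int


def compute_maf(dosage_column: np.ndarray) -> tuple[float, bool]:
    """Alternate-allele frequency of one SNV, recoded to the minor allele.

    Returns ``(frequency, flipped)`` where ``flipped`` indicates the column
    refers to the reference allele (frequency > 0.5) and dosages must be
    recoded as ``2 - dosage``.  The returned frequency is always in [0, 0.5].
    """
    col = np.asarray(dosage_column, dtype=float)
    called = col[~np.isnan(col)]
    if called.size == 0:
        raise UncallableSNVError("SNV has no called genotypes")
    freq = called.sum() / (2.0 * called.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def recode_to_minor(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, AlleleFrequencySet]:
    """Recode every SNV to minor-allele dosage and return its MAF.

    Monomorphic SNVs (MAF = 0) must be removed before this is used for
    scoring; they are reported with maf 0 here so callers can filter.
    """
    n, k = gm.dosages.shape
    maf = np.empty(k)
    flipped = np.zeros(k, dtype=bool)
    dosages = gm.dosages.copy()
    for j in range(k):
        maf[j], flipped[j] = compute_maf(dosages[:, j])
        if flipped[j]:
            dosages[:, j] = 2.0 - dosages[:, j]
    recoded = GenotypeMatrix(dosages, gm.snv_ids, gm.positions, gm.chrom, gm.sample_ids)
    freqs = AlleleFrequencySet.__new__(AlleleFrequencySet)  # allow maf == 0 pre-filter
    freqs.maf = maf
    freqs.flipped = flipped
    return recoded, freqs


def snv_weight(maf):
    """Rare-variant up-weighting w = 1/sqrt(p(1-p)), strictly decreasing on (0, 0.5]."""
    p = np.asarray(maf, dtype=float)
    if np.any(p <= 0.0) or np.any(p > 0.5):
        raise ValueError("MAF must be in (0, 0.5]")
    return 1.0 / np.sqrt(p * (1.0 - p))


def burden_scores(
    genotypes: GenotypeMatrix,
    freqs: AlleleFrequencySet,
    missing: Literal["impute", "listwise"] = "impute",
) -> BurdenScores:
    """Weighted-sum burden score a_j = sum w_k v_jk / (2 sum w_k).

    Missing dosages are imputed to the SNV mean (2 * MAF) by default;
    ``missing="listwise"`` instead marks samples with any missing call as
    NaN so the caller can drop them.
    """
    v = genotypes.dosages
    if v.shape[1] != freqs.maf.size:
        raise ValueError(
            f"genotypes have {v.shape[1]} SNVs but freqs has {freqs.maf.size}"
        )
    w = snv_weight(freqs.maf)
    miss = np.isnan(v)
    if miss.any():
        if missing == "impute":
            v = np.where(miss, 2.0 * freqs.maf, v)
        elif missing == "listwise":
            pass  # NaN propagates below
        else:
            raise ValueError(f"unknown missing policy {missing!r}")
    a = (v @ w) / (2.0 * w.sum())
    return BurdenScores(a=a, weights=w)


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit sample-variance scaling; a constant vector maps to zeros."""
    x = np.asarray(x, dtype=float)
    c = x - x.mean()
    sd = c.std(ddof=1)
    if sd == 0.0:
        return np.zeros_like(c)
    return c / sd


def gaussian_similarity(values: np.ndarray, config: KernelConfig) -> np.ndarray:
    """Gaussian similarity matrix exp(-(x_i - x_j)^2 / denom).

    Symmetric with unit diagonal and entries in (0, 1], monotone decreasing
    in |x_i - x_j|.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("similarity input must be finite")
    denom = config.denominator(x.size)
    d = x[:, None] - x[None, :]
    s = np.exp(-(d * d) / denom)
    np.fill_diagonal(s, 1.0)
    return s


def rank_phenotype(values: Sequence[float] | np.ndarray) -> RankedPhenotype:
    """Tie-averaged ranks 1..n with their empirical mean and sample variance."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two samples to rank")
    ranks = rankdata(y)
    var = ranks.var(ddof=1)
    if var == 0.0:
        raise DegeneratePhenotypeError("phenotype is constant after ranking")
    return RankedPhenotype(ranks=ranks, mean=float(ranks.mean()), variance=float(var))


def phenotype_kernel(rp: RankedPhenotype) -> np.ndarray:
    """U kernel h(y_i, y_j) = (y_i - E(Y))(y_j - E(Y)) / Var(Y).

    The outer product of centered ranks scaled by the sample variance.  The
    off-diagonal sum is identically -(n-1) because centered ranks sum to
    zero and their squares sum to (n-1) Var(Y).
    """
    if rp.variance <= 0.0:
        raise DegeneratePhenotypeError("zero phenotype variance")
    c = rp.ranks - rp.mean
    return np.outer(c, c) / rp.variance


def u_statistic(
    f: np.ndarray | None,
    g: np.ndarray | None,
    h: np.ndarray,
    mode: Literal["G", "T", "GT"] | None = None,
) -> UStatResult:
    """Weighted U statistic U = sum_{i != j} f_ij g_ij h_ij.

    ``f`` (genotype similarity) and/or ``g`` (expression similarity) may be
    ``None``, meaning a constant kernel of ones.  The diagonal is excluded.
    Accumulated as a matrix contraction; a literal double loop is kept as a
    test oracle.
    """
    h = np.asarray(h, dtype=float)
    n = h.shape[0]
    if h.shape != (n, n):
        raise ValueError("h must be square")
    if mode is None:
        mode = {(True, True): "GT", (True, False): "G", (False, True): "T",
                (False, False): "GT"}[(f is not None, g is not None)]
    w = np.ones((n, n)) if f is None else np.asarray(f, dtype=float)
    if w.shape != (n, n):
        raise ValueError("f dimension mismatch")
    if g is not None:
        g = np.asarray(g, dtype=float)
        if g.shape != (n, n):
            raise ValueError("g dimension mismatch")
        w = w * g
    prod = w * h
    u = float(prod.sum() - np.trace(prod))
    return UStatResult(u=u, mode=mode, n=n)
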