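"""Readers and writers for the standard input formats, and sample alignment.

Genotypes come from VCF 4.x (biallelic SNVs; dosages are alternate-allele
counts from the GT field), expression from a probes x samples TSV, phenotype
and covariates from CSV.  All cross-source joins pass through a single
SampleAlignment; nothing reorders samples implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .core import GenotypeMatrix
from .regions import GeneRegion

logger = logging.getLogger("wustat")

__all__ = [
    "VcfGenotypes",
    "SampleAlignment",
    "read_vcf",
    "read_genotypes",
    "read_expression",
    "read_phenotypes",
    "align_samples",
    "write_results",
    "write_qq",
]


@dataclass
class VcfGenotypes:
    """In-memory dosage store for one VCF: per-chromosome sorted SNV arrays.

    Loading once and slicing per region keeps a genome screen O(1) per
    region lookup instead of re-parsing the file.
    """

    sample_ids: list[str]
    chroms: dict = field(default_factory=dict)
    # chroms[chrom] = dict(positions=int64[], snv_ids=[...], dosages=float32[n, k])
    n_multiallelic_skipped: int = 0
    n_non_snv_skipped: int = 0

    def extract(self, region: GeneRegion) -> GenotypeMatrix:
        """GenotypeMatrix of SNVs in the region's closed testing window."""
        store = self.chroms.get(str(region.chrom))
        if store is None:
            raise KeyError(f"chromosome {region.chrom} not in VCF")
        pos = store["positions"]
        lo = np.searchsorted(pos, region.test_start, side="left")
        hi = np.searchsorted(pos, region.test_end, side="right")
        if hi <= lo:
            raise ValueError(f"no SNVs in region {region.gene_id}")
        return GenotypeMatrix(
            dosages=np.asarray(store["dosages"][:, lo:hi], dtype=float),
            snv_ids=store["snv_ids"][lo:hi],
            positions=pos[lo:hi],
            chrom=str(region.chrom),
            sample_ids=self.sample_ids,
        )


def _record_dosages(rec, n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.float32)
    for i, sample in enumerate(rec.samples.values()):
        gt = sample.get("GT")
        if gt is None or any(a is None for a in gt):
            out[i] = np.nan
        else:
            out[i] = float(sum(1 for a in gt if a == 1))
    return out


def read_vcf(path: str) -> VcfGenotypes:
    """Load a whole VCF into a VcfGenotypes store.

    Multiallelic records are skipped (splitting them is a user preprocessing
    step) and counted; non-SNV records likewise.  Missing genotypes (./.)
    become NaN; phased and unphased separators are equivalent.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    n = len(samples)
    per_chrom: dict[str, dict] = {}
    n_multi = n_nonsnv = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_nonsnv += 1
            continue
        store = per_chrom.setdefault(
            str(rec.chrom), {"positions": [], "snv_ids": [], "dosages": []}
        )
        store["positions"].append(rec.pos)
        store["snv_ids"].append(rec.id or f"{rec.chrom}:{rec.pos}")
        store["dosages"].append(_record_dosages(rec, n))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    if n_nonsnv:
        logger.info("skipped %d non-SNV records", n_nonsnv)
    out = VcfGenotypes(sample_ids=samples, n_multiallelic_skipped=n_multi,
                       n_non_snv_skipped=n_nonsnv)
    for chrom, store in per_chrom.items():
        pos = np.asarray(store["positions"], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        out.chroms[chrom] = {
            "positions": pos[order],
            "snv_ids": [store["snv_ids"][i] for i in order],
            "dosages": np.column_stack([store["dosages"][i] for i in order])
            if store["dosages"] else np.empty((n, 0), dtype=np.float32),
        }
    return out


def read_genotypes(path: str, region: GeneRegion) -> GenotypeMatrix:
    """Dosage matrix for one region straight from a VCF file."""
    return read_vcf(path).extract(region)


def read_expression(path: str) -> pd.DataFrame:
    """Probes x samples expression TSV: first column probe_id, header row sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name is None or df.columns.size == 0:
        raise ValueError("expression TSV needs a probe_id column and a sample header row")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe rows: {dups}")
    for probe, row in df.iterrows():
        bad = row[pd.to_numeric(row, errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"non-numeric expression at probe {probe}, sample {bad.index[0]}")
    return df.astype(float)


def read_phenotypes(path: str, phenotype_column: str = "phenotype") -> pd.DataFrame:
    """Phenotype/covariate CSV with mandatory sample_id and phenotype columns.

    Remaining columns are covariates unless their name starts with "PC"
    (those are treated as precomputed principal components).
    """
    df = pd.read_csv(path)
    for col in ("sample_id", phenotype_column):
        if col not in df.columns:
            raise ValueError(f"phenotype table needs a {col!r} column")
    return df


def align_samples(sources: dict[str, list[str]], order_by: str = "phenotype") -> "SampleAlignment":
    """Ordered intersection of sample ids across sources.

    Order follows the ``order_by`` source (the phenotype table).  Ids missing
    from any source are dropped and logged per source; an empty intersection
    is a hard error.
    """
    if order_by not in sources:
        raise ValueError(f"no source named {order_by!r}")
    common = set(sources[order_by])
    for ids in sources.values():
        common &= set(ids)
    ordered = [s for s in sources[order_by] if s in common]
    if not ordered:
        raise ValueError("no samples shared by all sources")
    for name, ids in sources.items():
        dropped = [s for s in ids if s not in common]
        if dropped:
            logger.info("alignment: dropped %d samples only in %s: %s%s",
                        len(dropped), name, dropped[:5], "..." if len(dropped) > 5 else "")
    return SampleAlignment(
        sample_ids=ordered,
        index_maps={name: [list(ids).index(s) for s in ordered] for name, ids in sources.items()},
    )


@dataclass
class SampleAlignment:
    """Single source of truth for sample order across genotype/expression/phenotype."""

    sample_ids: list[str]
    index_maps: dict = field(default_factory=dict)

    def take(self, source: str, array: np.ndarray, axis: int = 0) -> np.ndarray:
        """Reorder an array from ``source`` into the alignment order."""
        return np.take(np.asarray(array), self.index_maps[source], axis=axis)


def _header_comment(seed, cfg_hash: str) -> str:
    from . import __version__

    return f"# wustat v{__version__} seed={seed} config={cfg_hash}\n"


def write_results(df: pd.DataFrame, path: str, seed, cfg_hash: str) -> None:
    """Results TSV with a version/seed/config header comment."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_qq(df: pd.DataFrame, path: str, seed, cfg_hash: str) -> None:
    """QQ data TSV (expected vs observed -log10 p) with the same header."""
    write_results(df, path, seed, cfg_hash)
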