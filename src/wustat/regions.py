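"""Gene +/- 5 kb testing regions: annotation parsing, probe pairing, SNV filters.

Regions are 1-based closed intervals (the VCF convention); BED input is
converted at parse time.  An SNV belongs to a region iff
start - flank <= pos <= end + flank (closed on both sides), and may belong
to several overlapping regions.  Screening filters, applied in order:
regions with no matched expression probe are discarded, SNVs with MAF = 0
in the analysis sample are dropped, and regions left with no SNV are
discarded.  A reconciliation report accounts for every input region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("wustat")

DEFAULT_FLANK = 5_000

__all__ = [
    "GeneRegion",
    "RegionSNVIndex",
    "read_annotation",
    "assign_snvs",
    "filter_monomorphic",
    "pair_regions_probes",
    "region_report",
]


@dataclass
class GeneRegion:
    """One gene region: 1-based inclusive gene bounds plus a symmetric flank."""

    chrom: str
    start: int
    end: int
    gene_id: str
    flank: int = DEFAULT_FLANK
    probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.flank < 0:
            raise ValueError("flank must be nonnegative")

    @property
    def test_start(self) -> int:
        """Left bound of the testing window, floored at 1."""
        return max(1, self.start - self.flank)

    @property
    def test_end(self) -> int:
        return self.end + self.flank


@dataclass
class RegionSNVIndex:
    """Per-region SNV identifiers surviving filters."""

    snv_ids: dict = field(default_factory=dict)   # gene_id -> list of SNV ids

    def n_snv(self, gene_id: str) -> int:
        return len(self.snv_ids.get(gene_id, ()))


def read_annotation(path: str, flank: int = DEFAULT_FLANK) -> list[GeneRegion]:
    """Read gene regions from GFF3 (gene features) or 4+-column BED.

    GFF3 is 1-based closed; BED is 0-based half-open and converted.  The
    gene identifier is the GFF3 ``ID``/``gene_id``/``Name`` attribute or the
    BED name column.  Row order does not matter: output is sorted by
    (chrom, start, gene_id).
    """
    if str(path).endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        regions = []
        for feat in db.features_of_type("gene"):
            gid = (feat.attributes.get("ID") or feat.attributes.get("gene_id")
                   or feat.attributes.get("Name") or [feat.id])[0]
            regions.append(GeneRegion(chrom=feat.seqid, start=feat.start,
                                      end=feat.end, gene_id=gid, flank=flank))
    else:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
        if bed.shape[1] < 4:
            raise ValueError("BED annotation needs at least 4 columns (chrom, start, end, name)")
        regions = [
            GeneRegion(chrom=str(row[0]), start=int(row[1]) + 1, end=int(row[2]),
                       gene_id=str(row[3]), flank=flank)
            for row in bed.itertuples(index=False)
        ]
    regions.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return regions


def assign_snvs(
    region: GeneRegion,
    positions: np.ndarray,
    snv_ids: list[str],
    chrom: str | None = None,
) -> list[str]:
    """SNV ids inside the closed testing window [start - flank, end + flank].

    ``positions`` are 1-based coordinates on the region's chromosome;
    passing a different ``chrom`` yields an empty (logged) assignment.
    """
    if chrom is not None and str(chrom) != str(region.chrom):
        logger.warning("region %s on %s got SNVs from %s; empty assignment",
                       region.gene_id, region.chrom, chrom)
        return []
    pos = np.asarray(positions, dtype=np.int64)
    mask = (pos >= region.test_start) & (pos <= region.test_end)
    return [snv_ids[i] for i in np.flatnonzero(mask)]


def filter_monomorphic(index: RegionSNVIndex, maf: dict) -> tuple[RegionSNVIndex, list[str]]:
    """Drop MAF = 0 SNVs; drop regions whose SNV list becomes empty.

    ``maf`` maps SNV id to minor allele frequency computed on the analysis
    sample.  Returns the filtered index and the list of dropped gene ids.
    """
    out = RegionSNVIndex()
    dropped_regions = []
    for gene_id, ids in index.snv_ids.items():
        kept = [s for s in ids if maf.get(s, 0.0) > 0.0]
        if kept:
            out.snv_ids[gene_id] = kept
        else:
            dropped_regions.append(gene_id)
            logger.info("region %s dropped: all SNVs monomorphic", gene_id)
    return out, dropped_regions


def pair_regions_probes(
    regions: list[GeneRegion],
    probe_map: pd.DataFrame,
) -> tuple[list[GeneRegion], list[str]]:
    """Attach expression probes; discard (and return) regions with none.

    ``probe_map`` has columns (gene_id, probe_id); duplicate rows are
    deduplicated with a warning.  An empty probe map empties the screen and
    is loudly warned about.
    """
    pm = probe_map.iloc[:, :2].copy()
    pm.columns = ["gene_id", "probe_id"]
    ndup = int(pm.duplicated().sum())
    if ndup:
        logger.warning("probe map: %d duplicate (gene, probe) rows deduplicated", ndup)
        pm = pm.drop_duplicates()
    if pm.empty:
        logger.warning("probe map is empty: every region will be discarded")
    lookup = pm.groupby("gene_id")["probe_id"].apply(list).to_dict()
    retained, dropped = [], []
    for region in regions:
        probes = lookup.get(region.gene_id, [])
        if probes:
            region.probe_ids = sorted(probes)
            retained.append(region)
        else:
            dropped.append(region.gene_id)
            logger.info("region %s dropped: no probe", region.gene_id)
    return retained, dropped


def region_report(
    n_input: int,
    dropped_no_probe: list[str],
    dropped_no_snv: list[str],
    dropped_monomorphic: list[str],
    retained: list[GeneRegion],
) -> pd.DataFrame:
    """Per-region retention status; counts reconcile with the input total."""
    rows = [
        *({"gene_id": g, "status": "dropped", "reason": "no_probe"} for g in dropped_no_probe),
        *({"gene_id": g, "status": "dropped", "reason": "no_snv"} for g in dropped_no_snv),
        *({"gene_id": g, "status": "dropped", "reason": "all_monomorphic"} for g in dropped_monomorphic),
        *({"gene_id": r.gene_id, "status": "retained", "reason": ""} for r in retained),
    ]
    report = pd.DataFrame(rows, columns=["gene_id", "status", "reason"])
    if len(report) != n_input:
        raise AssertionError(
            f"region accounting does not reconcile: {len(report)} rows for {n_input} inputs"
        )
    return report.sort_values("gene_id").reset_index(drop=True)
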