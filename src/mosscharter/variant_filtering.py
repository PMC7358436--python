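"""Quality pre-filter, the calibrated three-step SNP filter, spike-in
calibration, gene-space intersection, and the haploid/diploid comparison.

The three-step filter is:

(i)   per-record read-coverage filter: DP >= 9, AD >= 7 and the allele
      fraction AD/DP strictly above 0.77;
(ii)  cohort support filter: a site (chrom, pos, alt) must be called in at
      least three samples;
(iii) indel removal.

Thresholds live in :class:`FilterConfig`; the defaults are the values
calibrated so that sequencing-error calls on spike-in transcripts do not
pass while true variants do.  Records with absent DP/AD fail closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneModel, SampleName, VariantRecord
from .exclusivity import PresenceMatrix, build_presence

logger = logging.getLogger("mosscharter")


@dataclass
class FilterConfig:
    min_dp: int = 9
    min_ad: int = 7
    min_fc: float = 0.77  # allele fraction AD/DP, strict >
    min_samples: int = 3
    drop_indels: bool = True
    hq_gq: float = 90.0  # strict >
    hq_qual_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.min_fc <= 1:
            raise ValueError("min_fc must lie in (0, 1]")
        if self.min_ad > self.min_dp:
            raise ValueError("min_ad cannot exceed min_dp")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class FilterReport:
    """Record counts entering/leaving each filter step."""

    n_input_records: int = 0
    n_after_hq: Optional[int] = None
    n_after_coverage: int = 0
    n_sites_after_coverage: int = 0
    n_sites_after_support: int = 0
    n_sites_after_indel: int = 0
    per_sample_survivors: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input_records", self.n_input_records)]
        if self.n_after_hq is not None:
            rows.append(("records_after_hq", self.n_after_hq))
        rows += [
            ("records_after_coverage", self.n_after_coverage),
            ("sites_after_coverage", self.n_sites_after_coverage),
            ("sites_after_support", self.n_sites_after_support),
            ("sites_after_indel", self.n_sites_after_indel),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


@dataclass
class PloidyComparison:
    n1_count: int
    n2_count: int
    ratio_pct: Optional[float]
    het_fraction: Optional[float]


def hq_prefilter(
    records: Sequence[VariantRecord], cfg: FilterConfig
) -> list[VariantRecord]:
    """Per-sample quality pre-filter: GQ strictly above ``hq_gq`` and QUAL at
    or above the sample's own ``hq_qual_percentile``-th QUAL percentile."""
    if not records:
        return []
    quals = np.array(
        [r.qual if r.qual is not None else -np.inf for r in records]
    )
    finite = quals[np.isfinite(quals)]
    if finite.size == 0:
        return []
    cutoff = np.percentile(finite, cfg.hq_qual_percentile)  # linear interp
    return [
        r
        for r, q in zip(records, quals)
        if r.gq is not None and r.gq > cfg.hq_gq and q >= cutoff
    ]


def coverage_filter(record: VariantRecord, cfg: FilterConfig) -> bool:
    """Read-coverage filter: DP >= min_dp, AD >= min_ad, AD/DP > min_fc."""
    if record.dp is None or record.ad_alt is None:
        logger.warning(
            "record %s:%d has absent DP/AD; failing closed",
            record.chrom, record.pos,
        )
        return False
    if record.dp < cfg.min_dp or record.ad_alt < cfg.min_ad:
        return False
    return record.ad_alt / record.dp > cfg.min_fc


def cohort_filter(
    samples: Sequence[tuple[SampleName, Sequence[VariantRecord]]],
    cfg: Optional[FilterConfig] = None,
    apply_hq: bool = False,
) -> tuple[
    list[tuple[SampleName, list[VariantRecord]]], PresenceMatrix, FilterReport
]:
    """Run the three-step filter across a cohort.

    Returns the surviving per-sample records, the presence matrix over the
    surviving sites, and a step-by-step report.
    """
    if not samples:
        raise ValueError("cohort_filter needs at least one sample")
    cfg = cfg or FilterConfig()
    report = FilterReport(
        n_input_records=sum(len(r) for _, r in samples)
    )
    if apply_hq:
        samples = [(n, hq_prefilter(list(r), cfg)) for n, r in samples]
        report.n_after_hq = sum(len(r) for _, r in samples)
    # step (i): per-record coverage
    covered = [
        (n, [r for r in recs if coverage_filter(r, cfg)]) for n, recs in samples
    ]
    report.n_after_coverage = sum(len(r) for _, r in covered)
    matrix = build_presence(covered)
    report.n_sites_after_coverage = len(matrix.sites)
    # step (ii): site support across the whole cohort
    matrix = matrix.subset_sites(matrix.support() >= cfg.min_samples)
    report.n_sites_after_support = len(matrix.sites)
    # step (iii): indel removal
    if cfg.drop_indels:
        matrix = matrix.drop_indels()
    report.n_sites_after_indel = len(matrix.sites)
    keep = {s.key for s in matrix.sites}
    surviving = [
        (n, [r for r in recs if (r.chrom, r.pos, r.alt) in keep])
        for n, recs in covered
    ]
    report.per_sample_survivors = {
        str(n): len(recs) for n, recs in surviving
    }
    return surviving, matrix, report


def spikein_calibration(
    samples: Sequence[tuple[SampleName, Sequence[VariantRecord]]],
    spikein_contigs: Sequence[str],
    dp_grid: Sequence[int],
    ad_grid: Sequence[int],
    fc_grid: Sequence[float],
) -> pd.DataFrame:
    """False-positive counts on spike-in contigs per threshold triple.

    Spike-in transcripts carry no true variants, so every call on them is a
    sequencing/computation error; the table shows how many such calls pass
    the coverage filter at each (min_dp, min_ad, min_fc) combination.
    """
    if not (len(dp_grid) and len(ad_grid) and len(fc_grid)):
        raise ValueError("threshold grids must be non-empty")
    spike = set(spikein_contigs)
    spike_records = [
        r for _, recs in samples for r in recs if r.chrom in spike
    ]
    rows = []
    for dp in dp_grid:
        for ad in ad_grid:
            for fc in fc_grid:
                n_pass = sum(
                    1
                    for r in spike_records
                    if r.dp is not None
                    and r.ad_alt is not None
                    and r.dp >= dp
                    and r.ad_alt >= ad
                    and r.ad_alt / r.dp > fc
                )
                rows.append(
                    {
                        "min_dp": dp,
                        "min_ad": ad,
                        "min_fc": fc,
                        "n_spikein_records": len(spike_records),
                        "n_pass": n_pass,
                    }
                )
    return pd.DataFrame(rows)


def genespace_intersect(
    records: Sequence[VariantRecord], genes: Sequence[GeneModel]
) -> list[VariantRecord]:
    """Keep records whose position lies within at least one gene span.

    Each record is emitted at most once regardless of how many genes overlap
    it (transcriptome comparability filter for gDNA-derived calls).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append((g.start, g.end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, iv in spans.items():
        iv.sort()
        starts_ends[chrom] = (
            np.array([s for s, _ in iv]),
            np.array([e for _, e in iv]),
        )
    out = []
    for r in records:
        if r.chrom not in starts_ends:
            continue
        starts, ends = starts_ends[r.chrom]
        if bool(np.any((starts <= r.pos) & (r.pos <= ends))):
            out.append(r)
    return out


def ploidy_compare(
    n1_records: Sequence[VariantRecord],
    n2_records: Sequence[VariantRecord],
) -> PloidyComparison:
    """Compare haploid vs diploid call sets of the same sample by call count.

    ``ratio_pct`` is 100 * |n1| / |n2|; ``het_fraction`` is the fraction of
    0/1 genotype codes among the diploid calls.  Both are ``None`` when the
    diploid set is empty (undefined, flagged by the caller's log).
    """
    n1, n2 = len(n1_records), len(n2_records)
    if n2 == 0:
        logger.warning("diploid call set empty; ploidy ratio undefined")
        return PloidyComparison(n1, n2, None, None)
    het = sum(1 for r in n2_records if sorted(r.gt.split("/")) == ["0", "1"])
    return PloidyComparison(
        n1_count=n1,
        n2_count=n2,
        ratio_pct=100.0 * n1 / n2,
        het_fraction=het / n2,
    )
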