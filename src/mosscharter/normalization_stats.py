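"""Normalization and cohort statistics: SNPs per covered base pair, the
read-count regression, per-chromosome enrichment, hotspot windows, and the
observed somatic mutation rate.

"Covered base pairs" are positions whose read depth meets a floor (default
9, matching the DP floor of the coverage filter): they define the fraction
of the gene space actually observable for SNP calling in a given sample,
and hence the denominator for density normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import CoverageTrack


@dataclass
class NormalizationReport:
    sample_id: str
    snp_count: int
    covered_bp: int
    bp_per_snp: Optional[float]  # "one SNP per X bp"; None when no SNPs
    read_count: Optional[int] = None


@dataclass
class RateEstimate:
    older: str
    newer: str
    elapsed_years: float
    snp_delta: int
    covered_bp: int
    rate: float  # substitutions per bp per year


def coverage_normalize(
    snp_count: int, track: CoverageTrack, min_depth: int = 9
) -> Optional[float]:
    """Base pairs per SNP over the depth-covered genome.

    Returns ``None`` (reported as "no SNPs") when ``snp_count`` is 0; raises
    when no position meets the depth floor, since the density is then
    undefined.
    """
    if snp_count < 0:
        raise ValueError("snp_count must be >= 0")
    covered = track.covered_bp(min_depth)
    if covered == 0:
        raise ValueError(
            f"no position reaches depth {min_depth}; bp-per-SNP undefined"
        )
    if snp_count == 0:
        return None
    return covered / snp_count


def reads_regression(
    read_counts: Sequence[float], snp_counts: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of SNP count on read count across samples: (slope, intercept, R^2)."""
    x = np.asarray(read_counts, dtype=float)
    y = np.asarray(snp_counts, dtype=float)
    if x.size < 3:
        raise ValueError("reads_regression needs >= 3 samples")
    if np.var(x) == 0:
        raise ValueError("read counts have zero variance; slope undefined")
    if np.var(y) == 0:
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def chromosome_bias(
    snp_positions: Mapping[str, Sequence[int]],
    chrom_lengths: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome SNP enrichment via Fisher's exact test + BH correction.

    For each chromosome, the 2x2 table contrasts base pairs with vs without
    SNPs on that chromosome against all other chromosomes pooled.  Distinct
    SNP positions count once.  Chromosomes with q <= ``alpha`` are flagged.
    """
    for chrom in snp_positions:
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} absent from length table")
    chroms = sorted(chrom_lengths)
    snp_bp = {c: len(set(snp_positions.get(c, ()))) for c in chroms}
    total_bp = sum(chrom_lengths[c] for c in chroms)
    total_snp = sum(snp_bp.values())
    rows = []
    for c in chroms:
        a = snp_bp[c]
        b = chrom_lengths[c] - a
        cc = total_snp - a
        dd = (total_bp - chrom_lengths[c]) - cc
        _, p = stats.fisher_exact([[a, b], [cc, dd]], alternative="two-sided")
        rows.append({"chrom": c, "snp_bp": a, "chrom_bp": chrom_lengths[c],
                     "p": p})
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df["significant"] = df["q"] <= alpha
    return df


def hotspot_windows(
    snp_positions: Mapping[str, Mapping[str, Sequence[int]]],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    min_count: Optional[int] = None,
) -> tuple[dict[str, list[tuple[str, int, int, int]]],
           list[tuple[str, int, int]]]:
    """Fixed 100-kbp-window SNP hotspots per group plus the shared regions.

    ``snp_positions`` maps group -> chrom -> positions.  Chromosomes are
    tiled into non-overlapping windows [k*window+1, (k+1)*window] (1-based;
    final partial window kept).  A window is a hotspot when its SNP count
    reaches ``min_count`` (default: the 95th percentile of the group's
    non-empty window counts).  Shared regions are windows flagged in every
    group (exact window identity).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    per_group: dict[str, list[tuple[str, int, int, int]]] = {}
    flagged_keys: list[set[tuple[str, int]]] = []
    for group in sorted(snp_positions):
        counts: dict[tuple[str, int], int] = {}
        for chrom, positions in snp_positions[group].items():
            pos = np.asarray(sorted(set(positions)), dtype=np.int64)
            if pos.size == 0:
                continue
            idx = (pos - 1) // window
            for w, c in zip(*np.unique(idx, return_counts=True)):
                counts[(chrom, int(w))] = int(c)
        if not counts:
            per_group[group] = []
            flagged_keys.append(set())
            continue
        threshold = (
            min_count
            if min_count is not None
            else float(np.percentile(list(counts.values()), 95))
        )
        hits = []
        for (chrom, w), c in sorted(counts.items()):
            if c >= threshold:
                start = w * window + 1
                end = min((w + 1) * window, chrom_lengths.get(chrom, (w + 1) * window))
                hits.append((chrom, start, end, c))
        per_group[group] = hits
        flagged_keys.append({(chrom, s) for chrom, s, _, _ in hits})
    shared: list[tuple[str, int, int]] = []
    if flagged_keys and all(flagged_keys):
        common = set.intersection(*flagged_keys)
        for group_hits in per_group.values():
            for chrom, s, e, _ in group_hits:
                if (chrom, s) in common and (chrom, s, e) not in shared:
                    shared.append((chrom, s, e))
    shared.sort()
    return per_group, shared


def hotspots_to_bed(hits: Sequence[tuple[str, int, int, int]]) -> str:
    """Render hotspot windows as BED lines (0-based half-open)."""
    return "\n".join(
        f"{chrom}\t{start - 1}\t{end}\t{count}" for chrom, start, end, count in hits
    )


def mutation_rate(
    exclusive_snp_count: int,
    covered_bp: int,
    elapsed_years: float,
    older: str = "older",
    newer: str = "newer",
) -> RateEstimate:
    """Observed mutation rate: exclusive-SNP delta between two dated
    snapshots of a pedigree, per covered base pair per year."""
    if elapsed_years <= 0:
        raise ValueError("elapsed_years must be positive")
    if covered_bp <= 0:
        raise ValueError("covered_bp must be positive")
    if exclusive_snp_count < 0:
        raise ValueError("exclusive_snp_count must be >= 0")
    return RateEstimate(
        older=older,
        newer=newer,
        elapsed_years=elapsed_years,
        snp_delta=exclusive_snp_count,
        covered_bp=covered_bp,
        rate=exclusive_snp_count / (covered_bp * elapsed_years),
    )


def normalization_report(
    sample_id: str,
    snp_count: int,
    track: CoverageTrack,
    read_count: Optional[int] = None,
    min_depth: int = 9,
) -> NormalizationReport:
    return NormalizationReport(
        sample_id=sample_id,
        snp_count=snp_count,
        covered_bp=track.covered_bp(min_depth),
        bp_per_snp=coverage_normalize(snp_count, track, min_depth),
        read_count=read_count,
    )
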