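"""Variant-effect classification against gene models and the Ka/Ks
selection screen.

Effects are classified per (site, gene) pair: a SNP overlapping several
genes yields one call per gene.  Coding changes are translated with the
standard nuclear codon table on the coding strand; splice-region means the
first or last two bases of an intron.  The Ka/Ks screen regresses
non-synonymous counts on synonymous counts across samples and classifies
each sample against the 99% prediction band of that line: below the band
suggests purifying (negative) selection, above it positive (Darwinian)
selection, inside it neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Seq import Seq

from .io_core import GeneModel, VariantRecord

CATEGORIES = (
    "upstream",
    "downstream",
    "intergenic",
    "intron",
    "splice_region",
    "utr",
    "synonymous",
    "non_synonymous",
    "start_change",
    "stop_change",
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class EffectCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    category: str


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic CDS positions in transcription order."""
    pos: list[int] = []
    for s, e in gene.cds:
        pos.extend(range(s, e + 1))
    if gene.strand == "-":
        pos.reverse()
    return pos


def cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Coding-strand CDS sequence assembled from the genome."""
    chrom_seq = genome[gene.chrom]
    seq = "".join(chrom_seq[s - 1 : e] for s, e in gene.cds)
    return _revcomp(seq) if gene.strand == "-" else seq


def _classify_coding(
    record: VariantRecord, gene: GeneModel, genome: Mapping[str, str]
) -> str:
    positions = _cds_positions(gene)
    idx = positions.index(record.pos)  # offset within the coding sequence
    cds = cds_sequence(gene, genome)
    base = record.alt if gene.strand == "+" else record.alt.translate(_COMP)
    codon_i = idx // 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    alt_codon = list(ref_codon)
    alt_codon[idx % 3] = base
    alt_codon = "".join(alt_codon)
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0 and ref_codon != alt_codon:
        return "start_change"
    if ref_aa != alt_aa and ("*" in (ref_aa, alt_aa)):
        return "stop_change"
    return "synonymous" if ref_aa == alt_aa else "non_synonymous"


def classify_effect(
    record: VariantRecord,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    flank: int = 1000,
) -> list[EffectCall]:
    """Classify one SNP against every gene it touches.

    Returns one call per overlapped gene; when the SNP lies outside every
    gene span, a single call is emitted (upstream/downstream of the nearest
    flanking gene within ``flank`` bp, else intergenic).
    """
    if record.is_indel:
        raise ValueError("effect classification handles SNPs only")
    genome_base = genome[record.chrom][record.pos - 1]
    if genome_base != record.ref:
        raise ValueError(
            f"{record.chrom}:{record.pos} REF {record.ref!r} does not match "
            f"the genome base {genome_base!r} (corrupt input)"
        )
    calls: list[EffectCall] = []
    pos = record.pos
    for gene in genes:
        if gene.chrom != record.chrom or not gene.contains(pos):
            continue
        in_cds = any(s <= pos <= e for s, e in gene.cds)
        if in_cds:
            category = _classify_coding(record, gene, genome)
        else:
            in_exon = any(s <= pos <= e for s, e in gene.exons)
            if in_exon:
                category = "utr"
            else:
                category = "intron"
                for s, e in gene.introns():
                    if s <= pos <= e and (pos - s < 2 or e - pos < 2):
                        category = "splice_region"  # first/last 2 intron bp
                        break
        calls.append(
            EffectCall(record.chrom, pos, record.ref, record.alt,
                       gene.gene_id, category)
        )
    if calls:
        return calls
    # not inside any gene span: nearest gene within the flank window decides
    best: Optional[tuple[int, GeneModel]] = None
    for gene in genes:
        if gene.chrom != record.chrom:
            continue
        if gene.start - flank <= pos < gene.start:
            dist = gene.start - pos
        elif gene.end < pos <= gene.end + flank:
            dist = pos - gene.end
        else:
            continue
        if best is None or dist < best[0]:
            best = (dist, gene)
    if best is None:
        return [EffectCall(record.chrom, pos, record.ref, record.alt, None,
                           "intergenic")]
    gene = best[1]
    before_start = pos < gene.start
    if gene.strand == "+":
        category = "upstream" if before_start else "downstream"
    else:
        category = "downstream" if before_start else "upstream"
    return [EffectCall(record.chrom, pos, record.ref, record.alt,
                       gene.gene_id, category)]


def effect_summary(
    calls_per_sample: Mapping[str, Sequence[EffectCall]]
) -> pd.DataFrame:
    """Per-sample category count table; row sums conserve call counts."""
    rows = {}
    for sample, calls in calls_per_sample.items():
        counts = dict.fromkeys(CATEGORIES, 0)
        for call in calls:
            counts[call.category] += 1
        rows[sample] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))


@dataclass
class SampleSelection:
    sample_id: str
    synonymous: int
    non_synonymous: int
    ka_ks: Optional[float]  # count ratio; defined only when synonymous > 0
    classification: str  # negative | positive | neutral


@dataclass
class SelectionReport:
    samples: list[SampleSelection]
    slope: float
    intercept: float
    r_squared: float
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": s.sample_id,
                    "synonymous": s.synonymous,
                    "non_synonymous": s.non_synonymous,
                    "ka_ks": s.ka_ks,
                    "classification": s.classification,
                }
                for s in self.samples
            ]
        )


def selection_analysis(
    summary: pd.DataFrame, alpha: float = 0.01
) -> SelectionReport:
    """Ka/Ks screen across samples.

    ``summary`` must carry per-sample ``synonymous`` and ``non_synonymous``
    columns (as produced by :func:`effect_summary`).  Fits OLS of
    non-synonymous on synonymous counts; samples outside the
    ``1 - alpha`` prediction band are classified negative (below) or
    positive (above); the rest neutral.
    """
    if len(summary) < 3:
        raise ValueError("selection_analysis needs >= 3 samples")
    syn = summary["synonymous"].to_numpy(dtype=float)
    nonsyn = summary["non_synonymous"].to_numpy(dtype=float)
    if not np.any(syn > 0):
        raise ValueError("all synonymous counts are zero; Ka/Ks undefined")
    X = sm.add_constant(syn)
    model = sm.OLS(nonsyn, X).fit()
    pred = model.get_prediction(X).summary_frame(alpha=alpha)
    lower = pred["obs_ci_lower"].to_numpy()
    upper = pred["obs_ci_upper"].to_numpy()
    samples = []
    for i, sample_id in enumerate(summary.index):
        if nonsyn[i] < lower[i]:
            cls = "negative"
        elif nonsyn[i] > upper[i]:
            cls = "positive"
        else:
            cls = "neutral"
        samples.append(
            SampleSelection(
                sample_id=str(sample_id),
                synonymous=int(syn[i]),
                non_synonymous=int(nonsyn[i]),
                ka_ks=float(nonsyn[i] / syn[i]) if syn[i] > 0 else None,
                classification=cls,
            )
        )
    return SelectionReport(
        samples=samples,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        alpha=alpha,
    )
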