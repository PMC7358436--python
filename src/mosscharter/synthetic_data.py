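"""Synthetic cohort generator with planted accession/pedigree structure.

Emulates the study design the pipeline is built for: several accessions of a
haploid, predominantly selfing moss, each maintained as a handful of
laboratory pedigrees; RNA-seq-derived variant calls restricted to the gene
space; spike-in contigs that must carry zero true variants (any call on them
is a sequencing/mapping error); uneven per-position read depth.

Planted true variants always satisfy the calibrated read-coverage filter
(DP >= 9, AD >= 7, AD/DP > 0.77) in every carrier sample; planted error
calls always violate at least one of those conditions (low depth 3-8, or
allele fraction <= 0.7).  This makes filter recovery a provable property of
the construction rather than a statistical accident.

All randomness flows from one ``numpy`` generator seeded by the config;
identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_core import (
    ACCESSION_CODES,
    CoverageTrack,
    GeneModel,
    SampleName,
    VariantRecord,
    write_fasta,
    write_gff3,
    write_vcf,
)

BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")

# fixed gene architecture: 2 introns so splice regions exist; UTR stubs on
# both terminal exons; CDS length 540 (divisible by 3)
_EXON1, _INTRON1, _EXON2, _INTRON2, _EXON3 = 150, 100, 300, 80, 150
_UTR5, _UTR3 = 30, 30
_GENE_FOOTPRINT = _EXON1 + _INTRON1 + _EXON2 + _INTRON2 + _EXON3


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    The per-accession exclusive-SNP counts default to a 1:2:5:10:12 gradient
    mirroring how genetic distance tracks geographic distance across the
    five accessions.
    """

    n_chroms: int = 3
    chrom_length: int = 20_000
    genes_per_chrom: int = 8
    n_accessions: int = 5
    samples_per_accession: int = 6
    pedigrees_per_accession: int = 2
    snps_exclusive_per_accession: tuple[int, ...] = (12, 24, 60, 120, 144)
    snps_shared_all: int = 5
    snps_private_per_pedigree: int = 3
    indel_fraction: float = 0.1
    error_calls_per_sample: int = 10
    spikein_contigs: int = 2
    spikein_length: int = 2_000
    spikein_error_calls: int = 15
    depth_mean: float = 30.0
    dropout_fraction: float = 0.10
    diploid_extra_het_fraction: float = 0.53
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.snps_exclusive_per_accession, int):
            self.snps_exclusive_per_accession = (
                self.snps_exclusive_per_accession,
            ) * self.n_accessions
        counts = (
            self.n_chroms,
            self.chrom_length,
            self.genes_per_chrom,
            self.n_accessions,
            self.samples_per_accession,
            self.pedigrees_per_accession,
            self.snps_shared_all,
            self.snps_private_per_pedigree,
            self.error_calls_per_sample,
            self.spikein_contigs,
            self.spikein_error_calls,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_accessions > len(ACCESSION_CODES):
            raise ValueError(
                f"at most {len(ACCESSION_CODES)} accessions supported"
            )
        if len(self.snps_exclusive_per_accession) < self.n_accessions:
            raise ValueError("need one exclusive-SNP count per accession")

    @property
    def accessions(self) -> tuple[str, ...]:
        return ACCESSION_CODES[: self.n_accessions]


@dataclass
class PlantedVariant:
    """Truth label for one planted variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    is_indel: bool
    owner: str  # accession | pedigree | universal | error | spikein
    group: Optional[str]  # accession code or pedigree label; None otherwise
    samples: tuple[str, ...]

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class SyntheticTruth:
    variants: list[PlantedVariant]

    def by_owner(self, owner: str) -> list[PlantedVariant]:
        return [v for v in self.variants if v.owner == owner]

    @property
    def true_sites(self) -> set[tuple[str, int, str]]:
        return {
            v.site
            for v in self.variants
            if v.owner in ("accession", "pedigree", "universal")
        }

    @property
    def error_sites(self) -> set[tuple[str, int, str]]:
        return {v.site for v in self.variants if v.owner in ("error", "spikein")}


@dataclass
class Cohort:
    samples: list[tuple[SampleName, list[VariantRecord]]]
    tracks: dict[str, CoverageTrack]
    truth: SyntheticTruth
    diploid_samples: list[tuple[SampleName, list[VariantRecord]]]


# ---------------------------------------------------------------------------
# reference generation

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n-2) random non-stop codons + one random stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _place_gene(
    seq: np.ndarray, start: int, strand: str, gene_id: str, chrom: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Write one 3-exon gene into ``seq`` starting at 1-based ``start``."""
    e1 = (start, start + _EXON1 - 1)
    i1_end = e1[1] + _INTRON1
    e2 = (i1_end + 1, i1_end + _EXON2)
    i2_end = e2[1] + _INTRON2
    e3 = (i2_end + 1, i2_end + _EXON3)
    if strand == "+":
        cds = [(e1[0] + _UTR5, e1[1]), e2, (e3[0], e3[1] - _UTR3)]
    else:
        cds = [(e1[0] + _UTR3, e1[1]), e2, (e3[0], e3[1] - _UTR5)]
    cds_len = sum(e - s + 1 for s, e in cds)
    assert cds_len % 3 == 0
    cds_seq = _random_cds(rng, cds_len // 3)
    # lay the coding sequence onto the genome in transcription order
    positions: list[int] = []
    for s, e in cds:
        positions.extend(range(s, e + 1))
    if strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        cds_seq = "".join(comp[b] for b in reversed(cds_seq))
    for p, b in zip(positions, cds_seq):
        seq[p - 1] = b
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=e1[0],
        end=e3[1],
        exons=[e1, e2, e3],
        cds=cds,
    )


def generate_reference(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel], dict[str, str]]:
    """Generate (genome FASTA dict, gene models, spike-in FASTA dict)."""
    rng = np.random.default_rng(config.seed)
    min_gap = 150
    need = config.genes_per_chrom * (_GENE_FOOTPRINT + min_gap) + min_gap
    if config.chrom_length < need:
        raise ValueError(
            f"chrom_length {config.chrom_length} cannot pack "
            f"{config.genes_per_chrom} genes (needs >= {need} bp)"
        )
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    slack = config.chrom_length - need
    for ci in range(config.n_chroms):
        chrom = f"Chr{ci + 1:02d}"
        seq = rng.choice(BASES, config.chrom_length)
        cursor = min_gap + 1
        per_gene_slack = slack // max(config.genes_per_chrom, 1)
        for gi in range(config.genes_per_chrom):
            cursor += int(rng.integers(0, per_gene_slack + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _place_gene(
                seq, cursor, strand, f"{chrom}G{gi + 1:03d}", chrom, rng
            )
            genes.append(gene)
            cursor = gene.end + min_gap
        genome[chrom] = "".join(seq)
    spikeins = {
        f"spike{si + 1:02d}": "".join(rng.choice(BASES, config.spikein_length))
        for si in range(config.spikein_contigs)
    }
    if set(spikeins) & set(genome):
        raise ValueError("spike-in contig ids collide with genome contigs")
    return genome, genes, spikeins


# ---------------------------------------------------------------------------
# cohort generation

def _sample_names(config: SyntheticConfig) -> list[SampleName]:
    names = []
    for acc in config.accessions:
        for si in range(config.samples_per_accession):
            ped = si % config.pedigrees_per_accession + 1
            names.append(
                SampleName(
                    accession=acc,
                    pedigree=f"LAB-{ped}",
                    experiment="I",
                    replicate=si // config.pedigrees_per_accession % 5 + 1,
                    layout="PE",
                    exp_type="WTY",
                )
            )
    return names


def _gene_space_positions(genes: list[GeneModel], chrom: str) -> np.ndarray:
    pos = []
    for g in genes:
        if g.chrom == chrom:
            pos.extend(range(g.start, g.end + 1))
    return np.array(sorted(set(pos)), dtype=np.int64)


class _PositionPool:
    """Draws variant positions from the gene space with >= 2 bp spacing."""

    def __init__(self, genes: list[GeneModel], chroms: list[str],
                 rng: np.random.Generator):
        cands = []
        for chrom in chroms:
            for p in _gene_space_positions(genes, chrom):
                cands.append((chrom, int(p)))
        order = rng.permutation(len(cands))
        self._queue = [cands[i] for i in order]
        self._blocked: set[tuple[str, int]] = set()

    def draw(self) -> tuple[str, int]:
        while self._queue:
            chrom, pos = self._queue.pop()
            if any((chrom, pos + d) in self._blocked for d in (-1, 0, 1)):
                continue
            self._blocked.add((chrom, pos))
            return chrom, pos
        raise ValueError(
            "requested variant count exceeds available gene-space positions"
        )


def _true_support(rng: np.random.Generator, depth_mean: float) -> tuple[int, int]:
    """(dp, ad_alt) guaranteed to satisfy DP>=9, AD>=7, AD/DP>0.77."""
    dp = 9 + int(rng.poisson(max(depth_mean - 9.0, 0.0)))
    ad = dp - int(rng.binomial(dp, 0.02))
    ad = min(dp, max(ad, 7, math.floor(0.77 * dp) + 1))
    return dp, ad


def _error_support(rng: np.random.Generator, depth_mean: float) -> tuple[int, int]:
    """(dp, ad_alt) guaranteed to fail the coverage filter."""
    if rng.random() < 0.5:
        dp = int(rng.integers(3, 9))  # depth below the floor of 9
        ad = int(rng.integers(1, dp + 1))
    else:
        dp = 9 + int(rng.poisson(max(depth_mean - 9.0, 0.0)))
        ad = max(1, math.floor(0.7 * dp))  # allele fraction <= 0.7
    return dp, ad


def _alt_allele(rng: np.random.Generator, ref_base: str, indel: bool,
                next_base: str) -> tuple[str, str, bool]:
    """Return (ref, alt, is_indel) for one planted variant."""
    if not indel:
        choices = [b for b in "ACGT" if b != ref_base]
        return ref_base, choices[rng.integers(3)], False
    if rng.random() < 0.5:  # insertion
        return ref_base, ref_base + "ACGT"[rng.integers(4)], True
    return ref_base + next_base, ref_base, True  # deletion of the next base


def generate_cohort(
    config: SyntheticConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    spikeins: Optional[dict[str, str]] = None,
) -> Cohort:
    """Plant universal/accession/pedigree variants plus error calls."""
    rng = np.random.default_rng(config.seed + 1)
    spikeins = spikeins or {}
    names = _sample_names(config)
    by_acc: dict[str, list[str]] = {}
    by_ped: dict[tuple[str, str], list[str]] = {}
    for n in names:
        by_acc.setdefault(n.accession, []).append(str(n))
        by_ped.setdefault((n.accession, n.pedigree), []).append(str(n))

    pool = _PositionPool(genes, sorted(genome), rng)
    truth: list[PlantedVariant] = []

    def plant(owner: str, group: Optional[str], samples: list[str]) -> None:
        chrom, pos = pool.draw()
        ref_base = genome[chrom][pos - 1]
        next_base = genome[chrom][pos] if pos < len(genome[chrom]) else "A"
        indel = rng.random() < config.indel_fraction
        ref, alt, is_indel = _alt_allele(rng, ref_base, indel, next_base)
        truth.append(
            PlantedVariant(chrom, pos, ref, alt, is_indel, owner, group,
                           tuple(samples))
        )

    all_samples = [str(n) for n in names]
    for _ in range(config.snps_shared_all):
        plant("universal", None, all_samples)
    for acc, count in zip(config.accessions, config.snps_exclusive_per_accession):
        for _ in range(count):
            plant("accession", acc, by_acc[acc])
    for (acc, ped), members in sorted(by_ped.items()):
        for _ in range(config.snps_private_per_pedigree):
            plant("pedigree", f"{acc}:{ped}", members)

    # per-sample record construction
    samples: list[tuple[SampleName, list[VariantRecord]]] = []
    diploid: list[tuple[SampleName, list[VariantRecord]]] = []
    carrier_index: dict[str, list[PlantedVariant]] = {s: [] for s in all_samples}
    for v in truth:
        for s in v.samples:
            carrier_index[s].append(v)

    spike_names = sorted(spikeins)
    for name in names:
        sid = str(name)
        records: list[VariantRecord] = []
        for v in carrier_index[sid]:
            dp, ad = _true_support(rng, config.depth_mean)
            records.append(
                VariantRecord(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    dp=dp, ad_alt=ad,
                    gq=float(rng.integers(91, 100)),
                    qual=float(np.round(rng.uniform(100, 1000), 2)),
                    gt="1",
                )
            )
        # per-sample error calls in the gene space
        for _ in range(config.error_calls_per_sample):
            chrom, pos = pool.draw()
            ref_base = genome[chrom][pos - 1]
            ref, alt, is_indel = _alt_allele(rng, ref_base, False, "A")
            dp, ad = _error_support(rng, config.depth_mean)
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt, dp=dp, ad_alt=ad,
                gq=float(rng.integers(20, 100)),
                qual=float(np.round(rng.uniform(10, 200), 2)),
                gt="1",
            )
            records.append(rec)
            truth.append(
                PlantedVariant(chrom, pos, ref, alt, is_indel, "error", None,
                               (sid,))
            )
        # spike-in artifact calls (sequencing errors on spike-in contigs)
        for _ in range(config.spikein_error_calls):
            if not spike_names:
                break
            chrom = spike_names[int(rng.integers(len(spike_names)))]
            pos = int(rng.integers(1, len(spikeins[chrom]) + 1))
            ref_base = spikeins[chrom][pos - 1]
            choices = [b for b in "ACGT" if b != ref_base]
            alt = choices[rng.integers(3)]
            dp, ad = _error_support(rng, config.depth_mean)
            rec = VariantRecord(
                chrom=chrom, pos=pos, ref=ref_base, alt=alt, dp=dp, ad_alt=ad,
                gq=float(rng.integers(20, 100)),
                qual=float(np.round(rng.uniform(10, 200), 2)),
                gt="1",
            )
            records.append(rec)
            truth.append(
                PlantedVariant(chrom, pos, ref_base, alt, False, "spikein",
                               None, (sid,))
            )
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        samples.append((name, records))

        # diploid-style encoding of the same sample: every haploid call is
        # homozygous alt, plus extra low-allele-fraction heterozygous calls
        # (the inflation a diploid caller shows on a haploid organism)
        dip = [
            VariantRecord(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt, dp=r.dp,
                ad_alt=r.ad_alt, gq=r.gq, qual=r.qual, gt="1/1",
            )
            for r in records
        ]
        n_extra = round(config.diploid_extra_het_fraction * len(records))
        for _ in range(n_extra):
            chrom, pos = pool.draw()
            ref_base = genome[chrom][pos - 1]
            choices = [b for b in "ACGT" if b != ref_base]
            alt = choices[rng.integers(3)]
            dp = 9 + int(rng.poisson(max(config.depth_mean - 9.0, 0.0)))
            dip.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref_base, alt=alt, dp=dp,
                    ad_alt=max(1, dp // 2),
                    gq=float(rng.integers(20, 100)),
                    qual=float(np.round(rng.uniform(10, 500), 2)),
                    gt="0/1",
                )
            )
        dip.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        diploid.append((name, dip))

    # depth tracks: dropout positions below the depth floor, the rest around
    # depth_mean; record positions pinned to the record's own DP
    tracks: dict[str, CoverageTrack] = {}
    contigs = {c: len(s) for c, s in genome.items()}
    contigs.update({c: len(s) for c, s in spikeins.items()})
    for name, records in samples:
        depths = {}
        for chrom, length in sorted(contigs.items()):
            drop = rng.random(length) < config.dropout_fraction
            low = rng.integers(0, 9, length)
            high = 9 + rng.poisson(max(config.depth_mean - 9.0, 0.0), length)
            depths[chrom] = np.where(drop, low, high).astype(np.int32)
        for r in records:
            if r.dp is not None:
                depths[r.chrom][r.pos - 1] = r.dp
        tracks[str(name)] = CoverageTrack(depths)

    return Cohort(samples=samples, tracks=tracks,
                  truth=SyntheticTruth(truth), diploid_samples=diploid)


def generate_blind_samples(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    n: int,
    seed: int,
) -> list[tuple[str, list[VariantRecord]]]:
    """Held-out samples carrying one accession's planted variants.

    Returns ``(true_accession, records)`` pairs for blind-assignment tests;
    each sample carries its accession's exclusive variants plus the
    universal ones, with fresh support draws.
    """
    rng = np.random.default_rng(seed)
    out = []
    accs = list(config.accessions)
    for _ in range(n):
        acc = accs[int(rng.integers(len(accs)))]
        records = []
        for v in truth.variants:
            if v.owner == "universal" or (v.owner == "accession" and v.group == acc):
                dp, ad = _true_support(rng, config.depth_mean)
                records.append(
                    VariantRecord(
                        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                        dp=dp, ad_alt=ad, gq=95.0, qual=500.0, gt="1",
                    )
                )
        records.sort(key=lambda r: (r.chrom, r.pos, r.alt))
        out.append((acc, records))
    return out


# ---------------------------------------------------------------------------
# reports and file output

def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """One row per planted variant with owner label and carrier samples."""
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "is_indel": v.is_indel,
            "owner": v.owner,
            "group": v.group if v.group is not None else ".",
            "samples": ",".join(v.samples),
        }
        for v in truth.variants
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "is_indel", "owner", "group",
                 "samples"],
    )


def write_run_dir(
    run_dir: str | Path,
    config: SyntheticConfig,
    genome: dict[str, str],
    genes: list[GeneModel],
    spikeins: dict[str, str],
    cohort: Cohort,
) -> None:
    """Write the full synthetic dataset as standard files."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(run_dir / "genome.fasta", genome)
    write_fasta(run_dir / "spikeins.fasta", spikeins)
    write_gff3(run_dir / "annotation.gff3", genes)
    contigs = {c: len(s) for c, s in genome.items()}
    contigs.update({c: len(s) for c, s in spikeins.items()})
    vcf_dir = run_dir / "vcf"
    depth_dir = run_dir / "depth"
    vcf_dir.mkdir(exist_ok=True)
    depth_dir.mkdir(exist_ok=True)
    for name, records in cohort.samples:
        write_vcf(vcf_dir / f"{name}.vcf", records, str(name), contigs)
        cohort.tracks[str(name)].to_table(depth_dir / f"{name}.depth.tsv")
    truth_report(cohort.truth).to_csv(
        run_dir / "truth.tsv", sep="\t", index=False
    )
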