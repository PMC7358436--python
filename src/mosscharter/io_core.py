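"""File I/O, sample nomenclature, and shared domain types.

All coordinates are 1-based inclusive throughout the package, matching the
VCF and GFF3 conventions of the files it consumes.  Multi-allelic VCF lines
are split into one record per alternate allele so that every
:class:`VariantRecord` describes a single REF->ALT substitution.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mosscharter")

ACCESSION_CODES = ("Gd", "Re", "Ka", "Vx", "Wi")
LAYOUTS = ("SE", "PE")
EXP_TYPES = ("MUT", "WTY")
_ROMAN_RE = re.compile(r"^[IVXLCDM]+$")


class SampleNameError(ValueError):
    """Raised when a sample name violates the nomenclature."""


@dataclass(frozen=True)
class SampleName:
    """A sample identifier in the underscore-separated lab nomenclature.

    Example: ``Gd_MR-WT11_XX_1_PE_WTY`` = accession Gd, pedigree
    MR-WT11, experiment XX (roman), replicate 1, paired-end, wild type.
    """

    accession: str
    pedigree: str
    experiment: str
    replicate: int
    layout: str
    exp_type: str

    def __post_init__(self) -> None:
        if self.accession not in ACCESSION_CODES:
            raise SampleNameError(
                f"unknown accession code {self.accession!r}; "
                f"expected one of {ACCESSION_CODES}"
            )
        if not self.pedigree or "_" in self.pedigree:
            raise SampleNameError(
                f"pedigree {self.pedigree!r} must be non-empty and free of underscores"
            )
        if not _ROMAN_RE.match(self.experiment):
            raise SampleNameError(
                f"experiment {self.experiment!r} is not a roman-numeral string"
            )
        if not 1 <= int(self.replicate) <= 5:
            raise SampleNameError(f"replicate {self.replicate!r} outside 1-5")
        if self.layout not in LAYOUTS:
            raise SampleNameError(f"layout {self.layout!r} not in {LAYOUTS}")
        if self.exp_type not in EXP_TYPES:
            raise SampleNameError(f"exp_type {self.exp_type!r} not in {EXP_TYPES}")

    def __str__(self) -> str:
        return "_".join(
            (
                self.accession,
                self.pedigree,
                self.experiment,
                str(self.replicate),
                self.layout,
                self.exp_type,
            )
        )


def parse_sample_name(name: str) -> SampleName:
    """Parse an underscore-separated sample name into its six fields."""
    fields = name.split("_")
    if len(fields) != 6:
        raise SampleNameError(
            f"sample name {name!r} has {len(fields)} underscore-separated "
            "fields; expected 6 (accession_pedigree_experiment_replicate_layout_type)"
        )
    accession, pedigree, experiment, replicate, layout, exp_type = fields
    try:
        rep = int(replicate)
    except ValueError as exc:
        raise SampleNameError(f"replicate field {replicate!r} is not an integer") from exc
    return SampleName(accession, pedigree, experiment, rep, layout, exp_type)


def format_sample_name(sample: SampleName) -> str:
    return str(sample)


_ALLELE_RE = re.compile(r"^[ACGT]+$")


@dataclass
class VariantRecord:
    """One called variant: a single REF->ALT substitution or indel.

    ``dp``/``ad_alt``/``gq`` are ``None`` when the caller did not emit the
    corresponding FORMAT field; downstream filters treat absence as failure.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    dp: Optional[int] = None
    ad_alt: Optional[int] = None
    gq: Optional[float] = None
    qual: Optional[float] = None
    gt: str = "1"
    is_indel: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1 (coordinates are 1-based)")
        for allele in (self.ref, self.alt):
            if not allele:
                raise ValueError("empty allele")
            if not (_ALLELE_RE.match(allele) or allele.startswith("<")):
                raise ValueError(f"allele {allele!r} not over ACGT nor symbolic")
        if self.dp is not None and self.ad_alt is not None and self.ad_alt > self.dp:
            raise ValueError(f"ad_alt {self.ad_alt} exceeds dp {self.dp}")
        if self.is_indel is None:
            symbolic = self.alt.startswith("<")
            self.is_indel = symbolic or len(self.ref) != len(self.alt)

    @property
    def site(self) -> tuple[str, int, str]:
        """Site identity used for cross-sample support counting."""
        return (self.chrom, self.pos, self.alt)

    @property
    def fold_change(self) -> Optional[float]:
        if self.dp in (None, 0) or self.ad_alt is None:
            return None
        return self.ad_alt / self.dp


class CoverageTrack:
    """Per-contig read-depth arrays (index 0 holds position 1)."""

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self.depths = {c: np.asarray(d, dtype=np.int32) for c, d in depths.items()}

    def covered_bp(self, min_depth: int = 9) -> int:
        """Number of positions with depth >= ``min_depth``."""
        return int(sum(int((d >= min_depth).sum()) for d in self.depths.values()))

    def total_bp(self) -> int:
        return int(sum(d.size for d in self.depths.values()))

    def depth_at(self, chrom: str, pos: int) -> int:
        return int(self.depths[chrom][pos - 1])

    @classmethod
    def from_table(cls, path: str | Path) -> "CoverageTrack":
        """Read a 3-column (chrom, pos, depth) table with all positions printed."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
        depths = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            arr = np.zeros(int(pos.max()), dtype=np.int32)
            arr[pos - 1] = sub["depth"].to_numpy()
            depths[str(chrom)] = arr
        return cls(depths)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.depths:
                d = self.depths[chrom]
                for i in range(d.size):
                    fh.write(f"{chrom}\t{i + 1}\t{d[i]}\n")


@dataclass
class GeneModel:
    """A gene with exon and CDS intervals (1-based inclusive, sorted)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)

def _vcf_header(sample_id: str, contig_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth at this position")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(sample_id)
    return header


def write_vcf(
    path: str | Path,
    records: Sequence[VariantRecord],
    sample_id: str,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write one single-sample VCF; records must carry 1-based coordinates."""
    header = _vcf_header(sample_id, contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            v = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,  # pysam is 0-based internally
                alleles=(rec.ref, rec.alt),
            )
            if rec.qual is not None:
                v.qual = rec.qual
            gt_fields = rec.gt.replace("|", "/").split("/")
            v.samples[sample_id]["GT"] = tuple(
                None if g == "." else int(g) for g in gt_fields
            )
            if rec.dp is not None:
                v.samples[sample_id]["DP"] = rec.dp
            if rec.ad_alt is not None and rec.dp is not None:
                v.samples[sample_id]["AD"] = (rec.dp - rec.ad_alt, rec.ad_alt)
            if rec.gq is not None:
                v.samples[sample_id]["GQ"] = int(rec.gq)
            out.write(v)


def read_vcf(path: str | Path) -> tuple[str, list[VariantRecord]]:
    """Read a single-sample VCF into records, splitting multi-allelic lines.

    Returns ``(vcf_sample_id, records)``.  Missing DP/AD/GQ fields are kept
    as ``None`` (absent, not zero).
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        if len(sample_ids) != 1:
            raise ValueError(
                f"{path}: expected a single-sample VCF with a genotype column, "
                f"found {len(sample_ids)} samples"
            )
        sid = sample_ids[0]
        for v in vcf:
            call = v.samples[sid]
            dp = call.get("DP")
            ad = call.get("AD")
            gq = call.get("GQ")
            gt = call.get("GT")
            alts = v.alts or ()
            for i, alt in enumerate(alts):
                ad_alt = None
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    ad_alt = int(ad[i + 1])
                if gt is None or all(g is None for g in gt):
                    gt_code = "."
                else:
                    gt_code = "/".join("." if g is None else str(g) for g in gt)
                records.append(
                    VariantRecord(
                        chrom=v.chrom,
                        pos=v.pos,  # pysam .pos is 1-based
                        ref=v.ref,
                        alt=alt,
                        dp=None if dp is None else int(dp),
                        ad_alt=ad_alt,
                        gq=None if gq is None else float(gq),
                        qual=None if v.qual is None else float(v.qual),
                        gt=gt_code,
                    )
                )
    return sid, records


def load_cohort(
    vcf_paths: Sequence[str | Path],
    depth_paths: Sequence[str | Path] = (),
    name_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[tuple[SampleName, list[VariantRecord]]], dict[str, CoverageTrack]]:
    """Load a cohort of single-sample VCFs plus optional depth tracks.

    Sample names are taken from the VCF genotype column; names that do not
    follow the nomenclature may be remapped through ``name_map`` (keyed by
    the raw id or the file stem).
    """
    name_map = dict(name_map or {})
    samples: list[tuple[SampleName, list[VariantRecord]]] = []
    for path in vcf_paths:
        raw_id, records = read_vcf(path)
        stem = Path(path).name.removesuffix(".gz").removesuffix(".vcf")
        candidate = name_map.get(raw_id, name_map.get(stem, raw_id))
        try:
            sample = parse_sample_name(candidate)
        except SampleNameError as exc:
            raise SampleNameError(
                f"{path}: sample id {raw_id!r} is unparseable and absent "
                f"from the name map ({exc})"
            ) from exc
        samples.append((sample, records))
    tracks: dict[str, CoverageTrack] = {}
    for (sample, _), dpath in zip(samples, depth_paths):
        tracks[str(sample)] = CoverageTrack.from_table(dpath)
    return samples, tracks


# ---------------------------------------------------------------------------
# FASTA / GFF3

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models (gene + exon + CDS features) from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = [(f.start, f.end) for f in db.children(g, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(g, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exons=exons,
                cds=cds,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tmosscharter\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tmosscharter\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tmosscharter\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            # phase bookkeeping: cumulative CDS length before each piece,
            # walked in transcription order
            pieces = g.cds if g.strand == "+" else list(reversed(g.cds))
            consumed = 0
            phases = {}
            for s, e in pieces:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tmosscharter\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
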