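"""Restriction-site scanning, SNP/site overlap, RFLP assay candidate
selection, and in-silico digestion.

An RFLP assay turns a diagnostic SNP into a gel readout: when the variant
allele creates or destroys a restriction-enzyme recognition site inside a
PCR amplicon, carrier and non-carrier material yield different fragment
patterns after digestion.  Scanning is IUPAC-ambiguity aware on both
strands; ``N`` in the *sequence* never matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site plus top-strand cut
    offset (bases 5' of the cut within the site)."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if any(b not in IUPAC for b in site):
            raise ValueError(f"{self.name}: site {site!r} has non-IUPAC letters")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"{self.name}: cut offset {self.cut_offset} outside site"
            )

    @property
    def site_len(self) -> int:
        return len(self.site)

    @property
    def palindromic(self) -> bool:
        return self.site == iupac_revcomp(self.site)


# common commercially available enzymes; cut offset counts bases before ^
BUILTIN_ENZYMES: tuple[Enzyme, ...] = (
    Enzyme("NdeI", "CATATG", 2),      # CA^TATG
    Enzyme("SwaI", "ATTTAAAT", 4),    # ATTT^AAAT
    Enzyme("XbaI", "TCTAGA", 1),      # T^CTAGA
    Enzyme("EcoRI", "GAATTC", 1),     # G^AATTC
    Enzyme("EcoRV", "GATATC", 3),     # GAT^ATC
    Enzyme("HindIII", "AAGCTT", 1),   # A^AGCTT
    Enzyme("BamHI", "GGATCC", 1),     # G^GATCC
    Enzyme("DraI", "TTTAAA", 3),      # TTT^AAA
    Enzyme("SspI", "AATATT", 3),      # AAT^ATT
    Enzyme("HinfI", "GANTC", 1),      # G^ANTC
    Enzyme("NotI", "GCGGCCGC", 2),    # GC^GGCCGC
    Enzyme("PacI", "TTAATTAA", 5),    # TTAAT^TAA
)


def load_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Load a tab-separated enzyme table: name, IUPAC site, cut_offset."""
    enzymes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, site, offset = line.split("\t")[:3]
        enzymes.append(Enzyme(name, site, int(offset)))
    return enzymes


@dataclass(frozen=True)
class SiteMatch:
    enzyme: Enzyme
    pos: int  # 1-based start of the matched window on the top strand
    strand: str  # "+" or "-"


def _site_regex(site: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(f"[{IUPAC[b]}]" for b in site)
    return re.compile(f"(?=({body}))")


def scan_sites(
    sequence: str,
    enzymes: Sequence[Enzyme],
    min_len: int = 5,
) -> list[SiteMatch]:
    """All recognition-site matches on both strands, IUPAC-aware.

    Enzymes with sites shorter than ``min_len`` are excluded up front;
    palindromic sites are reported once per position (strand "+").
    """
    usable = [e for e in enzymes if e.site_len >= min_len]
    if not usable:
        raise ValueError(
            f"no enzymes with recognition sites of >= {min_len} bp"
        )
    seq = sequence.upper()
    matches: list[SiteMatch] = []
    for enz in usable:
        for m in _site_regex(enz.site).finditer(seq):
            matches.append(SiteMatch(enz, m.start() + 1, "+"))
        if not enz.palindromic:
            for m in _site_regex(iupac_revcomp(enz.site)).finditer(seq):
                matches.append(SiteMatch(enz, m.start() + 1, "-"))
    matches.sort(key=lambda s: (s.pos, s.enzyme.name, s.strand))
    return matches


@dataclass
class Amplicon:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("sequence length must equal end - start + 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DigestResult:
    enzyme: Enzyme
    cut_positions: list[int]  # cut falls after this 1-based base
    fragments: list[int]
    gel_invisible: list[int] = field(default_factory=list)  # fragments < 50 bp

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def digest(amplicon: Amplicon | str, enzyme: Enzyme) -> DigestResult:
    """Predict digestion fragments of a linear amplicon.

    Top-strand matches cut after ``match_start - 1 + cut_offset``; matches of
    a non-palindromic site on the reverse strand cut at the top-strand
    coordinate implied by the site geometry
    (``match_start - 1 + site_len - cut_offset``).  Fragment lengths always
    sum to the amplicon length; 0 matches leaves one full-length fragment.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon
    seq = seq.upper()
    length = len(seq)
    cuts = set()
    for m in scan_sites(seq, [enzyme], min_len=enzyme.site_len):
        if m.strand == "+":
            cut = m.pos - 1 + enzyme.cut_offset
        else:
            cut = m.pos - 1 + enzyme.site_len - enzyme.cut_offset
        if 0 < cut < length:
            cuts.add(cut)
    ordered = sorted(cuts)
    bounds = [0] + ordered + [length]
    fragments = [b - a for a, b in zip(bounds, bounds[1:])]
    return DigestResult(
        enzyme=enzyme,
        cut_positions=ordered,
        fragments=fragments,
        gel_invisible=[f for f in fragments if f < 50],
    )


def snp_site_overlap(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme],
) -> list[tuple[Enzyme, str]]:
    """Enzymes whose recognition-site match status flips at a SNP.

    Returns (enzyme, effect) pairs, effect in {"destroys_site",
    "creates_site"}: destroys when the reference allele completes a site the
    alternate breaks, creates for the converse.
    """
    seq = genome[chrom]
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("snp_site_overlap handles single-base SNPs only")
    if seq[pos - 1] != ref:
        raise ValueError(
            f"{chrom}:{pos} REF {ref!r} does not match genome base "
            f"{seq[pos - 1]!r}"
        )
    max_len = max(e.site_len for e in enzymes)
    lo = max(pos - max_len, 0)  # 0-based window start
    hi = min(pos - 1 + max_len, len(seq))
    ref_local = seq[lo:hi]
    snp_off = pos - 1 - lo  # 0-based offset of the SNP within the window
    alt_local = ref_local[:snp_off] + alt + ref_local[snp_off + 1 :]
    out = []
    for enz in enzymes:
        def covering(local: str) -> int:
            n = 0
            for m in scan_sites(local, [enz], min_len=enz.site_len):
                start0 = m.pos - 1
                if start0 <= snp_off < start0 + enz.site_len:
                    n += 1
            return n
        ref_n, alt_n = covering(ref_local), covering(alt_local)
        if ref_n > 0 and alt_n == 0:
            out.append((enz, "destroys_site"))
        elif ref_n == 0 and alt_n > 0:
            out.append((enz, "creates_site"))
    return out


@dataclass
class RflpCandidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    group: str
    enzyme: Enzyme
    effect: str  # destroys_site | creates_site
    extra_cuts: int  # additional same-enzyme cuts within the +/- 2 kbp window
    amplicon: Amplicon
    carrier_fragments: list[int]
    noncarrier_fragments: list[int]


def candidate_select(
    exclusive_sets: Mapping[str, "object"],
    genome: Mapping[str, str],
    enzymes: Sequence[Enzyme] = BUILTIN_ENZYMES,
    site_lengths: Sequence[int] = (6, 8),
    max_extra_cuts: int = 1,
    window: int = 2000,
    amplicon_range: tuple[int, int] = (700, 1400),
) -> list[RflpCandidate]:
    """Select RFLP assay candidates from exclusive SNP panels.

    Constraints (defaults): recognition site 6 or 8 nt; at most one
    additional cut of the same enzyme within +/- 2 kbp of the SNP; an
    amplicon of 700-1,400 bp containing the SNP.  Candidates are sorted by
    (fewest extra cuts, longest site).  Returns an empty list when nothing
    qualifies.
    """
    eligible = [e for e in enzymes if e.site_len in set(site_lengths)]
    candidates: list[RflpCandidate] = []
    for group, es in sorted(exclusive_sets.items()):
        for member in es.members:
            site = member.site
            if site.is_indel:
                continue
            flips = snp_site_overlap(
                site.chrom, site.pos, site.ref, site.alt, genome, eligible
            )
            for enz, effect in flips:
                chrom_seq = genome[site.chrom]
                lo = max(site.pos - window, 1)
                hi = min(site.pos + window, len(chrom_seq))
                flank_seq = chrom_seq[lo - 1 : hi]
                snp_off = site.pos - lo  # 0-based in flank
                n_extra = 0
                for m in scan_sites(flank_seq, [enz], min_len=enz.site_len):
                    start0 = m.pos - 1
                    if not (start0 <= snp_off < start0 + enz.site_len):
                        n_extra += 1
                if n_extra > max_extra_cuts:
                    continue
                amplicon = _design_amplicon(
                    site.chrom, site.pos, chrom_seq, amplicon_range
                )
                if amplicon is None:
                    continue
                off = site.pos - amplicon.start
                alt_seq = (
                    amplicon.sequence[:off]
                    + site.alt
                    + amplicon.sequence[off + 1 :]
                )
                carrier = digest(alt_seq, enz).fragments
                noncarrier = digest(amplicon, enz).fragments
                candidates.append(
                    RflpCandidate(
                        chrom=site.chrom,
                        pos=site.pos,
                        ref=site.ref,
                        alt=site.alt,
                        group=group,
                        enzyme=enz,
                        effect=effect,
                        extra_cuts=n_extra,
                        amplicon=amplicon,
                        carrier_fragments=carrier,
                        noncarrier_fragments=noncarrier,
                    )
                )
    candidates.sort(
        key=lambda c: (c.extra_cuts, -c.enzyme.site_len, c.chrom, c.pos)
    )
    return candidates


def _design_amplicon(
    chrom: str,
    pos: int,
    chrom_seq: str,
    amplicon_range: tuple[int, int],
) -> Optional[Amplicon]:
    """Window of mid-range length centered on the SNP, clipped to the contig."""
    lo_len, hi_len = amplicon_range
    target = (lo_len + hi_len) // 2
    half = target // 2
    start = max(pos - half, 1)
    end = min(start + target - 1, len(chrom_seq))
    start = max(min(start, end - target + 1), 1)
    if end - start + 1 < lo_len or not (start <= pos <= end):
        return None
    return Amplicon(
        chrom=chrom, start=start, end=end,
        sequence=chrom_seq[start - 1 : end],
    )
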