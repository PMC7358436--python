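"""Cross-sample presence matrix and exclusive (diagnostic) SNP panels.

An *exclusive* (synonymously *unique*) variant is one carried by nearly all
samples of one group and by no sample of any other group; such variants act
as diagnostic markers for assigning material of unknown origin to an
accession or laboratory pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import SampleName, VariantRecord


@dataclass(frozen=True, order=True)
class Site:
    chrom: str
    pos: int
    alt: str
    ref: str
    is_indel: bool

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used for support counting: the same alt must recur."""
        return (self.chrom, self.pos, self.alt)


class PresenceMatrix:
    """Sites x samples incidence built from per-sample call sets."""

    def __init__(
        self,
        sites: Sequence[Site],
        samples: Sequence[SampleName],
        incidence: np.ndarray,
    ):
        self.sites = list(sites)
        self.samples = list(samples)
        self.incidence = np.asarray(incidence, dtype=bool)
        if self.incidence.shape != (len(self.sites), len(self.samples)):
            raise ValueError("incidence dimensions must be |sites| x |samples|")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.samples]

    @property
    def accessions(self) -> list[str]:
        return sorted({s.accession for s in self.samples})

    def sample_mask(self, accession: Optional[str] = None,
                    pedigree: Optional[str] = None) -> np.ndarray:
        mask = np.ones(len(self.samples), dtype=bool)
        if accession is not None:
            mask &= np.array([s.accession == accession for s in self.samples])
        if pedigree is not None:
            mask &= np.array([s.pedigree == pedigree for s in self.samples])
        return mask

    def support(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-site number of supporting samples (within ``mask`` if given)."""
        if mask is None:
            return self.incidence.sum(axis=1)
        return self.incidence[:, mask].sum(axis=1)

    def subset_sites(self, keep: np.ndarray) -> "PresenceMatrix":
        keep = np.asarray(keep)
        return PresenceMatrix(
            [s for s, k in zip(self.sites, keep) if k],
            self.samples,
            self.incidence[keep],
        )

    def drop_indels(self) -> "PresenceMatrix":
        return self.subset_sites(
            np.array([not s.is_indel for s in self.sites], dtype=bool)
        )

    def to_samples(self) -> list[tuple[SampleName, list[Site]]]:
        out = []
        for j, sample in enumerate(self.samples):
            out.append(
                (sample, [s for i, s in enumerate(self.sites)
                          if self.incidence[i, j]])
            )
        return out


def build_presence(
    samples: Sequence[tuple[SampleName, Sequence[VariantRecord]]],
) -> PresenceMatrix:
    """Group all samples' calls into one sites x samples incidence matrix.

    Sites are the union over samples, sorted by (chrom, pos, alt); incidence
    is call-based (a sample supports a site iff its call set contains it).
    """
    ids = [str(name) for name, _ in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")
    site_map: dict[tuple[str, int, str], Site] = {}
    for _, records in samples:
        for r in records:
            key = (r.chrom, r.pos, r.alt)
            if key not in site_map:
                site_map[key] = Site(r.chrom, r.pos, r.alt, r.ref, r.is_indel)
    sites = [site_map[k] for k in sorted(site_map)]
    index = {s.key: i for i, s in enumerate(sites)}
    incidence = np.zeros((len(sites), len(samples)), dtype=bool)
    for j, (_, records) in enumerate(samples):
        for r in records:
            incidence[index[(r.chrom, r.pos, r.alt)], j] = True
    return PresenceMatrix(sites, [name for name, _ in samples], incidence)


@dataclass
class ExclusiveMember:
    site: Site
    support: int
    rank: Optional[int] = None


@dataclass
class ExclusiveSet:
    group: str
    rule: str  # "threshold" or "top-k"
    members: list[ExclusiveMember]

    @property
    def sites(self) -> set[tuple[str, int, str]]:
        return {m.site.key for m in self.members}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group": self.group,
                    "chrom": m.site.chrom,
                    "pos": m.site.pos,
                    "ref": m.site.ref,
                    "alt": m.site.alt,
                    "support": m.support,
                    "rank": m.rank if m.rank is not None else ".",
                }
                for m in self.members
            ],
            columns=["group", "chrom", "pos", "ref", "alt", "support", "rank"],
        )


def accession_exclusive(
    matrix: PresenceMatrix,
    support_frac: float = 0.90,
    drop_indels: bool = False,
) -> dict[str, ExclusiveSet]:
    """Per-accession exclusive panels under the strict >90% / zero-leakage rule.

    A site qualifies for accession A iff it is supported by strictly more
    than ``support_frac`` of A's samples and by zero samples of every other
    accession.  The read-coverage filter is deliberately not assumed
    upstream of this mode; callers pass whichever matrix they built.
    """
    accs = matrix.accessions
    if len(accs) < 2:
        raise ValueError("accession-exclusive extraction needs >= 2 accessions")
    if drop_indels:
        matrix = matrix.drop_indels()
    support_by_acc = {a: matrix.support(matrix.sample_mask(accession=a))
                      for a in accs}
    n_by_acc = {a: int(matrix.sample_mask(accession=a).sum()) for a in accs}
    out: dict[str, ExclusiveSet] = {}
    for acc in accs:
        own = support_by_acc[acc]
        others = sum(support_by_acc[a] for a in accs if a != acc)
        qual = (own > support_frac * n_by_acc[acc]) & (others == 0)
        members = [
            ExclusiveMember(site=s, support=int(own[i]))
            for i, s in enumerate(matrix.sites)
            if qual[i]
        ]
        out[acc] = ExclusiveSet(group=acc, rule="threshold", members=members)
    return out


def pedigree_rank(
    matrix: PresenceMatrix,
    accession: str,
    top_k: int = 5,
    restrict_to_accession_exclusive: bool = True,
) -> dict[str, ExclusiveSet]:
    """Top-k pedigree panels ranked by supporting-sample count.

    Candidate sites must be present in exactly one pedigree of the chosen
    accession; by default they must also be absent from every other
    accession (the panels derive from the accession's own exclusive sites).
    Ties at the k-th support level break by (chrom, pos) ascending.
    """
    acc_mask = matrix.sample_mask(accession=accession)
    if not acc_mask.any():
        raise ValueError(f"no samples for accession {accession!r}")
    pedigrees = sorted(
        {s.pedigree for s in matrix.samples if s.accession == accession}
    )
    if restrict_to_accession_exclusive:
        outside = matrix.support(~acc_mask)
        matrix = matrix.subset_sites(outside == 0)
    ped_support = {
        p: matrix.support(matrix.sample_mask(accession=accession, pedigree=p))
        for p in pedigrees
    }
    n_peds_with_site = sum((ped_support[p] > 0).astype(int) for p in pedigrees)
    out: dict[str, ExclusiveSet] = {}
    for ped in pedigrees:
        cand = (ped_support[ped] > 0) & (n_peds_with_site == 1)
        scored = [
            (int(ped_support[ped][i]), matrix.sites[i])
            for i in np.flatnonzero(cand)
        ]
        scored.sort(key=lambda t: (-t[0], t[1].chrom, t[1].pos))
        members = [
            ExclusiveMember(site=s, support=sup, rank=r + 1)
            for r, (sup, s) in enumerate(scored[:top_k])
        ]
        out[ped] = ExclusiveSet(group=f"{accession}:{ped}", rule="top-k",
                                members=members)
    return out


def assign_accession(
    records: Sequence[VariantRecord],
    exclusive_sets: dict[str, ExclusiveSet],
) -> tuple[str, dict[str, int]]:
    """Assign a sample to the accession whose exclusive panel it overlaps most."""
    calls = {(r.chrom, r.pos, r.alt) for r in records}
    overlaps = {
        acc: len(calls & es.sites) for acc, es in exclusive_sets.items()
    }
    best = max(sorted(overlaps), key=lambda a: overlaps[a])
    return best, overlaps
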