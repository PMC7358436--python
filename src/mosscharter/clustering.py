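"""SNP-based sample clustering: artificial alignment, 0/1/2 encoding,
distances, neighbor-joining, and a 3-component PCA.

The *artificial alignment* has one column per SNP site: a sample contributes
its alternate base where it carries the SNP and the reference base
otherwise, so samples with no calls collapse onto the reference row.  The
0/1/2 matrix additionally keeps indels (reference 0, SNP 1, indel 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exclusivity import PresenceMatrix, Site
from .io_core import write_fasta


@dataclass
class ArtificialAlignment:
    column_sites: list[Site]
    sequences: dict[str, str]  # sample id -> sequence, insertion-ordered
    reference: str

    def __post_init__(self) -> None:
        n = len(self.column_sites)
        if len(self.reference) != n or any(
            len(s) != n for s in self.sequences.values()
        ):
            raise ValueError("all sequences must span every SNP column")

    def to_fasta(self, path) -> None:
        out = {"reference": self.reference}
        out.update(self.sequences)
        write_fasta(path, out)


@dataclass
class EncodedMatrix:
    sites: list[Site]
    sample_ids: list[str]
    codes: np.ndarray  # samples x sites, values in {0, 1, 2}

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s.chrom}:{s.pos}:{s.alt}" for s in self.sites]
        return pd.DataFrame(self.codes, index=self.sample_ids, columns=cols)


@dataclass
class TreeResult:
    newick: str
    labels: list[str]
    distances: np.ndarray
    branch_scale: Optional[dict[str, float]] = None


def build_artificial_alignment(matrix: PresenceMatrix) -> ArtificialAlignment:
    """One FASTA record per sample; column j holds the sample's alt base if
    it carries site j, else the reference base.  Indel sites are excluded
    (this view clusters SNPs only)."""
    matrix = matrix.drop_indels()
    sites = matrix.sites
    ref = "".join(s.ref for s in sites)
    seqs: dict[str, str] = {}
    for j, sid in enumerate(matrix.sample_ids):
        seqs[sid] = "".join(
            s.alt if matrix.incidence[i, j] else s.ref
            for i, s in enumerate(sites)
        )
    return ArtificialAlignment(column_sites=sites, sequences=seqs, reference=ref)


def encode_matrix(matrix: PresenceMatrix) -> EncodedMatrix:
    """0/1/2 coding over all sites: reference 0, SNP 1, indel 2."""
    site_code = np.array(
        [2 if s.is_indel else 1 for s in matrix.sites], dtype=np.int8
    )
    codes = (matrix.incidence.T * site_code[None, :]).astype(np.int8)
    return EncodedMatrix(
        sites=list(matrix.sites),
        sample_ids=matrix.sample_ids,
        codes=codes,
    )


def distance_matrix(
    data: ArtificialAlignment | EncodedMatrix, metric: Optional[str] = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise distances: uncorrected p-distance for alignments, Euclidean
    norm of code-vector differences for 0/1/2 matrices."""
    if isinstance(data, ArtificialAlignment):
        metric = metric or "p-distance"
        labels = list(data.sequences)
        n_cols = len(data.column_sites)
        if n_cols == 0:
            raise ValueError("alignment has zero columns")
        arr = np.array(
            [list(data.sequences[lbl]) for lbl in labels], dtype="U1"
        )
        if metric != "p-distance":
            raise ValueError(f"unsupported alignment metric {metric!r}")
        mism = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
        dist = mism / n_cols
    else:
        metric = metric or "euclidean"
        labels = list(data.sample_ids)
        if data.codes.shape[1] == 0:
            raise ValueError("encoded matrix has zero columns")
        if metric != "euclidean":
            raise ValueError(f"unsupported matrix metric {metric!r}")
        diff = data.codes[:, None, :].astype(float) - data.codes[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
    if len(labels) < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    return dist, labels


# ---------------------------------------------------------------------------
# neighbor joining (Saitou & Nei agglomeration)

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(
            f"{c.newick()}:{bl:.12g}" for c, bl in self.children
        )
        return f"({inner})"


def nj_tree(
    dist: np.ndarray,
    labels: Sequence[str],
    branch_scale: Optional[Mapping[str, float]] = None,
) -> TreeResult:
    """Classical neighbor joining on a distance matrix.

    Negative branch lengths are clamped to zero.  When ``branch_scale``
    maps each sample to its covered base pairs, every leaf's terminal
    branch is multiplied by max(covered_bp) / covered_bp(sample), the
    coverage correction applied when samples differ in observable sequence
    space.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape must match labels")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distance matrix must be symmetric, non-negative, "
                         "with a zero diagonal")

    scale: dict[str, float] = {}
    if branch_scale is not None:
        max_cov = max(branch_scale[lbl] for lbl in labels)
        scale = {lbl: max_cov / branch_scale[lbl] for lbl in labels}

    nodes: list[_Node] = [_Node(label=lbl) for lbl in labels]
    active = list(range(n))

    def attach(parent: _Node, child_idx: int, length: float) -> None:
        length = max(length, 0.0)
        child = nodes[child_idx]
        if not child.children and scale:
            length *= scale[child.label]
        parent.children.append((child, length))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        a, b = active[i_s], active[j_s]
        dij = d[a, b]
        li = 0.5 * dij + (r[i_s] - r[j_s]) / (2 * (m - 2))
        lj = dij - li
        parent = _Node()
        attach(parent, a, li)
        attach(parent, b, lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[a, :] + d[b, :] - dij)
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, :k] = new_row
        d[:k, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [k]

    # terminal star join of the last three nodes
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node()
    attach(root, a, la)
    attach(root, b, lb)
    attach(root, c, lc)

    dist_out = np.asarray(dist, dtype=float)
    return TreeResult(
        newick=root.newick() + ";",
        labels=list(labels),
        distances=dist_out,
        branch_scale=scale or None,
    )


def pca3(encoded: EncodedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """First three principal components of the centered 0/1/2 matrix.

    Returns (coordinates: samples x 3, explained_variance: 3).  The sign of
    each component is fixed by making its largest-magnitude loading
    positive, so outputs are reproducible.
    """
    X = encoded.codes.astype(float)
    n, p = X.shape
    if n < 3 or p < 3:
        raise ValueError("pca3 needs >= 3 samples and >= 3 sites")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        return np.zeros((n, 3)), np.zeros(3)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = 3
    coords = np.zeros((n, k))
    ev = np.zeros(k)
    avail = min(k, s.size)
    for comp in range(avail):
        load = vt[comp]
        j = int(np.argmax(np.abs(load)))
        sign = 1.0 if load[j] >= 0 else -1.0
        coords[:, comp] = sign * u[:, comp] * s[comp]
        ev[comp] = s[comp] ** 2 / max(n - 1, 1)
    return coords, ev
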