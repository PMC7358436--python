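"""Artificial alignment, 0/1/2 encoding, distances, neighbor joining, PCA."""

import numpy as np
import pytest
import dendropy

from mosscharter.clustering import (
    build_artificial_alignment,
    distance_matrix,
    encode_matrix,
    nj_tree,
    pca3,
)
from mosscharter.exclusivity import build_presence
from mosscharter.io_core import SampleName, VariantRecord
from mosscharter.synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    generate_reference,
)
from mosscharter.variant_filtering import cohort_filter


def _rec(pos, ref="A", alt="T", chrom="c1"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, dp=20,
                         ad_alt=19, gt="1")


def _sample(acc, rep=1, ped="P1"):
    return SampleName(acc, ped, "I", rep, "PE", "WTY")


def _bipartitions(newick, taxa):
    """Set of leaf-name frozensets induced by internal edges (unrooted)."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.encode_bipartitions()
    out = set()
    full = frozenset(taxa)
    for edge in tree.bipartition_edge_map.values():
        side = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        if 2 <= len(side) <= len(full) - 2:
            out.add(min(side, full - side, key=sorted))
    return out


def _is_monophyletic(newick, taxa, group):
    group = frozenset(group)
    full = frozenset(taxa)
    if len(group) in (1, len(full)):
        return True
    canon = min(group, full - group, key=sorted)
    return canon in _bipartitions(newick, taxa)


class TestArtificialAlignment:
    def test_columns_hold_alt_or_reference(self):
        samples = [
            (_sample("Gd"), [_rec(100)]),
            (_sample("Re"), []),
        ]
        aln = build_artificial_alignment(build_presence(samples))
        assert aln.sequences["Gd_P1_I_1_PE_WTY"] == "T"
        assert aln.sequences["Re_P1_I_1_PE_WTY"] == "A"
        assert aln.reference == "A"

    def test_carrier_of_all_sites_gets_concatenated_alts(self):
        recs = [_rec(100, "A", "T"), _rec(200, "C", "G"), _rec(300, "G", "A")]
        samples = [(_sample("Gd"), recs), (_sample("Re"), [])]
        aln = build_artificial_alignment(build_presence(samples))
        assert aln.sequences["Gd_P1_I_1_PE_WTY"] == "TGA"
        assert aln.sequences["Re_P1_I_1_PE_WTY"] == aln.reference == "ACG"

    def test_indel_columns_excluded(self):
        recs = [_rec(100), VariantRecord("c1", 200, "C", "CT", dp=20,
                                         ad_alt=19, gt="1")]
        samples = [(_sample("Gd"), recs), (_sample("Re"), [_rec(100)])]
        aln = build_artificial_alignment(build_presence(samples))
        assert len(aln.column_sites) == 1


class TestEncodeMatrix:
    def test_codes_zero_one_two(self):
        recs = [_rec(100), VariantRecord("c1", 200, "C", "CT", dp=20,
                                         ad_alt=19, gt="1")]
        samples = [(_sample("Gd"), recs), (_sample("Re"), [])]
        enc = encode_matrix(build_presence(samples))
        assert enc.codes.tolist() == [[1, 2], [0, 0]]


class TestDistances:
    def test_p_distance(self):
        samples = [
            (_sample("Gd"), [_rec(100)]),  # "TA"
            (_sample("Re"), [_rec(200, "A", "G")]),  # "AG" vs ref "AA"
        ]
        aln = build_artificial_alignment(build_presence(samples))
        d, labels = distance_matrix(aln)
        assert d[0, 1] == pytest.approx(1.0)  # both columns mismatch
        aln.sequences[labels[1]] = aln.sequences[labels[0]]
        d2, _ = distance_matrix(aln)
        assert d2[0, 1] == 0.0

    def test_p_distance_half(self):
        samples = [
            (_sample("Gd"), [_rec(100), _rec(200, "C", "G")]),
            (_sample("Re"), [_rec(200, "C", "G")]),
        ]
        aln = build_artificial_alignment(build_presence(samples))
        d, _ = distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.5)

    def test_euclidean_codes(self):
        recs_a = [_rec(100), VariantRecord("c1", 300, "G", "GT", dp=20,
                                           ad_alt=19, gt="1")]
        samples = [
            (_sample("Gd"), recs_a),
            (_sample("Re"), [_rec(200, "C", "G")]),
            (_sample("Ka"), []),
        ]
        enc = encode_matrix(build_presence(samples))
        d, labels = distance_matrix(enc)
        i, k = labels.index("Gd_P1_I_1_PE_WTY"), labels.index("Ka_P1_I_1_PE_WTY")
        assert d[i, k] == pytest.approx(np.sqrt(5))  # codes (1,0,2) vs zeros

    def test_p_distance_bounds_and_triangle(self, cohort):
        _, matrix, _ = cohort_filter(cohort.samples)
        aln = build_artificial_alignment(matrix)
        d, _ = distance_matrix(aln)
        assert (d >= 0).all() and (d <= 1).all()
        n = d.shape[0]
        for i in range(0, n, 5):
            for j in range(n):
                for k in range(0, n, 7):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def _random_additive_tree(rng, n_taxa):
    """Random binary topology with positive lengths; returns (dendropy tree,
    distance matrix, labels)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length = rng.uniform(0.5, 2.0)
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i != j:
                d[i, j] = pdm.distance(ti, tj)
    return tree, d, labels


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # distances from ((A:1,B:1):1,(C:1,D:1):1)
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 2, 3, 3],
                [2, 0, 3, 3],
                [3, 3, 0, 2],
                [3, 3, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(d, labels)
        assert _is_monophyletic(tree.newick, labels, {"A", "B"})
        assert _is_monophyletic(tree.newick, labels, {"C", "D"})

    def test_identical_samples_form_zero_length_cherry(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float)
        tree = nj_tree(d, labels)
        t = dendropy.Tree.get(data=tree.newick, schema="newick", preserve_underscores=True)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(0.0)

    def test_too_few_taxa_raise(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["A", "B"])

    @pytest.mark.parametrize("seed", range(10))
    def test_random_six_taxon_additive_trees_reconstructed_exactly(self, seed):
        import random

        rng = random.Random(seed)
        true_tree, d, labels = _random_additive_tree(rng, 6)
        result = nj_tree(d, labels)
        true_newick = true_tree.as_string(schema="newick")
        assert _bipartitions(result.newick, labels) == _bipartitions(
            true_newick, labels
        )
        # additive distances are reproduced by the reconstructed tree
        t = dendropy.Tree.get(data=result.newick, schema="newick",
                              taxon_namespace=true_tree.taxon_namespace)
        pdm = t.phylogenetic_distance_matrix()
        taxa = list(true_tree.taxon_namespace)
        for i, ti in enumerate(taxa):
            for j, tj in enumerate(taxa):
                if i < j:
                    li = labels.index(ti.label)
                    lj = labels.index(tj.label)
                    assert pdm.distance(ti, tj) == pytest.approx(
                        d[li, lj], abs=1e-9
                    )

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_skbio_on_noisy_distances(self, seed):
        # independent-oracle route: scikit-bio's neighbor joining on the
        # same non-additive random matrix must produce the same topology
        from io import StringIO

        from skbio import DistanceMatrix, TreeNode
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        n = 8
        labels = [f"s{i}" for i in range(n)]
        raw = rng.uniform(1.0, 10.0, size=(n, n))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        ours = nj_tree(d, labels)
        theirs = skbio_nj(DistanceMatrix(d, ids=labels))
        ours_tree = TreeNode.read(StringIO(ours.newick))
        assert ours_tree.compare_rfd(theirs) == 0.0

    def test_branch_scale_multiplies_terminal_branches(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            dtype=float,
        )
        plain = nj_tree(d, labels)
        scaled = nj_tree(
            d, labels, branch_scale={"A": 50, "B": 100, "C": 100, "D": 100}
        )
        def leaf_lengths(newick):
            t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
            return {
                lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()
            }
        lp, ls = leaf_lengths(plain.newick), leaf_lengths(scaled.newick)
        assert ls["A"] == pytest.approx(2 * lp["A"])  # max_cov / cov = 2
        for lbl in "BCD":
            assert ls[lbl] == pytest.approx(lp[lbl])

    def test_cohort_samples_monophyletic_by_accession(self, cohort):
        _, matrix, _ = cohort_filter(cohort.samples)
        aln = build_artificial_alignment(matrix)
        d, labels = distance_matrix(aln)
        tree = nj_tree(d, labels)
        for acc in ("Gd", "Re", "Ka", "Vx", "Wi"):
            group = {l for l in labels if l.startswith(acc + "_")}
            assert _is_monophyletic(tree.newick, labels, group)


class TestPca3:
    def test_duplicated_samples_identical_coordinates(self, cohort):
        _, matrix, _ = cohort_filter(cohort.samples)
        enc = encode_matrix(matrix)
        enc.codes = np.vstack([enc.codes, enc.codes[0]])
        enc.sample_ids = enc.sample_ids + ["dup"]
        coords, ev = pca3(enc)
        assert np.allclose(coords[0], coords[-1], atol=1e-9)
        assert ev[0] >= ev[1] >= ev[2] >= 0

    def test_matches_full_eigendecomposition_oracle(self, cohort):
        _, matrix, _ = cohort_filter(cohort.samples)
        enc = encode_matrix(matrix)
        coords, ev = pca3(enc)
        X = enc.codes.astype(float)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(ev, eigvals[:3], atol=1e-8)
        # coordinate magnitudes match projections up to sign
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for comp in range(3):
            proj = Xc @ v[:, order[comp]]
            assert np.allclose(np.abs(coords[:, comp]), np.abs(proj),
                               atol=1e-8)

    def test_two_cluster_matrix_separates_on_pc1(self):
        from mosscharter.clustering import EncodedMatrix
        from mosscharter.exclusivity import Site

        rng = np.random.default_rng(0)
        base = np.zeros((10, 20), dtype=np.int8)
        base[:5, :10] = 1
        base[5:, 10:] = 1
        flip = rng.random((10, 20)) < 0.05
        codes = np.where(flip, 1 - base, base).astype(np.int8)
        enc = EncodedMatrix(
            sites=[Site("c1", i + 1, "T", "A", False) for i in range(20)],
            sample_ids=[f"s{i}" for i in range(10)],
            codes=codes,
        )
        coords, _ = pca3(enc)
        a, b = coords[:5, 0], coords[5:, 0]
        assert min(a) > max(b) or min(b) > max(a)

    def test_constant_matrix_gives_zero_coordinates(self):
        from mosscharter.clustering import EncodedMatrix
        from mosscharter.exclusivity import Site

        enc = EncodedMatrix(
            sites=[Site("c1", i + 1, "T", "A", False) for i in range(4)],
            sample_ids=["a", "b", "c"],
            codes=np.ones((3, 4), dtype=np.int8),
        )
        coords, ev = pca3(enc)
        assert np.all(coords == 0) and np.all(ev == 0)


class TestClusteringRecovery:
    def test_monophyly_rate_over_seeds(self):
        """With >= 50 exclusive SNPs per accession, NJ groups samples
        monophyletically by accession in >= 95% of seeded replicates."""
        n_ok = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SyntheticConfig(
                snps_exclusive_per_accession=(50, 60, 80, 100, 120),
                seed=1000 + seed,
            )
            genome, genes, spikeins = generate_reference(cfg)
            cohort = generate_cohort(cfg, genome, genes, spikeins)
            _, matrix, _ = cohort_filter(cohort.samples)
            aln = build_artificial_alignment(matrix)
            d, labels = distance_matrix(aln)
            tree = nj_tree(d, labels)
            ok = all(
                _is_monophyletic(
                    tree.newick, labels,
                    {l for l in labels if l.startswith(acc + "_")},
                )
                for acc in cfg.accessions
            )
            n_ok += ok
        assert n_ok / n_rep >= 0.95
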