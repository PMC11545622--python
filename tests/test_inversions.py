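"""Local PCA, MDS, permutation test, karyotype clustering and LD checks."""

import numpy as np
import pytest

from islescan.io import MISSING
from islescan.inversions import (
    InversionCandidate,
    classify_inversions,
    genotype_clusters,
    heterozygosity_check,
    local_pca_windows,
    mds_embed,
    mds_outlier_windows,
    permutation_chromosome_test,
    region_ld,
    window_distance,
)

from conftest import make_site_table


def pca_windows_from(gt, snps_per_window, positions=None, chrom="chr1"):
    table = make_site_table(gt, positions=positions, is_variant=np.ones(len(gt), bool),
                            chrom=chrom)
    return local_pca_windows(table, snps_per_window=snps_per_window)


class TestLocalPCA:
    def test_partition_keeps_half_full_terminal(self, rng):
        gt = rng.integers(0, 3, size=(2500, 10)).astype(np.int8)
        wins = pca_windows_from(gt, 1000)
        assert [w.n_snps for w in wins] == [1000, 1000, 500]

    def test_short_terminal_dropped(self, rng):
        gt = rng.integers(0, 3, size=(2400, 10)).astype(np.int8)
        wins = pca_windows_from(gt, 1000)
        assert [w.n_snps for w in wins] == [1000, 1000]

    def test_identical_samples_zero_eigenvalues(self):
        gt = np.tile(np.array([[1]] * 50, dtype=np.int8), (1, 8))
        wins = pca_windows_from(gt, 50)
        np.testing.assert_allclose(wins[0].eigenvalues, 0, atol=1e-12)

    def test_eigenvalues_match_full_decomposition(self, rng):
        for _ in range(10):
            gt = rng.integers(0, 3, size=(80, 12)).astype(np.int8)
            w = pca_windows_from(gt, 80)[0]
            X = gt.T.astype(float)
            X = X - X.mean(axis=0)
            C = X @ X.T / (80 - 1)
            full = np.sort(np.linalg.eigvalsh(C))[::-1][:2]
            np.testing.assert_allclose(w.eigenvalues, full, atol=1e-8)


class TestWindowDistance:
    def test_zero_on_self(self, rng):
        gt = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        w = pca_windows_from(gt, 60)[0]
        assert window_distance(w, w) == 0.0

    def test_sign_flip_invariant(self, rng):
        gt = rng.integers(0, 3, size=(60, 10)).astype(np.int8)
        w1 = pca_windows_from(gt, 60)[0]
        import copy

        w2 = copy.deepcopy(w1)
        w2.scores[:, 0] *= -1  # PC1 sign is arbitrary
        assert window_distance(w1, w2) == pytest.approx(0.0, abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        wins = []
        for _ in range(12):
            gt = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
            wins.append(pca_windows_from(gt, 50)[0])
        for _ in range(50):
            a, b, c = rng.choice(12, 3, replace=False)
            dab = window_distance(wins[a], wins[b])
            dba = window_distance(wins[b], wins[a])
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= window_distance(wins[a], wins[c]) + window_distance(
                wins[c], wins[b]
            ) + 1e-9


class TestMDS:
    def test_zero_distances_zero_coordinates(self):
        emb = mds_embed(np.zeros((5, 5)), k=4)
        np.testing.assert_allclose(emb.coordinates, 0, atol=1e-12)

    def test_line_recovered_on_first_axis(self):
        x = np.linspace(0, 10, 30)
        dist = np.abs(x[:, None] - x[None, :])
        emb = mds_embed(dist, k=5)
        r = np.corrcoef(emb.coordinates[:, 0], x)[0, 1]
        assert abs(r) > 0.999

    def test_euclidean_input_reproduced(self, rng):
        pts = rng.normal(size=(20, 3))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = mds_embed(dist, k=10)
        recon = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(recon, dist, atol=1e-6)


class TestMDSOutliers:
    def embed(self, coords):
        from islescan.inversions import MDSEmbedding

        return MDSEmbedding(coordinates=coords, eigenvalues=np.ones(coords.shape[1]))

    def test_normal_coordinates_rarely_flagged(self, rng):
        coords = rng.standard_normal((1000, 3))
        flags = mds_outlier_windows(self.embed(coords))
        assert flags.sum(axis=0).max() <= 2

    def test_displaced_window_flagged(self, rng):
        coords = rng.standard_normal((200, 2))
        coords[17, 0] += 10 * coords[:, 0].std()
        flags = mds_outlier_windows(self.embed(coords))
        assert flags[17, 0]

    def test_constant_axis_guarded(self):
        coords = np.ones((50, 2))
        assert not mds_outlier_windows(self.embed(coords)).any()


class TestPermutationTest:
    def test_concentration_detected(self, rng):
        chroms = np.repeat([f"c{i}" for i in range(30)], 20)
        mask = np.zeros(600, bool)
        mask[:10] = True  # all outliers on c0
        p = permutation_chromosome_test(mask, chroms, n_perm=1000, rng=rng)
        assert p["c0"] <= 0.01

    def test_proportional_scatter_not_significant(self, rng):
        chroms = np.repeat(["c0", "c1", "c2"], 100)
        mask = np.zeros(300, bool)
        mask[rng.choice(300, 15, replace=False)] = True
        p = permutation_chromosome_test(mask, chroms, n_perm=500, rng=rng)
        assert min(p.values()) > 0.01

    def test_deterministic_given_seed(self):
        chroms = np.repeat(["a", "b"], 25)
        mask = np.zeros(50, bool)
        mask[[1, 2, 3]] = True
        p1 = permutation_chromosome_test(mask, chroms, 200, np.random.default_rng(5))
        p2 = permutation_chromosome_test(mask, chroms, 200, np.random.default_rng(5))
        assert p1 == p2


class TestValidationChecks:
    def test_kmeans_from_stated_centres(self):
        # PC1-like scores with three well-separated groups
        scores = np.array([-5.1, -5.0, -4.9, -0.1, 0.1, 5.0, 5.2])
        # feed a genotype matrix whose PC1 reproduces these scores:
        # one SNP column proportional to the scores (plus centring)
        gt = np.tile((scores - scores.min()).round().astype(np.int8), (40, 1))
        labels, pc1 = genotype_clusters(gt)
        sizes = tuple(int((labels == g).sum()) for g in range(3))
        # PC1 orientation is arbitrary: the {-5.1,-5.0,-4.9} trio forms one
        # extreme cluster, the pairs form the middle and other extreme
        assert sorted(sizes) == [2, 2, 3]
        assert len({labels[0], labels[1], labels[2]}) == 1
        assert len({labels[3], labels[4]}) == 1 and labels[3] == 1
        assert len({labels[5], labels[6]}) == 1

    def test_degenerate_scores_single_cluster(self):
        gt = np.ones((30, 8), dtype=np.int8)
        labels, _ = genotype_clusters(gt)
        assert set(labels) == {0}

    def test_heterozygosity_ordering(self):
        gt = np.zeros((100, 9), dtype=np.int8)
        gt[:, 3:6] = 1  # middle cluster heterozygous everywhere
        gt[:5, 6:] = 2
        labels = np.repeat([0, 1, 2], 3)
        means, ok = heterozygosity_check(gt, labels)
        assert ok and means[1] == pytest.approx(1.0)

    def test_heterozygosity_fails_when_mid_not_highest(self):
        gt = np.zeros((50, 6), dtype=np.int8)
        gt[:, :2] = 1  # low cluster most heterozygous
        labels = np.repeat([0, 1, 2], 2)
        _, ok = heterozygosity_check(gt, labels)
        assert not ok

    def test_empty_middle_group_fails(self):
        gt = np.zeros((50, 4), dtype=np.int8)
        labels = np.array([0, 0, 2, 2])
        _, ok = heterozygosity_check(gt, labels)
        assert not ok

    def test_duplicated_snps_r2_one(self):
        row = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=np.int8)
        gt = np.tile(row, (10, 1))
        mean_r2, mat = region_ld(gt)
        assert mean_r2 == pytest.approx(1.0)

    def test_independent_snps_low_r2(self, rng):
        gt = rng.integers(0, 3, size=(150, 24)).astype(np.int8)
        mean_r2, _ = region_ld(gt)
        assert mean_r2 < 0.1

    def test_conjunction_requires_high_ld(self):
        cand = InversionCandidate(
            "chr1", 1, 100, 0, [0], cluster_sizes=(3, 3, 3),
            mean_het=(0.1, 0.5, 0.1), mean_r2=0.05,
            checks={"three_clusters": True, "het_elevated": True},
        )
        classify_inversions([cand])
        assert cand.status == "rejected"
        cand.mean_r2 = 0.5
        classify_inversions([cand])
        assert cand.status == "putative_inversion"


class TestEndToEnd:
    def planted(self, seed):
        from islescan.simulate import Feature, SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            seed=seed, chrom_plan=(("chr1", 2_000_000),),
            features=(Feature("inversion", "chr1", 900_001, 950_000, {"q": 0.5, "d": 0.3}),),
        )
        return simulate_dataset(cfg)

    def test_planted_inversion_recovered_with_tight_boundaries(self):
        from islescan.inversions import detect_inversions

        ds = self.planted(51)
        cands, _ = detect_inversions(ds.table, snps_per_window=100, n_perm=200, seed=3)
        putative = [c for c in cands if c.status == "putative_inversion"]
        assert len(putative) == 1
        c = putative[0]
        window_bp = 100 / 0.01  # snps_per_window / variant density
        assert abs(c.start - 900_001) <= window_bp
        assert abs(c.end - 950_000) <= window_bp

    def test_detection_invariant_to_allele_label_swap(self):
        from islescan.inversions import detect_inversions

        ds = self.planted(52)
        cands1, _ = detect_inversions(ds.table, snps_per_window=100, n_perm=50, seed=3)
        t2 = ds.table.subset(np.ones(ds.table.n_sites, bool))
        g = t2.genotypes.copy()
        swap = t2.is_variant  # flip every variant site's labels
        sub = g[swap]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        g[swap] = sub
        t2.genotypes = g
        cands2, _ = detect_inversions(t2, snps_per_window=100, n_perm=50, seed=3)
        spans1 = sorted((c.chrom, c.start, c.end, c.status) for c in cands1)
        spans2 = sorted((c.chrom, c.start, c.end, c.status) for c in cands2)
        assert spans1 == spans2

    def test_null_dataset_yields_no_putative_inversions(self):
        from islescan.inversions import detect_inversions
        from islescan.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(seed=53, chrom_plan=(("chr1", 2_000_000),))
        ds = simulate_dataset(cfg)
        cands, _ = detect_inversions(ds.table, snps_per_window=100, n_perm=50, seed=3)
        assert all(c.status == "rejected" for c in cands)
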