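"""Windowed estimators against hand-worked values and brute-force oracles.

The oracles enumerate allele pairs (pi, d_xy), re-derive the
Weir-Cockerham variance components from the textbook formulas in an
independent coding, and recompute Tajima's D from first principles.
"""

import itertools

import numpy as np
import pytest

from islescan.io import MISSING
from islescan.windows import (
    compute_landscape,
    site_pi_components,
    tile_windows,
    window_dxy,
    window_fst,
    window_pi,
    window_tajimas_d,
)

from conftest import even_split, make_site_table

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def site_alleles(genotypes_row):
    """Flatten one site's diploid codes into a list of allele values."""
    out = []
    for g in genotypes_row:
        if g == MISSING:
            continue
        out.extend([1, 1] if g == 2 else ([0, 1] if g == 1 else [0, 0]))
    return out


def brute_pi(gt):
    diffs = comps = 0
    for row in np.atleast_2d(gt):
        alleles = site_alleles(row)
        for a, b in itertools.combinations(alleles, 2):
            comps += 1
            diffs += a != b
    return diffs / comps if comps else np.nan


def brute_dxy(ga, gb):
    diffs = comps = 0
    for ra, rb in zip(np.atleast_2d(ga), np.atleast_2d(gb)):
        for a in site_alleles(ra):
            for b in site_alleles(rb):
                comps += 1
                diffs += a != b
    return diffs / comps if comps else np.nan


def brute_wc_fst(ga, gb):
    """Independent Weir & Cockerham (1984) coding, r=2, site loop in python."""
    A = B = C = 0.0
    any_valid = False
    for ra, rb in zip(np.atleast_2d(ga), np.atleast_2d(gb)):
        ra = ra[ra != MISSING]
        rb = rb[rb != MISSING]
        n1, n2 = len(ra), len(rb)
        nbar = (n1 + n2) / 2
        if n1 < 1 or n2 < 1 or nbar <= 1:
            continue
        r = 2
        p1 = ra.sum() / (2 * n1)
        p2 = rb.sum() / (2 * n2)
        h1 = (ra == 1).mean()
        h2 = (rb == 1).mean()
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        any_valid = True
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    den = A + B + C
    return A / den if any_valid and den > 0 else np.nan


def brute_tajimas_d(gt):
    gt = np.atleast_2d(gt)
    seg_n = []
    khat = 0.0
    for row in gt:
        alleles = site_alleles(row)
        n = len(alleles)
        if n < 4:
            continue
        k = sum(alleles)
        if 0 < k < n:
            seg_n.append(n)
            khat += k * (n - k) / (n * (n - 1) / 2)
    S = len(seg_n)
    if S == 0:
        return np.nan
    n = int(round(S / sum(1 / x for x in seg_n)))
    if n < 4:
        return np.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (khat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def random_genotypes(rng, n_sites, n_samples, missing_rate=0.1):
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = MISSING
    return g


# ---------------------------------------------------------------------------
# hand-worked examples
# ---------------------------------------------------------------------------


class TestHandWorked:
    def test_site_components_two_hets(self):
        assert site_pi_components(np.array([1, 1], dtype=np.int8)) == (4, 6)

    def test_site_components_invariant_and_missing(self):
        assert site_pi_components(np.array([0, 0], dtype=np.int8)) == (0, 6)
        assert site_pi_components(np.array([MISSING, MISSING], dtype=np.int8)) == (0, 0)

    def test_pi_deflation_without_invariant_sites(self):
        window = np.array([[0, 0], [0, 0], [0, 0], [1, 1]], dtype=np.int8)
        assert window_pi(window) == pytest.approx(4 / 24)
        assert window_pi(window[3:]) == pytest.approx(4 / 6)

    def test_dxy_fixed_difference_with_shared_invariants(self):
        ga = np.array([[0, 0]] * 4, dtype=np.int8)
        gb = np.array([[0, 0], [0, 0], [0, 0], [2, 2]], dtype=np.int8)
        assert window_dxy(ga, gb) == pytest.approx(16 / 64)

    def test_dxy_identical_monomorphic(self):
        g = np.zeros((3, 2), dtype=np.int8)
        assert window_dxy(g, g) == 0.0

    def test_fst_fixed_difference_is_one(self):
        ga = np.full((1, 6), 0, dtype=np.int8)
        gb = np.full((1, 6), 2, dtype=np.int8)
        assert window_fst(ga, gb) == pytest.approx(1.0)

    def test_fst_fully_missing_population_undefined(self):
        ga = np.full((2, 4), MISSING, dtype=np.int8)
        gb = np.array([[1, 1, 0, 0]] * 2, dtype=np.int8)
        assert np.isnan(window_fst(ga, gb))

    def test_tajimas_d_no_segregating_sites(self):
        assert np.isnan(window_tajimas_d(np.zeros((5, 10), dtype=np.int8)))

    def test_tajimas_d_singletons_negative(self):
        # n = 20 alleles, S = 5, every segregating site a singleton
        g = np.zeros((5, 10), dtype=np.int8)
        for i in range(5):
            g[i, i] = 1
        d = window_tajimas_d(g)
        assert d < 0
        assert d == pytest.approx(brute_tajimas_d(g), abs=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalence on random windows
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    N_WINDOWS = 300

    def test_pi_dxy_fst_tajd_match_brute_force(self, rng):
        for _ in range(self.N_WINDOWS):
            n_sites = int(rng.integers(1, 12))
            na, nb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            ga = random_genotypes(rng, n_sites, na)
            gb = random_genotypes(rng, n_sites, nb)
            np.testing.assert_allclose(window_pi(ga), brute_pi(ga), atol=1e-12)
            np.testing.assert_allclose(window_dxy(ga, gb), brute_dxy(ga, gb), atol=1e-12)
            np.testing.assert_allclose(window_fst(ga, gb), brute_wc_fst(ga, gb), atol=1e-10)
            np.testing.assert_allclose(
                window_tajimas_d(ga), brute_tajimas_d(ga), atol=1e-10
            )

    def test_single_site_equal_frequencies(self):
        # p = 0.5 both sides, 12+12 diploids: exact textbook value
        ga = np.array([[1] * 12], dtype=np.int8)
        gb = np.array([[1] * 12], dtype=np.int8)
        assert window_fst(ga, gb) == pytest.approx(brute_wc_fst(ga, gb), abs=1e-12)


# ---------------------------------------------------------------------------
# invariants and landscape assembly
# ---------------------------------------------------------------------------


class TestProperties:
    def test_allele_label_swap_invariance(self, rng):
        for _ in range(20):
            ga = random_genotypes(rng, 8, 5)
            gb = random_genotypes(rng, 8, 5)
            swap = rng.random(8) < 0.5
            ga2, gb2 = ga.copy(), gb.copy()
            for g in (ga2, gb2):
                sub = g[swap]
                sub[sub != MISSING] = 2 - sub[sub != MISSING]
                g[swap] = sub
            np.testing.assert_allclose(window_pi(ga), window_pi(ga2), atol=1e-12)
            np.testing.assert_allclose(window_dxy(ga, gb), window_dxy(ga2, gb2), atol=1e-12)

    def test_bounds_on_filtered_data(self, neutral_dataset):
        from islescan.io import filter_sites

        land = compute_landscape(filter_sites(neutral_dataset.table), neutral_dataset.split)
        for col in ("dxy", "pi_island", "pi_mainland"):
            vals = land[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()

    def test_self_dxy_matches_pooled_pi_in_expectation(self, rng):
        # random halves of one population: d_xy ~= pi of the pool
        g = random_genotypes(rng, 4000, 12, missing_rate=0.0)
        d = window_dxy(g[:, :6], g[:, 6:])
        p = window_pi(g)
        assert d == pytest.approx(p, rel=0.02)

    def test_tiling(self):
        assert tile_windows(25_000, 10_000) == [(1, 10_000), (10_001, 20_000), (20_001, 25_000)]
        assert tile_windows(0, 10_000) == []

    def test_landscape_sample_permutation_invariance(self, neutral_dataset, rng):
        table = neutral_dataset.table
        split = neutral_dataset.split
        land1 = compute_landscape(table, split, window_size=50_000)
        perm = rng.permutation(table.n_samples)
        t2 = table.subset(np.ones(table.n_sites, bool))
        t2.samples = [table.samples[i] for i in perm]
        t2.genotypes = table.genotypes[:, perm]
        t2.depth = table.depth[:, perm]
        t2.gq = table.gq[:, perm]
        land2 = compute_landscape(t2, split, window_size=50_000)
        for col in ("fst", "dxy", "pi_island", "pi_mainland", "tajd_island", "tajd_mainland"):
            np.testing.assert_allclose(land1[col], land2[col], atol=1e-12)

    def test_landscape_locality_across_chromosomes(self):
        g1 = np.array([[1, 1, 0, 0], [0, 2, 0, 0]], dtype=np.int8)
        g2 = np.array([[2, 2, 0, 0]], dtype=np.int8)
        t1 = make_site_table(g1, positions=[100, 200], chrom="chr1")
        t2 = make_site_table(g2, positions=[150], chrom="chr2")
        combined = make_site_table(
            np.vstack([g1, g2]), positions=[100, 200, 150]
        )
        combined.chrom = np.array(["chr1", "chr1", "chr2"], dtype=object)
        split = even_split(t1.samples)
        import pandas as pd

        sep = pd.concat(
            [compute_landscape(t1, split), compute_landscape(t2, split)],
            ignore_index=True,
        )
        joint = compute_landscape(combined, split)
        pd.testing.assert_frame_equal(joint, sep)

    def test_empty_window_row_present(self):
        g = np.array([[1, 1, 0, 0]], dtype=np.int8)
        table = make_site_table(g, positions=[15_000])
        land = compute_landscape(table, even_split(table.samples))
        assert len(land) == 2
        first = land.iloc[0]
        assert np.isnan(first.fst) and np.isnan(first.pi_island)
        assert first.mean_depth == 0.0 and first.n_sites == 0


class TestSimulationCalibration:
    def test_balding_nichols_f02_recovers_fst(self):
        from islescan.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            seed=77, chrom_plan=(("chr1", 500_000),), f_island=0.2, f_mainland=0.2,
            missing_rate=0.0,
        )
        ds = simulate_dataset(cfg)
        t = ds.table
        var = t.is_variant
        isl = ds.split.indices(t, "island")
        mld = ds.split.indices(t, "mainland")
        fst = window_fst(t.genotypes[var][:, isl], t.genotypes[var][:, mld])
        assert 0.17 <= fst <= 0.23

    def test_neutral_background_tajimas_d_band(self):
        from islescan.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            seed=78, chrom_plan=(("chr1", 2_000_000),), f_island=0.0, f_mainland=0.0
        )
        ds = simulate_dataset(cfg)
        land = compute_landscape(ds.table, ds.split)
        assert len(land) >= 200
        assert abs(land.tajd_island.mean()) <= 0.5
        assert abs(land.tajd_mainland.mean()) <= 0.5
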