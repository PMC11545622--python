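"""Windowed landscape statistics in non-overlapping windows.

All estimators are invariant-site aware: pi and d_xy ratios put every
genotyped site (variant or not) into the denominator, so missing data and
monomorphic sequence are not conflated.  Windows tile each chromosome
from position 1; the terminal window may be short.  Undefined values
(zero denominator, too few chromosomes for Tajima's D) propagate as NaN
and are never coerced to zero.

Estimators
----------
pi, d_xy      ratio-of-sums over per-site difference / comparison counts
F_ST          Weir & Cockerham (1984) variance components, window-level
              ratio of sums (``hudson`` available as an alternative)
Tajima's D    Tajima (1989), constants at the window's harmonic-mean
              allele sample size
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from islescan.io import ISLAND, MAINLAND, MISSING, PopulationSplit, SiteTable

LANDSCAPE_COLUMNS = [
    "chrom", "start", "end", "n_sites", "n_variant", "fst", "dxy",
    "pi_island", "pi_mainland", "tajd_island", "tajd_mainland", "mean_depth",
]


def _allele_counts(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count) for a genotype block."""
    gt = np.atleast_2d(gt)
    called = gt != MISSING
    n_alleles = 2 * called.sum(axis=1)
    n_alt = np.where(called, gt, 0).sum(axis=1)
    return n_alt.astype(np.int64), n_alleles.astype(np.int64)


def site_pi_components(genotypes: np.ndarray) -> tuple[int, int]:
    """Pairwise difference and comparison counts at one site, one population.

    ``comparisons = C(n_alleles, 2)`` and ``diffs = n_alt * (n_alleles -
    n_alt)``; a fully missing site contributes ``(0, 0)`` and an invariant
    site ``(0, C(n_alleles, 2))``.
    """
    n_alt, n_alleles = _allele_counts(np.asarray(genotypes).reshape(1, -1))
    comps = int(n_alleles[0] * (n_alleles[0] - 1) // 2)
    diffs = int(n_alt[0] * (n_alleles[0] - n_alt[0]))
    return diffs, comps


def window_pi(genotypes: np.ndarray) -> float:
    """Nucleotide diversity over a window: sum(diffs) / sum(comparisons).

    ``genotypes`` holds every site of the window (variant and invariant)
    for one population, shape (n_sites, n_samples).  NaN when no pair of
    alleles was genotyped anywhere in the window.
    """
    gt = np.atleast_2d(genotypes)
    if gt.shape[0] == 0:
        return np.nan
    n_alt, n_alleles = _allele_counts(gt)
    comps = (n_alleles * (n_alleles - 1) // 2).sum()
    diffs = (n_alt * (n_alleles - n_alt)).sum()
    return float(diffs / comps) if comps > 0 else np.nan


def window_dxy(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Absolute divergence between two populations over a window.

    Per site, ``diffs = c_a (n_b - c_b) + (n_a - c_a) c_b`` over the
    ``n_a * n_b`` inter-population allele pairs; the window value is the
    ratio of sums across all sites.  NaN when no inter-population pair is
    genotyped.
    """
    ga, gb = np.atleast_2d(genotypes_a), np.atleast_2d(genotypes_b)
    if ga.shape[0] == 0:
        return np.nan
    ca, na = _allele_counts(ga)
    cb, nb = _allele_counts(gb)
    diffs = (ca * (nb - cb) + (na - ca) * cb).sum()
    comps = (na * nb).sum()
    return float(diffs / comps) if comps > 0 else np.nan


def _wc84_components(ga: np.ndarray, gb: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components a, b, c.

    Two populations, diploid individuals, unequal and per-site sample
    sizes.  Sites with fewer than one called individual in either
    population, or mean sample size <= 1, are excluded (zero weight).
    """
    ga, gb = np.atleast_2d(ga), np.atleast_2d(gb)
    called_a, called_b = ga != MISSING, gb != MISSING
    na = called_a.sum(axis=1).astype(float)  # individuals
    nb = called_b.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(called_a, ga, 0).sum(axis=1) / (2 * na)
        pb = np.where(called_b, gb, 0).sum(axis=1) / (2 * nb)
        ha = (ga == 1).sum(axis=1) / na
        hb = (gb == 1).sum(axis=1) / nb

        nbar = (na + nb) / 2.0
        nc = 2.0 * nbar - (na**2 + nb**2) / (2.0 * nbar)
        pbar = (na * pa + nb * pb) / (2.0 * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / nbar
        hbar = (na * ha + nb * hb) / (2.0 * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    valid = (na >= 1) & (nb >= 1) & (nbar > 1) & (nc > 0)
    return a, b, c, valid


def _hudson_components(ga: np.ndarray, gb: np.ndarray):
    """Per-site Hudson F_ST numerator/denominator (Bhatia et al. 2013 form)."""
    ga, gb = np.atleast_2d(ga), np.atleast_2d(gb)
    ca, na = _allele_counts(ga)
    cb, nb = _allele_counts(gb)
    na_f, nb_f = na.astype(float), nb.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa, pb = ca / na_f, cb / nb_f
        num = (pa - pb) ** 2 - pa * (1 - pa) / (na_f - 1) - pb * (1 - pb) / (nb_f - 1)
        den = pa * (1 - pb) + pb * (1 - pa)
    valid = (na >= 2) & (nb >= 2)
    return num, den, valid


def window_fst(
    genotypes_a: np.ndarray, genotypes_b: np.ndarray, estimator: str = "wc84"
) -> float:
    """Window F_ST as a ratio of summed per-site components over variant sites.

    NaN when the summed denominator is non-positive or no variant site is
    usable (e.g. one population entirely missing).
    """
    if estimator == "wc84":
        a, b, c, valid = _wc84_components(genotypes_a, genotypes_b)
        num = np.nansum(a[valid])
        den = np.nansum((a + b + c)[valid])
    elif estimator == "hudson":
        num_s, den_s, valid = _hudson_components(genotypes_a, genotypes_b)
        num = np.nansum(num_s[valid])
        den = np.nansum(den_s[valid])
    else:
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    if not np.any(valid) or den <= 0:
        return np.nan
    return float(num / den)


def tajimas_d_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for allele sample size ``n``."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def window_tajimas_d(genotypes: np.ndarray) -> float:
    """Tajima's D for one population over a window's variant sites.

    Segregating sites require at least two called genotypes.  With missing
    data the allele sample size varies by site; the standard constants are
    evaluated once per window at the rounded harmonic mean of the per-site
    allele counts.  NaN when S = 0 or the effective n is below 4.
    """
    gt = np.atleast_2d(genotypes)
    if gt.shape[0] == 0:
        return np.nan
    n_alt, n_alleles = _allele_counts(gt)
    seg = (n_alt > 0) & (n_alt < n_alleles) & (n_alleles >= 4)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    n_seg_alleles = n_alleles[seg].astype(float)
    n_eff = int(round(S / (1.0 / n_seg_alleles).sum()))
    if n_eff < 4:
        return np.nan
    k = (
        n_alt[seg] * (n_alleles[seg] - n_alt[seg])
        / (n_alleles[seg] * (n_alleles[seg] - 1) / 2.0)
    ).sum()
    c = tajimas_d_constants(n_eff)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:
        return np.nan
    return float((k - S / c["a1"]) / np.sqrt(var))


def tile_windows(length: int, window_size: int) -> list[tuple[int, int]]:
    """1-based closed windows tiling ``1..length`` (terminal window short)."""
    if length < 1:
        return []
    starts = np.arange(1, length + 1, window_size)
    return [(int(s), int(min(s + window_size - 1, length))) for s in starts]


def compute_landscape(
    table: SiteTable,
    split: PopulationSplit,
    window_size: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    fst_estimator: str = "wc84",
) -> pd.DataFrame:
    """Per-window landscape table over every chromosome of ``table``.

    Every window is reported, including empty ones (all statistics NaN,
    ``mean_depth`` 0).  Chromosome lengths default to the last site
    position seen on each chromosome.

    Returns a DataFrame with columns ``chrom, start, end, n_sites,
    n_variant, fst, dxy, pi_island, pi_mainland, tajd_island,
    tajd_mainland, mean_depth``.
    """
    isl = split.indices(table, ISLAND)
    mld = split.indices(table, MAINLAND)
    rows = []
    for chrom in table.chromosomes():
        sub = table.for_chrom(chrom)
        length = int(chrom_lengths[chrom]) if chrom_lengths else int(sub.pos.max())
        usable = ~(sub.is_indel | sub.is_multiallelic)
        for start, end in tile_windows(length, window_size):
            lo = np.searchsorted(sub.pos, start, side="left")
            hi = np.searchsorted(sub.pos, end, side="right")
            idx = np.arange(lo, hi)[usable[lo:hi]]
            g = sub.genotypes[idx]
            g_isl, g_mld = g[:, isl], g[:, mld]
            var = sub.is_variant[idx]

            _, n_all = _allele_counts(g) if len(idx) else (None, np.zeros(0, dtype=int))
            n_sites = int((n_all >= 2).sum())
            n_variant = int(var.sum())

            depth_block = sub.depth[lo:hi]
            dvals = depth_block[depth_block != MISSING]
            mean_depth = float(dvals.mean()) if dvals.size else 0.0

            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": n_sites,
                    "n_variant": n_variant,
                    "fst": window_fst(g_isl[var], g_mld[var], estimator=fst_estimator)
                    if n_variant
                    else np.nan,
                    "dxy": window_dxy(g_isl, g_mld),
                    "pi_island": window_pi(g_isl),
                    "pi_mainland": window_pi(g_mld),
                    "tajd_island": window_tajimas_d(g_isl[var]),
                    "tajd_mainland": window_tajimas_d(g_mld[var]),
                    "mean_depth": mean_depth,
                }
            )
    return pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS)
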