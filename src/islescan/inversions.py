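"""Putative chromosomal-inversion detection via local PCA / MDS.

A segregating inversion suppresses recombination between orientations,
so windows inside it share an unusual relatedness pattern: local PCA per
1000-SNP window, distances between windows' rank-2 covariance
approximations, classical MDS into 40 axes, and per-axis 4-SD outlier
windows locate candidate regions.  Candidates are validated the way the
karyotype structure predicts: genotype PCA splits samples into three
clusters (the two orientations plus heterokaryotypes) via k-means on PC1
seeded at the min / mid / max of the score range, the middle cluster
shows elevated heterozygosity, and the region shows high composite LD.
Only candidates passing all three checks are classified
``putative_inversion``.

The window distance deliberately compares scale-normalised rank-2
covariance approximations rather than raw PC score vectors: scores are
sign- and rotation-unstable, the covariance approximation is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from islescan.io import MISSING, SiteTable


@dataclass
class LocalPCAWindow:
    index: int
    chrom: str
    span: tuple[int, int]  # first / last SNP position (1-based, closed)
    n_snps: int
    eigenvalues: np.ndarray  # top-2, descending, >= 0
    scores: np.ndarray  # (n_samples, 2)

    def rank2_covariance(self) -> np.ndarray:
        """Scale-normalised rank-2 approximation of the sample covariance."""
        M = self.scores @ self.scores.T  # = sum_k lambda_k u_k u_k^T
        norm = np.linalg.norm(M)
        return M / norm if norm > 0 else M


@dataclass
class MDSEmbedding:
    coordinates: np.ndarray  # (n_windows, k)
    eigenvalues: np.ndarray


@dataclass
class InversionCandidate:
    chrom: str
    start: int
    end: int
    mds_axis: int
    window_indices: list[int]
    perm_p: float = np.nan
    cluster_sizes: tuple[int, int, int] = (0, 0, 0)
    mean_het: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    mean_r2: float = np.nan
    checks: dict = field(default_factory=dict)
    status: str = "rejected"


# ---------------------------------------------------------------------------
# local PCA
# ---------------------------------------------------------------------------


def _centered_genotype_matrix(gt: np.ndarray) -> np.ndarray:
    """Samples x SNPs float matrix, per-SNP mean-centred, missing -> 0."""
    X = gt.T.astype(float)  # samples x snps
    mask = X != MISSING
    X = np.where(mask, X, np.nan)
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    X = X - mu
    return np.where(np.isnan(X), 0.0, X)


def _top2_eig(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:2]
    return np.maximum(vals[order], 0.0), vecs[:, order]


def local_pca_windows(
    table: SiteTable, snps_per_window: int = 1000
) -> list[LocalPCAWindow]:
    """Top-2 PCA of every non-overlapping ``snps_per_window``-SNP window.

    All samples pooled, variant sites only.  A terminal window shorter
    than half of ``snps_per_window`` is dropped.
    """
    out: list[LocalPCAWindow] = []
    index = 0
    for chrom in table.chromosomes():
        sub = table.for_chrom(chrom)
        keep = sub.is_variant & ~sub.is_indel & ~sub.is_multiallelic
        gt = sub.genotypes[keep]
        pos = sub.pos[keep]
        m = gt.shape[0]
        for lo in range(0, m, snps_per_window):
            hi = min(lo + snps_per_window, m)
            if hi - lo < max(1, snps_per_window // 2) and lo > 0:
                break
            X = _centered_genotype_matrix(gt[lo:hi])
            C = (X @ X.T) / max(hi - lo - 1, 1)
            vals, vecs = _top2_eig(C)
            out.append(
                LocalPCAWindow(
                    index=index,
                    chrom=chrom,
                    span=(int(pos[lo]), int(pos[hi - 1])),
                    n_snps=hi - lo,
                    eigenvalues=vals,
                    scores=vecs * np.sqrt(vals),
                )
            )
            index += 1
    return out


def window_distance(w1: LocalPCAWindow, w2: LocalPCAWindow) -> float:
    """Frobenius distance between normalised rank-2 covariance approximations."""
    return float(np.linalg.norm(w1.rank2_covariance() - w2.rank2_covariance()))


def distance_matrix(windows: list[LocalPCAWindow]) -> np.ndarray:
    """Symmetric matrix of :func:`window_distance` over all window pairs."""
    from scipy.spatial.distance import pdist

    if len(windows) < 2:
        return np.zeros((len(windows), len(windows)))
    flat = np.stack([w.rank2_covariance().ravel() for w in windows])
    return squareform(pdist(flat))


def mds_embed(dist: np.ndarray, k: int = 40) -> MDSEmbedding:
    """Classical (Torgerson) multidimensional scaling into ``k`` axes.

    Axes beyond ``min(k, n-1)`` or with non-positive eigenvalues are
    zero.  Coordinates are centred per axis by construction.
    """
    n = dist.shape[0]
    k_eff = min(k, max(n - 1, 0))
    if n == 0:
        return MDSEmbedding(np.zeros((0, k)), np.zeros(k))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, k))
    eig_out = np.zeros(k)
    for a in range(k_eff):
        if vals[a] > 1e-12:
            coords[:, a] = vecs[:, a] * np.sqrt(vals[a])
            eig_out[a] = vals[a]
    return MDSEmbedding(coordinates=coords, eigenvalues=eig_out)


def mds_outlier_windows(embedding: MDSEmbedding, sd_mult: float = 4.0) -> np.ndarray:
    """Boolean (n_windows, k) flags: |coord - mean| > sd_mult * sd per axis.

    Axes with zero spread yield no flags.
    """
    C = embedding.coordinates
    mu = C.mean(axis=0)
    sd = C.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        flags = np.abs(C - mu) > sd_mult * sd
    flags[:, sd == 0] = False
    return flags


def permutation_chromosome_test(
    outlier_mask: np.ndarray,
    window_chroms: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Are one axis's outlier windows concentrated on particular chromosomes?

    The statistic is the observed outlier-window count per chromosome;
    the null permutes window->chromosome assignment preserving
    per-chromosome window totals.  ``p = (1 + #{perm >= obs}) /
    (n_perm + 1)`` per chromosome.
    """
    rng = rng or np.random.default_rng()
    outlier_mask = np.asarray(outlier_mask, bool)
    window_chroms = np.asarray(window_chroms)
    chroms = pd.unique(window_chroms)
    obs = {c: int(outlier_mask[window_chroms == c].sum()) for c in chroms}
    exceed = {c: 0 for c in chroms}
    for _ in range(n_perm):
        perm = rng.permutation(outlier_mask)
        for c in chroms:
            if int(perm[window_chroms == c].sum()) >= obs[c]:
                exceed[c] += 1
    return {str(c): (1 + exceed[c]) / (n_perm + 1) for c in chroms}


# ---------------------------------------------------------------------------
# candidate validation
# ---------------------------------------------------------------------------


def genotype_clusters(gt_region: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """K-means (k=3) karyotype clustering on PC1 of region genotypes.

    Initial centres are the minimum, midpoint and maximum of the PC1
    score range (deterministic); returns ``(labels, pc1_scores)`` with
    labels 0/1/2 ordered low/mid/high along PC1.
    """
    X = _centered_genotype_matrix(gt_region)
    C = (X @ X.T) / max(X.shape[1] - 1, 1)
    vals, vecs = _top2_eig(C)
    pc1 = (vecs[:, 0] * np.sqrt(vals[0])).astype(float)
    lo, hi = pc1.min(), pc1.max()
    if hi - lo <= 1e-12:
        return np.zeros(pc1.size, dtype=int), pc1
    init = np.array([[lo], [(lo + hi) / 2.0], [hi]])
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300).fit(pc1.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(3, dtype=int)
    relabel[order] = np.arange(3)
    return relabel[km.labels_], pc1


def heterozygosity_check(
    gt_region: np.ndarray, labels: np.ndarray
) -> tuple[tuple[float, float, float], bool]:
    """Mean per-individual heterozygosity per cluster; pass iff mid is highest.

    Individual heterozygosity is the fraction of called region genotypes
    that are heterozygous.  The check fails when any cluster is empty.
    """
    called = gt_region != MISSING
    with np.errstate(invalid="ignore"):
        het = (gt_region == 1).sum(axis=0) / called.sum(axis=0)
    means = []
    for g in range(3):
        sel = labels == g
        vals = het[sel]
        vals = vals[~np.isnan(vals)]
        means.append(float(vals.mean()) if vals.size else np.nan)
    ok = (
        not any(np.isnan(m) for m in means)
        and means[1] > means[0]
        and means[1] > means[2]
    )
    return (means[0], means[1], means[2]), ok


def region_ld(gt_region: np.ndarray, max_snps: int = 200) -> tuple[float, np.ndarray]:
    """Composite-LD r^2 among region SNPs from genotype dosages.

    Pairwise-complete Pearson correlation of genotype codes, squared;
    evenly subsampled to at most ``max_snps`` SNPs.  Returns (mean over
    defined off-diagonal pairs, full r^2 matrix).
    """
    m = gt_region.shape[0]
    if m > max_snps:
        idx = np.linspace(0, m - 1, max_snps).round().astype(int)
        gt_region = gt_region[np.unique(idx)]
    X = np.where(gt_region == MISSING, np.nan, gt_region.astype(float))
    r = pd.DataFrame(X.T).corr().to_numpy()  # pairwise-complete
    r2 = r**2
    iu = np.triu_indices(r2.shape[0], k=1)
    vals = r2[iu]
    vals = vals[~np.isnan(vals)]
    return (float(vals.mean()) if vals.size else np.nan), r2


def classify_inversions(
    candidates: list[InversionCandidate], ld_threshold: float = 0.3
) -> list[InversionCandidate]:
    """Final conjunction: putative_inversion iff all three checks pass."""
    for cand in candidates:
        cand.checks["high_ld"] = bool(
            not np.isnan(cand.mean_r2) and cand.mean_r2 >= ld_threshold
        )
        cand.status = (
            "putative_inversion"
            if cand.checks.get("three_clusters")
            and cand.checks.get("het_elevated")
            and cand.checks["high_ld"]
            else "rejected"
        )
    return candidates


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def detect_inversions(
    table: SiteTable,
    snps_per_window: int = 1000,
    k_mds: int = 40,
    sd_mult: float = 4.0,
    max_gap_windows: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
    ld_threshold: float = 0.3,
    require_permutation: bool = False,
    perm_alpha: float = 0.05,
) -> tuple[list[InversionCandidate], dict]:
    """Full local-PCA -> MDS -> validation inversion scan.

    Returns the candidate list (every MDS-outlier region, with status)
    and a diagnostics dict (windows, embedding, outlier flags,
    permutation p-values).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    windows = local_pca_windows(table, snps_per_window=snps_per_window)
    diagnostics: dict = {"windows": windows}
    if len(windows) < 3:
        diagnostics.update(embedding=None, outlier_flags=None, perm_p={})
        return [], diagnostics

    dist = distance_matrix(windows)
    embedding = mds_embed(dist, k=k_mds)
    flags = mds_outlier_windows(embedding, sd_mult=sd_mult)
    window_chroms = np.array([w.chrom for w in windows])
    diagnostics.update(embedding=embedding, outlier_flags=flags)

    perm_p_by_axis: dict[int, dict[str, float]] = {}
    candidates: list[InversionCandidate] = []
    for axis in range(flags.shape[1]):
        ax_mask = flags[:, axis]
        if not ax_mask.any():
            continue
        perm_p_by_axis[axis] = permutation_chromosome_test(
            ax_mask, window_chroms, n_perm=n_perm, rng=rng
        )
        for chrom in pd.unique(window_chroms[ax_mask]):
            idx = [i for i in np.flatnonzero(ax_mask) if windows[i].chrom == chrom]
            runs: list[list[int]] = [[idx[0]]]
            for i in idx[1:]:
                if i - runs[-1][-1] - 1 <= max_gap_windows:
                    runs[-1].append(i)
                else:
                    runs.append([i])
            p_chrom = perm_p_by_axis[axis][str(chrom)]
            for run in runs:
                if require_permutation and p_chrom > perm_alpha:
                    continue
                cand = InversionCandidate(
                    chrom=str(chrom),
                    start=windows[run[0]].span[0],
                    end=windows[run[-1]].span[1],
                    mds_axis=axis,
                    window_indices=run,
                    perm_p=p_chrom,
                )
                if any(
                    c.chrom == cand.chrom and c.start <= cand.end and cand.start <= c.end
                    for c in candidates
                ):
                    continue  # already covered by a lower axis
                candidates.append(cand)
    diagnostics["perm_p"] = perm_p_by_axis

    for cand in candidates:
        sub = table.for_chrom(cand.chrom)
        sel = (
            sub.is_variant
            & ~sub.is_indel
            & ~sub.is_multiallelic
            & (sub.pos >= cand.start)
            & (sub.pos <= cand.end)
        )
        gt = sub.genotypes[sel]
        if gt.shape[0] == 0:
            cand.checks = {"three_clusters": False, "het_elevated": False}
            continue
        labels, pc1 = genotype_clusters(gt)
        sizes = tuple(int((labels == g).sum()) for g in range(3))
        cand.cluster_sizes = sizes  # type: ignore[assignment]
        three = all(s > 0 for s in sizes) and (pc1.max() - pc1.min()) > 1e-12
        cand.checks["three_clusters"] = bool(three)
        het_means, het_ok = heterozygosity_check(gt, labels)
        cand.mean_het = het_means
        cand.checks["het_elevated"] = bool(het_ok and three)
        cand.mean_r2, _ = region_ld(gt)
    classify_inversions(candidates, ld_threshold=ld_threshold)
    return candidates, diagnostics
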