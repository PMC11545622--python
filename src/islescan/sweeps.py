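"""Cross-population extended haplotype homozygosity (XP-EHH) sweep scan.

EHH here is the site variant computed over *all* haplotypes of a
population (not stratified by core allele), which is the quantity whose
integral (iES) the cross-population statistic ratio-compares: a sweep
near fixation in one population leaves long shared haplotypes there
while the other population stays diverse, so ln(iES_island /
iES_mainland) spikes.  Scores are standardized genome-wide and turned
into two-sided normal p-values; cores with -log10 p >= 3 are called
significant, and significant cores adjacent to zero-coverage windows are
flagged as likely artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from islescan.io import ConfigurationError

#: EHH truncation threshold (curve points below it are discarded).
EHH_TRUNCATION = 0.05

SCAN_COLUMNS = [
    "chrom", "core_pos", "ies_island", "ies_mainland",
    "xpehh_raw", "xpehh_std", "p", "neglog10p", "significant", "artifact_flag",
]


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes of one population on one chromosome.

    ``haplotypes`` has shape (2 * n_diploids, n_sites), entries 0/1, no
    missing data; ``positions`` are 1-based bp, strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    haplotypes: np.ndarray
    population: str

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] < 2:
            raise ConfigurationError("panel needs at least 2 haplotypes")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("positions / haplotype column mismatch")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size


def _pair_homozygosity(group_ids: np.ndarray, denom: float) -> float:
    _, counts = np.unique(group_ids, return_counts=True)
    return float((counts * (counts - 1) // 2).sum() / denom)


def ehh_curve(
    panel: HaplotypePanel,
    core_index: int,
    direction: str,
    truncation: float = EHH_TRUNCATION,
) -> list[tuple[int, float]]:
    """EHH values marching away from the core in one direction.

    EHH at marker x is the fraction of haplotype pairs identical over all
    markers from the core through x (the core's own alleles included).
    The first point is the core itself with EHH 1 by convention.  The
    walk stops at the chromosome end, when EHH falls below ``truncation``
    (that point is excluded), or when every haplotype is already unique.
    """
    H, pos = panel.haplotypes, panel.positions
    if not (0 <= core_index < pos.size):
        raise IndexError(f"core index {core_index} out of range")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    n = H.shape[0]
    denom = n * (n - 1) / 2.0
    step = 1 if direction == "right" else -1

    curve = [(int(pos[core_index]), 1.0)]
    group = H[:, core_index].astype(np.int64).copy()
    n_groups = len(np.unique(group))
    j = core_index + step
    while 0 <= j < pos.size:
        key = group * 2 + H[:, j]
        _, group = np.unique(key, return_inverse=True)
        n_groups = group.max() + 1
        ehh = _pair_homozygosity(group, denom)
        if ehh < truncation:
            break
        curve.append((int(pos[j]), ehh))
        if n_groups == n:  # all unique: EHH stays at 0 hereafter
            break
        j += step
    return curve


def ies(panel: HaplotypePanel, core_index: int, truncation: float = EHH_TRUNCATION) -> float:
    """Two-sided trapezoidal integral of the EHH curve over bp.

    An identical-haplotype panel spanning L bp integrates to L; a panel
    whose EHH drops below the truncation threshold immediately on both
    sides integrates to 0.
    """
    left = ehh_curve(panel, core_index, "left", truncation)
    right = ehh_curve(panel, core_index, "right", truncation)
    points = list(reversed(left)) + right[1:]
    if len(points) < 2:
        return 0.0
    xs = np.array([p for p, _ in points], dtype=float)
    ys = np.array([v for _, v in points], dtype=float)
    return float(np.trapezoid(ys, xs))


def _ies_all_cores(panel: HaplotypePanel, truncation: float) -> np.ndarray:
    return np.array([ies(panel, i, truncation) for i in range(panel.n_sites)])


def xpehh_scan(
    island,
    mainland,
    truncation: float = EHH_TRUNCATION,
    sig_neglog10p: float = 3.0,
    min_cores: int = 50,
) -> pd.DataFrame:
    """Genome-wide XP-EHH scan over one or more chromosome panel pairs.

    ``island`` / ``mainland`` are single :class:`HaplotypePanel`s or
    equal-length sequences of them (one per chromosome; positions must
    match pairwise).  Per core SNP the raw score is ln(iES_island /
    iES_mainland); cores with either integral zero are dropped; scores
    are standardized over all surviving cores genome-wide and converted
    to two-sided normal p-values.  Fewer than ``min_cores`` surviving
    cores is an error (no usable null distribution).
    """
    if isinstance(island, HaplotypePanel):
        island, mainland = [island], [mainland]
    if len(island) != len(mainland):
        raise ConfigurationError("panel lists differ in length")

    frames = []
    for p_isl, p_mld in zip(island, mainland):
        if p_isl.chrom != p_mld.chrom or not np.array_equal(p_isl.positions, p_mld.positions):
            raise ConfigurationError(
                f"panel position mismatch on {p_isl.chrom!r} vs {p_mld.chrom!r}"
            )
        ies_i = _ies_all_cores(p_isl, truncation)
        ies_m = _ies_all_cores(p_mld, truncation)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": p_isl.chrom,
                    "core_pos": p_isl.positions,
                    "ies_island": ies_i,
                    "ies_mainland": ies_m,
                }
            )
        )
    scan = pd.concat(frames, ignore_index=True)
    scan = scan[(scan.ies_island > 0) & (scan.ies_mainland > 0)].reset_index(drop=True)
    if len(scan) < min_cores:
        raise ConfigurationError(
            f"only {len(scan)} scannable cores (< {min_cores}); refusing standardization"
        )
    raw = np.log(scan.ies_island.to_numpy() / scan.ies_mainland.to_numpy())
    sd = raw.std(ddof=0)
    std = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    p = 2.0 * stats.norm.sf(np.abs(std))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    scan["xpehh_raw"] = raw
    scan["xpehh_std"] = std
    scan["p"] = p
    scan["neglog10p"] = neglog
    scan["significant"] = neglog >= sig_neglog10p
    scan["artifact_flag"] = False
    return scan[SCAN_COLUMNS]


def flag_sweep_artifacts(
    scan: pd.DataFrame, landscape: pd.DataFrame, max_distance: int = 100_000
) -> pd.DataFrame:
    """Flag significant cores within ``max_distance`` of a zero-coverage window.

    Peaks adjacent to unsequenced spans (centromeres, repeat tracts) are
    alignment artifacts rather than sweeps; ``landscape`` supplies window
    ``mean_depth`` per chromosome.
    """
    scan = scan.copy()
    flags = np.zeros(len(scan), dtype=bool)
    zero = landscape[landscape.mean_depth == 0]
    for chrom, zwin in zero.groupby("chrom", sort=False):
        on_chrom = (scan.chrom == chrom) & scan.significant
        if not on_chrom.any():
            continue
        pos = scan.core_pos.to_numpy()
        near = np.zeros(len(scan), dtype=bool)
        for _, w in zwin.iterrows():
            dist = np.where(
                pos < w.start, w.start - pos, np.where(pos > w.end, pos - w.end, 0)
            )
            near |= dist <= max_distance
        flags |= on_chrom.to_numpy() & near
    scan["artifact_flag"] = flags
    return scan
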