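"""Genome-scan outlier calling and landscape classification.

Window statistics are turned into Z-scores, normal p-values and
Benjamini-Hochberg rejections at FDR 0.05; consecutive outlier windows
are merged into regions; merged F_ST-high regions whose windows
co-occur with d_xy-low and pi-low outliers are classified under the
recurrent-selection model (repeated selection before and after the
island-mainland split carves diversity valleys under differentiation
peaks); regions are cross-referenced with sweep-scan cores and
intersected with gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from islescan.io import GeneAnnotation

#: Default tail scanned per landscape statistic (the recurrent-selection
#: rule consumes the lower tail of d_xy and pi).
DEFAULT_TAILS = {
    "fst": "upper",
    "dxy": "lower",
    "pi_island": "lower",
    "pi_mainland": "lower",
    "tajd_island": "two_sided",
    "tajd_mainland": "two_sided",
}


class DegenerateInputError(ValueError):
    """Z-scoring impossible (fewer than 2 defined values or zero spread)."""


@dataclass
class OutlierRegion:
    chrom: str
    start: int
    end: int
    statistic: str
    direction: str  # "high" or "low"
    n_windows: int
    peak_value: float
    window_indices: list[int] = field(default_factory=list)
    artifact_flag: bool = False
    sweep_support: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("inverted region")
        if self.n_windows < 1:
            raise ValueError("region must span at least one window")


@dataclass
class LandscapeCall:
    region: OutlierRegion
    model: str  # "recurrent_selection" | "unclassified"
    evidence: dict


def zscore_pvalues(values, tail: str = "upper") -> np.ndarray:
    """Normal p-values of the Z-scores of ``values`` for the requested tail.

    NaN entries are excluded from the mean/sd and propagate as NaN
    p-values.  Raises :class:`DegenerateInputError` when fewer than two
    values are defined or their standard deviation is zero.
    """
    x = np.asarray(values, dtype=float)
    defined = ~np.isnan(x)
    if defined.sum() < 2:
        raise DegenerateInputError("need >= 2 defined values to Z-score")
    mu = x[defined].mean()
    sd = x[defined].std(ddof=0)
    if sd == 0:
        raise DegenerateInputError("zero standard deviation")
    z = (x - mu) / sd
    if tail == "upper":
        p = stats.norm.sf(z)
    elif tail == "lower":
        p = stats.norm.cdf(z)
    elif tail == "two_sided":
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = np.where(defined, p, np.nan)
    return p


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR ``q``.

    NaN p-values are never rejected and do not count toward the number
    of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    defined = ~np.isnan(p)
    if defined.any():
        reject[defined] = multipletests(p[defined], alpha=q, method="fdr_bh")[0]
    return reject


def merge_outlier_windows(
    flags,
    windows: pd.DataFrame,
    statistic: str,
    direction: str,
    values=None,
    max_gap_windows: int = 0,
) -> list[OutlierRegion]:
    """Merge runs of flagged windows (per chromosome) into regions.

    ``windows`` must carry ``chrom``, ``start``, ``end`` in genome order;
    unflagged gaps of at most ``max_gap_windows`` windows are bridged.
    ``peak_value`` is the extreme of ``values`` over the region's flagged
    windows (max for ``direction='high'``, min for ``'low'``).
    """
    flags = np.asarray(flags, dtype=bool)
    if values is None:
        values = np.full(len(flags), np.nan)
    values = np.asarray(values, dtype=float)
    regions: list[OutlierRegion] = []
    chroms = windows["chrom"].to_numpy()
    run: list[int] = []

    def close(run: list[int]) -> None:
        if not run:
            return
        vals = values[run]
        vals = vals[~np.isnan(vals)]
        peak = float((vals.max() if direction == "high" else vals.min())) if vals.size else np.nan
        regions.append(
            OutlierRegion(
                chrom=str(chroms[run[0]]),
                start=int(windows["start"].iloc[run[0]]),
                end=int(windows["end"].iloc[run[-1]]),
                statistic=statistic,
                direction=direction,
                n_windows=len(run),
                peak_value=peak,
                window_indices=list(run),
            )
        )

    for i in range(len(flags)):
        if not flags[i]:
            continue
        if run and (chroms[i] != chroms[run[-1]] or i - run[-1] - 1 > max_gap_windows):
            close(run)
            run = []
        run.append(i)
    close(run)
    return regions


def landscape_outlier_flags(
    landscape: pd.DataFrame,
    q: float = 0.05,
    tails: dict[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """BH-rejection flags per statistic column of a landscape table."""
    tails = {**DEFAULT_TAILS, **(tails or {})}
    flags = {}
    for stat, tail in tails.items():
        if stat not in landscape.columns:
            continue
        try:
            p = zscore_pvalues(landscape[stat].to_numpy(), tail=tail)
        except DegenerateInputError:
            flags[stat] = np.zeros(len(landscape), dtype=bool)
            continue
        flags[stat] = bh_fdr(p, q=q)
    return flags


def classify_recurrent_selection(
    landscape: pd.DataFrame,
    flags: dict[str, np.ndarray] | None = None,
    q: float = 0.05,
    co_occurrence: float = 0.5,
    max_gap_windows: int = 0,
) -> list[LandscapeCall]:
    """Call merged F_ST-high regions under the recurrent-selection model.

    A region is called ``recurrent_selection`` when at least
    ``co_occurrence`` of its windows are simultaneously d_xy-low outliers
    and pi-low outliers in at least one population.  Negative Tajima's D
    outlier evidence is recorded in the evidence dict but not required.
    """
    if flags is None:
        flags = landscape_outlier_flags(landscape, q=q)
    # window order must not matter: sort by (chrom, start) and carry flags along
    order = np.lexsort((landscape["start"].to_numpy(), landscape["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(landscape))):
        landscape = landscape.iloc[order].reset_index(drop=True)
        flags = {k: np.asarray(v)[order] for k, v in flags.items()}
    fst_flags = flags.get("fst", np.zeros(len(landscape), bool))
    regions = merge_outlier_windows(
        fst_flags, landscape, "fst", "high",
        values=landscape["fst"].to_numpy(), max_gap_windows=max_gap_windows,
    )
    dxy_low = flags.get("dxy", np.zeros(len(landscape), bool))
    pi_low = flags.get("pi_island", np.zeros(len(landscape), bool)) | flags.get(
        "pi_mainland", np.zeros(len(landscape), bool)
    )
    tajd_neg = np.zeros(len(landscape), bool)
    for col in ("tajd_island", "tajd_mainland"):
        if col in landscape.columns:
            vals = landscape[col].to_numpy()
            tajd_neg |= flags.get(col, np.zeros(len(landscape), bool)) & (vals < 0)

    calls = []
    for region in regions:
        idx = np.array(region.window_indices)
        co = dxy_low[idx] & pi_low[idx]
        frac = float(co.mean())
        model = "recurrent_selection" if frac >= co_occurrence else "unclassified"
        calls.append(
            LandscapeCall(
                region=region,
                model=model,
                evidence={
                    "co_occurrence_fraction": frac,
                    "n_dxy_low": int(dxy_low[idx].sum()),
                    "n_pi_low": int(pi_low[idx].sum()),
                    "n_tajd_negative": int(tajd_neg[idx].sum()),
                },
            )
        )
    return calls


def overlap_scans(regions: list[OutlierRegion], sweep_scan: pd.DataFrame) -> list[OutlierRegion]:
    """Set ``sweep_support`` where an unflagged significant core lies inside."""
    if len(sweep_scan):
        usable = sweep_scan[sweep_scan.significant & ~sweep_scan.artifact_flag]
    else:
        usable = sweep_scan
    for region in regions:
        if len(usable):
            hit = (
                (usable.chrom == region.chrom)
                & (usable.core_pos >= region.start)
                & (usable.core_pos <= region.end)
            )
            region.sweep_support = bool(hit.any())
        else:
            region.sweep_support = False
    return regions


def intersect_genes(
    regions: list[OutlierRegion], annotation: GeneAnnotation
) -> list[list[str]]:
    """Gene ids overlapping each region by >= 1 bp (closed intervals).

    Returned per region, deduplicated and sorted by gene start position.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, gid in annotation.intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, (start, gid))
    out = []
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None:
            out.append([])
            continue
        hits = tree.overlap(region.start, region.end + 1)
        seen = {}
        for iv in hits:
            start, gid = iv.data
            if gid not in seen or start < seen[gid]:
                seen[gid] = start
        out.append([gid for gid, _ in sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))])
    return out
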