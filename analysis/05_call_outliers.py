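"""Z-score/BH-FDR outlier windows, region merging, recurrent-selection calls.

Also demonstrates candidate-gene extraction by intersecting the merged
F_ST-high regions with a synthetic gene annotation (random gene models
laid over the simulated chromosomes; purely illustrative since the
simulated genome has no real genes).
"""

import numpy as np
from common import (
    FST_REGIONS,
    LANDSCAPE,
    OUTLIER_WINDOWS,
    SEED,
    SWEEPS_FULL,
    SYNTHETIC_GENES,
)

from islescan.io import read_annotation, read_windows, write_regions_bed, write_windows
from islescan.outliers import (
    classify_recurrent_selection,
    intersect_genes,
    landscape_outlier_flags,
    overlap_scans,
)
from islescan.pipeline import _regions_frame


def synthetic_annotation(rng, n_genes=120):
    """Random non-overlapping gene models over both chromosomes (synthetic)."""
    genes = []
    for chrom in ("chr1", "chr2"):
        starts = np.sort(rng.choice(np.arange(1, 1_490_000, 2000), n_genes // 2, replace=False))
        for i, s in enumerate(starts):
            genes.append((chrom, int(s), int(s + rng.integers(2000, 12_000)), f"{chrom}_g{i:03d}"))
    return genes


def main() -> None:
    land = read_windows(LANDSCAPE)
    flags = landscape_outlier_flags(land)
    flag_table = land[["chrom", "start", "end"]].copy()
    for stat, f in flags.items():
        flag_table[f"outlier_{stat}"] = f
    write_windows(flag_table, OUTLIER_WINDOWS)
    for stat, f in flags.items():
        print(f"outlier windows [{stat}]: {int(f.sum())}")

    calls = classify_recurrent_selection(land, flags=flags)
    regions = [c.region for c in calls]
    overlap_scans(regions, read_windows(SWEEPS_FULL))

    rng = np.random.default_rng(SEED)
    write_regions_bed(synthetic_annotation(rng), SYNTHETIC_GENES)
    annotation = read_annotation(SYNTHETIC_GENES, format="bed")
    genes = intersect_genes(regions, annotation)

    frame = _regions_frame(regions, genes)
    frame["model"] = [c.model for c in calls]
    write_windows(frame, FST_REGIONS)
    print(f"{len(calls)} merged F_ST-high regions -> {FST_REGIONS}")
    for c, gl in zip(calls, genes):
        r = c.region
        print(f"  {r.chrom}:{r.start}-{r.end} model={c.model} "
              f"sweep_support={r.sweep_support} genes={len(gl)}")


if __name__ == "__main__":
    main()
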