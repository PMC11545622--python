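"""Final counts: outlier windows, sweep cores, inversion candidates, genes.

Regenerates everything from the persisted result tables alone.
"""

from common import FST_REGIONS, INVERSIONS, OUTLIER_WINDOWS, SWEEPS_SIGNIFICANT

from islescan.io import read_windows


def main() -> None:
    flags = read_windows(OUTLIER_WINDOWS)
    print("windows:", len(flags))
    for col in [c for c in flags.columns if c.startswith("outlier_")]:
        print(f"outlier windows [{col[8:]}]: {int(flags[col].sum())}")
    hits = read_windows(SWEEPS_SIGNIFICANT)
    print(f"significant sweep cores: {len(hits)} "
          f"({int(hits.artifact_flag.sum())} artifact-flagged)")
    regions = read_windows(FST_REGIONS)
    print(f"F_ST outlier regions: {len(regions)}; recurrent-selection calls: "
          f"{int((regions.model == 'recurrent_selection').sum())}")
    n_genes = sum(len([g for g in str(gl).split(',') if g and g != 'nan'])
                  for gl in regions.genes.fillna(""))
    print(f"genes in outlier regions: {n_genes}")
    inv = read_windows(INVERSIONS)
    print(f"inversion candidates: {len(inv)}; putative inversions: "
          f"{int((inv.status == 'putative_inversion').sum())}")


if __name__ == "__main__":
    main()
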