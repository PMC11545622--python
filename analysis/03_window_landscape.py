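"""Windowed landscape: F_ST, d_xy, pi and Tajima's D in 10-kb windows.

Writes results/landscape.tsv and prints the genome-wide means next to
the planted recurrent-selection region, which should show the
characteristic F_ST peak over d_xy / pi valleys.
"""

from common import LANDSCAPE, POPULATIONS, RECURRENT_REGION, RESULTS, VCF

from islescan.io import filter_sites, read_population_split, read_sites, write_windows
from islescan.windows import compute_landscape


def main() -> None:
    table = filter_sites(read_sites(VCF))
    split = read_population_split(POPULATIONS)
    land = compute_landscape(table, split)
    RESULTS.mkdir(exist_ok=True)
    write_windows(land, LANDSCAPE)
    print(f"{len(land)} windows -> {LANDSCAPE}")

    chrom, start, end = RECURRENT_REGION
    inside = (land.chrom == chrom) & (land.start >= start) & (land.end <= end)
    cols = ["fst", "dxy", "pi_island", "pi_mainland"]
    print("genome-wide means:")
    print(land[cols].mean().round(4).to_string())
    print(f"planted recurrent region {chrom}:{start}-{end}:")
    print(land.loc[inside, cols].mean().round(4).to_string())


if __name__ == "__main__":
    main()
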