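"""Apply the hard filters (depth 10-40, GQ >= 30, mac >= 2, <= 25% missing).

Reports how many variant and invariant records survive each class; the
filtered table is recomputed on the fly by later stages (it is cheap),
so only the counts are persisted.
"""

import pandas as pd
from common import RESULTS, VCF

from islescan.io import filter_sites, read_sites


def main() -> None:
    table = read_sites(VCF)
    filtered = filter_sites(table)
    counts = pd.DataFrame(
        {
            "class": ["variant", "invariant", "total"],
            "input": [
                int(table.is_variant.sum()),
                int((~table.is_variant).sum()),
                table.n_sites,
            ],
            "surviving": [
                int(filtered.is_variant.sum()),
                int((~filtered.is_variant).sum()),
                filtered.n_sites,
            ],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    counts.to_csv(RESULTS / "filter_counts.tsv", sep="\t", index=False)
    print(counts.to_string(index=False))
    masked = (filtered.genotypes == -1).mean()
    print(f"missing-genotype fraction after masking: {masked:.3f}")


if __name__ == "__main__":
    main()
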