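"""Generate the study dataset: two populations, three planted features.

Writes the VCF fixture (variant + invariant sites, phased GT, DP/GQ),
the population assignment table and the truth ledger under
scratch/fixture/, and prints what was planted where.
"""

from common import FIXTURE, SIM_CONFIG

from islescan.pipeline import run_simulate


def main() -> None:
    paths = run_simulate(SIM_CONFIG, FIXTURE)
    print(f"fixture written to {FIXTURE}")
    for name, path in paths.items():
        print(f"  {name}: {path.name} ({path.stat().st_size / 1e6:.1f} MB)")
    print("planted features:")
    for feat in SIM_CONFIG.features:
        print(f"  {feat.kind:10s} {feat.chrom}:{feat.start}-{feat.end} {feat.params}")
    print("zero-coverage gaps:", list(SIM_CONFIG.zero_coverage_gaps))


if __name__ == "__main__":
    main()
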