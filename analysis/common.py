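"""Shared paths and the study design for the analysis drivers.

The study emulates one island-mainland resequencing contrast at desk
scale: two 1.5-Mb chromosomes, 12 + 12 diploids at ~18x depth, with a
selective sweep, a recurrent-selection region and a zero-coverage gap on
chr1, and a segregating inversion on chr2.  Large raw artefacts (the
VCF fixture, full per-core scan) live under scratch/, summary tables
under results/.
"""

from pathlib import Path

from islescan.simulate import Feature, SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
FIXTURE = SCRATCH / "fixture"

SEED = 11

SWEEP_REGION = ("chr1", 400_001, 500_000)
RECURRENT_REGION = ("chr1", 800_001, 850_000)
INVERSION_REGION = ("chr2", 700_001, 800_000)
COVERAGE_GAP = ("chr1", 1_200_001, 1_250_000)

SIM_CONFIG = SimulationConfig(
    seed=SEED,
    chrom_plan=(("chr1", 1_500_000), ("chr2", 1_500_000)),
    zero_coverage_gaps=(COVERAGE_GAP,),
    features=(
        Feature("sweep", *SWEEP_REGION, {"s": 0.9}),
        Feature("recurrent", *RECURRENT_REGION, {"r": 5, "k_div": 10}),
        Feature("inversion", *INVERSION_REGION, {"q": 0.5, "d": 0.3}),
    ),
)

#: 100-SNP local-PCA windows: at ~15 variants/kb post-filter this keeps
#: ~100 windows per chromosome, enough for a stable MDS background at
#: desk scale (the field default of 1000 SNPs suits full genomes).
SNPS_PER_WINDOW = 100

VCF = FIXTURE / "sites.vcf"
POPULATIONS = FIXTURE / "populations.tsv"
TRUTH = FIXTURE / "truth.json"
LANDSCAPE = RESULTS / "landscape.tsv"
SWEEPS_FULL = SCRATCH / "sweeps_full.tsv"
SWEEPS_SIGNIFICANT = RESULTS / "sweep_hits.tsv"
OUTLIER_WINDOWS = RESULTS / "outlier_windows.tsv"
FST_REGIONS = RESULTS / "fst_outlier_regions.tsv"
INVERSIONS = RESULTS / "inversion_candidates.tsv"
SYNTHETIC_GENES = RESULTS / "synthetic_genes.bed"
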