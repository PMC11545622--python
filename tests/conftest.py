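"""Shared fixtures: tiny hand-written VCFs and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from islescan.io import ISLAND, MAINLAND, MISSING, PopulationSplit, SiteTable
from islescan.simulate import SimulationConfig, simulate_dataset

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, records, samples=("s1", "s2", "s3", "s4")):
    """Write header + tab-joined record rows to ``path``; returns the path."""
    body = "\n".join("\t".join(r) for r in records)
    path.write_text(VCF_HEADER.format(samples="\t".join(samples)) + body + "\n")
    return path


def rec(pos, ref, alt, calls):
    """One VCF record row from (pos, ref, alt, list of GT:DP:GQ strings)."""
    return ["chr1", str(pos), ".", ref, alt, ".", "PASS", "."] + ["GT:DP:GQ"] + list(calls)


@pytest.fixture
def toy_filter_vcf(tmp_path):
    """Six variant records exercising every hard-filter rule.

    indel, triallelic, all-GQ-20, all-depth-50, and two clean records
    (the clean ones carry minor allele count >= 2 and full calls).
    """
    ok = "{gt}:20:80"
    records = [
        rec(100, "A", "T", [ok.format(gt=g) for g in ("0/1", "0/1", "0/0", "0/0")]),
        rec(200, "A", "AT", [ok.format(gt=g) for g in ("0/1", "0/1", "0/0", "0/0")]),
        rec(300, "A", "T,G", ["0/1:20:80", "0/2:20:80", "0/0:20:80", "0/0:20:80"]),
        rec(400, "A", "T", [f"{g}:20:20" for g in ("0/1", "0/1", "0/0", "0/0")]),
        rec(500, "A", "T", [f"{g}:50:80" for g in ("0/1", "0/1", "0/0", "0/0")]),
        rec(600, "C", "G", ["1/1:15:60", "1/1:30:70", "0/0:25:99", "0/0:12:45"]),
    ]
    return write_vcf_text(tmp_path / "toy.vcf", records)


def make_site_table(genotypes, positions=None, is_variant=None, depth=20, gq=80,
                    samples=None, chrom="chr1"):
    """SiteTable from a genotype matrix with uniform depth/quality."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if is_variant is None:
        is_variant = np.array([(row[row != MISSING] != 0).any() for row in g])
    samples = samples or [f"s{i}" for i in range(n_samples)]
    return SiteTable(
        samples=list(samples),
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.where(np.asarray(is_variant, bool), "T", "").astype(object),
        genotypes=g,
        depth=np.full((n_sites, n_samples), depth, dtype=np.int16),
        gq=np.full((n_sites, n_samples), gq, dtype=np.int16),
        is_variant=np.asarray(is_variant, bool),
        is_indel=np.zeros(n_sites, bool),
        is_multiallelic=np.zeros(n_sites, bool),
    )


def even_split(samples):
    half = len(samples) // 2
    return PopulationSplit(
        sample_ids=list(samples),
        assignment={s: (ISLAND if i < half else MAINLAND) for i, s in enumerate(samples)},
    )


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small no-feature dataset with moderate drift, reused across tests."""
    cfg = SimulationConfig(
        seed=42, chrom_plan=(("chr1", 400_000),), f_island=0.2, f_mainland=0.05
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


E2E_SIM = dict(
    seed=11,
    chrom_plan=(("chr1", 1_500_000), ("chr2", 1_500_000)),
    zero_coverage_gaps=(("chr1", 1_200_001, 1_250_000),),
)


def e2e_features():
    from islescan.simulate import Feature

    return (
        Feature("sweep", "chr1", 400_001, 500_000, {"s": 0.9}),
        Feature("recurrent", "chr1", 800_001, 850_000, {"r": 5, "k_div": 10}),
        Feature("inversion", "chr2", 700_001, 800_000, {"q": 0.5, "d": 0.3}),
    )


@pytest.fixture(scope="session")
def e2e_run(tmp_path_factory):
    """Full pipeline run (twice, for determinism) on a two-chromosome fixture.

    Returns a dict with the fixture dir, config, output paths of the
    first run, and the per-file digests of both runs.
    """
    import hashlib

    from islescan.pipeline import RunConfig, run_full, run_simulate

    root = tmp_path_factory.mktemp("e2e")
    sim = SimulationConfig(**E2E_SIM, features=e2e_features())
    fixture = run_simulate(sim, root / "fixture")
    cfg = RunConfig(
        vcf=str(fixture["vcf"]),
        populations=str(fixture["populations"]),
        out_dir=str(root / "out"),
        snps_per_window=100,
        n_perm=200,
        seed=5,
    )
    digest = lambda p: hashlib.sha256(p.read_bytes()).hexdigest()
    paths = run_full(cfg)
    first = {name: digest(p) for name, p in paths.items()}
    paths2 = run_full(cfg)
    second = {name: digest(p) for name, p in paths2.items()}
    return {
        "sim": sim, "fixture": fixture, "config": cfg, "paths": paths,
        "digests": (first, second),
    }
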