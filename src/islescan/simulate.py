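"""Synthetic island-mainland datasets with known planted truth.

The generator emulates the data a two-population resequencing contrast
produces, at desk scale: two diploid populations diverged from a common
ancestor (Balding-Nichols drift around an ancestral frequency drawn from
a 1/x density, so the island bottleneck appears as a larger drift
parameter and lower diversity), invariant sites interleaved between
SNPs, Poisson read depth around 18x with zero-coverage gaps, missing
genotypes, and three kinds of planted features with a truth ledger:

``sweep``       a fraction s of island haplotypes in a region replaced by
                copies of one founder haplotype (long shared haplotypes,
                the XP-EHH signal);
``inversion``   two non-recombining haplotype pools fixed differently at
                a fraction d of region SNPs, karyotypes drawn at
                frequency q (three genotype clusters, elevated
                heterokaryotype heterozygosity, high regional LD);
``recurrent``   variant density thinned by a factor r plus k_div sites
                near-fixed for alternate alleles (an F_ST peak over
                valleys of d_xy and pi).

Parametric Balding-Nichols generation (rather than coalescent machinery)
keeps closed-form expectations: the genome-wide Weir-Cockerham F_ST of a
two-population draw is approximately the shared drift parameter F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from islescan.io import (
    ISLAND,
    MAINLAND,
    MISSING,
    ConfigurationError,
    PopulationSplit,
    SiteTable,
    write_population_split,
    write_vcf,
)
from islescan.sweeps import HaplotypePanel

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class Feature:
    """One planted genomic feature.

    kind is ``sweep`` (param ``s``), ``inversion`` (params ``q``, ``d``)
    or ``recurrent`` (params ``r``, ``k_div``); the region is 1-based
    closed on ``chrom``.
    """

    kind: str
    chrom: str
    start: int
    end: int
    params: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_island: int = 12
    n_mainland: int = 12
    chrom_plan: tuple[tuple[str, int], ...] = (("chr1", 2_000_000),)
    variant_density: float = 0.01
    invariant_density: float = 0.02
    f_island: float = 0.3
    f_mainland: float = 0.05
    missing_rate: float = 0.02
    mean_depth: float = 18.0
    zero_coverage_gaps: tuple[tuple[str, int, int], ...] = ()
    features: tuple[Feature, ...] = ()
    #: 2N of the notional ancestral population; truncates the 1/x ancestral
    #: frequency density to [1/2N, 1 - 1/2N].
    n_ancestral: int = 50
    gq_range: tuple[int, int] = (50, 100)
    inversion_founders: int = 2

    def __post_init__(self) -> None:
        if self.variant_density <= 0 or self.invariant_density <= 0:
            raise ConfigurationError("site densities must be > 0")
        for f in (self.f_island, self.f_mainland):
            if not (0 <= f < 1):
                raise ConfigurationError("drift parameters must lie in [0, 1)")
        lengths = dict(self.chrom_plan)
        regions: dict[str, list[tuple[int, int]]] = {}
        for feat in self.features:
            if feat.chrom not in lengths:
                raise ConfigurationError(f"feature on unknown chromosome {feat.chrom}")
            if not (1 <= feat.start <= feat.end <= lengths[feat.chrom]):
                raise ConfigurationError(f"feature region out of bounds: {feat}")
            for s, e in regions.setdefault(feat.chrom, []):
                if feat.start <= e and s <= feat.end:
                    raise ConfigurationError("feature regions overlap")
            regions[feat.chrom].append((feat.start, feat.end))


@dataclass
class SimTruth:
    """Ledger of what was planted, for recovery tests."""

    features: list[dict]
    sample_ids: list[str]
    #: chrom -> dict with positions / p_island / p_mainland arrays.
    frequencies: dict = field(default_factory=dict)
    #: sample -> karyotype (0=AA, 1=AB, 2=BB) for each planted inversion,
    #: keyed by "chrom:start-end".
    karyotypes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "features": self.features,
            "sample_ids": self.sample_ids,
            "karyotypes": {k: {s: int(v) for s, v in d.items()} for k, d in self.karyotypes.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            features=d["features"], sample_ids=d["sample_ids"], karyotypes=d.get("karyotypes", {})
        )


@dataclass
class SimulatedDataset:
    table: SiteTable
    panels: dict[str, tuple[HaplotypePanel, HaplotypePanel]]  # chrom -> (island, mainland)
    split: PopulationSplit
    truth: SimTruth


def _ancestral_frequencies(m: int, n_anc: int, rng: np.random.Generator) -> np.ndarray:
    # density proportional to 1/x on [1/2N, 1-1/2N]: inverse-CDF sampling
    lo, hi = 1.0 / (2 * n_anc), 1.0 - 1.0 / (2 * n_anc)
    u = rng.random(m)
    return lo * (hi / lo) ** u


def _population_frequencies(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    if f == 0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1 - p) * scale, 1e-9))


def genotypes_from_haplotypes(haps: np.ndarray) -> np.ndarray:
    """Diploid genotype codes from a (2*n, m) haplotype matrix."""
    return (haps[0::2].astype(np.int16) + haps[1::2]).astype(np.int8)


# ---------------------------------------------------------------------------
# feature planting
# ---------------------------------------------------------------------------


def plant_sweep(
    island: HaplotypePanel,
    mainland: HaplotypePanel,
    region: tuple[int, int],
    s: float,
    rng: np.random.Generator,
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Replace a fraction ``s`` of island haplotypes in ``region`` by one founder.

    The mainland panel is untouched.  Caller regenerates genotypes from
    the returned panels.
    """
    if not (0 <= s <= 1):
        raise ConfigurationError("sweep fraction s must lie in [0, 1]")
    start, end = region
    cols = (island.positions >= start) & (island.positions <= end)
    n_hap = island.haplotypes.shape[0]
    k = int(round(s * n_hap))
    if k == 0 or not cols.any():
        return island, mainland
    founder = int(rng.integers(n_hap))
    carriers = rng.choice(n_hap, size=k, replace=False)
    haps = island.haplotypes.copy()
    haps[np.ix_(carriers, np.flatnonzero(cols))] = haps[founder, cols]
    return (
        HaplotypePanel(island.chrom, island.positions.copy(), haps, island.population),
        mainland,
    )


def plant_inversion(
    island: HaplotypePanel,
    mainland: HaplotypePanel,
    region: tuple[int, int],
    q: float,
    d: float,
    rng: np.random.Generator,
    n_founders: int = 2,
) -> tuple[tuple[HaplotypePanel, HaplotypePanel], np.ndarray]:
    """Overwrite region haplotypes with two non-recombining orientation pools.

    A fraction ``d`` of the region's SNPs is fixed differently between
    pools A and B; each pool holds ``n_founders`` whole haplotypes derived
    from the ancestral (pre-planting) region haplotypes, and every
    individual across both populations draws both of its region
    haplotypes whole from the pools of its karyotype (AA/AB/BB with
    probabilities (1-q)^2, 2q(1-q), q^2).  Returns the modified panel
    pair and the per-individual karyotype vector (island then mainland;
    0=AA, 1=AB, 2=BB).

    Both orientation classes are modelled as reduced-diversity pools:
    recombination suppression in heterokaryotypes lowers the effective
    recombination of both arrangements once the inversion segregates at
    intermediate frequency.  Planting at ``q = 0`` is a strict no-op
    (an inversion absent from the sample leaves no trace).
    """
    if not (0 <= q <= 1):
        raise ConfigurationError("inversion frequency q must lie in [0, 1]")
    if not (0 < d <= 1):
        raise ConfigurationError("pool divergence d must lie in (0, 1]")
    n_ind = (island.haplotypes.shape[0] + mainland.haplotypes.shape[0]) // 2
    if q == 0:
        return (island, mainland), np.zeros(n_ind, dtype=int)
    start, end = region
    cols = np.flatnonzero((island.positions >= start) & (island.positions <= end))
    if cols.size == 0:
        raise ConfigurationError("inversion region contains no SNPs")

    ancestral = np.vstack([island.haplotypes[:, cols], mainland.haplotypes[:, cols]])
    m = cols.size
    n_div = max(1, int(round(d * m)))
    div_sites = rng.choice(m, size=n_div, replace=False)

    pool_a = ancestral[rng.choice(ancestral.shape[0], size=n_founders, replace=False)].copy()
    pool_b = ancestral[rng.choice(ancestral.shape[0], size=n_founders, replace=False)].copy()
    pool_a[:, div_sites] = 0
    pool_b[:, div_sites] = 1
    pools = (pool_a, pool_b)

    n_isl = island.haplotypes.shape[0] // 2
    n_mld = mainland.haplotypes.shape[0] // 2
    karyo = rng.choice(3, size=n_isl + n_mld, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])

    new_isl = island.haplotypes.copy()
    new_mld = mainland.haplotypes.copy()
    for ind in range(n_isl + n_mld):
        hap_pools = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(karyo[ind])]
        target = new_isl if ind < n_isl else new_mld
        row0 = 2 * ind if ind < n_isl else 2 * (ind - n_isl)
        for off, which in enumerate(hap_pools):
            target[row0 + off, cols] = pools[which][rng.integers(n_founders)]
    out = (
        HaplotypePanel(island.chrom, island.positions.copy(), new_isl, island.population),
        HaplotypePanel(mainland.chrom, mainland.positions.copy(), new_mld, mainland.population),
    )
    return out, karyo


def plant_recurrent(
    island: HaplotypePanel,
    mainland: HaplotypePanel,
    region: tuple[int, int],
    r: float,
    k_div: int,
    rng: np.random.Generator,
) -> tuple[HaplotypePanel, HaplotypePanel, np.ndarray]:
    """Thin region variant density by ``r`` and near-fix ``k_div`` divergent sites.

    Keeps every ``r``-th region SNP (removing polymorphism in both
    populations alike) and redraws ``k_div`` of the surviving SNPs with
    island alt-allele frequency 0.97 and mainland 0.03.  Returns the
    modified panels plus the boolean keep-mask over the original SNP
    columns (the caller drops the same columns from its site table).
    """
    if r <= 0:
        raise ConfigurationError("thinning factor r must be > 0")
    start, end = region
    in_region = (island.positions >= start) & (island.positions <= end)
    cols = np.flatnonzero(in_region)
    keep = np.ones(island.positions.size, dtype=bool)
    if cols.size and r > 1:
        drop = cols[np.mod(np.arange(cols.size), round(r)) != 0]
        keep[drop] = False

    kept_region = np.flatnonzero(in_region & keep)
    new_isl = island.haplotypes[:, keep].copy()
    new_mld = mainland.haplotypes[:, keep].copy()
    if k_div > 0 and kept_region.size:
        # re-index region columns into the kept matrix
        kept_idx = np.flatnonzero(keep)
        pos_in_kept = np.searchsorted(kept_idx, kept_region)
        chosen = rng.choice(pos_in_kept, size=min(k_div, pos_in_kept.size), replace=False)
        for j in chosen:
            new_isl[:, j] = (rng.random(new_isl.shape[0]) < 0.97).astype(np.uint8)
            new_mld[:, j] = (rng.random(new_mld.shape[0]) < 0.03).astype(np.uint8)
    out_isl = HaplotypePanel(island.chrom, island.positions[keep].copy(), new_isl, island.population)
    out_mld = HaplotypePanel(
        mainland.chrom, mainland.positions[keep].copy(), new_mld, mainland.population
    )
    return out_isl, out_mld, keep


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _unique_positions(length: int, density: float, rng: np.random.Generator) -> np.ndarray:
    m = rng.poisson(length * density)
    m = min(m, length)
    return np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset (site table, phased panels, split, truth).

    Deterministic given ``config.seed``; each chromosome consumes an
    independent substream so chromosome order never couples draws.
    """
    master = np.random.SeedSequence(config.seed)
    n_chrom = len(config.chrom_plan)
    streams = master.spawn(n_chrom + 1)
    rng_global = np.random.default_rng(streams[-1])

    sample_ids = [f"isl_{i:02d}" for i in range(config.n_island)] + [
        f"mld_{i:02d}" for i in range(config.n_mainland)
    ]
    split = PopulationSplit(
        sample_ids=sample_ids,
        assignment={
            s: (ISLAND if s.startswith("isl") else MAINLAND) for s in sample_ids
        },
    )
    truth = SimTruth(features=[], sample_ids=sample_ids)
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in config.zero_coverage_gaps:
        gaps_by_chrom.setdefault(chrom, []).append((s, e))

    chroms, poss, refs, alts = [], [], [], []
    gt_blocks, dp_blocks, gq_blocks = [], [], []
    isvar_blocks = []
    panels: dict[str, tuple[HaplotypePanel, HaplotypePanel]] = {}

    for (chrom, length), stream in zip(config.chrom_plan, streams[:-1]):
        rng = np.random.default_rng(stream)
        var_pos = _unique_positions(length, config.variant_density, rng)
        m = var_pos.size

        p_anc = _ancestral_frequencies(m, config.n_ancestral, rng)
        p_isl = _population_frequencies(p_anc, config.f_island, rng)
        p_mld = _population_frequencies(p_anc, config.f_mainland, rng)
        truth.frequencies[chrom] = {
            "positions": var_pos, "p_island": p_isl, "p_mainland": p_mld,
        }

        hap_isl = (rng.random((2 * config.n_island, m)) < p_isl).astype(np.uint8)
        hap_mld = (rng.random((2 * config.n_mainland, m)) < p_mld).astype(np.uint8)
        panel_isl = HaplotypePanel(chrom, var_pos.copy(), hap_isl, ISLAND)
        panel_mld = HaplotypePanel(chrom, var_pos.copy(), hap_mld, MAINLAND)

        for feat in config.features:
            if feat.chrom != chrom:
                continue
            region = (feat.start, feat.end)
            entry = {
                "kind": feat.kind, "chrom": chrom, "start": feat.start, "end": feat.end,
                "params": dict(feat.params),
            }
            if feat.kind == "sweep":
                panel_isl, panel_mld = plant_sweep(
                    panel_isl, panel_mld, region, feat.params["s"], rng
                )
            elif feat.kind == "inversion":
                (panel_isl, panel_mld), karyo = plant_inversion(
                    panel_isl, panel_mld, region,
                    feat.params["q"], feat.params["d"], rng,
                    n_founders=config.inversion_founders,
                )
                key = f"{chrom}:{feat.start}-{feat.end}"
                truth.karyotypes[key] = dict(zip(sample_ids, karyo.tolist()))
            elif feat.kind == "recurrent":
                panel_isl, panel_mld, _keep = plant_recurrent(
                    panel_isl, panel_mld, region,
                    feat.params["r"], feat.params.get("k_div", 0), rng,
                )
                var_pos = panel_isl.positions
            else:
                raise ConfigurationError(f"unknown feature kind {feat.kind!r}")
            truth.features.append(entry)

        panels[chrom] = (panel_isl, panel_mld)
        m = var_pos.size
        gt_var = np.hstack(
            [
                genotypes_from_haplotypes(panel_isl.haplotypes).T,
                genotypes_from_haplotypes(panel_mld.haplotypes).T,
            ]
        )  # sites x samples

        inv_pos = _unique_positions(length, config.invariant_density, rng)
        inv_pos = np.setdiff1d(inv_pos, var_pos)
        all_pos = np.concatenate([var_pos, inv_pos])
        order = np.argsort(all_pos, kind="stable")
        all_pos = all_pos[order]
        isvar = np.concatenate([np.ones(m, bool), np.zeros(inv_pos.size, bool)])[order]

        n_samp = len(sample_ids)
        gt_all = np.zeros((all_pos.size, n_samp), dtype=np.int8)
        gt_all[isvar] = gt_var

        depth = rng.poisson(config.mean_depth, size=(all_pos.size, n_samp)).astype(np.int16)
        for s, e in gaps_by_chrom.get(chrom, []):
            depth[(all_pos >= s) & (all_pos <= e)] = 0
        gt_all[depth == 0] = MISSING
        if config.missing_rate > 0:
            gt_all[rng.random((all_pos.size, n_samp)) < config.missing_rate] = MISSING
        gq = rng.integers(
            config.gq_range[0], config.gq_range[1], size=(all_pos.size, n_samp)
        ).astype(np.int16)

        ref_b = _BASES[rng_global.integers(0, 4, size=all_pos.size)]
        alt_off = rng_global.integers(1, 4, size=all_pos.size)
        base_idx = np.searchsorted(_BASES, ref_b)
        alt_b = _BASES[(base_idx + alt_off) % 4]
        alt_col = np.where(isvar, alt_b, "")

        chroms.append(np.full(all_pos.size, chrom, dtype=object))
        poss.append(all_pos.astype(np.int64))
        refs.append(ref_b.astype(object))
        alts.append(alt_col.astype(object))
        gt_blocks.append(gt_all)
        dp_blocks.append(depth)
        gq_blocks.append(gq)
        isvar_blocks.append(isvar)

    n_total = sum(p.size for p in poss)
    isvar_all = np.concatenate(isvar_blocks) if isvar_blocks else np.zeros(0, bool)
    table = SiteTable(
        samples=sample_ids,
        chrom=np.concatenate(chroms) if chroms else np.zeros(0, object),
        pos=np.concatenate(poss) if poss else np.zeros(0, np.int64),
        ref=np.concatenate(refs) if refs else np.zeros(0, object),
        alt=np.concatenate(alts) if alts else np.zeros(0, object),
        genotypes=np.vstack(gt_blocks) if gt_blocks else np.zeros((0, len(sample_ids)), np.int8),
        depth=np.vstack(dp_blocks) if dp_blocks else np.zeros((0, len(sample_ids)), np.int16),
        gq=np.vstack(gq_blocks) if gq_blocks else np.zeros((0, len(sample_ids)), np.int16),
        is_variant=isvar_all,
        is_indel=np.zeros(n_total, bool),
        is_multiallelic=np.zeros(n_total, bool),
    )
    return SimulatedDataset(table=table, panels=panels, split=split, truth=truth)


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path,
                  chrom_lengths: dict[str, int] | None = None) -> dict[str, Path]:
    """Write VCF + population TSV + truth ledger; returns the paths.

    The VCF carries phased GT (from the simulation haplotypes) plus DP
    and GQ, so it feeds both the site-filter path and the phased-panel
    path of the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = dataset.table

    hap_rows = []
    for chrom in table.chromosomes():
        isl, mld = dataset.panels[chrom]
        hap_rows.append(np.hstack([isl.haplotypes.T, mld.haplotypes.T]))
    haps = np.vstack(hap_rows) if hap_rows else None

    paths = {
        "vcf": out_dir / "sites.vcf",
        "populations": out_dir / "populations.tsv",
        "truth": out_dir / "truth.json",
    }
    write_vcf(table, paths["vcf"], contig_lengths=chrom_lengths, haplotypes=haps)
    write_population_split(dataset.split, paths["populations"])
    paths["truth"].write_text(dataset.truth.to_json() + "\n")
    return paths
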