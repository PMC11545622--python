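"""End-to-end orchestration: filter -> landscape -> sweeps -> outliers -> inversions.

Every stage persists its result as plain TSV/BED under the output
directory, each file opening with a provenance comment carrying the
config hash and seed, so any stage can be re-run or inspected in
isolation and a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from islescan import io as iio
from islescan.io import ConfigurationError
from islescan.inversions import detect_inversions
from islescan.outliers import (
    classify_recurrent_selection,
    intersect_genes,
    landscape_outlier_flags,
    overlap_scans,
)
from islescan.sweeps import flag_sweep_artifacts, xpehh_scan
from islescan.windows import compute_landscape


@dataclass
class RunConfig:
    """All knobs of a full run; defaults follow the scan's standard settings."""

    vcf: str = ""
    populations: str = ""
    out_dir: str = "islescan_out"
    annotation: str | None = None
    annotation_format: str | None = None
    window_size: int = 10_000
    snps_per_window: int = 1000
    fdr_q: float = 0.05
    xpehh_threshold: float = 3.0
    sd_mult: float = 4.0
    n_perm: int = 1000
    ld_threshold: float = 0.3
    seed: int = 0
    fst_estimator: str = "wc84"
    tails: dict = field(default_factory=dict)
    chromosomes: list[str] | None = None
    max_gap_windows: int = 0
    inversion_max_gap: int = 3
    artifact_distance: int = 100_000
    require_permutation: bool = False
    co_occurrence: float = 0.5
    min_cores: int = 50

    def __post_init__(self) -> None:
        positive = {
            "window_size": self.window_size,
            "snps_per_window": self.snps_per_window,
            "fdr_q": self.fdr_q,
            "xpehh_threshold": self.xpehh_threshold,
            "sd_mult": self.sd_mult,
            "n_perm": self.n_perm,
            "ld_threshold": self.ld_threshold,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must hold a mapping")
        return cls.from_dict(data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"islescan config_sha256={config.hash()} seed={config.seed}"


def _regions_frame(regions, genes=None) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(regions):
        rows.append(
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "statistic": r.statistic, "direction": r.direction,
                "n_windows": r.n_windows, "peak_value": r.peak_value,
                "sweep_support": r.sweep_support,
                "genes": ",".join(genes[i]) if genes is not None else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "statistic", "direction",
            "n_windows", "peak_value", "sweep_support", "genes",
        ],
    )


def run_full(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order and write the report bundle.

    Returns the mapping of output names to paths.  Any stage error
    propagates with the stage named, leaving earlier outputs in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    log: list[str] = [f"# {prov}"]
    paths: dict[str, Path] = {}

    def stage(name):
        log.append(f"stage={name}")
        return name

    try:
        stage("read")
        table = iio.read_sites(config.vcf, include_invariant=True)
        split = iio.read_population_split(config.populations)
        if set(split.sample_ids) != set(table.samples):
            raise ConfigurationError("population file samples do not match VCF samples")
        if config.chromosomes:
            table = table.subset(np.isin(table.chrom, config.chromosomes))
        log.append(f"  sites_in={table.n_sites} samples={table.n_samples}")

        stage("filter")
        filtered = iio.filter_sites(table)
        log.append(f"  sites_out={filtered.n_sites} variant={int(filtered.is_variant.sum())}")

        stage("landscape")
        landscape = compute_landscape(
            filtered, split, window_size=config.window_size,
            fst_estimator=config.fst_estimator,
        )
        paths["landscape"] = out / "landscape.tsv"
        iio.write_windows(landscape, paths["landscape"], header_comment=prov)
        log.append(f"  windows={len(landscape)}")

        stage("sweeps")
        panels = iio.read_phased_panels(config.vcf, split)
        kept = {}
        for chrom, (p_isl, p_mld) in panels.items():
            surviving = set(
                filtered.pos[(filtered.chrom == chrom) & filtered.is_variant].tolist()
            )
            keep = np.isin(p_isl.positions, list(surviving))
            if keep.sum() == 0:
                continue
            kept[chrom] = (
                dataclasses.replace(
                    p_isl, positions=p_isl.positions[keep], haplotypes=p_isl.haplotypes[:, keep]
                ),
                dataclasses.replace(
                    p_mld, positions=p_mld.positions[keep], haplotypes=p_mld.haplotypes[:, keep]
                ),
            )
        chrom_order = [c for c in filtered.chromosomes() if c in kept]
        scan = xpehh_scan(
            [kept[c][0] for c in chrom_order],
            [kept[c][1] for c in chrom_order],
            sig_neglog10p=config.xpehh_threshold,
            min_cores=config.min_cores,
        )
        scan = flag_sweep_artifacts(scan, landscape, max_distance=config.artifact_distance)
        paths["sweeps"] = out / "sweeps.tsv"
        iio.write_windows(scan, paths["sweeps"], header_comment=prov)
        log.append(
            f"  cores={len(scan)} significant={int(scan.significant.sum())}"
            f" artifact_flagged={int(scan.artifact_flag.sum())}"
        )

        stage("outliers")
        flags = landscape_outlier_flags(landscape, q=config.fdr_q, tails=config.tails or None)
        flag_table = landscape[["chrom", "start", "end"]].copy()
        for stat, f in flags.items():
            flag_table[f"outlier_{stat}"] = f
        paths["outlier_flags"] = out / "outlier_windows.tsv"
        iio.write_windows(flag_table, paths["outlier_flags"], header_comment=prov)

        calls = classify_recurrent_selection(
            landscape, flags=flags, co_occurrence=config.co_occurrence,
            max_gap_windows=config.max_gap_windows,
        )
        fst_regions = [c.region for c in calls]
        overlap_scans(fst_regions, scan)
        annotation = None
        genes = None
        if config.annotation:
            annotation = iio.read_annotation(config.annotation, format=config.annotation_format)
            genes = intersect_genes(fst_regions, annotation)
        regions_df = _regions_frame(fst_regions, genes)
        regions_df["model"] = [c.model for c in calls]
        regions_df["co_occurrence_fraction"] = [
            c.evidence["co_occurrence_fraction"] for c in calls
        ]
        paths["fst_regions"] = out / "fst_outlier_regions.tsv"
        iio.write_windows(regions_df, paths["fst_regions"], header_comment=prov)
        paths["fst_bed"] = out / "fst_outlier_regions.bed"
        iio.write_regions_bed(
            [(r.chrom, r.start, r.end, r.statistic) for r in fst_regions],
            paths["fst_bed"], header_comment=prov,
        )
        log.append(
            f"  fst_regions={len(fst_regions)}"
            f" recurrent={sum(c.model == 'recurrent_selection' for c in calls)}"
        )

        stage("inversions")
        candidates, _diag = detect_inversions(
            filtered,
            snps_per_window=config.snps_per_window,
            sd_mult=config.sd_mult,
            n_perm=config.n_perm,
            seed=config.seed,
            ld_threshold=config.ld_threshold,
            max_gap_windows=config.inversion_max_gap,
            require_permutation=config.require_permutation,
        )
        cand_df = pd.DataFrame(
            [
                {
                    "chrom": c.chrom, "start": c.start, "end": c.end,
                    "mds_axis": c.mds_axis, "perm_p": c.perm_p,
                    "n_windows": len(c.window_indices),
                    "cluster_low": c.cluster_sizes[0],
                    "cluster_mid": c.cluster_sizes[1],
                    "cluster_high": c.cluster_sizes[2],
                    "het_low": c.mean_het[0], "het_mid": c.mean_het[1],
                    "het_high": c.mean_het[2],
                    "mean_r2": c.mean_r2,
                    "three_clusters": c.checks.get("three_clusters", False),
                    "het_elevated": c.checks.get("het_elevated", False),
                    "high_ld": c.checks.get("high_ld", False),
                    "status": c.status,
                }
                for c in candidates
            ],
            columns=[
                "chrom", "start", "end", "mds_axis", "perm_p", "n_windows",
                "cluster_low", "cluster_mid", "cluster_high",
                "het_low", "het_mid", "het_high", "mean_r2",
                "three_clusters", "het_elevated", "high_ld", "status",
            ],
        )
        paths["inversions"] = out / "inversion_candidates.tsv"
        iio.write_windows(cand_df, paths["inversions"], header_comment=prov)
        paths["inversions_bed"] = out / "putative_inversions.bed"
        iio.write_regions_bed(
            [
                (c.chrom, c.start, c.end, f"mds_axis_{c.mds_axis}")
                for c in candidates
                if c.status == "putative_inversion"
            ],
            paths["inversions_bed"], header_comment=prov,
        )
        log.append(
            f"  candidates={len(candidates)}"
            f" putative={sum(c.status == 'putative_inversion' for c in candidates)}"
        )

        stage("report")
        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text(report_summary(out) + "\n")
    except Exception as exc:
        log.append(f"ERROR in stage {log[-1] if log else '?'}: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise
    paths["log"] = out / "run.log"
    paths["log"].write_text("\n".join(log) + "\n")
    return paths


def run_simulate(sim_config, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset fixture consumable by :func:`run_full`."""
    from islescan.simulate import simulate_dataset, write_fixture

    dataset = simulate_dataset(sim_config)
    return write_fixture(dataset, out_dir, chrom_lengths=dict(sim_config.chrom_plan))


def report_summary(out_dir: str | Path) -> str:
    """Counts-only summary regenerable from the persisted files alone."""
    out = Path(out_dir)
    lines = ["islescan run summary"]

    def load(name):
        p = out / name
        return iio.read_windows(p) if p.exists() else None

    landscape = load("landscape.tsv")
    lines.append(f"windows: {0 if landscape is None else len(landscape)}")
    flags = load("outlier_windows.tsv")
    if flags is not None:
        for col in [c for c in flags.columns if c.startswith("outlier_")]:
            lines.append(f"outlier windows [{col[8:]}]: {int(flags[col].sum())}")
    sweeps = load("sweeps.tsv")
    n_sig = 0 if sweeps is None or not len(sweeps) else int(sweeps.significant.sum())
    n_art = 0 if sweeps is None or not len(sweeps) else int(sweeps.artifact_flag.sum())
    lines.append(f"sweep cores significant: {n_sig} (artifact-flagged: {n_art})")
    regions = load("fst_outlier_regions.tsv")
    if regions is None or not len(regions):
        lines.append("fst outlier regions: 0")
        lines.append("recurrent-selection calls: 0")
        lines.append("genes in outlier regions: 0")
    else:
        lines.append(f"fst outlier regions: {len(regions)}")
        lines.append(
            f"recurrent-selection calls: {int((regions.model == 'recurrent_selection').sum())}"
        )
        gene_lists = regions.genes.fillna("")
        n_genes = sum(len([g for g in str(gl).split(',') if g]) for gl in gene_lists)
        lines.append(f"genes in outlier regions: {n_genes}")
    inv = load("inversion_candidates.tsv")
    if inv is None or not len(inv):
        lines.append("inversion candidates: 0 (putative: 0)")
    else:
        lines.append(
            f"inversion candidates: {len(inv)}"
            f" (putative: {int((inv.status == 'putative_inversion').sum())})"
        )
    return "\n".join(lines)
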