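"""Standard-format input/output and site filtering.

The central container is :class:`SiteTable`, a columnar table of variant
*and* invariant genotyped sites.  Keeping invariant sites distinct from
missing data is what makes the windowed pi / d_xy estimators downstream
unbiased: a site that was sequenced but monomorphic contributes to the
denominator, a site that was never genotyped does not.

Coordinates are 1-based closed internally (VCF convention); BED files are
read and written 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype / unknown depth / unknown quality.
MISSING = -1

ISLAND = "island"
MAINLAND = "mainland"


class ConfigurationError(ValueError):
    """User-facing configuration problem (sample mismatch, bad parameter)."""


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteTable:
    """Per-site genotype records for variant and invariant sites.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, defining the column order of the matrices.
    chrom : ndarray of str
        Chromosome identifier per site.
    pos : ndarray of int
        1-based coordinate, strictly increasing within each chromosome.
    ref, alt : ndarray of str
        Alleles; ``alt`` is the empty string for invariant sites.
    genotypes : ndarray, shape (n_sites, n_samples), int8
        Diploid codes 0 (hom-ref), 1 (het), 2 (hom-alt), ``MISSING``.
    depth, gq : ndarray, shape (n_sites, n_samples), int16
        Per-genotype read depth and phred-like genotype quality;
        ``MISSING`` where the VCF lacks the field.
    is_variant : ndarray of bool
        False for invariant (monomorphic reference) records.
    is_indel, is_multiallelic : ndarray of bool
        Flags set at read time and consumed by :func:`filter_sites`.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    depth: np.ndarray
    gq: np.ndarray
    is_variant: np.ndarray
    is_indel: np.ndarray
    is_multiallelic: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask: np.ndarray) -> "SiteTable":
        """Row-subset (boolean mask or index array), preserving order."""
        return SiteTable(
            samples=list(self.samples),
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            genotypes=self.genotypes[mask],
            depth=self.depth[mask],
            gq=self.gq[mask],
            is_variant=self.is_variant[mask],
            is_indel=self.is_indel[mask],
            is_multiallelic=self.is_multiallelic[mask],
        )

    def chromosomes(self) -> list[str]:
        """Chromosome ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def for_chrom(self, chrom: str) -> "SiteTable":
        return self.subset(self.chrom == chrom)

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise ConfigurationError(f"sample {exc.args[0]!r} not in table") from exc

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        inv = ~self.is_variant
        if np.any(self.alt[inv] != ""):
            raise ValueError("invariant site with non-empty alt allele")
        g_inv = self.genotypes[inv]
        if g_inv.size and np.any((g_inv != 0) & (g_inv != MISSING)):
            raise ValueError("invariant site with non-reference genotype")
        clean = ~(self.is_indel | self.is_multiallelic)
        g = self.genotypes[clean]
        if g.size and np.any((g < MISSING) | (g > 2)):
            raise ValueError("genotype code outside {0,1,2,MISSING}")


@dataclass
class PopulationSplit:
    """Assignment of every sample to the island or mainland population."""

    sample_ids: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        pops = set(self.assignment.values())
        if not pops <= {ISLAND, MAINLAND}:
            raise ConfigurationError(f"unknown population label(s): {pops - {ISLAND, MAINLAND}}")
        missing = [s for s in self.sample_ids if s not in self.assignment]
        if missing:
            raise ConfigurationError(f"samples without population: {missing}")
        if not self.population(ISLAND) or not self.population(MAINLAND):
            raise ConfigurationError("both populations must be non-empty")

    def population(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.assignment[s] == label]

    def indices(self, table: SiteTable, label: str) -> np.ndarray:
        return table.sample_indices(self.population(label))


@dataclass
class GeneAnnotation:
    """Gene intervals normalised to 1-based closed coordinates."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end, gene_id in self.intervals:
            if start > end:
                raise ValueError(f"inverted interval {chrom}:{start}-{end}")
            if not gene_id:
                raise ValueError(f"empty gene id at {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def read_sites(vcf_path: str | Path, include_invariant: bool = True) -> SiteTable:
    """Read a VCF (optionally with invariant sites) into a :class:`SiteTable`.

    One row per record.  Indel and multi-allelic records are retained but
    flagged for :func:`filter_sites`.  Phase is ignored at this layer;
    half-calls and ``./.`` become ``MISSING``.  Absent DP/GQ FORMAT fields
    yield the ``MISSING`` sentinel (treated as unfilterable downstream).
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    n = len(samples)

    chrom, pos, ref, alt = [], [], [], []
    gts, dps, gqs = [], [], []
    is_variant, is_indel, is_multi = [], [], []
    for v in vcf:
        alts = [a for a in v.ALT if a not in (".", "")]
        variant = len(alts) > 0
        if not variant and not include_invariant:
            continue
        indel = len(v.REF) != 1 or any(len(a) != 1 or a.startswith("<") for a in alts)
        multi = len(alts) > 1

        g = np.empty(n, dtype=np.int8)
        for i, call in enumerate(v.genotypes):
            a0, a1 = call[0], call[1]
            if a0 < 0 or a1 < 0:
                g[i] = MISSING
            else:
                # alleles beyond the first alt collapse to "non-reference";
                # such records are multi-allelic-flagged and dropped later
                g[i] = min(a0, 1) + min(a1, 1)

        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            dp_row = np.full(n, MISSING, dtype=np.int16)
        else:
            dp_row = dp.reshape(n).astype(np.int32)
            dp_row = np.where(dp_row < 0, MISSING, dp_row).astype(np.int16)
        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        if gq is None:
            gq_row = np.full(n, MISSING, dtype=np.int16)
        else:
            gq_row = gq.reshape(n).astype(np.int32)
            gq_row = np.where(gq_row < 0, MISSING, gq_row).astype(np.int16)

        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(alts[0] if variant else "")
        gts.append(g)
        dps.append(dp_row)
        gqs.append(gq_row)
        is_variant.append(variant)
        is_indel.append(indel)
        is_multi.append(multi)

    empty_gt = np.empty((0, n), dtype=np.int8)
    empty_i16 = np.empty((0, n), dtype=np.int16)
    return SiteTable(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=np.vstack(gts) if gts else empty_gt,
        depth=np.vstack(dps) if dps else empty_i16,
        gq=np.vstack(gqs) if gqs else empty_i16,
        is_variant=np.array(is_variant, dtype=bool),
        is_indel=np.array(is_indel, dtype=bool),
        is_multiallelic=np.array(is_multi, dtype=bool),
    )


def read_population_split(path: str | Path) -> PopulationSplit:
    """Read a two-column TSV of ``sample<TAB>population`` (island/mainland)."""
    sample_ids: list[str] = []
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sample, pop = parts
            if sample in assignment:
                raise ConfigurationError(f"sample {sample!r} assigned twice")
            sample_ids.append(sample)
            assignment[sample] = pop
    return PopulationSplit(sample_ids=sample_ids, assignment=assignment)


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------


def filter_sites(
    table: SiteTable,
    depth_range: tuple[int, int] = (10, 40),
    min_gq: int = 30,
    min_mac: int = 2,
    max_missing: float = 0.25,
) -> SiteTable:
    """Apply the hard-filter rules used for short-read genotype panels.

    Variant sites: indel and multi-allelic records are removed; individual
    genotypes are masked to ``MISSING`` where depth falls outside
    ``depth_range`` or GQ is below ``min_gq``; records are then dropped
    when the minor allele count (computed on the masked record) is below
    ``min_mac`` or the missing-genotype fraction exceeds ``max_missing``.

    Invariant sites: the same per-genotype depth and GQ masks and the
    missingness cap are applied, but no allele-count rule (there is no
    alternate allele).  Masking invariant sites identically keeps the
    pi / d_xy denominators comparable across site classes.

    Idempotent: filtering a filtered table changes nothing.
    """
    lo, hi = depth_range
    g = table.genotypes.copy()
    bad_depth = (table.depth != MISSING) & ((table.depth < lo) | (table.depth > hi))
    bad_gq = (table.gq != MISSING) & (table.gq < min_gq)
    g[bad_depth | bad_gq] = MISSING

    called = g != MISSING
    n_called = called.sum(axis=1)
    miss_frac = 1.0 - n_called / table.n_samples

    keep = miss_frac <= max_missing
    var = table.is_variant
    keep &= ~(var & (table.is_indel | table.is_multiallelic))

    n_alt = np.where(called, g, 0).sum(axis=1)
    n_alleles = 2 * n_called
    mac = np.minimum(n_alt, n_alleles - n_alt)
    keep &= ~(var & ~table.is_indel & ~table.is_multiallelic & (mac < min_mac))

    out = table.subset(keep)
    out.genotypes = g[keep]
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read gene intervals from BED4 (0-based half-open) or GFF3 (1-based).

    For GFF3 only records of type ``gene`` carrying an ``ID`` or
    ``gene_id`` attribute are kept.  Both formats are normalised to
    1-based closed coordinates.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if format == "bed":
        return _read_bed_annotation(path)
    if format == "gff3":
        return _read_gff3_annotation(path)
    raise ConfigurationError(f"unknown annotation format {format!r}")


def _read_bed_annotation(path: Path) -> GeneAnnotation:
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED4 line needs 4 fields")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end0 <= start0:
                raise ParseError(f"{path}:{lineno}: empty or inverted BED interval")
            intervals.append((parts[0], start0 + 1, end0, parts[3]))
    return GeneAnnotation(intervals=intervals)


def _read_gff3_annotation(path: Path) -> GeneAnnotation:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{path}: failed to parse GFF3: {exc}") from exc
    intervals = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", [None])[0] or feat.id
        if not gid:
            continue
        intervals.append((feat.seqid, feat.start, feat.end, gid))
    return GeneAnnotation(intervals=intervals)


# ---------------------------------------------------------------------------
# tabular / BED output
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_windows(rows: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a window-statistics table as TSV (``NA`` for undefined)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        rows.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_windows(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def write_regions_bed(
    regions: Iterable[tuple], path: str | Path, header_comment: str | None = None
) -> None:
    """Write ``(chrom, start, end[, name...])`` 1-based closed regions as BED."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for region in regions:
            chrom, start, end, *rest = region
            fields = [str(chrom), str(int(start) - 1), str(int(end))] + [str(r) for r in rest]
            fh.write("\t".join(fields) + "\n")


def read_regions_bed(path: str | Path) -> list[tuple]:
    """Inverse of :func:`write_regions_bed`: 1-based closed tuples."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED line needs 3 fields")
            out.append(tuple([parts[0], int(parts[1]) + 1, int(parts[2])] + parts[3:]))
    return out


# ---------------------------------------------------------------------------
# phased haplotypes
# ---------------------------------------------------------------------------


def read_phased_panels(vcf_path: str | Path, split: PopulationSplit):
    """Read phased biallelic SNP haplotypes, one panel pair per chromosome.

    Only fully-called, fully-phased biallelic SNP records enter the panels
    (EHH computations need complete haplotypes, so incomplete sites are
    dropped rather than imputed).  Returns ``{chrom: (island_panel,
    mainland_panel)}``.
    """
    from cyvcf2 import VCF

    from islescan.sweeps import HaplotypePanel

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if set(samples) != set(split.sample_ids):
        raise ConfigurationError("VCF samples do not match the population split")
    isl = [samples.index(s) for s in split.population(ISLAND)]
    mld = [samples.index(s) for s in split.population(MAINLAND)]

    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    for v in vcf:
        alts = [a for a in v.ALT if a not in (".", "")]
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            continue
        calls = v.genotypes
        alleles = np.empty(2 * len(samples), dtype=np.uint8)
        ok = True
        for i, call in enumerate(calls):
            a0, a1, phased = call[0], call[1], call[2]
            if a0 < 0 or a1 < 0 or (not phased and a0 != a1):
                ok = False
                break
            alleles[2 * i] = a0
            alleles[2 * i + 1] = a1
        if not ok:
            continue
        positions, rows = per_chrom.setdefault(v.CHROM, ([], []))
        positions.append(v.POS)
        rows.append(alleles)

    panels = {}
    for chrom, (positions, rows) in per_chrom.items():
        allmat = np.vstack(rows)  # sites x (2*samples)
        pos = np.array(positions, dtype=np.int64)

        def pop_panel(idx: list[int], label: str):
            cols = np.array([[2 * i, 2 * i + 1] for i in idx]).reshape(-1)
            return HaplotypePanel(
                chrom=chrom, positions=pos.copy(), haplotypes=allmat[:, cols].T.copy(),
                population=label,
            )

        panels[chrom] = (pop_panel(isl, ISLAND), pop_panel(mld, MAINLAND))
    return panels


# ---------------------------------------------------------------------------
# VCF writing (simulation fixtures)
# ---------------------------------------------------------------------------

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    table: SiteTable,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    haplotypes: np.ndarray | None = None,
) -> None:
    """Emit a plain-text VCF 4.2 with GT:DP:GQ.

    ``haplotypes`` may give per-sample phased alleles for variant sites as
    an ``(n_variant_sites, 2 * n_samples)`` matrix (in table sample order);
    when provided, called genotypes at variant sites are written phased
    (``a|b``), which lets the file feed both the site-filter path and the
    phased-panel path.  Missing genotypes are always ``./.``.
    """
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    else:
        for c in table.chromosomes():
            lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples)
    )

    variant_row = -1
    for i in range(table.n_sites):
        if table.is_variant[i]:
            variant_row += 1
        alt = table.alt[i] if table.is_variant[i] else "."
        fields = [
            str(table.chrom[i]), str(table.pos[i]), ".", str(table.ref[i]), str(alt),
            ".", "PASS", ".", "GT:DP:GQ",
        ]
        for j in range(table.n_samples):
            code = int(table.genotypes[i, j])
            if code == MISSING:
                gt = "./."
            elif table.is_variant[i] and haplotypes is not None:
                a0 = haplotypes[variant_row, 2 * j]
                a1 = haplotypes[variant_row, 2 * j + 1]
                gt = f"{a0}|{a1}"
            else:
                gt = _GT_UNPHASED[code]
            dp = table.depth[i, j]
            gq = table.gq[i, j]
            fields.append(f"{gt}:{'.' if dp == MISSING else dp}:{'.' if gq == MISSING else gq}")
        lines.append("\t".join(fields))

    Path(path).write_text("\n".join(lines) + "\n")


def write_population_split(split: PopulationSplit, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in split.sample_ids:
            fh.write(f"{s}\t{split.assignment[s]}\n")
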