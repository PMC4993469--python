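"""Genotype matrices and VCF I/O.

The in-memory model is a site-by-sample grid of categorical genotype calls
(hom_ref / het / hom_alt / missing) with optional per-call read depth, plus a
site table carrying positional keys and alleles. Sites are identified by
(chromosome, 1-based position, variant class); alleles are deliberately
excluded from the identity so that catalogues produced by different callers
can be intersected positionally. Only biallelic records are retained;
multi-allelic records are dropped and accounted for in a load report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from ._util import chrom_sort_key

# genotype state codes used throughout the package
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

STATE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

SNP = "SNP"
INDEL = "indel"

# depth sentinel for "absent" (DP not provided for the call)
NO_DEPTH: int = -1


class VcfFormatError(ValueError):
    """The file is not a readable/consistent VCF."""


class InputError(ValueError):
    """Inputs violate a contract (e.g. zero samples, unknown sample name)."""


@dataclass(frozen=True, order=True)
class SiteKey:
    """Positional identity of a variant site.

    Equality and hashing use (chromosome, position, variant_class) only —
    alleles are excluded so that loci can be matched across catalogues. An
    indel and a SNP anchored at the same coordinate are distinct sites.
    """

    chrom: str
    pos: int  # 1-based
    variant_class: str = SNP

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.variant_class not in (SNP, INDEL):
            raise ValueError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class Site:
    """A site key plus its (biallelic) REF/ALT alleles."""

    key: SiteKey
    ref: str
    alt: str


@dataclass(eq=False)
class GenotypeMatrix:
    """Sites x samples grid of genotype calls.

    calls is int8 with codes HOM_REF/HET/HOM_ALT/MISSING; depth (optional)
    is int32 with NO_DEPTH marking calls that carry no DP value.
    """

    sites: list[Site]
    samples: list[str]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape differs from calls shape")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate site keys in matrix")
        for s in self.sites:
            if "," in s.alt:
                raise ValueError(f"multi-allelic site {s.key}: ALT {s.alt!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> list[SiteKey]:
        return [s.key for s in self.sites]

    def key_index(self) -> dict[SiteKey, int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    # -- transforms ------------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=list(self.samples),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
        )

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Restrict to sites selected by a boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            calls=self.calls[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise InputError(f"unknown samples: {missing}")
        idx = [pos[n] for n in names]
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=list(names),
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        if self.sites != other.sites or self.samples != other.samples:
            return False
        if not np.array_equal(self.calls, other.calls):
            return False
        if (self.depth is None) != (other.depth is None):
            return False
        if self.depth is not None and not np.array_equal(self.depth, other.depth):
            return False
        return True


@dataclass
class TruthSet:
    """Reference genotype matrix plus a completeness convention.

    completeness = "complete": a position absent from the truth matrix is
    taken to be homozygous-reference in every sample (appropriate for truth
    from deep whole-genome resequencing with near-complete coverage).
    completeness = "partial": absent positions are not comparable.
    """

    matrix: GenotypeMatrix
    completeness: str = "complete"

    def __post_init__(self):
        if self.completeness not in ("complete", "partial"):
            raise ValueError(f"bad completeness {self.completeness!r}")


@dataclass
class LoadReport:
    """Accounting of every record seen while loading a VCF."""

    total_records: int = 0
    loaded: int = 0
    dropped: list[tuple[str, int, str]] = field(default_factory=list)  # chrom,pos,reason

    @property
    def n_multiallelic(self) -> int:
        return sum(1 for _, _, r in self.dropped if r == "multi_allelic")

    @property
    def n_malformed(self) -> int:
        return sum(1 for _, _, r in self.dropped if r != "multi_allelic")

    def summary(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, r in self.dropped:
            out[r] = out.get(r, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["chrom", "pos", "reason"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize_chrom(name: str, strip_chr: bool = True) -> str:
    """Chromosome name normalization: optional stripping of a 'chr' prefix."""
    if strip_chr and name.lower().startswith("chr") and len(name) > 3:
        return name[3:]
    return name


def _gt_to_code(gt: tuple | None) -> int:
    if gt is None:
        return MISSING
    alleles = [a for a in gt]
    if any(a is None for a in alleles):
        return MISSING  # half-missing ./x counts as missing
    if len(alleles) == 1:  # tolerate haploid records as homozygous calls
        alleles = alleles * 2
    s = sum(alleles)
    if s == 0:
        return HOM_REF
    if s == 1:
        return HET  # order-insensitive: 0/1 == 1/0; phased == unphased
    return HOM_ALT


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    strip_chr: bool = True,
) -> tuple[GenotypeMatrix, LoadReport]:
    """Load a VCF into a GenotypeMatrix, dropping multi-allelic records.

    Returns the matrix together with a LoadReport accounting for every input
    record (loaded + dropped == total). Sites are sorted by (chromosome,
    position) under a natural chromosome collation, then variant class.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError, FileNotFoundError) as exc:
        raise VcfFormatError(f"cannot read VCF {path}: {exc}") from exc

    all_samples = list(vf.header.samples)
    if not all_samples:
        raise InputError(f"VCF {path} has zero sample columns")
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in all_samples]
        if unknown:
            raise InputError(f"samples not in VCF {path}: {unknown}")
        samples = list(sample_subset)
    else:
        samples = all_samples

    report = LoadReport()
    sites: list[Site] = []
    calls_rows: list[list[int]] = []
    depth_rows: list[list[int]] = []
    # a DP declaration in the header means the matrix carries a depth grid,
    # even when zero records (or zero DP values) follow
    any_depth = "DP" in vf.header.formats
    seen: set[SiteKey] = set()

    for rec in vf:
        report.total_records += 1
        chrom = normalize_chrom(rec.chrom, strip_chr)
        alts = rec.alts
        if alts is None or len(alts) == 0 or rec.ref is None:
            report.dropped.append((chrom, rec.pos, "no_alt"))
            continue
        if len(alts) > 1:
            report.dropped.append((chrom, rec.pos, "multi_allelic"))
            continue
        ref, alt = rec.ref, alts[0]
        if alt in (".", "*", "<NON_REF>"):
            report.dropped.append((chrom, rec.pos, "symbolic_alt"))
            continue
        vclass = SNP if (len(ref) == 1 and len(alt) == 1) else INDEL
        key = SiteKey(chrom, rec.pos, vclass)
        if key in seen:
            report.dropped.append((chrom, rec.pos, "duplicate_site"))
            continue
        seen.add(key)

        row: list[int] = []
        drow: list[int] = []
        for name in samples:
            fmt = rec.samples[name]
            row.append(_gt_to_code(fmt.get("GT")))
            dp = fmt.get("DP")
            drow.append(NO_DEPTH if dp is None else int(dp))
        sites.append(Site(key, ref, alt))
        calls_rows.append(row)
        depth_rows.append(drow)
        report.loaded += 1
    vf.close()

    order = sorted(
        range(len(sites)),
        key=lambda i: (
            chrom_sort_key(sites[i].key.chrom),
            sites[i].key.pos,
            sites[i].key.variant_class,
        ),
    )
    sites = [sites[i] for i in order]
    calls = (
        np.array([calls_rows[i] for i in order], dtype=np.int8)
        if sites
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    depth = None
    if any_depth:
        depth = (
            np.array([depth_rows[i] for i in order], dtype=np.int32)
            if sites
            else np.zeros((0, len(samples)), dtype=np.int32)
        )
    return GenotypeMatrix(sites, samples, calls, depth), report


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Emit a minimal VCF 4.2 (GT, plus DP when the matrix carries depth).

    Inverse of read_vcf on valid matrices: read_vcf(write_vcf(m)) == m.
    """
    path = Path(path)
    has_dp = matrix.depth is not None
    chroms: list[str] = []
    for s in matrix.sites:
        if s.key.chrom not in chroms:
            chroms.append(s.key.chrom)
    lines = ["##fileformat=VCFv4.2", "##source=gbseval"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    fmt = "GT:DP" if has_dp else "GT"
    for i, s in enumerate(matrix.sites):
        cells = []
        for j in range(matrix.n_samples):
            g = _GT_STR[int(matrix.calls[i, j])]
            if has_dp:
                d = int(matrix.depth[i, j])
                g += ":" + ("." if d == NO_DEPTH else str(d))
            cells.append(g)
        lines.append(
            f"{s.key.chrom}\t{s.key.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(cells)
        )
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write VCF {path}: {exc}") from exc


def catalogue_sites(
    matrix: GenotypeMatrix, classes: Iterable[str] = (SNP,)
) -> set[SiteKey]:
    """Site keys of the matrix restricted to the requested variant classes."""
    cls = set(classes)
    bad = cls - {SNP, INDEL}
    if bad:
        raise ValueError(f"unknown variant classes: {bad}")
    return {s.key for s in matrix.sites if s.key.variant_class in cls}
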