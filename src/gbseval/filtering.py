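"""Shared site filters for GBS genotype matrices.

All catalogues are filtered under the same conditions before any accuracy
comparison: a per-call depth mask (minDP), then removal of sites exceeding
the maximum missing-data fraction (MaxMD), sites below the minimum minor
allele frequency (MinMAF), and finally the heterozygous-locus purge (sites
with more than half of their called genotypes heterozygous, the signature of
collapsed paralogs in highly homozygous material).

Boundary semantics: missing_rate <= max_missing retained; maf >= min_maf
retained; het_fraction > het_locus_threshold removed (strict).

The filter order is fixed (depth -> missing -> MAF -> het-locus): depth
masking changes missing rates and allele counts so it must come first, and
the het purge is a removal from the otherwise-final catalogue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, HET, HOM_ALT, MISSING, NO_DEPTH

_EPS = 1e-9  # guards count/total float comparisons at the stated boundaries


@dataclass
class FilterParams:
    """Thresholds of the shared filter conditions.

    min_depth: calls with depth below this become missing (minDP >= 2).
    max_missing: maximum tolerated per-site missing-data fraction (0.80).
    min_maf: minimum minor allele frequency among called genotypes (0.05).
    het_locus_threshold: sites with a strictly greater heterozygote fraction
        are purged from the final catalogue (0.50).
    """

    min_depth: int = 2
    max_missing: float = 0.80
    min_maf: float = 0.05
    het_locus_threshold: float = 0.50

    def __post_init__(self):
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("max_missing", "min_maf", "het_locus_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterLog:
    """Audit of one apply_filters run: removed + retained == input sites."""

    n_input: int
    n_retained: int
    n_depth_masked_calls: int
    records: pd.DataFrame  # chrom, pos, variant_class, rule, value

    @property
    def n_removed(self) -> int:
        return len(self.records)

    def summary(self) -> dict[str, int]:
        return self.records["rule"].value_counts().to_dict()

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def mask_low_depth(matrix: GenotypeMatrix, min_depth: int) -> GenotypeMatrix:
    """Set calls whose depth is below min_depth to missing; no site is removed.

    Calls whose depth is absent are left untouched. If the matrix carries no
    depth at all the operation is a no-op with a warning.
    """
    out = matrix.copy()
    if min_depth <= 0:
        return out
    if out.depth is None:
        warnings.warn("matrix has no depth; depth mask skipped", stacklevel=2)
        return out
    low = (out.depth != NO_DEPTH) & (out.depth < min_depth) & (out.calls != MISSING)
    out.calls[low] = MISSING
    return out


def n_low_depth_calls(matrix: GenotypeMatrix, min_depth: int) -> int:
    if matrix.depth is None or min_depth <= 0:
        return 0
    low = (
        (matrix.depth != NO_DEPTH)
        & (matrix.depth < min_depth)
        & (matrix.calls != MISSING)
    )
    return int(low.sum())


def site_statistics(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site missing_rate, minor allele frequency, and heterozygote fraction.

    MAF is computed from called genotypes only (hom = 2 copies of one allele,
    het = 1 of each); all-missing sites report maf 0 and het_fraction 0.
    """
    calls = matrix.calls
    n_samples = matrix.n_samples
    n_missing = (calls == MISSING).sum(axis=1)
    n_called = n_samples - n_missing
    n_het = (calls == HET).sum(axis=1)
    alt_alleles = n_het + 2 * (calls == HOM_ALT).sum(axis=1)
    total_alleles = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(total_alleles > 0, alt_alleles / np.maximum(total_alleles, 1), 0.0)
        het_fraction = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    maf = np.where(total_alleles > 0, maf, 0.0)
    missing_rate = n_missing / n_samples if n_samples else np.zeros(len(calls))
    keys = matrix.site_keys()
    return pd.DataFrame(
        {
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "variant_class": [k.variant_class for k in keys],
            "missing_rate": missing_rate,
            "maf": maf,
            "het_fraction": het_fraction,
            "n_called": n_called,
        }
    )


def apply_filters(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, FilterLog]:
    """Depth-mask then remove sites violating MaxMD, MinMAF, and the het purge.

    Each removed site is logged with the first rule it fails (rules tested in
    filter order) and the measured value. Idempotent: re-filtering the output
    changes nothing.
    """
    params = params or FilterParams()
    n_masked = n_low_depth_calls(matrix, params.min_depth)
    masked = mask_low_depth(matrix, params.min_depth) if n_masked else matrix.copy()
    stats = site_statistics(masked)

    fail_missing = stats["missing_rate"].to_numpy() > params.max_missing + _EPS
    fail_maf = ~fail_missing & (stats["maf"].to_numpy() < params.min_maf - _EPS)
    fail_het = (
        ~fail_missing
        & ~fail_maf
        & (stats["het_fraction"].to_numpy() > params.het_locus_threshold + _EPS)
    )
    keep = ~(fail_missing | fail_maf | fail_het)

    rows = []
    for i in np.flatnonzero(~keep):
        if fail_missing[i]:
            rule, value = "max_missing", stats.at[i, "missing_rate"]
        elif fail_maf[i]:
            rule, value = "min_maf", stats.at[i, "maf"]
        else:
            rule, value = "het_locus", stats.at[i, "het_fraction"]
        rows.append(
            (
                stats.at[i, "chrom"],
                stats.at[i, "pos"],
                stats.at[i, "variant_class"],
                rule,
                float(value),
            )
        )
    records = pd.DataFrame(
        rows, columns=["chrom", "pos", "variant_class", "rule", "value"]
    )
    filtered = masked.subset_sites(keep)
    log = FilterLog(
        n_input=matrix.n_sites,
        n_retained=filtered.n_sites,
        n_depth_masked_calls=n_masked,
        records=records,
    )
    return filtered, log


def count_het_loci(matrix: GenotypeMatrix, threshold: float = 0.50) -> int:
    """Number of sites whose heterozygote fraction strictly exceeds threshold."""
    stats = site_statistics(matrix)
    return int((stats["het_fraction"].to_numpy() > threshold + _EPS).sum())
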