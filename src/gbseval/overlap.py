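"""Overlap of SNP catalogues: pairwise tables, n-way partitions, accuracy.

Catalogues are positional site-key sets, so overlap is plain set arithmetic:
common and only-in-one counts are always derived from the sets themselves,
never from printed percentages. The n-way partition assigns every site of
the union to the exact subset of catalogues containing it (the cells of a
Venn diagram); per-cell accuracy pools matches over the catalogues that
contain each cell, and weighted means split cells into shared (called by at
least two pipelines) and unique (called by exactly one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._util import pct, round_half_up
from .genotype_io import SiteKey


@dataclass(frozen=True)
class PairwiseOverlap:
    """Set overlap between two catalogues with percentage views."""

    name_a: str
    name_b: str
    total_a: int
    total_b: int
    common: int
    kind: str = "pipeline"  # or "platform" for same-pipeline cross-platform runs

    @property
    def only_a(self) -> int:
        return self.total_a - self.common

    @property
    def only_b(self) -> int:
        return self.total_b - self.common

    @property
    def pct_common_of_a(self) -> float:
        return pct(self.common, self.total_a, 1)

    @property
    def pct_common_of_b(self) -> float:
        return pct(self.common, self.total_b, 1)

    @property
    def pct_common_of_a_int(self) -> int:
        return int(pct(self.common, self.total_a, 0))

    @property
    def pct_common_of_b_int(self) -> int:
        return int(pct(self.common, self.total_b, 0))


def pairwise_overlap(
    cat_a: set[SiteKey],
    cat_b: set[SiteKey],
    names: tuple[str, str] = ("A", "B"),
    kind: str = "pipeline",
) -> PairwiseOverlap:
    """Intersection/difference counts between two site-key catalogues."""
    common = len(cat_a & cat_b)
    return PairwiseOverlap(
        name_a=names[0],
        name_b=names[1],
        total_a=len(cat_a),
        total_b=len(cat_b),
        common=common,
        kind=kind,
    )


def platform_overlap(
    cat_platform_a: set[SiteKey],
    cat_platform_b: set[SiteKey],
    names: tuple[str, str] = ("platformA", "platformB"),
) -> PairwiseOverlap:
    """Overlap of one pipeline's catalogues from two sequencing platforms."""
    return pairwise_overlap(cat_platform_a, cat_platform_b, names, kind="platform")


MAX_CATALOGUES = 10  # 2^k - 1 cells must stay enumerable


@dataclass
class OverlapPartition:
    """Disjoint assignment of every union site to its catalogue subset."""

    catalogue_names: tuple[str, ...]
    cells: dict[frozenset, set] = field(repr=False)

    def cell_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.cells.items()}

    def union_size(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def marginal(self, name: str) -> int:
        """Catalogue size reconstructed from the cells containing it."""
        return sum(len(v) for k, v in self.cells.items() if name in k)

    def validate(self, catalogues: Mapping[str, set] | None = None) -> None:
        """Assert disjointness/conservation; raises AssertionError on violation."""
        seen: set = set()
        total = 0
        for subset, sites in self.cells.items():
            assert subset, "empty subset cell"
            assert not (seen & sites), "cells are not pairwise disjoint"
            seen |= sites
            total += len(sites)
        assert total == len(seen)
        if catalogues is not None:
            union = set().union(*catalogues.values()) if catalogues else set()
            assert seen == union, "partition does not cover the catalogue union"
            for name, cat in catalogues.items():
                assert self.marginal(name) == len(cat), f"marginal mismatch: {name}"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(subset)), len(subset), len(sites))
            for subset, sites in sorted(
                self.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "subset_size", "n_sites"])


def nway_partition(catalogues: Mapping[str, set]) -> OverlapPartition:
    """Partition the union of 1-10 catalogues into Venn cells."""
    names = tuple(catalogues.keys())
    if not 1 <= len(names) <= MAX_CATALOGUES:
        raise ValueError(
            f"need 1-{MAX_CATALOGUES} catalogues, got {len(names)} (cell explosion)"
        )
    cells: dict[frozenset, set] = {}
    union = set().union(*catalogues.values())
    for site in union:
        subset = frozenset(n for n in names if site in catalogues[n])
        cells.setdefault(subset, set()).add(site)
    return OverlapPartition(catalogue_names=names, cells=cells)


@dataclass
class PartitionAccuracy:
    """Per-cell pooled accuracy and shared/unique weighted means."""

    per_cell: pd.DataFrame  # subset, subset_size, n_sites, compared, matching, accuracy_pct
    weighted_shared_pct: float | None
    weighted_unique_pct: float | None


def partition_accuracy(
    partition: OverlapPartition,
    per_site_match: Mapping[str, Mapping[SiteKey, tuple[int, int]]],
) -> PartitionAccuracy:
    """Pool per-site (matching, compared) over each Venn cell.

    For a cell, matches are summed over the cell's sites in every catalogue
    of the cell's subset (a site shared by three pipelines contributes its
    three pipelines' genotype comparisons). Weighted means weight cells by
    their pooled compared-genotype counts: shared = subset size >= 2,
    unique = subset size 1. With a single catalogue the shared mean is
    undefined and reported as None.
    """
    missing = [n for n in partition.catalogue_names if n not in per_site_match]
    if missing:
        raise ValueError(f"no concordance data for catalogues: {missing}")
    rows = []
    shared_m = shared_c = unique_m = unique_c = 0
    for subset, sites in sorted(
        partition.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    ):
        m = c = 0
        for name in subset:
            data = per_site_match[name]
            for site in sites:
                if site in data:
                    sm, sc = data[site]
                    m += sm
                    c += sc
        acc = round_half_up(100.0 * m / c, 1) if c else None
        rows.append(("+".join(sorted(subset)), len(subset), len(sites), c, m, acc))
        if len(subset) >= 2:
            shared_m += m
            shared_c += c
        else:
            unique_m += m
            unique_c += c
    per_cell = pd.DataFrame(
        rows,
        columns=["subset", "subset_size", "n_sites", "compared", "matching", "accuracy_pct"],
    )
    multi = len(partition.catalogue_names) >= 2
    return PartitionAccuracy(
        per_cell=per_cell,
        weighted_shared_pct=(
            round_half_up(100.0 * shared_m / shared_c, 1) if multi and shared_c else None
        ),
        weighted_unique_pct=(
            round_half_up(100.0 * unique_m / unique_c, 1) if unique_c else None
        ),
    )


def pairwise_table(
    catalogues: Mapping[str, set], reference: str | None = None
) -> pd.DataFrame:
    """Overlap of every catalogue against a reference catalogue (table form)."""
    names = list(catalogues.keys())
    if reference is None:
        reference = names[0]
    if reference not in catalogues:
        raise ValueError(f"reference catalogue {reference!r} not provided")
    rows = []
    for name in names:
        if name == reference:
            continue
        ov = pairwise_overlap(
            catalogues[name], catalogues[reference], names=(name, reference)
        )
        rows.append(
            {
                "pipeline": name,
                "reference": reference,
                "total": ov.total_a,
                "common": ov.common,
                "pct_common": ov.pct_common_of_a,
                "other_only": ov.only_a,
                "reference_only": ov.only_b,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pipeline",
            "reference",
            "total",
            "common",
            "pct_common",
            "other_only",
            "reference_only",
        ],
    )
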