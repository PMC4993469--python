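"""Genotype concordance against a deep-resequencing truth set.

A GBS genotype matrix is scored cell-by-cell against the truth genotypes at
the same (chromosome, position, class) loci and samples. Missing GBS calls
are excluded from the comparison denominator but reported as a missing-data
percentage; a compared cell matches only on state identity (a heterozygote
against either homozygote is a mismatch, with no half credit for the shared
allele).

Sites absent from the truth matrix are handled under two conventions, both
always reported: "complete" treats an absent position as homozygous-
reference in every sample (appropriate when the truth comes from
near-complete whole-genome resequencing), "partial" excludes such cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .genotype_io import (
    GenotypeMatrix,
    HET,
    HOM_REF,
    InputError,
    MISSING,
    SiteKey,
    TruthSet,
)


@dataclass
class ConcordanceReport:
    """Accuracy/missing/heterozygosity summary for one pipeline's catalogue.

    Counts are authoritative; *_pct properties derive from them. accuracy_pct
    follows the truth set's completeness convention; both conventions'
    numerators and denominators are retained.
    """

    pipeline: str
    convention: str  # "complete" or "partial"
    n_sites: int
    n_samples: int
    n_missing: int
    n_het: int
    het_loci_purged: int
    # complete convention (truth-absent site => hom_ref)
    n_compared_complete: int
    n_matching_complete: int
    # partial convention (truth-absent site => excluded)
    n_compared_partial: int
    n_matching_partial: int
    n_excluded_partial: int  # non-missing GBS cells at sites absent from truth
    n_truth_missing: int  # non-missing GBS cells where the truth call is missing
    per_site: pd.DataFrame = field(repr=False, default=None)
    per_sample: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_genotype_cells(self) -> int:
        return self.n_sites * self.n_samples

    @property
    def missing_pct(self) -> float:
        return _safe_pct(self.n_missing, self.n_genotype_cells)

    @property
    def het_pct(self) -> float:
        """Heterozygous calls as a percentage of called (non-missing) genotypes."""
        return _safe_pct(self.n_het, self.n_genotype_cells - self.n_missing)

    @property
    def n_compared(self) -> int:
        if self.convention == "complete":
            return self.n_compared_complete
        return self.n_compared_partial

    @property
    def n_matching(self) -> int:
        if self.convention == "complete":
            return self.n_matching_complete
        return self.n_matching_partial

    @property
    def accuracy_pct(self) -> float:
        return _safe_pct(self.n_matching, self.n_compared)

    @property
    def accuracy_pct_complete(self) -> float:
        return _safe_pct(self.n_matching_complete, self.n_compared_complete)

    @property
    def accuracy_pct_partial(self) -> float:
        return _safe_pct(self.n_matching_partial, self.n_compared_partial)

    def rounded(self) -> dict[str, float]:
        """Percentages rounded to one decimal, half-up, for table output."""
        return {
            "missing_pct": round_half_up(self.missing_pct, 1),
            "het_pct": round_half_up(self.het_pct, 1),
            "accuracy_pct": round_half_up(self.accuracy_pct, 1),
        }


def _safe_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def genotype_cell_count(matrix, n_samples: int | None = None) -> int:
    """Total genotype cells: sites x samples.

    Accepts a GenotypeMatrix, or a site count together with n_samples (for
    recomputing published table rows from printed catalogue sizes).
    """
    if isinstance(matrix, GenotypeMatrix):
        return matrix.n_sites * matrix.n_samples
    if n_samples is None:
        raise TypeError("n_samples required when passing a site count")
    return int(matrix) * int(n_samples)


def compare_to_truth(
    matrix: GenotypeMatrix,
    truth: TruthSet,
    pipeline: str = "pipeline",
    het_loci_purged: int = 0,
) -> ConcordanceReport:
    """Score every called GBS genotype against the truth state.

    Conservation: missing + compared(partial) + excluded(partial) +
    truth-missing-excluded == n_sites * n_samples.
    """
    common = [s for s in matrix.samples if s in set(truth.matrix.samples)]
    if not common:
        raise InputError("no overlapping samples between matrix and truth")
    gbs = matrix.subset_samples(common) if common != matrix.samples else matrix
    tm = truth.matrix
    t_idx = tm.key_index()
    t_col = {s: j for j, s in enumerate(tm.samples)}
    col_map = np.array([t_col[s] for s in gbs.samples])

    n_sites, n_samples = gbs.n_sites, gbs.n_samples
    calls = gbs.calls
    in_truth = np.zeros(n_sites, dtype=bool)
    truth_states = np.full((n_sites, n_samples), HOM_REF, dtype=np.int8)
    for i, key in enumerate(gbs.site_keys()):
        row = t_idx.get(key)
        if row is not None:
            in_truth[i] = True
            truth_states[i] = tm.calls[row][col_map]

    called = calls != MISSING
    truth_called = truth_states != MISSING  # absent sites are hom_ref (called)
    comparable = called & truth_called
    match = comparable & (calls == truth_states)

    in_truth_cells = np.broadcast_to(in_truth[:, None], calls.shape)
    compared_complete = int(comparable.sum())
    matching_complete = int(match.sum())
    compared_partial = int((comparable & in_truth_cells).sum())
    matching_partial = int((match & in_truth_cells).sum())
    excluded_partial = int((called & ~in_truth_cells).sum())
    truth_missing = int((called & ~truth_called).sum())

    keys = gbs.site_keys()
    per_site = pd.DataFrame(
        {
            "chrom": [k.chrom for k in keys],
            "pos": [k.pos for k in keys],
            "variant_class": [k.variant_class for k in keys],
            "in_truth": in_truth,
            "compared": comparable.sum(axis=1),
            "matching": match.sum(axis=1),
        }
    )
    per_sample = pd.DataFrame(
        {
            "sample": gbs.samples,
            "compared": comparable.sum(axis=0),
            "matching": match.sum(axis=0),
            "missing": (~called).sum(axis=0),
        }
    )
    return ConcordanceReport(
        pipeline=pipeline,
        convention=truth.completeness,
        n_sites=n_sites,
        n_samples=n_samples,
        n_missing=int((~called).sum()),
        n_het=int((calls == HET).sum()),
        het_loci_purged=het_loci_purged,
        n_compared_complete=compared_complete,
        n_matching_complete=matching_complete,
        n_compared_partial=compared_partial,
        n_matching_partial=matching_partial,
        n_excluded_partial=excluded_partial,
        n_truth_missing=truth_missing,
        per_site=per_site,
        per_sample=per_sample,
    )


def per_site_match_map(report: ConcordanceReport) -> dict[SiteKey, tuple[int, int]]:
    """Map SiteKey -> (matching, compared) from a report's per-site table."""
    out: dict[SiteKey, tuple[int, int]] = {}
    for row in report.per_site.itertuples(index=False):
        out[SiteKey(row.chrom, int(row.pos), row.variant_class)] = (
            int(row.matching),
            int(row.compared),
        )
    return out


def cross_platform_compare(
    report_a: ConcordanceReport,
    report_b: ConcordanceReport,
    catalogue_a: set | None = None,
    catalogue_b: set | None = None,
) -> pd.DataFrame:
    """Side-by-side accuracy table for one pipeline run on two read sets.

    Rows mirror the published per-pipeline accuracy tables (site count,
    missing %, purged het loci, het %, accuracy %). An empty catalogue is
    flagged rather than compared.
    """
    cols = {}
    for rep, cat in ((report_a, catalogue_a), (report_b, catalogue_b)):
        if rep.n_sites == 0 or (cat is not None and len(cat) == 0):
            cols[rep.pipeline] = {
                "n_sites": rep.n_sites,
                "no_comparison": True,
            }
            continue
        cols[rep.pipeline] = {
            "n_sites": rep.n_sites,
            "missing_pct": round_half_up(rep.missing_pct, 1),
            "het_loci_purged": rep.het_loci_purged,
            "het_pct": round_half_up(rep.het_pct, 1),
            "accuracy_pct": round_half_up(rep.accuracy_pct, 1),
            "no_comparison": False,
        }
    df = pd.DataFrame(cols)
    if not df.loc["no_comparison"].any():
        df["delta"] = df[report_a.pipeline] - df[report_b.pipeline]
        df.loc["no_comparison", "delta"] = False
    return df
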