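"""Systematic attribution of unique inaccurate SNP calls.

Inaccurate sites (those with any genotype disagreeing with the truth set)
that are unique to a single pipeline are pushed through a decision tree:

  1. mapping multiplicity — are the supporting reads anchored at one genomic
     locus or several? A single locus points to a fault of the variant
     caller (sequencing/PCR error); multiple loci point to collapsed
     repeats or paralogs.
  2. masked remap — reads whose loci all vanish when mapped against the
     hard-masked reference derive from repetitive sequence.
  3. paralogy test — a BLAST-style rule: a read with at least `min_hits`
     hits, each covering the full read at >= `min_identity`, derives from a
     paralogue. Multi-position sites failing both tests are reported as an
     explicit unresolved remainder.

Evidence is consumed from tabular hit files (a simple TSV dialect or BLAST
outfmt-6 columns) or SAM, so the stage runs hermetically without invoking
an aligner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import pct
from .genotype_io import SiteKey

_EPS = 1e-9

# terminal causes
CALLER_ERROR = "caller_error"
REPETITIVE = "repetitive"
PARALOGOUS = "paralogous"
UNRESOLVED = "unresolved"
NOT_APPLICABLE = "not_applicable"

UNIQUE = "unique"
SHARED = "shared"


@dataclass(frozen=True)
class Hit:
    """One alignment/BLAST hit of a supporting read."""

    target: str
    start: int
    end: int
    coverage: float  # aligned fraction of the full read query length
    identity: float

    def __post_init__(self):
        if not (0.0 <= self.coverage <= 1.0 + _EPS and 0.0 <= self.identity <= 1.0 + _EPS):
            raise ValueError(f"coverage/identity out of [0,1]: {self}")


@dataclass
class SiteEvidence:
    """Hits of the reads supporting one site, on both references.

    normal: read id -> hits on the normal reference (non-empty per read).
    masked: read id -> hits on the hard-masked reference; an empty list
    records a read that failed to map anywhere once repeats were masked.
    An empty `masked` dict means no masked-reference evidence was collected.
    """

    normal: dict[str, list[Hit]] = field(default_factory=dict)
    masked: dict[str, list[Hit]] = field(default_factory=dict)

    @property
    def has_masked_evidence(self) -> bool:
        return len(self.masked) > 0


AlignmentEvidence = dict  # SiteKey -> SiteEvidence


@dataclass
class ParalogyRule:
    """BLAST-style paralogy thresholds: >=2 full-coverage hits at >=96% identity."""

    min_hits: int = 2
    min_coverage: float = 1.00
    min_identity: float = 0.96

    def __post_init__(self):
        if self.min_hits < 2:
            raise ValueError("min_hits must be >= 2")


@dataclass
class AttributionRecord:
    site: SiteKey
    pipeline: str
    sharing: str  # unique / shared
    cause: str
    n_hits: int = 0  # qualifying hits (paralogy), for the mean-hits statistic
    note: str = ""


@dataclass
class AttributionSummary:
    """Counts per pipeline in the shape of the published attribution table.

    Identities: unique_position + multiple_position + no_evidence ==
    unique_inaccurate; repetitive + paralogous + unresolved ==
    multiple_position. Percentages use the published denominators
    (unique/multiple position as % of unique inaccurate; repetitive and
    paralogous as % of multiple position).
    """

    pipeline: str
    n_catalogue: int
    unique_inaccurate: int
    unique_position: int
    multiple_position: int
    repetitive: int
    paralogous: int
    unresolved: int
    no_evidence: int
    mean_hits_paralogous: float | None

    @property
    def pct_of_catalogue(self) -> float:
        return pct(self.unique_inaccurate, self.n_catalogue, 1)

    @property
    def pct_unique_position(self) -> float:
        return pct(self.unique_position, self.unique_inaccurate, 1)

    @property
    def pct_multiple_position(self) -> float:
        return pct(self.multiple_position, self.unique_inaccurate, 1)

    @property
    def pct_repetitive(self) -> float:
        return pct(self.repetitive, self.multiple_position, 1)

    @property
    def pct_paralogous(self) -> float:
        return pct(self.paralogous, self.multiple_position, 1)

    def validate(self) -> None:
        assert (
            self.unique_position + self.multiple_position + self.no_evidence
            == self.unique_inaccurate
        ), "unique_position + multiple_position + no_evidence != unique_inaccurate"
        assert (
            self.repetitive + self.paralogous + self.unresolved
            == self.multiple_position
        ), "repetitive + paralogous + unresolved != multiple_position"


# ---------------------------------------------------------------------------
# tree stages
# ---------------------------------------------------------------------------

def split_accurate(
    per_site_match: Mapping[SiteKey, tuple[int, int]],
    min_site_accuracy: float | None = None,
) -> tuple[set[SiteKey], set[SiteKey]]:
    """Split sites into accurate and inaccurate by truth concordance.

    Default rule: a site is inaccurate iff any of its compared genotype
    cells mismatches. With min_site_accuracy set, a site is inaccurate iff
    its per-site accuracy falls below that threshold. Sites with no compared
    cells are counted as accurate (unassessable).
    """
    accurate: set[SiteKey] = set()
    inaccurate: set[SiteKey] = set()
    for site, (matching, compared) in per_site_match.items():
        if compared == 0:
            accurate.add(site)
        elif min_site_accuracy is None:
            (inaccurate if matching < compared else accurate).add(site)
        else:
            (inaccurate if matching / compared < min_site_accuracy - _EPS else accurate).add(site)
    return accurate, inaccurate


def classify_sharing(
    inaccurate_by_pipeline: Mapping[str, set[SiteKey]],
) -> dict[str, dict[SiteKey, str]]:
    """Label each pipeline's inaccurate sites unique vs shared.

    A site is unique iff it is inaccurate in exactly one pipeline (sites
    absent from, or accurate in, the others count toward uniqueness). With a
    single pipeline every label is not_applicable.
    """
    names = list(inaccurate_by_pipeline.keys())
    if len(names) < 2:
        warnings.warn("sharing needs >=2 pipelines; labels not_applicable", stacklevel=2)
        return {
            n: {s: NOT_APPLICABLE for s in sites}
            for n, sites in inaccurate_by_pipeline.items()
        }
    count: dict[SiteKey, int] = {}
    for sites in inaccurate_by_pipeline.values():
        for s in sites:
            count[s] = count.get(s, 0) + 1
    return {
        n: {s: (UNIQUE if count[s] == 1 else SHARED) for s in sites}
        for n, sites in inaccurate_by_pipeline.items()
    }


def _merged_locus_count(hits: Iterable[Hit]) -> int:
    """Distinct genomic loci after merging overlapping target intervals."""
    by_target: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        by_target.setdefault(h.target, []).append((min(h.start, h.end), max(h.start, h.end)))
    n = 0
    for ivs in by_target.values():
        ivs.sort()
        cur_end = None
        for s, e in ivs:
            if cur_end is None or s >= cur_end:
                n += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
    return n


def mapping_multiplicity(evidence: SiteEvidence, aggregation: str = "any") -> str:
    """unique_position vs multiple_positions from normal-reference hits.

    A read is multi-hit when its hits span >= 2 distinct loci (non-overlapping
    target intervals after merging). Site-level aggregation: "any" (default —
    one multi-hit read suffices) or "majority".
    """
    if not evidence.normal:
        raise ValueError("site has no normal-reference evidence")
    multi = [_merged_locus_count(hits) >= 2 for hits in evidence.normal.values()]
    if aggregation == "any":
        return "multiple_positions" if any(multi) else "unique_position"
    if aggregation == "majority":
        return "multiple_positions" if sum(multi) * 2 > len(multi) else "unique_position"
    raise ValueError(f"unknown aggregation {aggregation!r}")


def masked_remap_class(evidence: SiteEvidence) -> str:
    """repetitive iff every supporting read lost all hits on the masked genome."""
    if not evidence.has_masked_evidence:
        raise ValueError("site has no masked-reference evidence")
    if all(len(hits) == 0 for hits in evidence.masked.values()):
        return REPETITIVE
    return "retained"


def paralogy_test(
    evidence: SiteEvidence, rule: ParalogyRule | None = None
) -> tuple[str, int]:
    """Apply the BLAST-style paralogy rule; returns (label, qualifying hits).

    paralogous iff some supporting read has >= min_hits hits each with
    coverage >= min_coverage and identity >= min_identity. The returned hit
    count (max qualifying hits over reads) feeds the mean-hits statistic.
    """
    rule = rule or ParalogyRule()
    best = 0
    for hits in evidence.normal.values():
        q = sum(
            1
            for h in hits
            if h.coverage >= rule.min_coverage - _EPS
            and h.identity >= rule.min_identity - _EPS
        )
        best = max(best, q)
    if best >= rule.min_hits:
        return PARALOGOUS, best
    return UNRESOLVED, best


def attribute_errors(
    catalogues: Mapping[str, set[SiteKey]],
    per_site_match: Mapping[str, Mapping[SiteKey, tuple[int, int]]],
    evidence: Mapping[str, AlignmentEvidence],
    rule: ParalogyRule | None = None,
    aggregation: str = "any",
    min_site_accuracy: float | None = None,
) -> tuple[pd.DataFrame, dict[str, AttributionSummary]]:
    """Run the full decision tree for every pipeline.

    Returns per-site attribution records and per-pipeline summaries. Every
    unique inaccurate site receives exactly one terminal label; sites
    lacking evidence are carried in a separate no-evidence column.
    """
    rule = rule or ParalogyRule()
    inaccurate_by_pipeline = {
        name: split_accurate(per_site_match[name], min_site_accuracy)[1]
        for name in catalogues
    }
    sharing = classify_sharing(inaccurate_by_pipeline)

    records: list[AttributionRecord] = []
    summaries: dict[str, AttributionSummary] = {}
    for name, cat in catalogues.items():
        ev_map = evidence.get(name, {})
        n_unique = n_unipos = n_multi = n_rep = n_par = n_unres = n_noev = 0
        par_hits: list[int] = []
        for site, label in sharing[name].items():
            if label != UNIQUE:
                records.append(
                    AttributionRecord(site, name, label, NOT_APPLICABLE)
                )
                continue
            n_unique += 1
            ev = ev_map.get(site)
            if ev is None or not ev.normal:
                n_noev += 1
                records.append(
                    AttributionRecord(site, name, UNIQUE, UNRESOLVED, note="no_evidence")
                )
                continue
            if mapping_multiplicity(ev, aggregation) == "unique_position":
                n_unipos += 1
                records.append(AttributionRecord(site, name, UNIQUE, CALLER_ERROR))
                continue
            n_multi += 1
            if not ev.has_masked_evidence:
                # multi-position but no masked remap data: explicit remainder
                n_multi -= 1
                n_noev += 1
                records.append(
                    AttributionRecord(
                        site, name, UNIQUE, UNRESOLVED, note="no_masked_evidence"
                    )
                )
                continue
            if masked_remap_class(ev) == REPETITIVE:
                n_rep += 1
                records.append(AttributionRecord(site, name, UNIQUE, REPETITIVE))
                continue
            cause, k = paralogy_test(ev, rule)
            if cause == PARALOGOUS:
                n_par += 1
                par_hits.append(k)
                records.append(
                    AttributionRecord(site, name, UNIQUE, PARALOGOUS, n_hits=k)
                )
            else:
                n_unres += 1
                records.append(
                    AttributionRecord(site, name, UNIQUE, UNRESOLVED, n_hits=k)
                )
        summary = AttributionSummary(
            pipeline=name,
            n_catalogue=len(cat),
            unique_inaccurate=n_unique,
            unique_position=n_unipos,
            multiple_position=n_multi,
            repetitive=n_rep,
            paralogous=n_par,
            unresolved=n_unres,
            no_evidence=n_noev,
            mean_hits_paralogous=(float(np.mean(par_hits)) if par_hits else None),
        )
        summary.validate()
        summaries[name] = summary

    rec_df = pd.DataFrame(
        [
            {
                "pipeline": r.pipeline,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "variant_class": r.site.variant_class,
                "sharing": r.sharing,
                "cause": r.cause,
                "n_hits": r.n_hits,
                "note": r.note,
            }
            for r in records
        ],
        columns=[
            "pipeline", "chrom", "pos", "variant_class",
            "sharing", "cause", "n_hits", "note",
        ],
    )
    return rec_df, summaries


def summaries_to_frame(summaries: Mapping[str, AttributionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries.values():
        rows.append(
            {
                "pipeline": s.pipeline,
                "n_catalogue": s.n_catalogue,
                "unique_inaccurate": s.unique_inaccurate,
                "pct_of_catalogue": s.pct_of_catalogue,
                "unique_position": s.unique_position,
                "pct_unique_position": s.pct_unique_position,
                "multiple_position": s.multiple_position,
                "pct_multiple_position": s.pct_multiple_position,
                "repetitive": s.repetitive,
                "pct_repetitive": s.pct_repetitive,
                "paralogous": s.paralogous,
                "pct_paralogous": s.pct_paralogous,
                "unresolved": s.unresolved,
                "no_evidence": s.no_evidence,
                "mean_hits_paralogous": s.mean_hits_paralogous,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evidence loaders
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "chrom", "pos", "variant_class", "read_id", "reference",
    "target", "start", "end", "coverage", "identity",
]
NO_HIT_TARGET = "*"  # masked-reference row recording "mapped nowhere"


def load_evidence_tsv(path: str | Path) -> AlignmentEvidence:
    """Read the package's tabular evidence format (one hit per row).

    reference is "normal" or "masked"; a masked row with target "*" records
    a read with zero hits on the hard-masked genome.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "target": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence file {path} lacks columns: {sorted(missing)}")
    evidence: AlignmentEvidence = {}
    for row in df.itertuples(index=False):
        key = SiteKey(str(row.chrom), int(row.pos), row.variant_class)
        ev = evidence.setdefault(key, SiteEvidence())
        store = ev.normal if row.reference == "normal" else ev.masked
        hits = store.setdefault(str(row.read_id), [])
        if row.target != NO_HIT_TARGET:
            hits.append(
                Hit(
                    target=str(row.target),
                    start=int(row.start),
                    end=int(row.end),
                    coverage=float(row.coverage),
                    identity=float(row.identity),
                )
            )
    return evidence


def write_evidence_tsv(evidence: AlignmentEvidence, path: str | Path) -> None:
    rows = []
    for key, ev in evidence.items():
        for ref_name, store in (("normal", ev.normal), ("masked", ev.masked)):
            for read_id, hits in store.items():
                if not hits:
                    rows.append(
                        (key.chrom, key.pos, key.variant_class, read_id, ref_name,
                         NO_HIT_TARGET, 0, 0, 0.0, 0.0)
                    )
                for h in hits:
                    rows.append(
                        (key.chrom, key.pos, key.variant_class, read_id, ref_name,
                         h.target, h.start, h.end, h.coverage, h.identity)
                    )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_blast_tab(
    path: str | Path,
    read_to_site: Mapping[str, SiteKey],
    reference: str = "normal",
    evidence: AlignmentEvidence | None = None,
) -> AlignmentEvidence:
    """Read BLAST tabular hits (qseqid sseqid pident length qlen sstart send).

    coverage = length / qlen; identity = pident / 100. Reads absent from
    read_to_site are ignored. Pass an existing evidence dict to merge the
    masked-reference file into the same site records.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "qlen", "sstart", "send"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    evidence = evidence if evidence is not None else {}
    for row in df.itertuples(index=False):
        site = read_to_site.get(str(row.qseqid))
        if site is None:
            continue
        ev = evidence.setdefault(site, SiteEvidence())
        store = ev.normal if reference == "normal" else ev.masked
        store.setdefault(str(row.qseqid), []).append(
            Hit(
                target=str(row.sseqid),
                start=int(min(row.sstart, row.send)),
                end=int(max(row.sstart, row.send)),
                coverage=min(1.0, float(row.length) / float(row.qlen)),
                identity=float(row.pident) / 100.0,
            )
        )
    return evidence


def load_evidence_sam(
    path: str | Path,
    read_to_site: Mapping[str, SiteKey],
    reference: str = "normal",
    evidence: AlignmentEvidence | None = None,
) -> AlignmentEvidence:
    """Collect per-read hits (including secondary alignments) from a SAM file.

    Identity is derived from the NM tag when present (1 - NM/aligned_length);
    coverage is the aligned fraction of the full query length. Unmapped reads
    listed in read_to_site are recorded as zero-hit entries (meaningful for
    the masked reference).
    """
    import pysam

    evidence = evidence if evidence is not None else {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            name = aln.query_name
            site = read_to_site.get(name)
            if site is None:
                continue
            ev = evidence.setdefault(site, SiteEvidence())
            store = ev.normal if reference == "normal" else ev.masked
            hits = store.setdefault(name, [])
            if aln.is_unmapped:
                continue
            qlen = aln.infer_read_length() or aln.query_length or 0
            alen = aln.query_alignment_length or 0
            cov = alen / qlen if qlen else 0.0
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            ident = 1.0 - (nm / alen) if alen else 0.0
            hits.append(
                Hit(
                    target=sam.get_reference_name(aln.reference_id),
                    start=int(aln.reference_start),
                    end=int(aln.reference_end or aln.reference_start),
                    coverage=min(1.0, cov),
                    identity=max(0.0, min(1.0, ident)),
                )
            )
    return evidence
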