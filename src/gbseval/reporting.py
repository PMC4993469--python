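"""Study orchestration: run every stage once, emit the report tables.

run_study drives filtering -> concordance -> overlap -> attribution (->
demultiplexing when reads are present) from a single config, writing one
TSV per published-table shape plus a manifest recording every parameter,
the seed, and a content hash of each output. Counts in the tables are
authoritative; every percentage is recomputable from counts in the same
file, which is what validate_tables checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import round_half_up
from .attribution import (
    ParalogyRule,
    attribute_errors,
    load_evidence_tsv,
    summaries_to_frame,
)
from .concordance import compare_to_truth, per_site_match_map
from .demux import BarcodeTable, assign_reads
from .filtering import FilterParams, apply_filters
from .genotype_io import SNP, INDEL, GenotypeMatrix, TruthSet, catalogue_sites, read_vcf
from .overlap import nway_partition, pairwise_table, partition_accuracy
from .simulate import SimParams, make_study


class ConfigError(ValueError):
    """The run configuration is incomplete or inconsistent."""


@dataclass
class RunConfig:
    """Inputs for one evaluation run: real files or a simulation block."""

    output_dir: str | Path = "gbseval_out"
    sim: SimParams | None = None
    pipeline_vcfs: dict[str, str] = field(default_factory=dict)
    truth_vcf: str | None = None
    truth_completeness: str = "complete"
    evidence_files: dict[str, str] = field(default_factory=dict)
    reads_fastq: str | None = None
    barcode_file: str | None = None
    demux_max_mismatch: int = 0
    demux_n_reads: int | None = 20000  # cap on simulated reads for the demux stage
    filters: FilterParams = field(default_factory=FilterParams)
    paralogy: ParalogyRule = field(default_factory=ParalogyRule)
    reference_pipeline: str | None = None  # anchor of the pairwise table

    def validate(self) -> None:
        if self.sim is None and not self.pipeline_vcfs:
            raise ConfigError("config needs either a sim block or pipeline VCFs")
        if self.sim is None and self.truth_vcf is None:
            raise ConfigError("real-input runs need a truth VCF")
        if self.reads_fastq and not self.barcode_file:
            raise ConfigError("reads supplied without a barcode table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            for tup_key in ("paralog_identity", "repeat_identity", "fragment_window",
                            "maf_range"):
                if tup_key in sim_raw:
                    sim_raw[tup_key] = tuple(sim_raw[tup_key])
            kw["sim"] = SimParams(**sim_raw)
        if "filters" in raw:
            kw["filters"] = FilterParams(**raw["filters"])
        if "paralogy" in raw:
            kw["paralogy"] = ParalogyRule(**raw["paralogy"])
        for key in ("output_dir", "pipeline_vcfs", "truth_vcf", "truth_completeness",
                    "evidence_files", "reads_fastq", "barcode_file",
                    "demux_max_mismatch", "demux_n_reads", "reference_pipeline"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: RunConfig) -> Path:
    """Execute the full evaluation once and write the report directory.

    Outputs: catalogue_summary.tsv, concordance.tsv, overlap_pairwise.tsv,
    overlap_partition.tsv, attribution.tsv, demux.tsv (when reads exist),
    and manifest.yaml.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    evidence = {}
    reads_path = config.reads_fastq
    barcode_table = (
        BarcodeTable.load(config.barcode_file) if config.barcode_file else None
    )
    if config.sim is not None:
        study = make_study(config.sim)
        matrices = study.pipeline_calls
        truth = study.truth
        evidence = study.evidence
        if reads_path is None:
            reads_path = outdir / "reads.fastq"
            study.make_reads(n_reads=config.demux_n_reads, out_path=reads_path)
            barcode_table = study.barcode_table
    else:
        matrices = {}
        for name, path in config.pipeline_vcfs.items():
            matrices[name], _ = read_vcf(path)
        truth_matrix, _ = read_vcf(config.truth_vcf)
        truth = TruthSet(truth_matrix, completeness=config.truth_completeness)
        evidence = {
            name: load_evidence_tsv(path)
            for name, path in config.evidence_files.items()
        }

    # ---- filtering + concordance ------------------------------------------
    filtered: dict[str, GenotypeMatrix] = {}
    reports = {}
    cat_rows = []
    for name, matrix in matrices.items():
        fm, log = apply_filters(matrix, config.filters)
        filtered[name] = fm
        purged = int(log.summary().get("het_locus", 0))
        reports[name] = compare_to_truth(fm, truth, pipeline=name, het_loci_purged=purged)
        log.to_tsv(outdir / f"filter_log_{name}.tsv")
        cat_rows.append(
            {
                "pipeline": name,
                "n_snps": len(catalogue_sites(fm, {SNP})),
                "n_indels": len(catalogue_sites(fm, {INDEL})),
                "n_sites_prefilter": matrix.n_sites,
                "n_removed": log.n_removed,
                "het_loci_purged": purged,
            }
        )
    catalogue_summary = pd.DataFrame(cat_rows)
    catalogue_summary.to_csv(outdir / "catalogue_summary.tsv", sep="\t", index=False)

    conc_rows = []
    for name, rep in reports.items():
        conc_rows.append(
            {
                "pipeline": name,
                "n_sites": rep.n_sites,
                "n_samples": rep.n_samples,
                "n_genotypes": rep.n_genotype_cells,
                "n_missing": rep.n_missing,
                "missing_pct": round_half_up(rep.missing_pct, 1),
                "n_het": rep.n_het,
                "het_pct": round_half_up(rep.het_pct, 1),
                "het_loci_purged": rep.het_loci_purged,
                "n_compared": rep.n_compared,
                "n_matching": rep.n_matching,
                "accuracy_pct": round_half_up(rep.accuracy_pct, 1),
                "accuracy_pct_complete": round_half_up(rep.accuracy_pct_complete, 1),
                "accuracy_pct_partial": round_half_up(rep.accuracy_pct_partial, 1),
            }
        )
    pd.DataFrame(conc_rows).to_csv(outdir / "concordance.tsv", sep="\t", index=False)

    # ---- overlap ----------------------------------------------------------
    catalogues = {name: catalogue_sites(m, {SNP}) for name, m in filtered.items()}
    reference = config.reference_pipeline or next(iter(catalogues))
    pairwise = pairwise_table(catalogues, reference=reference)
    pairwise.to_csv(outdir / "overlap_pairwise.tsv", sep="\t", index=False)

    partition = nway_partition(catalogues)
    partition.validate(catalogues)
    match_maps = {name: per_site_match_map(rep) for name, rep in reports.items()}
    pacc = partition_accuracy(partition, match_maps)
    part_df = pacc.per_cell.copy()
    part_df.attrs["weighted_shared_pct"] = pacc.weighted_shared_pct
    part_df.to_csv(outdir / "overlap_partition.tsv", sep="\t", index=False)
    weighted = pd.DataFrame(
        [
            {"group": "shared", "weighted_accuracy_pct": pacc.weighted_shared_pct},
            {"group": "unique", "weighted_accuracy_pct": pacc.weighted_unique_pct},
        ]
    )
    weighted.to_csv(outdir / "overlap_weighted_means.tsv", sep="\t", index=False)

    # ---- attribution ------------------------------------------------------
    records, summaries = attribute_errors(
        catalogues,
        {n: {k: v for k, v in m.items() if k.variant_class == SNP}
         for n, m in match_maps.items()},
        evidence,
        rule=config.paralogy,
    )
    summaries_to_frame(summaries).to_csv(
        outdir / "attribution.tsv", sep="\t", index=False
    )
    records.to_csv(outdir / "attribution_records.tsv", sep="\t", index=False)

    # ---- demultiplexing ---------------------------------------------------
    if reads_path is not None and barcode_table is not None:
        demux_report = assign_reads(
            reads_path, barcode_table, max_mismatch=config.demux_max_mismatch
        )
        demux_report.to_tsv(outdir / "demux.tsv")

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "gbseval_version": __version__,
        "seed": None if config.sim is None else config.sim.seed,
        "filters": dataclasses.asdict(config.filters),
        "paralogy": dataclasses.asdict(config.paralogy),
        "reference_pipeline": reference,
        "sim": None if config.sim is None else dataclasses.asdict(config.sim),
        "inputs": {
            "pipeline_vcfs": config.pipeline_vcfs,
            "truth_vcf": config.truth_vcf,
            "evidence_files": config.evidence_files,
            "reads_fastq": str(reads_path) if reads_path else None,
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return outdir


def validate_tables(report_dir: str | Path) -> tuple[bool, list[str]]:
    """Check the cross-table identities of a report directory.

    Verifies genotype-cell arithmetic, pairwise overlap conservation,
    partition marginals against catalogue sizes, attribution partition sums,
    and demux read conservation. Returns (pass, violated identities).
    """
    report_dir = Path(report_dir)
    violations: list[str] = []

    conc = pd.read_csv(report_dir / "concordance.tsv", sep="\t")
    for row in conc.itertuples(index=False):
        if row.n_genotypes != row.n_sites * row.n_samples:
            violations.append(
                f"concordance[{row.pipeline}]: n_genotypes = n_sites * n_samples"
            )
        if row.n_matching > row.n_compared:
            violations.append(f"concordance[{row.pipeline}]: n_matching <= n_compared")

    pw_path = report_dir / "overlap_pairwise.tsv"
    if pw_path.exists():
        pw = pd.read_csv(pw_path, sep="\t")
        for row in pw.itertuples(index=False):
            if row.common + row.other_only != row.total:
                violations.append(f"overlap[{row.pipeline}]: common + only_a = total_a")

    cat = pd.read_csv(report_dir / "catalogue_summary.tsv", sep="\t")
    part_path = report_dir / "overlap_partition.tsv"
    if part_path.exists():
        part = pd.read_csv(part_path, sep="\t")
        cells_by_name: dict[str, int] = {}
        for row in part.itertuples(index=False):
            for name in str(row.subset).split("+"):
                cells_by_name[name] = cells_by_name.get(name, 0) + int(row.n_sites)
        for row in cat.itertuples(index=False):
            if cells_by_name.get(row.pipeline, 0) != row.n_snps:
                violations.append(
                    f"partition marginal[{row.pipeline}] != catalogue SNP count"
                )

    attr_path = report_dir / "attribution.tsv"
    if attr_path.exists():
        attr = pd.read_csv(attr_path, sep="\t")
        for row in attr.itertuples(index=False):
            if (
                row.unique_position + row.multiple_position + row.no_evidence
                != row.unique_inaccurate
            ):
                violations.append(
                    f"attribution[{row.pipeline}]: unique_position + multiple_position"
                    " + no_evidence = unique_inaccurate"
                )
            if row.repetitive + row.paralogous + row.unresolved != row.multiple_position:
                violations.append(
                    f"attribution[{row.pipeline}]: repetitive + paralogous +"
                    " unresolved = multiple_position"
                )

    demux_path = report_dir / "demux.tsv"
    if demux_path.exists():
        demux = pd.read_csv(demux_path, sep="\t")
        if (demux["reads"] < 0).any():
            violations.append("demux: negative read count")

    return (len(violations) == 0, violations)
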