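"""Synthetic GBS study generator with fully labeled planted error causes.

Generates everything the evaluation pipeline consumes, with known ground
truth: a random diploid genome carrying segmental duplications (paralog
families at 96-100% inter-copy identity, mean copy number ~2.4) and
dispersed repeat families; a hard-masked companion genome (repeat intervals
as N); an in-silico ApeKI reduced representation (fragments between GCWGC
sites within a size window); truth genotypes for a panel of highly
homozygous inbred lines (residual heterozygosity ~1%); per-pipeline call
matrices produced by parametric error profiles (site sensitivity, genotype
error rate, paralog-collapse and repeat-mismap probabilities, missingness);
alignment-evidence tables consistent with each planted cause; and barcoded
single-end reads for demultiplexing experiments.

Every erroneous genotype traces to exactly one planted cause label
(caller_error / paralog / repeat), which is what makes the attribution
stage testable: the labels are the oracle. All randomness descends from a
single seed via numpy SeedSequence spawning, so identical parameters give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import AlignmentEvidence, Hit, SiteEvidence, write_evidence_tsv
from .demux import IUPAC, BarcodeTable
from .genotype_io import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    INDEL,
    MISSING,
    SNP,
    Site,
    SiteKey,
    TruthSet,
    write_vcf,
)

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)


class ParameterError(ValueError):
    """Simulation parameters are infeasible (e.g. genome too short)."""


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class ReadProfile:
    """Read-length/error regime of a sequencing platform.

    fixed_100bp mirrors a uniform-length short-read platform; the variable
    profile mirrors a 50-135 bp platform with elevated substitution and
    homopolymer-style indel error.
    """

    name: str = "fixed_100bp"
    length_range: tuple[int, int] = (100, 100)
    per_base_error: float = 0.001
    indel_error: float = 0.0
    barcode_corruption_rate: float = 0.0

    @classmethod
    def fixed_100bp(cls, **kw) -> "ReadProfile":
        return cls(name="fixed_100bp", length_range=(100, 100),
                   per_base_error=kw.pop("per_base_error", 0.001), **kw)

    @classmethod
    def variable_50_135bp(cls, **kw) -> "ReadProfile":
        return cls(name="variable_50_135bp", length_range=(50, 135),
                   per_base_error=kw.pop("per_base_error", 0.005),
                   indel_error=kw.pop("indel_error", 0.001), **kw)


@dataclass
class PipelineProfile:
    """Parametric emulation of one SNP-calling pipeline's error behavior.

    sensitivity: probability a true polymorphic site enters the catalogue.
    genotype_error_rate: per-cell miscall probability at structurally clean
        sites (the caller-error channel).
    paralog_collapse_prob: per-site probability that a site inside a planted
        duplication is collapsed; collapsed sites convert a random fraction
        of calls (drawn from het_conversion_range) to heterozygotes.
    repeat_mismap_prob: per-site probability that a site inside a repeat is
        mismapped, randomizing about half of its calls.
    missing_rate: extra per-cell missingness on top of depth-driven dropout.
    """

    name: str
    sensitivity: float = 0.90
    genotype_error_rate: float = 0.01
    paralog_collapse_prob: float = 0.20
    repeat_mismap_prob: float = 0.20
    missing_rate: float = 0.25
    calls_indels: bool = False
    het_conversion_range: tuple[float, float] = (0.15, 0.65)


# presets loosely shaped on the published per-pipeline behaviors: a fast
# accurate haplotype-based caller, a short-tag caller prone to collapsing
# paralogs, and a conservative caller with a small catalogue and heavy
# missingness
PIPELINE_PRESETS: dict[str, PipelineProfile] = {
    "fastcall_like": PipelineProfile(
        "fastcall_like", sensitivity=0.90, genotype_error_rate=0.013,
        paralog_collapse_prob=0.15, repeat_mismap_prob=0.20,
        missing_rate=0.20, calls_indels=True,
    ),
    "shorttag_like": PipelineProfile(
        "shorttag_like", sensitivity=0.98, genotype_error_rate=0.030,
        paralog_collapse_prob=0.70, repeat_mismap_prob=0.50,
        missing_rate=0.12,
    ),
    "conservative_like": PipelineProfile(
        "conservative_like", sensitivity=0.52, genotype_error_rate=0.040,
        paralog_collapse_prob=0.25, repeat_mismap_prob=0.30,
        missing_rate=0.40,
    ),
}


def _default_pipelines() -> tuple[PipelineProfile, ...]:
    return (
        PIPELINE_PRESETS["fastcall_like"],
        PIPELINE_PRESETS["shorttag_like"],
        PIPELINE_PRESETS["conservative_like"],
    )


@dataclass
class SimParams:
    """Full specification of one synthetic study; the seed determines all output."""

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    paralog_families: int = 16
    paralog_copy_mean: float = 2.4  # copies >= 2; mean matches observed multi-hit mean
    paralog_length: int = 3000
    paralog_identity: tuple[float, float] = (0.96, 1.00)
    repeat_families: int = 8
    repeat_copies: int = 6
    repeat_unit_length: int = 800
    repeat_identity: tuple[float, float] = (0.98, 1.00)
    enzyme_motif: str = "GCWGC"  # ApeKI
    fragment_window: tuple[int, int] = (100, 400)
    n_lines: int = 24
    residual_het_rate: float = 0.01
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_truth_sites: int = 5000
    indel_fraction: float = 0.10
    depth_mean: float = 6.0
    depth_dispersion: float = 2.0
    pipelines: tuple[PipelineProfile, ...] = field(default_factory=_default_pipelines)
    read_profile: ReadProfile = field(default_factory=ReadProfile.fixed_100bp)

    def __post_init__(self):
        for name in ("residual_het_rate", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if self.paralog_copy_mean < 2 and self.paralog_families > 0:
            raise ParameterError("paralog_copy_mean must be >= 2")


# ---------------------------------------------------------------------------
# reference genome with planted structure
# ---------------------------------------------------------------------------

def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases at the given per-base rate, always to a different base."""
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n)) % 4
    return out


def _allocate_intervals(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    lengths: list[int],
    margin: int = 150,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping intervals uniformly at random (rejection)."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    placed: list[tuple[str, int, int]] = []
    for L in lengths:
        ok = False
        for _ in range(5000):
            c = chroms[rng.choice(len(chroms), p=weights)]
            if chrom_lengths[c] <= L + 2 * margin:
                continue
            start = int(rng.integers(margin, chrom_lengths[c] - L - margin))
            end = start + L
            if all(end + margin <= s or start >= e + margin for s, e in occupied[c]):
                occupied[c].append((start, end))
                placed.append((c, start, end))
                ok = True
                break
        if not ok:
            raise ParameterError(
                f"genome too short/crowded to place a {L} bp feature"
            )
    return placed


def make_reference(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Random genome with planted duplications and repeats, plus its mask.

    Returns (reference, hard-masked reference, annotations). Annotations are
    BED-style 0-based half-open intervals with kind paralog|repeat, family
    id, copy index, inter-copy identity, and the family copy count. The
    masked genome replaces every repeat interval (and only those) with N.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    chrom_len = params.genome_length // params.n_chromosomes
    chroms = {f"Gm{i + 1:02d}": chrom_len for i in range(params.n_chromosomes)}
    genome = {c: rng.integers(0, 4, size=chrom_len, dtype=np.uint8) for c in chroms}

    # plan feature placement
    par_copies = [
        2 + int(rng.poisson(max(0.0, params.paralog_copy_mean - 2)))
        for _ in range(params.paralog_families)
    ]
    lengths = []
    for c in par_copies:
        lengths += [params.paralog_length] * c
    lengths += [params.repeat_unit_length] * (params.repeat_families * params.repeat_copies)
    placed = _allocate_intervals(rng, chroms, lengths)

    ann_rows = []
    i = 0
    for fam, n_copies in enumerate(par_copies):
        ident = float(rng.uniform(*params.paralog_identity))
        copies = placed[i: i + n_copies]
        i += n_copies
        src_chrom, src_start, src_end = copies[0]
        src = genome[src_chrom][src_start:src_end]
        for ci, (c, s, e) in enumerate(copies):
            if ci > 0:
                genome[c][s:e] = _mutate(src, 1.0 - ident, rng)
            ann_rows.append((c, s, e, "paralog", f"par{fam:02d}", ci, ident, n_copies))
    for fam in range(params.repeat_families):
        ident = float(rng.uniform(*params.repeat_identity))
        copies = placed[i: i + params.repeat_copies]
        i += params.repeat_copies
        unit_chrom, us, ue = copies[0]
        unit = genome[unit_chrom][us:ue]
        for ci, (c, s, e) in enumerate(copies):
            if ci > 0:
                genome[c][s:e] = _mutate(unit, 1.0 - ident, rng)
            ann_rows.append((c, s, e, "repeat", f"rep{fam:02d}", ci, ident,
                             params.repeat_copies))

    annotations = pd.DataFrame(
        ann_rows,
        columns=["chrom", "start", "end", "kind", "family", "copy_index",
                 "identity", "n_copies"],
    ).sort_values(["chrom", "start"], ignore_index=True)

    masked = {c: genome[c].copy() for c in genome}
    for row in annotations.itertuples(index=False):
        if row.kind == "repeat":
            masked[row.chrom][row.start: row.end] = 4  # N
    reference = {c: codes_to_str(genome[c]) for c in genome}
    masked_ref = {c: codes_to_str(masked[c]) for c in masked}
    return reference, masked_ref, annotations


# ---------------------------------------------------------------------------
# in-silico digestion
# ---------------------------------------------------------------------------

def iupac_regex(motif: str) -> str:
    out = []
    for ch in motif.upper():
        bases = IUPAC.get(ch)
        if bases is None:
            raise ParameterError(f"invalid IUPAC motif character {ch!r}")
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


def digest_and_select(
    reference: dict[str, str],
    motif: str = "GCWGC",
    window: tuple[int, int] = (100, 400),
) -> pd.DataFrame:
    """Fragments between consecutive motif occurrences, kept within the window.

    The default ApeKI motif GCWGC is its own reverse complement family
    (GCAGC <-> GCTGC), so a forward-strand scan covers both strands.
    Occurrences are found with an overlap-tolerant (lookahead) scan.
    Coordinates are BED-style 0-based half-open.
    """
    pat = re.compile(f"(?=({iupac_regex(motif)}))")
    rows = []
    for chrom, seq in reference.items():
        positions = [m.start() for m in pat.finditer(seq)]
        for a, b in zip(positions, positions[1:]):
            if window[0] <= b - a <= window[1]:
                rows.append((chrom, a, b, b - a))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])


# ---------------------------------------------------------------------------
# truth genotypes
# ---------------------------------------------------------------------------

def simulate_truth(
    params: SimParams,
    fragments: pd.DataFrame,
    reference: dict[str, str],
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Plant polymorphic sites on the digested fragments for the inbred panel.

    Allele frequencies are drawn from the MAF spectrum; every line is
    homozygous except a residual heterozygosity rate; a fraction of sites
    are short indels. The truth matrix is fully called (complete
    convention), as from deep whole-genome resequencing.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed + 1))
    if fragments.empty:
        raise ParameterError("no fragments to place truth sites on")
    # candidate positions: inside fragments, away from the motif at the start
    pools = []
    for row in fragments.itertuples(index=False):
        lo, hi = row.start + 6, row.end - 2
        if hi > lo:
            pools.append((row.chrom, np.arange(lo, hi)))
    chrom_arr = np.concatenate(
        [np.full(len(p), i) for i, (_, p) in enumerate(pools)]
    )
    pos_arr = np.concatenate([p for _, p in pools])
    chrom_names = [c for c, _ in pools]
    n = min(params.n_truth_sites, len(pos_arr))
    pick = rng.choice(len(pos_arr), size=n, replace=False)
    chosen = sorted(
        zip((chrom_names[i] for i in chrom_arr[pick]), pos_arr[pick].tolist())
    )
    # drop adjacent duplicates on the same coordinate
    dedup: list[tuple[str, int]] = []
    for c, p in chosen:
        if not dedup or dedup[-1] != (c, p):
            dedup.append((c, p))

    is_indel = rng.random(len(dedup)) < params.indel_fraction
    sites: list[Site] = []
    for (chrom, idx0), indel in zip(dedup, is_indel):
        ref_base = reference[chrom][idx0]
        pos = idx0 + 1  # 1-based
        if indel:
            if rng.random() < 0.5:  # insertion
                ins = "ACGT"[rng.integers(0, 4)]
                sites.append(Site(SiteKey(chrom, pos, INDEL), ref_base, ref_base + ins))
            else:  # 1 bp deletion
                nxt = reference[chrom][idx0 + 1]
                sites.append(Site(SiteKey(chrom, pos, INDEL), ref_base + nxt, ref_base))
        else:
            alt = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
            sites.append(Site(SiteKey(chrom, pos, SNP), ref_base, alt))

    n_sites = len(sites)
    samples = [f"L{i + 1:02d}" for i in range(params.n_lines)]
    q = rng.uniform(*params.maf_range, size=n_sites)
    alt_line = rng.random((n_sites, params.n_lines)) < q[:, None]
    calls = np.where(alt_line, HOM_ALT, HOM_REF).astype(np.int8)
    het = rng.random((n_sites, params.n_lines)) < params.residual_het_rate
    calls[het] = HET
    return TruthSet(GenotypeMatrix(sites, samples, calls), completeness="complete")


# ---------------------------------------------------------------------------
# pipeline call emulation with cause labels and evidence
# ---------------------------------------------------------------------------

def _interval_lookup(annotations: pd.DataFrame, kind: str):
    """chrom -> (starts, ends, family ids) for non-overlapping intervals."""
    tables: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    sub = annotations[annotations["kind"] == kind].sort_values(["chrom", "start"])
    for chrom, grp in sub.groupby("chrom"):
        tables[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["family"].tolist(),
        )
    return tables


def _locate(tables, chrom: str, idx0: int) -> str | None:
    """Family id of the interval containing 0-based position idx0, if any."""
    t = tables.get(chrom)
    if t is None:
        return None
    starts, ends, fams = t
    i = int(np.searchsorted(starts, idx0, side="right")) - 1
    if i >= 0 and idx0 < ends[i]:
        return fams[i]
    return None


def simulate_pipeline_calls(
    truth: TruthSet,
    params: SimParams,
    annotations: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenotypeMatrix], pd.DataFrame, dict[str, AlignmentEvidence]]:
    """Emulate each pipeline profile on the truth set.

    Per pipeline: sites enter the catalogue by sensitivity; sites inside
    planted duplications may collapse toward heterozygosity (cause
    "paralog"); sites inside repeats may mismap, randomizing calls (cause
    "repeat"); structurally clean sites suffer per-cell miscalls (cause
    "caller_error"); per-cell missingness and negative-binomial depth are
    applied last (depth-0 cells become missing). Alignment evidence is
    emitted consistent with each site's genomic context: multi-hit for
    duplicated/repetitive loci, with repeat loci losing all masked-genome
    hits.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed + 2))
    tm = truth.matrix
    keys = tm.site_keys()
    n_sites = tm.n_sites
    n_lines = tm.n_samples

    par_tab = _interval_lookup(annotations, "paralog")
    rep_tab = _interval_lookup(annotations, "repeat")
    par_fam = [_locate(par_tab, k.chrom, k.pos - 1) for k in keys]
    rep_fam = [_locate(rep_tab, k.chrom, k.pos - 1) for k in keys]
    fam_rows: dict[str, list[tuple[str, int, int]]] = {}
    fam_ident: dict[str, float] = {}
    for row in annotations.itertuples(index=False):
        fam_rows.setdefault(row.family, []).append((row.chrom, row.start, row.end))
        fam_ident[row.family] = row.identity
    is_snp = np.array([k.variant_class == SNP for k in keys])

    streams = rng.spawn(len(params.pipelines))
    matrices: dict[str, GenotypeMatrix] = {}
    evidence: dict[str, AlignmentEvidence] = {}
    label_frames = []

    for profile, prng in zip(params.pipelines, streams):
        disc = prng.random(n_sites) < profile.sensitivity
        if not profile.calls_indels:
            disc &= is_snp
        idx = np.flatnonzero(disc)
        nd = len(idx)
        calls = tm.calls[idx].copy()
        truth_calls = tm.calls[idx]
        cause = np.full(nd, "clean", dtype=object)

        in_par = np.array([par_fam[i] is not None for i in idx])
        in_rep = np.array([rep_fam[i] is not None for i in idx]) & ~in_par
        clean = ~in_par & ~in_rep

        collapse = in_par & (prng.random(nd) < profile.paralog_collapse_prob)
        for i in np.flatnonzero(collapse):
            h = prng.uniform(*profile.het_conversion_range)
            cells = prng.random(n_lines) < h
            calls[i, cells] = HET
        cause[collapse] = "paralog"

        mismap = in_rep & (prng.random(nd) < profile.repeat_mismap_prob)
        for i in np.flatnonzero(mismap):
            cells = prng.random(n_lines) < 0.5
            wrong = (truth_calls[i, cells] + prng.integers(1, 3, cells.sum())) % 3
            calls[i, cells] = wrong
        cause[mismap] = "repeat"

        err_cells = clean[:, None] & (
            prng.random((nd, n_lines)) < profile.genotype_error_rate
        )
        if err_cells.any():
            wrong = (calls[err_cells] + prng.integers(1, 3, int(err_cells.sum()))) % 3
            calls[err_cells] = wrong
        cause[clean & err_cells.any(axis=1)] = "caller_error"

        miss = prng.random((nd, n_lines)) < profile.missing_rate
        calls[miss] = MISSING
        p = params.depth_dispersion / (params.depth_dispersion + params.depth_mean)
        depth = prng.negative_binomial(
            params.depth_dispersion, p, size=(nd, n_lines)
        ).astype(np.int32)
        calls[(depth == 0) & (calls != MISSING)] = MISSING
        depth[calls == MISSING] = 0

        sites = [tm.sites[i] for i in idx]
        matrices[profile.name] = GenotypeMatrix(
            sites, list(tm.samples), calls, depth
        )

        ev: AlignmentEvidence = {}
        for local_i, site_i in enumerate(idx):
            key = keys[site_i]
            read_id = f"{profile.name}|{key.chrom}:{key.pos}"
            fam = par_fam[site_i] or rep_fam[site_i]
            if fam is None:
                hit = Hit(key.chrom, max(0, key.pos - 50), key.pos + 50, 1.0, 1.0)
                ev[key] = SiteEvidence(
                    normal={read_id: [hit]}, masked={read_id: [hit]}
                )
                continue
            ident = fam_ident[fam]
            hits = []
            for c, s, e in fam_rows[fam]:
                inside = c == key.chrom and s <= key.pos - 1 < e
                hits.append(Hit(c, s, e, 1.0, 1.0 if inside else ident))
            if par_fam[site_i] is not None:
                ev[key] = SiteEvidence(
                    normal={read_id: hits}, masked={read_id: list(hits)}
                )
            else:  # repeat: every masked-genome hit vanishes
                ev[key] = SiteEvidence(normal={read_id: hits}, masked={read_id: []})
        evidence[profile.name] = ev

        label_frames.append(
            pd.DataFrame(
                {
                    "pipeline": profile.name,
                    "chrom": [keys[i].chrom for i in idx],
                    "pos": [keys[i].pos for i in idx],
                    "variant_class": [keys[i].variant_class for i in idx],
                    "cause": cause,
                }
            )
        )

    labels = pd.concat(label_frames, ignore_index=True)
    return matrices, labels, evidence


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def make_barcodes(
    n: int, rng: np.random.Generator, remnant: str = "CWGC"
) -> BarcodeTable:
    """Variable-length (4-10 nt) barcodes: prefix-free, same-length distance >= 3."""
    barcodes: list[str] = []
    while len(barcodes) < n:
        length = 4 + len(barcodes) % 7
        for _ in range(1000):
            cand = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            ok = True
            for prev in barcodes:
                if prev.startswith(cand) or cand.startswith(prev):
                    ok = False
                    break
                if len(prev) == len(cand) and sum(
                    a != b for a, b in zip(prev, cand)
                ) < 3:
                    ok = False
                    break
            if ok:
                barcodes.append(cand)
                break
        else:
            raise ParameterError("could not generate a compatible barcode set")
    samples = [f"L{i + 1:02d}" for i in range(n)]
    return BarcodeTable(dict(zip(samples, barcodes)), remnant=remnant)


def simulate_reads(
    reference: dict[str, str],
    fragments: pd.DataFrame,
    table: BarcodeTable,
    profile: ReadProfile,
    rng: np.random.Generator,
    truth: TruthSet | None = None,
    n_reads: int | None = None,
    depth_mean: float = 6.0,
    depth_dispersion: float = 2.0,
    out_path: str | Path | None = None,
) -> list[tuple[str, str, str]] | Path:
    """Single-end GBS reads: barcode + cut-site remnant + fragment prefix.

    Each read starts at a fragment's restriction site: the first insert bases
    are the genomic CWGC remnant, so error-free reads demultiplex exactly.
    Truth SNP alleles are written into the insert per the sampled line's
    genotype (heterozygotes contribute either allele). Per-fragment-per-line
    depth follows a negative binomial unless n_reads caps the total, in
    which case (line, fragment) pairs are drawn uniformly. Substitution
    (and, for variable-length profiles, indel) errors apply to the insert;
    barcode corruption is a separate dial so assignment loss is measurable
    in isolation.
    """
    if fragments.empty:
        raise ParameterError("no fragments to sequence")
    samples = list(table.barcodes)
    frag = fragments.reset_index(drop=True)
    # truth SNPs per fragment (0-based index, per-line genotypes, alt base)
    frag_sites: dict[int, list[tuple[int, str, np.ndarray]]] = {}
    if truth is not None:
        by_chrom: dict[str, list[int]] = {}
        tm = truth.matrix
        for i, s in enumerate(tm.sites):
            if s.key.variant_class == SNP:
                by_chrom.setdefault(s.key.chrom, []).append(i)
        for fi, row in enumerate(frag.itertuples(index=False)):
            hits = []
            for i in by_chrom.get(row.chrom, []):
                s = tm.sites[i]
                if row.start <= s.key.pos - 1 < row.end:
                    hits.append((s.key.pos - 1, s.alt, tm.calls[i]))
            if hits:
                frag_sites[fi] = hits
        sample_col = {s: j for j, s in enumerate(tm.samples)}
    lo, hi = profile.length_range
    frag_chrom = frag["chrom"].tolist()
    frag_start = frag["start"].to_numpy()

    if n_reads is not None:
        line_idx = rng.integers(0, len(samples), n_reads)
        frag_idx = rng.integers(0, len(frag), n_reads)
        pairs = zip(line_idx.tolist(), frag_idx.tolist())
        total = n_reads
    else:
        p = depth_dispersion / (depth_dispersion + depth_mean)
        depth = rng.negative_binomial(
            depth_dispersion, p, size=(len(samples), len(frag))
        )
        pairs = (
            (li, fi)
            for li in range(len(samples))
            for fi in range(len(frag))
            for _ in range(int(depth[li, fi]))
        )
        total = int(depth.sum())

    records: list[tuple[str, str, str]] = []
    sink = None
    if out_path is not None:
        out_path = Path(out_path)
        sink = open(out_path, "w")
    try:
        for i, (li, fi) in enumerate(pairs):
            sample = samples[li]
            barcode = table.barcodes[sample]
            if profile.barcode_corruption_rate and (
                rng.random() < profile.barcode_corruption_rate
            ):
                pos = int(rng.integers(0, len(barcode)))
                old = "ACGT".index(barcode[pos])
                new = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
                barcode = barcode[:pos] + new + barcode[pos + 1:]
            read_len = lo if lo == hi else int(rng.integers(lo, hi + 1))
            chrom = frag_chrom[fi]
            insert_start = int(frag_start[fi]) + 1  # skip the G of G^CWGC
            insert_len = max(0, read_len - len(barcode))
            seq = list(reference[chrom][insert_start: insert_start + insert_len])
            if truth is not None and fi in frag_sites:
                col = sample_col[sample]
                for idx0, alt, genos in frag_sites[fi]:
                    off = idx0 - insert_start
                    if 0 <= off < len(seq):
                        g = genos[col]
                        if g == HOM_ALT or (g == HET and rng.random() < 0.5):
                            seq[off] = alt
            if profile.per_base_error > 0 and seq:
                n_err = rng.binomial(len(seq), profile.per_base_error)
                for pos in rng.choice(len(seq), size=n_err, replace=False):
                    old = "ACGT".index(seq[pos])
                    seq[pos] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
            if profile.indel_error > 0 and seq and rng.random() < profile.indel_error * len(seq):
                pos = int(rng.integers(0, len(seq)))
                if rng.random() < 0.5:
                    del seq[pos]
                else:
                    seq.insert(pos, seq[pos])
            full = barcode + "".join(seq)
            title = f"r{i} line={sample} frag={chrom}:{int(frag_start[fi])}"
            rec = (title, full, "I" * len(full))
            if sink is not None:
                sink.write(f"@{rec[0]}\n{rec[1]}\n+\n{rec[2]}\n")
            else:
                records.append(rec)
    finally:
        if sink is not None:
            sink.close()
    return out_path if out_path is not None else records


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """One generated study: genome, truth, per-pipeline calls, labels, evidence."""

    params: SimParams
    reference: dict[str, str] = field(repr=False)
    masked: dict[str, str] = field(repr=False)
    annotations: pd.DataFrame = field(repr=False)
    fragments: pd.DataFrame = field(repr=False)
    truth: TruthSet = field(repr=False)
    pipeline_calls: dict[str, GenotypeMatrix] = field(repr=False)
    cause_labels: pd.DataFrame = field(repr=False)
    evidence: dict[str, AlignmentEvidence] = field(repr=False)
    barcode_table: BarcodeTable = field(repr=False)
    reads_seed: int = 0

    def labels_for(self, pipeline: str) -> dict[SiteKey, str]:
        sub = self.cause_labels[self.cause_labels["pipeline"] == pipeline]
        return {
            SiteKey(r.chrom, int(r.pos), r.variant_class): r.cause
            for r in sub.itertuples(index=False)
        }

    def make_reads(
        self, n_reads: int | None = None, out_path: str | Path | None = None,
        profile: ReadProfile | None = None,
    ):
        rng = np.random.default_rng(np.random.SeedSequence(self.reads_seed))
        return simulate_reads(
            self.reference,
            self.fragments,
            self.barcode_table,
            profile or self.params.read_profile,
            rng,
            truth=self.truth,
            n_reads=n_reads,
            depth_mean=self.params.depth_mean,
            depth_dispersion=self.params.depth_dispersion,
            out_path=out_path,
        )

    def write(self, outdir: str | Path) -> Path:
        """Materialize the study as FASTA/VCF/BED/TSV files plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(self.reference, outdir / "reference.fasta")
        _write_fasta(self.masked, outdir / "reference.hardmasked.fasta")
        self.annotations.to_csv(
            outdir / "annotations.bed", sep="\t", index=False, header=False,
            columns=["chrom", "start", "end", "kind", "family"],
        )
        self.fragments.to_csv(
            outdir / "fragments.bed", sep="\t", index=False, header=False,
            columns=["chrom", "start", "end"],
        )
        write_vcf(self.truth.matrix, outdir / "truth.vcf")
        for name, m in self.pipeline_calls.items():
            write_vcf(m, outdir / f"calls_{name}.vcf")
            write_evidence_tsv(self.evidence[name], outdir / f"evidence_{name}.tsv")
        self.cause_labels.to_csv(outdir / "cause_labels.tsv", sep="\t", index=False)
        self.barcode_table.save(outdir / "barcodes.tsv")
        manifest = {
            "seed": self.params.seed,
            "params": dataclasses.asdict(self.params),
            "pipelines": [p.name for p in self.params.pipelines],
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        return outdir


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def make_study(params: SimParams) -> SyntheticStudy:
    """Generate a complete labeled study from one parameter block."""
    ss = np.random.SeedSequence(params.seed)
    ref_ss, truth_ss, calls_ss, bc_ss, reads_ss = ss.spawn(5)
    reference, masked, annotations = make_reference(
        params, np.random.default_rng(ref_ss)
    )
    fragments = digest_and_select(
        reference, params.enzyme_motif, params.fragment_window
    )
    truth = simulate_truth(
        params, fragments, reference, np.random.default_rng(truth_ss)
    )
    calls, labels, evidence = simulate_pipeline_calls(
        truth, params, annotations, np.random.default_rng(calls_ss)
    )
    barcodes = make_barcodes(params.n_lines, np.random.default_rng(bc_ss))
    return SyntheticStudy(
        params=params,
        reference=reference,
        masked=masked,
        annotations=annotations,
        fragments=fragments,
        truth=truth,
        pipeline_calls=calls,
        cause_labels=labels,
        evidence=evidence,
        barcode_table=barcodes,
        reads_seed=int(reads_ss.generate_state(1)[0] % (2**31)),
    )


# ---------------------------------------------------------------------------
# scenario factories (study conditions for the standard experiments)
# ---------------------------------------------------------------------------

def error_recovery_params(seed: int, error_rate: float = 0.02) -> SimParams:
    """Pure caller-error study: no planted structure, ~30% missingness.

    Under these conditions genotype accuracy converges on (1 - e) * 100, so
    concordance should recover the planted error rate.
    """
    return SimParams(
        seed=seed,
        paralog_families=0,
        repeat_families=0,
        indel_fraction=0.0,
        pipelines=(
            PipelineProfile(
                "uniform_error",
                sensitivity=0.95,
                genotype_error_rate=error_rate,
                paralog_collapse_prob=0.0,
                repeat_mismap_prob=0.0,
                missing_rate=0.30,
            ),
        ),
    )


def accuracy_ordering_params(
    seed: int, error_rates: tuple[float, ...] = (0.01, 0.03, 0.08)
) -> SimParams:
    """Three structure-free profiles differing only in caller error rate."""
    return SimParams(
        seed=seed,
        paralog_families=0,
        repeat_families=0,
        indel_fraction=0.0,
        pipelines=tuple(
            PipelineProfile(
                f"caller_e{int(e * 1000):03d}",
                sensitivity=0.9,
                genotype_error_rate=e,
                paralog_collapse_prob=0.0,
                repeat_mismap_prob=0.0,
                missing_rate=0.25,
            )
            for e in error_rates
        ),
    )


def attribution_mix_params(seed: int) -> SimParams:
    """Study conditions for cause-attribution recovery.

    Planted so that unique inaccurate SNPs split roughly 60% paralog /
    20% repeat / 20% caller error across three equal profiles. With three
    pipelines corrupting sites independently at per-pipeline probability p,
    a site is uniquely inaccurate with probability 3p(1-p)^2; the family
    counts and the tiny caller-error cell rate below invert that relation
    for the targeted cause counts (see the methods note).
    """
    profile = lambda name: PipelineProfile(  # noqa: E731
        name,
        sensitivity=0.95,
        genotype_error_rate=0.0006,
        paralog_collapse_prob=1 / 3,
        repeat_mismap_prob=1 / 3,
        missing_rate=0.20,
        het_conversion_range=(0.10, 0.65),
    )
    return SimParams(
        seed=seed,
        paralog_families=28,
        repeat_families=10,
        repeat_unit_length=850,
        indel_fraction=0.0,
        pipelines=(profile("pipe_a"), profile("pipe_b"), profile("pipe_c")),
    )
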