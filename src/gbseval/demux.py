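"""Barcode demultiplexing of GBS reads and assignment-loss measurement.

GBS reads begin with an inline sample barcode (4-10 nt, variable length)
followed by the restriction-enzyme cut-site remnant (CWGC for ApeKI, IUPAC
codes allowed). A read is assigned to the unique sample whose barcode
matches the read prefix within the mismatch budget AND is followed by the
remnant; barcodes are tried longest-first so that no read lands on a
barcode that is a prefix of a longer matching one. Ambiguous reads (two or
more candidates at the winning length) and unmatched reads are counted as
unassigned; every input read appears exactly once across per-sample outputs
plus the unassigned pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genotype_io import InputError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

APEKI_REMNANT = "CWGC"  # 5' half-site left by ApeKI (G^CWGC)

UNASSIGNED = "unassigned"


class FastqFormatError(ValueError):
    """Malformed FASTQ record, reported with its record index."""


def iupac_matches(pattern: str, seq: str) -> bool:
    """True iff seq matches the IUPAC pattern exactly (equal lengths)."""
    if len(pattern) != len(seq):
        return False
    for p, b in zip(pattern, seq):
        if b not in IUPAC.get(p, ""):
            return False
    return True


@dataclass
class BarcodeTable:
    """sample -> barcode map plus the enzyme remnant pattern."""

    barcodes: dict[str, str]
    remnant: str = APEKI_REMNANT

    def __post_init__(self):
        seqs = list(self.barcodes.values())
        if len(set(seqs)) != len(seqs):
            raise InputError("duplicate barcode sequences")
        for s in seqs:
            if not s or any(c not in "ACGT" for c in s):
                raise InputError(f"barcode {s!r} is not plain DNA")
        if any(c not in IUPAC for c in self.remnant):
            raise InputError(f"remnant {self.remnant!r} has non-IUPAC characters")
        # a barcode that is a prefix of another, with the gap looking like the
        # remnant, would alias reads between samples; refuse such tables
        for a in seqs:
            for b in seqs:
                if a != b and b.startswith(a):
                    gap = b[len(a): len(a) + len(self.remnant)]
                    if iupac_matches(self.remnant[: len(gap)], gap):
                        raise InputError(
                            f"barcode {a!r} is a remnant-ambiguous prefix of {b!r}"
                        )

    @classmethod
    def load(cls, path: str | Path, remnant: str = APEKI_REMNANT) -> "BarcodeTable":
        """Read a 2-column TSV (sample, barcode); lines starting # ignored."""
        barcodes: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"bad barcode line: {line!r}")
            barcodes[parts[0]] = parts[1].upper()
        return cls(barcodes, remnant=remnant)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{b}\n" for s, b in self.barcodes.items())
        )


@dataclass
class DemuxReport:
    """Per-sample read counts plus the unassigned pool."""

    counts: dict[str, int]
    unassigned: int
    max_mismatch: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unassigned

    @property
    def unassigned_fraction(self) -> float:
        return self.unassigned / self.total if self.total else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "reads": n} for s, n in self.counts.items()]
        rows.append({"sample": UNASSIGNED, "reads": self.unassigned})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _hamming_leq(a: str, b: str, budget: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > budget:
                return False
    return True


def match_read(seq: str, table: BarcodeTable, max_mismatch: int = 0) -> tuple[str | None, int]:
    """Resolve one read: (sample or None, trim length).

    Barcodes are tried grouped by length, longest first; within the longest
    length that yields any candidate, a unique candidate wins and ties are
    unassigned. The trim length covers barcode + remnant.
    """
    seq = seq.upper()
    by_len: dict[int, list[tuple[str, str]]] = {}
    for sample, bc in table.barcodes.items():
        by_len.setdefault(len(bc), []).append((sample, bc))
    rem = table.remnant
    for length in sorted(by_len, reverse=True):
        if len(seq) < length + len(rem):
            continue
        candidates = [
            sample
            for sample, bc in by_len[length]
            if _hamming_leq(seq[:length], bc, max_mismatch)
            and iupac_matches(rem, seq[length: length + len(rem)])
        ]
        if len(candidates) == 1:
            return candidates[0], length + len(rem)
        if len(candidates) > 1:
            return None, 0  # ambiguous tie
    return None, 0


def _iter_fastq(source) -> Iterator[tuple[str, str, str]]:
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    it = FastqGeneralIterator(handle)
    i = 0
    try:
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"record {i}: {exc}") from exc
            i += 1
            yield rec
    finally:
        if close:
            handle.close()


def assign_reads(
    reads,
    table: BarcodeTable,
    max_mismatch: int = 0,
    out_dir: str | Path | None = None,
) -> DemuxReport:
    """Demultiplex a FASTQ stream (path or handle) against a barcode table.

    Assigned reads are trimmed of barcode + remnant; with out_dir set, one
    FASTQ per sample plus unassigned.fastq are written. Assignment is
    deterministic and independent of read order.
    """
    counts = {s: 0 for s in table.barcodes}
    unassigned = 0
    handles: dict[str, object] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def sink(name: str):
        if out_path is None:
            return None
        if name not in handles:
            handles[name] = open(out_path / f"{name}.fastq", "w")
        return handles[name]

    n_total = 0
    try:
        for title, seq, qual in _iter_fastq(reads):
            n_total += 1
            sample, trim = match_read(seq, table, max_mismatch)
            if sample is None:
                unassigned += 1
                h = sink(UNASSIGNED)
                if h:
                    h.write(f"@{title}\n{seq}\n+\n{qual}\n")
            else:
                counts[sample] += 1
                h = sink(sample)
                if h:
                    h.write(f"@{title}\n{seq[trim:]}\n+\n{qual[trim:]}\n")
    finally:
        for h in handles.values():
            h.close()
    if n_total == 0:
        raise InputError("empty read stream")
    return DemuxReport(counts=counts, unassigned=unassigned, max_mismatch=max_mismatch)


def demux_delta(report_a: DemuxReport, report_b: DemuxReport) -> dict:
    """Per-sample and total assignment deltas between two runs on the same reads.

    recovered_points is the drop in unassigned percentage from A to B
    (e.g. 19.7% -> 2.0% gives 17.7 points).
    """
    if report_a.total != report_b.total:
        raise InputError(
            f"reports cover different read totals: {report_a.total} vs {report_b.total}"
        )
    samples = sorted(set(report_a.counts) | set(report_b.counts))
    per_sample = pd.DataFrame(
        {
            "sample": samples,
            "reads_a": [report_a.counts.get(s, 0) for s in samples],
            "reads_b": [report_b.counts.get(s, 0) for s in samples],
        }
    )
    per_sample["delta"] = per_sample["reads_b"] - per_sample["reads_a"]
    return {
        "per_sample": per_sample,
        "unassigned_a": report_a.unassigned,
        "unassigned_b": report_b.unassigned,
        "unassigned_delta": report_b.unassigned - report_a.unassigned,
        "recovered_points": 100.0
        * (report_a.unassigned_fraction - report_b.unassigned_fraction),
    }
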