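"""Quality filtering and primer trimming for 16S amplicon contig reads.

Implements the filter set used for merged 341F/787R amplicon contigs:
length window 135-152 bp, mean Phred >= 25, no run of more than 3
consecutive low-quality bases, per-base floor Q3, at least 75% of bases
high-quality, and zero ambiguous bases. Reads are single-end merged
contigs in Sanger FASTQ (Phred+33).

The threshold defining a "low-quality" base for the run rule and the
75% rule is Q < 25 by default (the same cutoff as the mean-quality rule)
and is exposed as ``lowq_run_threshold``. The 75% rule is interpreted as
a total fraction of high-quality bases rather than a single contiguous
block; see docs/methods.md for the alternative reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# rule evaluation order; a rejected read is attributed to the first rule it fails
RULES = ("length", "avg_quality", "lowq_run", "q_floor", "highq_frac", "ambiguous")

FWD_PRIMER_341F = "CCTACGGGRSGCAGCAG"
REV_PRIMER_787R = "CTACNRGGGTATCTAA"


@dataclass
class ReadRecord:
    """A sequencing read with per-base Sanger Phred scores."""

    id: str
    sequence: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quals)}"
            )
        if any(q < 0 or q > 93 for q in self.quals):
            raise ValueError(f"read {self.id!r}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class QcParams:
    """Thresholds for read filtering and primer trimming.

    Defaults reproduce the stated amplicon filter set; every knob is
    configurable. ``lowq_run_threshold`` defines "low quality" for both
    the consecutive-run rule and the high-quality-fraction rule.
    """

    min_len: int = 135
    max_len: int = 152
    min_avg_q: float = 25.0
    max_lowq_run: int = 3
    lowq_run_threshold: int = 25
    min_q_floor: int = 3
    min_highq_frac: float = 0.75
    max_ambiguous: int = 0
    fwd_primer: str = FWD_PRIMER_341F
    rev_primer: str = REV_PRIMER_787R
    max_primer_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        for name in ("min_len", "max_len", "min_avg_q", "max_lowq_run",
                     "lowq_run_threshold", "min_q_floor", "max_ambiguous",
                     "max_primer_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.min_highq_frac <= 1:
            raise ValueError("min_highq_frac must lie in [0, 1]")
        for primer in (self.fwd_primer, self.rev_primer):
            bad = set(primer.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"invalid IUPAC character(s) {sorted(bad)} in primer {primer!r}")


@dataclass
class QcReport:
    """Totals and per-rule first-cause rejection counts for one filter run."""

    total: int = 0
    kept: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"total": self.total, "kept": self.kept, "rejected": self.rejected},
            indent=2,
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC degeneracy codes preserved."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _mismatches(window: str, primer: str, limit: int) -> int:
    """Count non-matching positions, stopping early past `limit`."""
    n = 0
    for base, code in zip(window, primer):
        if base not in IUPAC_SETS[code]:
            n += 1
            if n > limit:
                break
    return n


def trim_primers(read: ReadRecord, params: QcParams) -> ReadRecord | None:
    """Strip the forward primer prefix and reverse-primer-complement suffix.

    Primers are given 5'->3'; the reverse primer is matched as its reverse
    complement at the 3' end of the read. IUPAC degeneracy codes in the
    primer match their base sets. Returns the trimmed read, or ``None``
    when either primer is not found within ``max_primer_mismatch``.
    """
    fwd = params.fwd_primer.upper()
    rev = reverse_complement(params.rev_primer)
    seq = read.sequence.upper()
    nf, nr = len(fwd), len(rev)
    if len(seq) < nf + nr:
        return None
    if _mismatches(seq[:nf], fwd, params.max_primer_mismatch) > params.max_primer_mismatch:
        return None
    if _mismatches(seq[-nr:], rev, params.max_primer_mismatch) > params.max_primer_mismatch:
        return None
    return ReadRecord(
        id=read.id,
        sequence=read.sequence[nf : len(seq) - nr],
        quals=read.quals[nf : len(seq) - nr],
    )


def first_failed_rule(read: ReadRecord, params: QcParams) -> str | None:
    """Name of the first filter rule the read fails, or ``None`` if it passes all."""
    n = len(read)
    if n < params.min_len or n > params.max_len:
        return "length"
    quals = read.quals
    if sum(quals) / n < params.min_avg_q:
        return "avg_quality"
    run = 0
    longest = 0
    for q in quals:
        if q < params.lowq_run_threshold:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    if longest > params.max_lowq_run:
        return "lowq_run"
    if min(quals) < params.min_q_floor:
        return "q_floor"
    n_high = sum(1 for q in quals if q >= params.lowq_run_threshold)
    if n_high / n < params.min_highq_frac:
        return "highq_frac"
    n_ambig = sum(1 for b in read.sequence.upper() if b not in "ACGT")
    if n_ambig > params.max_ambiguous:
        return "ambiguous"
    return None


def qc_filter(
    reads: Iterable[ReadRecord],
    params: QcParams | None = None,
    trim: bool = False,
) -> tuple[list[ReadRecord], QcReport]:
    """Apply the filter rules to a read stream.

    A read is kept iff it satisfies every rule; a rejected read is counted
    under the first rule it fails, in the fixed order ``RULES`` (with
    ``primer_not_found`` first when ``trim`` is enabled). The per-rule
    counts plus the kept count always sum to the total.
    """
    if params is None:
        params = QcParams()
    report = QcReport(rejected={})
    kept: list[ReadRecord] = []
    for read in reads:
        report.total += 1
        if trim:
            trimmed = trim_primers(read, params)
            if trimmed is None:
                report.rejected["primer_not_found"] = (
                    report.rejected.get("primer_not_found", 0) + 1
                )
                continue
            read = trimmed
        rule = first_failed_rule(read, params)
        if rule is None:
            report.kept += 1
            kept.append(read)
        else:
            report.rejected[rule] = report.rejected.get(rule, 0) + 1
    return kept, report


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Sanger (Phred+33) FASTQ records.

    Emits a warning-style error if scores suggest a Phred+64 file: Sanger
    instrument scores essentially never exceed Q60, so any higher score in
    the first records indicates the wrong encoding.
    """
    checked = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if checked < 100:
            checked += 1
            if any(q > 60 for q in quals):
                import warnings

                warnings.warn(
                    f"read {rec.id!r} has a Phred score > 60; the file may be "
                    "Phred+64 encoded, not Sanger Phred+33",
                    stacklevel=2,
                )
        yield ReadRecord(id=rec.id, sequence=str(rec.seq), quals=list(quals))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    with path.open("w") as fh:
        SeqIO.write(records, fh, "fastq")
    return path


def qc_fastq_file(
    in_path: str | Path,
    out_path: str | Path,
    report_path: str | Path | None = None,
    params: QcParams | None = None,
    trim: bool = False,
) -> QcReport:
    """Filter a FASTQ file to another FASTQ file, optionally writing a JSON report."""
    kept, report = qc_filter(read_fastq(in_path), params=params, trim=trim)
    write_fastq(kept, out_path)
    if report_path is not None:
        Path(report_path).write_text(report.to_json() + "\n", encoding="utf-8")
    return report
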