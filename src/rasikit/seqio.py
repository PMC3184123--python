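"""Sequence and tabular I/O plus the basic sequence utilities shared by every stage.

All coordinates are 0-based half-open internally; user-facing report writers
convert to 1-based inclusive positions.  Small-RNA tags are canonicalized to
the DNA alphabet (U -> T) before any matching; the original alphabet is kept
on the record for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

DNA_SYMBOLS = set("ACGTN")
RNA_SYMBOLS = set("ACGUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

STOP = "*"


def detect_alphabet(sequence: str) -> str:
    """Return ``"RNA"`` if the sequence contains U, else ``"DNA"``.

    A sequence containing both T and U is rejected.
    """
    s = set(sequence)
    has_t = "T" in s
    has_u = "U" in s
    if has_t and has_u:
        raise ValueError("sequence mixes T and U symbols")
    if not s <= (RNA_SYMBOLS | DNA_SYMBOLS):
        bad = sorted(s - (RNA_SYMBOLS | DNA_SYMBOLS))
        raise ValueError(f"invalid nucleotide symbol(s): {bad}")
    return "RNA" if has_u else "DNA"


def canonical_dna(sequence: str) -> str:
    """Uppercase and convert to the DNA alphabet (U -> T).

    This is the canonical form used for all exact matching; N is preserved
    (and never matches anything downstream).
    """
    seq = sequence.upper().replace("U", "T")
    if not set(seq) <= DNA_SYMBOLS:
        bad = sorted(set(seq) - DNA_SYMBOLS)
        raise ValueError(f"invalid nucleotide symbol(s): {bad}")
    return seq


def to_rna(sequence: str) -> str:
    """Convert a canonical DNA string to RNA for display (T -> U)."""
    return sequence.upper().replace("T", "U")


@dataclass
class SequenceRecord:
    """A single sequence with optional Phred qualities.

    Invariants: the sequence is uppercase, qualities (when present) have one
    score per base, and the alphabet is consistent with the symbols used.
    """

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    alphabet: str = field(default="")

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        detected = detect_alphabet(self.sequence) if self.sequence else "DNA"
        if not self.alphabet:
            self.alphabet = detected
        elif self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        elif self.sequence:
            symbols = RNA_SYMBOLS if self.alphabet == "RNA" else DNA_SYMBOLS
            if not set(self.sequence) <= symbols:
                raise ValueError(
                    f"record {self.id!r}: sequence symbols inconsistent with "
                    f"declared alphabet {self.alphabet}"
                )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality scores for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LibrarySummary:
    """Read accounting for one library (the flow-of-filtration table).

    The conservation identity ``raw_reads == low_quality + no_adapter +
    too_short + high_quality_reads`` is enforced; reads emptied by
    homopolymer trimming are counted under ``too_short``.
    """

    library_id: str
    raw_reads: int
    low_quality: int
    no_adapter: int
    too_short: int
    high_quality_reads: int
    unique_tags: int

    def __post_init__(self) -> None:
        counts = (
            self.raw_reads,
            self.low_quality,
            self.no_adapter,
            self.too_short,
            self.high_quality_reads,
            self.unique_tags,
        )
        if any(c < 0 for c in counts):
            raise ValueError("library summary counts must be non-negative")
        total = self.low_quality + self.no_adapter + self.too_short + self.high_quality_reads
        if total != self.raw_reads:
            raise ValueError(
                f"library {self.library_id!r}: read accounting identity violated "
                f"({self.raw_reads} raw != {total} categorized)"
            )


def read_sequences(path: str | Path, format: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA or FASTQ (Sanger Phred+33) file into SequenceRecords.

    ``format`` is inferred from the extension when omitted.  Records are
    returned in file order with per-record alphabet auto-detection.  An empty
    file yields an empty list with a warning; malformed records raise
    ``ValueError``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    records: list[SequenceRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            quals = rec.letter_annotations.get("phred_quality")
            records.append(
                SequenceRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(quals) if quals is not None else None,
                )
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    if not records:
        warnings.warn(f"{path}: no records parsed", stacklevel=2)
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path,
                    format: Optional[str] = None) -> int:
    """Write records as FASTA or FASTQ; returns the number written."""
    path = Path(path)
    fmt = format or _infer_format(path)
    n = 0
    with open(path, "w") as handle:
        for rec in records:
            if fmt == "fastq":
                quals = rec.qualities
                if quals is None:
                    raise ValueError(f"record {rec.id!r} has no qualities for FASTQ output")
                qstr = "".join(chr(q + 33) for q in quals)
                handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")
            else:
                handle.write(f">{rec.id}\n{rec.sequence}\n")
            n += 1
    return n


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from {path.name!r}")


def iter_fastq(path: str | Path):
    """Fast (id, sequence, quality-string) iterator over a FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def reverse_complement(sequence: str, alphabet: Optional[str] = None) -> str:
    """Reverse complement; U<->A pairing in RNA mode.  An involution."""
    seq = sequence.upper()
    alpha = alphabet or detect_alphabet(seq)
    table = _RNA_COMPLEMENT if alpha == "RNA" else _DNA_COMPLEMENT
    symbols = RNA_SYMBOLS if alpha == "RNA" else DNA_SYMBOLS
    if not set(seq) <= symbols:
        bad = sorted(set(seq) - symbols)
        raise ValueError(f"invalid symbol(s) for {alpha}: {bad}")
    return seq.translate(table)[::-1]


def six_frame_orfs(sequence: str) -> dict:
    """Translate all six frames and report the longest Met...Stop ORF peptide.

    Returns ``{"frames": {name: peptide}, "longest_orf": peptide}`` where the
    frame names are ``+1..+3`` and ``-1..-3``.  An ORF requires both the
    initiator Met and a terminating stop inside the frame; the reported
    peptide excludes the stop.  Used to check that a transcript is
    non-coding (no substantial ORF).
    """
    seq = canonical_dna(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(seq, "DNA")
    frames: dict[str, str] = {}
    for offset in range(3):
        frames[f"+{offset + 1}"] = _translate_frame(seq[offset:])
        frames[f"-{offset + 1}"] = _translate_frame(rc[offset:])
    longest = ""
    for name in ("+1", "+2", "+3", "-1", "-2", "-3"):
        for orf in _orfs_in_peptide(frames[name]):
            if len(orf) > len(longest):
                longest = orf
    return {"frames": frames, "longest_orf": longest}


def _translate_frame(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    if usable == 0:
        return ""
    return str(Seq(seq[:usable]).translate())


def _orfs_in_peptide(peptide: str) -> list[str]:
    """All Met..Stop spans in one translated frame (stop excluded)."""
    orfs = []
    i = 0
    while True:
        m = peptide.find("M", i)
        if m == -1:
            break
        stop = peptide.find(STOP, m)
        if stop == -1:
            break
        orfs.append(peptide[m:stop])
        i = m + 1
    return orfs


def write_library_summaries(summaries: Iterable[LibrarySummary], path: str | Path) -> None:
    """TSV writer mirroring the flow-of-filtration table columns."""
    with open(path, "w") as fh:
        fh.write(
            "library_id\traw_reads\tlow_quality\tno_adapter\ttoo_short\t"
            "high_quality_reads\tunique_tags\n"
        )
        for s in summaries:
            fh.write(
                f"{s.library_id}\t{s.raw_reads}\t{s.low_quality}\t{s.no_adapter}\t"
                f"{s.too_short}\t{s.high_quality_reads}\t{s.unique_tags}\n"
            )


def read_library_summaries(path: str | Path) -> list[LibrarySummary]:
    summaries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            summaries.append(
                LibrarySummary(
                    library_id=row["library_id"],
                    raw_reads=int(row["raw_reads"]),
                    low_quality=int(row["low_quality"]),
                    no_adapter=int(row["no_adapter"]),
                    too_short=int(row["too_short"]),
                    high_quality_reads=int(row["high_quality_reads"]),
                    unique_tags=int(row["unique_tags"]),
                )
            )
    return summaries
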