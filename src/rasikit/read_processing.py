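"""Raw-read filter cascade: quality filter -> adapter clipping -> homopolymer
trimming -> length filter -> redundancy collapse.

The 3' adapter is located by a semi-global dynamic-programming alignment of
the adapter against every read suffix (unit match +1, mismatch -1, gap -2).
The model of a read is ``insert + 3'-adapter`` with the adapter possibly
truncated by the end of the read, so an adapter occurrence starting at offset
``t`` must explain the whole suffix ``read[t:]``.  For each offset the best
alignment score, its edit count (substitutions + indels) and the number of
adapter bases consumed ("overlap") are defined; an offset is *feasible* when
``overlap >= min_overlap`` and ``edits <= floor(error_rate * overlap)``.  The
clipper picks the feasible offset with the maximal score, breaking ties
toward the longest insert (largest offset).  After 3' clipping, any
5'-adapter remnant at the start of the insert is removed under the same
criteria on the reversed sequences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import LibrarySummary, canonical_dna, iter_fastq

# Adapters from the library-construction protocol: the 3' adapter is ligated
# last and is read through by the sequencer; the 5' adapter is an RNA oligo
# (canonicalized to DNA here).
ADAPTER3 = "ATCTCGTATGCCGTCTTCTGCTTG"
ADAPTER5 = canonical_dna("GUUCAGAGUUCUACAGUCCGACGAUC")

GAP = -2
MATCH = 1
MISMATCH = -1


@dataclass
class ProcessingParams:
    """Tunable knobs of the filter cascade (defaults are the pipeline defaults)."""

    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    min_overlap: int = 6
    error_rate: float = 0.2
    max_homopolymer: int = 12
    min_length: int = 11      # "longer than 10 nt" read strictly
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.adapter3:
            raise ValueError("3' adapter must be non-empty")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        self.adapter3 = canonical_dna(self.adapter3)
        if self.adapter5:
            self.adapter5 = canonical_dna(self.adapter5)


@dataclass
class ClipResult:
    """Outcome of the full per-read cascade for a single read."""

    insert: str
    status: str  # kept | no_adapter | too_short | low_quality | homopolymer_empty
    adapter3_found: bool = False
    adapter3_start: int = -1
    adapter3_edits: int = 0
    adapter3_overlap: int = 0
    adapter5_clipped: bool = False
    internal_homopolymer: bool = False


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-library copy counts."""

    tag_id: str
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------

def filter_quality(sequence: str, qualities: Optional[Sequence[int]],
                   min_mean_q: float = 20.0, max_n_frac: float = 0.1) -> bool:
    """Pass/fail quality filter: mean Phred and N-fraction thresholds.

    Reads without qualities pass (the N-fraction rule still applies).
    """
    if sequence and sequence.count("N") / len(sequence) > max_n_frac:
        return False
    if qualities is None:
        return True
    if len(qualities) == 0:
        return True
    return float(np.mean(qualities)) >= min_mean_q


# ---------------------------------------------------------------------------
# adapter clipping
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _offset_scores(read: str, adapter: str) -> np.ndarray:
    """Best alignment score for every adapter-start offset in one DP pass.

    Works on the reversed strings: a free start over the reversed adapter
    encodes the truncation of the adapter by the read end, and the column at
    which the final row is read off encodes the offset.  Returns an array
    ``scores[t]`` for ``t = 0..len(read)-1``.  N never matches.
    """
    n, m = len(read), len(adapter)
    rread = _encode(read[::-1])
    radap = _encode(adapter[::-1])
    ncode = ord("N")
    idx2 = 2 * np.arange(n + 1, dtype=np.int64)
    # row[j] = F[i][j]; F[i][0] = 0 encodes the free start in the adapter
    row = -2 * np.arange(n + 1, dtype=np.int64)
    row[0] = 0
    for i in range(1, m + 1):
        a = radap[i - 1]
        sub = np.where((rread == a) & (a != ncode) & (rread != ncode), MATCH, MISMATCH)
        nxt = np.empty_like(row)
        nxt[0] = 0
        nxt[1:] = np.maximum(row[:-1] + sub, row[1:] + GAP)
        # chain horizontal gaps (read bases left unmatched) via running max
        np.maximum.accumulate(nxt + idx2, out=nxt)
        nxt -= idx2
        row = nxt
    # score(t) = F[m][n - t]
    return row[1:][::-1]


def _align_suffix(suffix: str, adapter: str) -> tuple[int, int, int]:
    """Best (score, edits, overlap) aligning the whole suffix to an adapter prefix.

    Maximizes score, then minimizes edits, then maximizes the number of
    adapter bases consumed.  Quadratic DP on tuple cells; the strings are
    tiny (reads are at most a few tens of nt).
    """
    ns, m = len(suffix), len(adapter)
    # cell = (score, -edits); propagate lexicographically
    prev = [(-2 * i, -i) for i in range(m + 1)]
    for j in range(1, ns + 1):
        cur = [(prev[0][0] + GAP, prev[0][1] - 1)]
        sj = suffix[j - 1]
        for i in range(1, m + 1):
            ai = adapter[i - 1]
            eq = sj == ai and sj != "N"
            diag = (prev[i - 1][0] + (MATCH if eq else MISMATCH),
                    prev[i - 1][1] - (0 if eq else 1))
            up = (prev[i][0] + GAP, prev[i][1] - 1)
            left = (cur[i - 1][0] + GAP, cur[i - 1][1] - 1)
            cur.append(max(diag, up, left))
        prev = cur
    best_i = max(range(m + 1), key=lambda i: (prev[i], i))
    score, negedits = prev[best_i]
    return score, -negedits, best_i


def find_adapter3(read: str, adapter: str, min_overlap: int = 6,
                  error_rate: float = 0.2) -> Optional[tuple[int, int, int]]:
    """Locate the 3' adapter; returns (offset, edits, overlap) or None.

    Fast path: the rightmost exact full occurrence of the adapter scores the
    global maximum and wins every tie, so no DP is needed.  Otherwise the
    per-offset DP scores rank the candidates and each is verified against
    the feasibility rule until one passes.
    """
    n, m = len(read), len(adapter)
    if n == 0:
        return None
    t = read.rfind(adapter)
    if t != -1:
        return t, 0, m
    scores = _offset_scores(read, adapter)
    max_edits = math.floor(error_rate * m)
    # a feasible best alignment satisfies score >= overlap - 3*edits, so
    # nothing below this can ever pass the feasibility rule
    hard_floor = min_overlap - 3 * max_edits
    order = sorted(range(n), key=lambda i: (scores[i], i), reverse=True)
    for t in order:
        s = int(scores[t])
        L = n - t
        if s < hard_floor:
            break
        if s == L:
            # a score equal to the suffix length is only achievable by a
            # perfect ungapped match of the whole suffix to the adapter prefix
            if L >= min_overlap:
                return t, 0, L
            continue
        # cheap necessary conditions before the exact verification:
        # each edit costs at least 1 and at most 3 score units, and the
        # overlap can exceed the suffix length only by the gap edits
        emin = -((s - L) // 3)          # ceil((L - s) / 3)
        if emin > math.floor(error_rate * min(m, L + emin)):
            continue
        score, edits, overlap = _align_suffix(read[t:], adapter)
        if overlap >= min_overlap and edits <= math.floor(error_rate * overlap):
            return t, edits, overlap
    return None


def clip_adapters(read: str, adapter3: str = ADAPTER3, adapter5: str = ADAPTER5,
                  min_overlap: int = 6, error_rate: float = 0.2) -> ClipResult:
    """Clip the 3' adapter (mandatory) and any 5'-adapter remnant from a read.

    Reads without a 3' adapter are flagged ``no_adapter`` (discarded
    downstream).  The 5'-adapter check aligns a suffix of the 5' adapter to
    the insert prefix under the same overlap/edit criteria.
    """
    seq = canonical_dna(read)
    a3 = canonical_dna(adapter3)
    hit = find_adapter3(seq, a3, min_overlap, error_rate)
    if hit is None:
        return ClipResult(insert="", status="no_adapter")
    t, edits, overlap = hit
    insert = seq[:t]
    result = ClipResult(
        insert=insert, status="kept", adapter3_found=True,
        adapter3_start=t, adapter3_edits=edits, adapter3_overlap=overlap,
    )
    if adapter5 and insert:
        a5 = canonical_dna(adapter5)
        # a 5'-adapter remnant is a *suffix* of the 5' adapter occupying the
        # insert prefix; reversing both maps this onto the 3' machinery
        hit5 = find_adapter3(insert[::-1], a5[::-1], min_overlap, error_rate)
        if hit5 is not None:
            t5, _, _ = hit5
            prefix_len = len(insert) - t5
            result.insert = insert[prefix_len:]
            result.adapter5_clipped = True
    return result


# ---------------------------------------------------------------------------
# homopolymer and length filters
# ---------------------------------------------------------------------------

def trim_homopolymers(sequence: str, max_run: int = 12) -> tuple[str, bool]:
    """Remove terminal single-base runs longer than ``max_run``, iteratively.

    Returns ``(trimmed, internal_flag)`` where the flag marks an internal run
    longer than ``max_run`` (the read is flagged, not split).  May return an
    empty string when the whole read is homopolymeric.
    """
    seq = sequence
    changed = True
    while changed and seq:
        changed = False
        run = _run_length(seq, 0, 1)
        if run > max_run:
            seq = seq[run:]
            changed = True
        if seq:
            run = _run_length(seq, len(seq) - 1, -1)
            if run > max_run:
                seq = seq[: len(seq) - run]
                changed = True
    internal = _has_internal_run(seq, max_run)
    return seq, internal


def _run_length(seq: str, start: int, step: int) -> int:
    base = seq[start]
    i = start
    n = 0
    while 0 <= i < len(seq) and seq[i] == base:
        n += 1
        i += step
    return n


def _has_internal_run(seq: str, max_run: int) -> bool:
    if not seq:
        return False
    run = 1
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            run += 1
            if run > max_run and i + 1 < len(seq) and seq[i + 1] != seq[i]:
                return True
        else:
            run = 1
    return False


def filter_length(sequence: str, min_length: int = 11) -> bool:
    """Pass iff the sequence is at least ``min_length`` nt."""
    return len(sequence) >= min_length


# ---------------------------------------------------------------------------
# per-read cascade and redundancy collapse
# ---------------------------------------------------------------------------

def process_read(sequence: str, qualities: Optional[Sequence[int]],
                 params: ProcessingParams) -> ClipResult:
    """Run one read through the full cascade in the fixed order:
    quality -> 3' clip -> 5' clip -> homopolymer trim -> length filter."""
    seq = canonical_dna(sequence)
    if not filter_quality(seq, qualities, params.min_mean_quality, params.max_n_fraction):
        return ClipResult(insert="", status="low_quality")
    result = clip_adapters(seq, params.adapter3, params.adapter5,
                           params.min_overlap, params.error_rate)
    if result.status != "kept":
        return result
    trimmed, internal = trim_homopolymers(result.insert, params.max_homopolymer)
    result.insert = trimmed
    result.internal_homopolymer = internal
    if not trimmed:
        result.status = "homopolymer_empty"
        return result
    if not filter_length(trimmed, params.min_length):
        result.status = "too_short"
        return result
    result.status = "kept"
    return result


def collapse_library(inserts: Iterable[str], library_id: str) -> list[UniqueTag]:
    """Collapse filtered inserts into unique tags counted for one library.

    Tag ids are assigned by descending count, then sequence, so the result
    is independent of input order.
    """
    counts = Counter(canonical_dna(s) for s in inserts)
    tags = []
    for i, (seq, c) in enumerate(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
    ):
        tags.append(UniqueTag(tag_id=f"tag_{i:06d}", sequence=seq,
                              counts={library_id: c}))
    return tags


def merge_tag_sets(tag_sets: Iterable[Sequence[UniqueTag]]) -> list[UniqueTag]:
    """Union per-library tag sets, keying count maps by sequence.

    Ids are reassigned by descending total count, then sequence.
    """
    merged: dict[str, dict[str, int]] = {}
    for tags in tag_sets:
        for tag in tags:
            bucket = merged.setdefault(tag.sequence, {})
            for lib, c in tag.counts.items():
                bucket[lib] = bucket.get(lib, 0) + c
    out = []
    ordered = sorted(merged.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    for i, (seq, counts) in enumerate(ordered, start=1):
        out.append(UniqueTag(tag_id=f"tag_{i:06d}", sequence=seq, counts=dict(counts)))
    return out


def process_records(records: Iterable[tuple[str, str, Optional[Sequence[int]]]],
                    library_id: str,
                    params: Optional[ProcessingParams] = None,
                    ) -> tuple[list[UniqueTag], LibrarySummary, Counter]:
    """Process (id, sequence, qualities) triples into unique tags + accounting.

    Returns ``(tags, summary, status_counter)``; ``homopolymer_empty`` reads
    are folded into ``too_short`` in the summary so the conservation identity
    holds.
    """
    params = params or ProcessingParams()
    statuses: Counter = Counter()
    inserts: list[str] = []
    for _rid, seq, quals in records:
        result = process_read(seq, quals, params)
        statuses[result.status] += 1
        if result.status == "kept":
            inserts.append(result.insert)
    tags = collapse_library(inserts, library_id)
    summary = LibrarySummary(
        library_id=library_id,
        raw_reads=sum(statuses.values()),
        low_quality=statuses["low_quality"],
        no_adapter=statuses["no_adapter"],
        too_short=statuses["too_short"] + statuses["homopolymer_empty"],
        high_quality_reads=statuses["kept"],
        unique_tags=len(tags),
    )
    return tags, summary, statuses


def process_fastq(path: str | Path, library_id: str,
                  params: Optional[ProcessingParams] = None,
                  ) -> tuple[list[UniqueTag], LibrarySummary, Counter]:
    """Process a FASTQ file (qualities decoded as Phred+33)."""

    def _records():
        for rid, seq, qual in iter_fastq(path):
            yield rid, seq, [ord(c) - 33 for c in qual]

    return process_records(_records(), library_id, params)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tag_fasta(tags: Sequence[UniqueTag], path: str | Path) -> None:
    """Collapsed-tag FASTA; the id carries the total copy count."""
    with open(path, "w") as fh:
        for tag in tags:
            fh.write(f">{tag.tag_id}|count={tag.total_count}\n{tag.sequence}\n")


def write_tag_counts(tags: Sequence[UniqueTag], libraries: Sequence[str],
                     path: str | Path) -> None:
    """Per-library count TSV: tag_id, sequence, one column per library."""
    with open(path, "w") as fh:
        fh.write("tag_id\tsequence\t" + "\t".join(libraries) + "\n")
        for tag in tags:
            row = "\t".join(str(tag.counts.get(lib, 0)) for lib in libraries)
            fh.write(f"{tag.tag_id}\t{tag.sequence}\t{row}\n")


def read_tag_counts(path: str | Path) -> tuple[list[UniqueTag], list[str]]:
    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libraries = header[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {lib: int(v) for lib, v in zip(libraries, parts[2:]) if int(v) > 0}
            tags.append(UniqueTag(tag_id=parts[0], sequence=parts[1], counts=counts))
    return tags, libraries
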