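"""Exact mapping of tags onto repeat consensi, rasiRNA classification,
contamination screening, tandem-repeat detection and copy density.

Mapping is an exact substring search on both strands: the annotation
criterion is 100% identity over the full tag length, so no alignment engine
is needed.  Only the ribosomal/tRNA degradation screen uses alignment: rDNA
by perfect match, tRNA by >= 95% full-length identity (edit-distance based,
via an infix alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib

from .read_processing import UniqueTag
from .seqio import canonical_dna, reverse_complement

CATEGORIES = ("TIR", "MITE", "LINE", "SSR", "Helitron", "NoCat")


@dataclass
class RepeatConsensus:
    """A repeat-family consensus sequence with its category label."""

    consensus_id: str
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown repeat category {self.category!r}; expected one of {CATEGORIES}"
            )
        self.sequence = canonical_dna(self.sequence)
        if not self.sequence:
            raise ValueError(f"consensus {self.consensus_id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MappingHit:
    """A perfect-match placement of a tag on a consensus (0-based half-open)."""

    tag_id: str
    consensus_id: str
    start: int
    end: int
    strand: str
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("hit interval must be non-empty")


@dataclass
class AnnotationRecord:
    """Per-tag annotation outcome."""

    tag_id: str
    is_rasirna: bool
    categories: set[str] = field(default_factory=set)
    contaminant: str = "none"  # rDNA | tRNA | none
    hits: list[MappingHit] = field(default_factory=list)


def map_exact(tag: UniqueTag | str, consensi: Iterable[RepeatConsensus],
              tag_id: Optional[str] = None) -> list[MappingHit]:
    """All perfect-match placements of a tag (both strands) on the consensi.

    Tags containing N are unmappable (N never matches).  Minus-strand hits
    report the interval occupied by the reverse complement of the tag.
    """
    if isinstance(tag, UniqueTag):
        seq, tid = tag.sequence, tag.tag_id
    else:
        seq, tid = canonical_dna(tag), tag_id or "tag"
    hits: list[MappingHit] = []
    if not seq or "N" in seq:
        return hits
    rc = reverse_complement(seq, "DNA")
    for cons in consensi:
        for strand, query in (("+", seq), ("-", rc)):
            start = cons.sequence.find(query)
            while start != -1:
                hits.append(MappingHit(tag_id=tid, consensus_id=cons.consensus_id,
                                       start=start, end=start + len(query),
                                       strand=strand))
                start = cons.sequence.find(query, start + 1)
    return hits


def screen_contaminants(tag: UniqueTag | str, rdna: Sequence[str],
                        trna: Sequence[str],
                        trna_min_identity: float = 0.95) -> str:
    """Label a tag as rDNA, tRNA or none.

    rDNA: exact substring of any ribosomal sequence on either strand
    (precedence over tRNA).  tRNA: full-length identity of at least
    ``trna_min_identity`` against a window of any tRNA, on either strand,
    where identity = 1 - edits/len(tag), rounded to 4 decimals.
    """
    seq = tag.sequence if isinstance(tag, UniqueTag) else canonical_dna(tag)
    if not seq or "N" in seq:
        return "none"
    rc = reverse_complement(seq, "DNA")
    for ref in rdna:
        ref = canonical_dna(ref)
        if seq in ref or rc in ref:
            return "rDNA"
    max_edits = len(seq)  # edlib prunes with k; identity bound gives a tighter k
    k = int(len(seq) * (1.0 - trna_min_identity)) + 1
    best = None
    for ref in trna:
        ref = canonical_dna(ref)
        for query in (seq, rc):
            res = edlib.align(query, ref, mode="HW", task="distance", k=min(k, max_edits))
            d = res["editDistance"]
            if d != -1 and (best is None or d < best):
                best = d
    if best is not None:
        identity = round(1.0 - best / len(seq), 4)
        if identity >= trna_min_identity:
            return "tRNA"
    return "none"


def classify_tag(tag: UniqueTag, hits: Sequence[MappingHit],
                 categories_by_consensus: dict[str, str],
                 contaminant: str = "none",
                 min_rasirna_len: int = 16) -> AnnotationRecord:
    """Build the per-tag annotation record.

    A tag is a rasiRNA iff it is non-contaminant, longer than 15 nt
    (``len >= min_rasirna_len``) and has at least one perfect hit.  The
    category set is the union over hit consensi, so one tag may count in
    several categories.
    """
    cats = {categories_by_consensus[h.consensus_id] for h in hits}
    is_rasi = (
        contaminant == "none"
        and len(tag.sequence) >= min_rasirna_len
        and len(hits) > 0
    )
    return AnnotationRecord(tag_id=tag.tag_id, is_rasirna=is_rasi,
                            categories=cats, contaminant=contaminant,
                            hits=list(hits))


def annotate_tags(tags: Sequence[UniqueTag], consensi: Sequence[RepeatConsensus],
                  rdna: Sequence[str] = (), trna: Sequence[str] = (),
                  min_rasirna_len: int = 16,
                  trna_min_identity: float = 0.95) -> list[AnnotationRecord]:
    """Convenience wrapper: screen, map and classify a whole tag collection."""
    cat_by_id = {c.consensus_id: c.category for c in consensi}
    records = []
    for tag in tags:
        label = screen_contaminants(tag, rdna, trna, trna_min_identity) \
            if (rdna or trna) else "none"
        hits = map_exact(tag, consensi)
        records.append(classify_tag(tag, hits, cat_by_id, label, min_rasirna_len))
    return records


# ---------------------------------------------------------------------------
# short tandem repeats
# ---------------------------------------------------------------------------

def find_tandem_repeats(sequence: str, min_unit: int = 2, max_unit: int = 8,
                        min_copies: int = 3) -> list[tuple[str, int, int]]:
    """Maximal perfect tandem arrays with unit length in [min_unit, max_unit].

    Returns ``(unit, start, copies)`` triples where ``unit`` is the
    lexicographically smallest rotation of the repeated word and ``start``
    is the 0-based array start.  Only primitive units are reported (an AC
    array is not re-reported as ACAC), and each array appears once.
    """
    seq = canonical_dna(sequence)
    n = len(seq)
    if not (1 <= min_unit <= max_unit <= n):
        raise ValueError("require 1 <= min_unit <= max_unit <= len(sequence)")
    results: list[tuple[str, int, int]] = []
    seen_spans: set[tuple[int, int]] = set()
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u < n:
            if seq[i] != seq[i + u]:
                i += 1
                continue
            # maximal stretch of period-u matches starting at i
            j = i
            while j + u < n and seq[j] == seq[j + u]:
                j += 1
            run = (j - i) + u      # total array length with period u
            copies = run // u
            if copies >= max(min_copies, 2):
                unit = seq[i:i + u]
                if _is_primitive(unit):
                    span = (i, i + copies * u)
                    if span not in seen_spans:
                        seen_spans.add(span)
                        results.append((_canonical_rotation(unit), i, copies))
            i = j + 1
    results.sort(key=lambda r: (r[1], len(r[0])))
    return results


def _is_primitive(unit: str) -> bool:
    """True when the unit is not a repetition of a shorter word."""
    u = len(unit)
    for d in range(1, u):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return False
    return True


def _canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def copy_density(hit_count: int, genomic_length: int) -> float:
    """Average genomic spacing of an element: nt of genome per copy."""
    if hit_count <= 0:
        raise ValueError("copy density undefined for zero copies")
    return genomic_length / hit_count


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_repeat_library(fasta_path: str | Path, category_path: str | Path
                        ) -> list[RepeatConsensus]:
    """Load consensus FASTA plus the two-column (consensus_id, category) TSV."""
    from .seqio import read_sequences

    categories: dict[str, str] = {}
    with open(category_path) as fh:
        header = fh.readline()
        if not header.startswith("consensus_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            cid, cat = line.rstrip("\n").split("\t")[:2]
            categories[cid] = cat
    consensi = []
    for rec in read_sequences(fasta_path, "fasta"):
        if rec.id not in categories:
            raise ValueError(f"consensus {rec.id!r} missing from category table")
        consensi.append(RepeatConsensus(rec.id, categories[rec.id], rec.sequence))
    return consensi


def write_repeat_library(consensi: Sequence[RepeatConsensus],
                         fasta_path: str | Path, category_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for c in consensi:
            fh.write(f">{c.consensus_id}\n{c.sequence}\n")
    with open(category_path, "w") as fh:
        fh.write("consensus_id\tcategory\n")
        for c in consensi:
            fh.write(f"{c.consensus_id}\t{c.category}\n")


def write_hits_bed(hits: Sequence[MappingHit], tags_by_id: dict[str, UniqueTag],
                   path: str | Path) -> None:
    """BED6-like hit table (0-based half-open), score = total tag count."""
    with open(path, "w") as fh:
        fh.write("consensus_id\tstart\tend\ttag_id\ttag_total_count\tstrand\n")
        for h in hits:
            total = tags_by_id[h.tag_id].total_count if h.tag_id in tags_by_id else 0
            fh.write(f"{h.consensus_id}\t{h.start}\t{h.end}\t{h.tag_id}\t{total}\t{h.strand}\n")


def write_annotation(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tis_rasiRNA\tcategories\tcontaminant\tn_hits\n")
        for r in records:
            cats = ",".join(sorted(r.categories)) or "-"
            fh.write(f"{r.tag_id}\t{int(r.is_rasirna)}\t{cats}\t{r.contaminant}\t{len(r.hits)}\n")
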