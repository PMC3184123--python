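"""Strand-specific cluster calling, count normalization, the cross-stage
expression matrix, differential count testing and positional nucleotide
composition.

Counts are normalized per library as a percentage of that library's
high-quality reads; no endogenous control is assumed.  Display rounding is
separate from computation: scientific per-tag values are printed as a
x10^-3 % mantissa truncated to 3 decimals, aggregates with 2 significant
figures capped at 3 decimal places (both reproduce the conventional
printed forms exactly); all arithmetic is full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .read_processing import UniqueTag
from .repeat_annotation import MappingHit
from .seqio import LibrarySummary, to_rna


@dataclass
class Cluster:
    """One uni-strand cluster: an overlap-connected component of hits."""

    cluster_id: str
    consensus_id: str
    strand: str
    span_start: int
    span_end: int
    members: list[str] = field(default_factory=list)
    per_library_counts: dict[str, int] = field(default_factory=dict)

    @property
    def member_count(self) -> int:
        return len(self.members)

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start


def call_clusters(hits: Sequence[MappingHit], min_members: int = 2,
                  min_overlap_nt: int = 1) -> tuple[list[Cluster], list[Cluster]]:
    """Single-linkage merge of hit intervals per (consensus, strand).

    Hits sharing at least ``min_overlap_nt`` nt on the same strand of the
    same consensus merge into one component; components with
    ``>= min_members`` distinct member tags become clusters (sorted by
    span start), smaller ones are returned as singletons.  Strands never
    merge, so the output clusters are uni-strand by construction.  The
    result is independent of input order.
    """
    groups: dict[tuple[str, str], list[MappingHit]] = {}
    for h in hits:
        groups.setdefault((h.consensus_id, h.strand), []).append(h)
    clusters: list[Cluster] = []
    singletons: list[Cluster] = []
    for (cons, strand) in sorted(groups):
        ordered = sorted(groups[(cons, strand)],
                         key=lambda h: (h.start, h.end, h.tag_id))
        component: list[MappingHit] = []
        comp_end = -1
        components: list[list[MappingHit]] = []
        for h in ordered:
            if component and h.start <= comp_end - min_overlap_nt:
                component.append(h)
                comp_end = max(comp_end, h.end)
            else:
                if component:
                    components.append(component)
                component = [h]
                comp_end = h.end
        if component:
            components.append(component)
        for comp in components:
            member_ids = sorted({h.tag_id for h in comp})
            cl = Cluster(
                cluster_id="",
                consensus_id=cons,
                strand=strand,
                span_start=min(h.start for h in comp),
                span_end=max(h.end for h in comp),
                members=member_ids,
            )
            (clusters if len(member_ids) >= min_members else singletons).append(cl)
    for seq_no, cl in enumerate(sorted(clusters, key=_cluster_key), start=1):
        cl.cluster_id = f"cluster_{seq_no}"
    clusters.sort(key=_cluster_key)
    for seq_no, cl in enumerate(sorted(singletons, key=_cluster_key), start=1):
        cl.cluster_id = f"singleton_{seq_no}"
    singletons.sort(key=_cluster_key)
    return clusters, singletons


def _cluster_key(cl: Cluster):
    return (cl.consensus_id, cl.strand, cl.span_start, cl.span_end)


def attach_counts(clusters: Iterable[Cluster], tags_by_id: dict[str, UniqueTag]) -> None:
    """Fill per-library member count totals on each cluster in place."""
    for cl in clusters:
        totals: dict[str, int] = {}
        for tid in cl.members:
            for lib, c in tags_by_id[tid].counts.items():
                totals[lib] = totals.get(lib, 0) + c
        cl.per_library_counts = dict(sorted(totals.items()))


# ---------------------------------------------------------------------------
# normalization and display rounding
# ---------------------------------------------------------------------------

def normalize_percent(count: int, library_total: int) -> float:
    """Copy count as a percent of the library's high-quality reads."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if not 0 <= count <= library_total:
        raise ValueError("count must lie in [0, library_total]")
    return 100.0 * count / library_total


def format_milli_percent(percent: float, decimals: int = 3) -> str:
    """Display form 'x.xxx' of a percentage expressed in units of 10^-3 %.

    The mantissa is truncated (not rounded) to ``decimals`` places, which is
    the convention that reproduces printed per-tag values exactly.
    """
    mantissa = percent * 1000.0
    scale = 10 ** decimals
    truncated = math.floor(round(mantissa * scale, 6)) / scale
    return f"{truncated:.{decimals}f}"


def format_aggregate_percent(percent: float) -> float:
    """Aggregate display rounding: 2 significant figures, at most 3 decimals."""
    if percent == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(percent)))
    ndigits = min(1 - exponent, 3)
    return round(percent, ndigits)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Tags x libraries percentages plus the per-library aggregate percent."""

    values: pd.DataFrame            # index tag_id, columns library ids, percent units
    sequences: pd.Series            # tag_id -> sequence
    library_totals: dict[str, int]
    aggregate_percent: pd.Series    # per-library percent of the tag subset

    def rank_normalized(self) -> pd.DataFrame:
        """Rank-normalized copy of the matrix (for heat-map display)."""
        n = len(self.values)
        if n == 0:
            return self.values.copy()
        return self.values.rank(axis=0, method="average") / n

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.copy()
        df.insert(0, "sequence", self.sequences)
        df.to_csv(path, sep="\t", index_label="tag_id")


def build_expression_matrix(tags: Sequence[UniqueTag],
                            summaries: Sequence[LibrarySummary],
                            subset: Optional[Iterable[str]] = None
                            ) -> ExpressionMatrix:
    """Build the tags x libraries percent matrix and per-library aggregates.

    ``subset`` optionally restricts to a set of tag ids (e.g. the rasiRNAs of
    one cluster pair); the aggregate is then the summed subset percent per
    library.
    """
    totals = {s.library_id: s.high_quality_reads for s in summaries}
    libraries = [s.library_id for s in summaries]
    chosen = list(tags)
    if subset is not None:
        wanted = set(subset)
        chosen = [t for t in tags if t.tag_id in wanted]
    for tag in chosen:
        for lib in tag.counts:
            if lib not in totals:
                raise ValueError(f"tag {tag.tag_id!r} counted in unknown library {lib!r}")
    data = {
        lib: [normalize_percent(t.counts.get(lib, 0), totals[lib]) for t in chosen]
        for lib in libraries
    }
    values = pd.DataFrame(data, index=[t.tag_id for t in chosen])
    seqs = pd.Series({t.tag_id: t.sequence for t in chosen}, dtype="object")
    agg = pd.Series(
        {
            lib: normalize_percent(sum(t.counts.get(lib, 0) for t in chosen), totals[lib])
            for lib in libraries
        }
    )
    return ExpressionMatrix(values=values, sequences=seqs,
                            library_totals=totals, aggregate_percent=agg)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_count_test(count1: int, total1: int, count2: int, total2: int) -> float:
    """Two-sided Fisher's exact test for one tag between two libraries.

    The 2x2 table is [[count1, total1-count1], [count2, total2-count2]].
    Exact at the extreme imbalances typical of small-RNA counts.
    """
    if not (0 <= count1 <= total1 and 0 <= count2 <= total2):
        raise ValueError("counts must not exceed library totals")
    if total1 <= 0 or total2 <= 0:
        raise ValueError("library totals must be positive")
    table = [[count1, total1 - count1], [count2, total2 - count2]]
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(min(p, 1.0))


def differential_table(tags: Sequence[UniqueTag], summaries: Sequence[LibrarySummary],
                       adjust: bool = False) -> pd.DataFrame:
    """Pairwise Fisher p-values for every tag across all library pairs.

    Raw p-values by default; ``adjust=True`` appends Benjamini-Hochberg
    adjusted columns.
    """
    totals = {s.library_id: s.high_quality_reads for s in summaries}
    libs = [s.library_id for s in summaries]
    rows = []
    for tag in tags:
        row: dict[str, object] = {"tag_id": tag.tag_id}
        for i in range(len(libs)):
            for j in range(i + 1, len(libs)):
                a, b = libs[i], libs[j]
                row[f"p_{a}_vs_{b}"] = differential_count_test(
                    tag.counts.get(a, 0), totals[a], tag.counts.get(b, 0), totals[b]
                )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("tag_id")
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests

        for col in list(df.columns):
            df[col + "_bh"] = multipletests(df[col].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# nucleotide composition
# ---------------------------------------------------------------------------

RNA_BASES = ("A", "C", "G", "U")


@dataclass
class CompositionMatrix:
    """Left-aligned positional base fractions with per-position depth."""

    fractions: pd.DataFrame   # index 1-based position, columns A/C/G/U
    depth: pd.Series
    overall: dict[str, float]
    max_bias: tuple[int, str, float]   # (1-based position, base, fraction)

    def to_tsv(self, path: str | Path) -> None:
        df = self.fractions.copy()
        df["depth"] = self.depth
        df.to_csv(path, sep="\t", index_label="position")


def composition_matrix(sequences: Sequence[str], align: str = "left") -> CompositionMatrix:
    """Positional nucleotide composition of a set of (ragged) sequences.

    Sequences are displayed in the RNA alphabet.  ``align='left'`` stacks
    them at their 5' ends; per-position fractions are over the sequences
    that reach that position (depth tracked).  The summary reports overall
    base fractions and the single strongest positional bias.
    """
    if align not in ("left", "none"):
        raise ValueError("align must be 'left' or 'none'")
    seqs = [to_rna(s.upper().replace("T", "U")) for s in sequences]
    if not seqs:
        raise ValueError("composition of an empty sequence set is undefined")
    length = max(len(s) for s in seqs)
    counts = np.zeros((length, len(RNA_BASES)), dtype=float)
    depth = np.zeros(length, dtype=int)
    index = {b: i for i, b in enumerate(RNA_BASES)}
    for s in seqs:
        for pos, base in enumerate(s):
            depth[pos] += 1
            if base in index:
                counts[pos, index[base]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = counts / depth[:, None]
    fracs = np.nan_to_num(fracs)
    df = pd.DataFrame(fracs, columns=list(RNA_BASES),
                      index=pd.RangeIndex(1, length + 1, name="position"))
    total = counts.sum(axis=0)
    overall = {b: float(v) for b, v in zip(RNA_BASES, total / total.sum())}
    best = (1, "A", 0.0)
    for pos in range(length):
        if depth[pos] == 0:
            continue
        for b in RNA_BASES:
            f = float(df.at[pos + 1, b])
            if f > best[2]:
                best = (pos + 1, b, f)
    return CompositionMatrix(fractions=df, depth=pd.Series(depth, index=df.index),
                             overall=overall, max_bias=best)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    """BED-like cluster table (0-based half-open spans)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tconsensus_id\tstrand\tspan_start\tspan_end\t"
                 "span_length\tmember_count\tmembers\tper_library_counts\n")
        for cl in clusters:
            counts = ",".join(f"{k}:{v}" for k, v in sorted(cl.per_library_counts.items()))
            fh.write(
                f"{cl.cluster_id}\t{cl.consensus_id}\t{cl.strand}\t{cl.span_start}\t"
                f"{cl.span_end}\t{cl.span_length}\t{cl.member_count}\t"
                f"{','.join(cl.members)}\t{counts or '-'}\n"
            )


def plot_expression_heatmap(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Optional heat-map rendering of the rank-normalized matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = matrix.rank_normalized()
    fig, ax = plt.subplots(figsize=(4, max(2, 0.12 * len(ranked))))
    im = ax.imshow(ranked.to_numpy(), aspect="auto", cmap="Reds")
    ax.set_xticks(range(len(ranked.columns)), ranked.columns)
    ax.set_ylabel("tags")
    fig.colorbar(im, ax=ax, label="rank-normalized expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
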