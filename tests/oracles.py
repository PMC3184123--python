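"""Independent brute-force oracles used by the property tests.

These deliberately re-derive each quantity by direct enumeration, staying
independent of the implementation paths they check.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# adapter clipping: per-offset enumeration
# ---------------------------------------------------------------------------

def _suffix_alignment(suffix: str, adapter: str) -> tuple[int, int, int]:
    """Best (score, edits, overlap) aligning the whole suffix against an
    adapter prefix: forward DP over (suffix position, adapter position),
    free end over the adapter.  Match +1, mismatch -1, gap -2; maximizes
    score, then minimal edits, then maximal adapter overlap."""
    ns, m = len(suffix), len(adapter)
    NEG = (-(10 ** 9), 0)
    table = [[NEG] * (m + 1) for _ in range(ns + 1)]
    table[0][0] = (0, 0)
    for i in range(1, m + 1):
        table[0][i] = (-2 * i, -i)
    for j in range(1, ns + 1):
        table[j][0] = (-2 * j, -j)
        for i in range(1, m + 1):
            eq = suffix[j - 1] == adapter[i - 1] and suffix[j - 1] != "N"
            cands = [
                (table[j - 1][i - 1][0] + (1 if eq else -1),
                 table[j - 1][i - 1][1] - (0 if eq else 1)),
                (table[j - 1][i][0] - 2, table[j - 1][i][1] - 1),
                (table[j][i - 1][0] - 2, table[j][i - 1][1] - 1),
            ]
            table[j][i] = max(cands)
    best = max(range(m + 1), key=lambda i: (table[ns][i], i))
    score, neg_edits = table[ns][best]
    return score, -neg_edits, best


def clip_oracle(read: str, adapter: str, min_overlap: int, error_rate: float):
    """Enumerate every adapter-start offset; return (offset, edits, overlap)
    of the winning feasible offset or None.  Max score wins; ties break
    toward the largest offset (longest insert)."""
    n = len(read)
    best = None
    for t in range(n):
        score, edits, overlap = _suffix_alignment(read[t:], adapter)
        if overlap < min_overlap or edits > math.floor(error_rate * overlap):
            continue
        key = (score, t)
        if best is None or key > best[0]:
            best = (key, (t, edits, overlap))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Fisher's exact test: hypergeometric tail enumeration
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]]: sum of the probabilities of
    all tables with the same margins whose probability does not exceed the
    observed one (with the customary 1+1e-7 tolerance for float ties)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# exact mapping: naive window scan
# ---------------------------------------------------------------------------

def map_oracle(tag: str, consensus: str, revcomp) -> list[tuple[int, int, str]]:
    """All perfect placements of tag / its reverse complement by comparing
    every window of the consensus."""
    hits = []
    if not tag or "N" in tag:
        return hits
    rc = revcomp(tag)
    L = len(tag)
    for start in range(len(consensus) - L + 1):
        window = consensus[start:start + L]
        if window == tag:
            hits.append((start, start + L, "+"))
        if window == rc:
            hits.append((start, start + L, "-"))
    return hits


# ---------------------------------------------------------------------------
# cluster calling: pairwise-overlap connected components
# ---------------------------------------------------------------------------

def cluster_oracle(intervals: list[tuple[int, int]], min_overlap: int = 1
                   ) -> list[list[int]]:
    """Connected components of the pairwise >= min_overlap-nt overlap graph,
    by depth-first search; returns sorted member-index lists."""
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            s1, e1 = intervals[i]
            s2, e2 = intervals[j]
            if min(e1, e2) - max(s1, s2) >= min_overlap:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return sorted(comps)


# ---------------------------------------------------------------------------
# tandem repeats: exhaustive unit/offset scan
# ---------------------------------------------------------------------------

def tandem_oracle(seq: str, min_unit: int, max_unit: int, min_copies: int
                  ) -> set[tuple[int, int, int]]:
    """All (start, unit_length, copies) maximal perfect arrays found by
    trying every start and unit length directly."""
    found = set()
    n = len(seq)
    for u in range(min_unit, max_unit + 1):
        for start in range(n - 2 * u + 1):
            unit = seq[start:start + u]
            # primitive units only
            if any(u % d == 0 and unit == unit[:d] * (u // d)
                   for d in range(1, u)):
                continue
            copies = 1
            while seq[start + copies * u: start + (copies + 1) * u] == unit:
                copies += 1
            if copies < min_copies or copies < 2:
                continue
            # left-maximality: the period-u relation must not extend left
            if start > 0 and seq[start - 1] == seq[start - 1 + u]:
                continue
            found.add((start, u, copies))
    return found


# ---------------------------------------------------------------------------
# local alignment identity (for the tRNA screen)
# ---------------------------------------------------------------------------

def edit_distance_infix(query: str, reference: str) -> int:
    """Minimum edit distance of query against any substring of reference
    (full dynamic-programming table, free start/end in the reference)."""
    nq, nr = len(query), len(reference)
    prev = [0] * (nr + 1)          # free start in reference
    for i in range(1, nq + 1):
        cur = [i] + [0] * nr
        qi = query[i - 1]
        for j in range(1, nr + 1):
            cost = 0 if qi == reference[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)               # free end in reference


# ---------------------------------------------------------------------------
# ORF scan
# ---------------------------------------------------------------------------

def longest_orf_oracle(seq: str, revcomp) -> str:
    """Longest Met..Stop peptide over all six frames by scanning every ATG."""
    from Bio.Data.CodonTable import standard_dna_table

    fwd = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    best = ""
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - 2):
            if strand_seq[i:i + 3] != "ATG":
                continue
            peptide = []
            j = i
            terminated = False
            while j + 3 <= len(strand_seq):
                codon = strand_seq[j:j + 3]
                if codon in stops:
                    terminated = True
                    break
                peptide.append(fwd.get(codon, "X"))
                j += 3
            if terminated and len(peptide) > len(best):
                best = "".join(peptide)
    return best
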