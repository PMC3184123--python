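"""Ground-truth simulator for every input the pipeline consumes.

The default scenario emulates the study conditions end to end: three
developmental small-RNA libraries (eggs, L2 larvae, pupae) with
stage-structured abundances of 46 planted rasiRNAs organized in two
uni-strand clusters (37 and 9 members) on a 2007-nt unclassified
transposable-element consensus carrying a 7x TGTCTGTT short tandem repeat
at one end; ribosomal and tRNA degradation products; homopolymer
artifacts; quality casualties; and a large background of unannotatable
reads.  Reads are laid out as ``insert + 3' adapter`` truncated to the
44-nt read length of the sequencer, with the 5' adapter consumed by the
sequencing primer.  A companion qPCR design simulates dilution series,
ChIP samples and genomic copy-number measurements from known truth.

All sampling goes through one explicitly seeded generator, so a scenario
is byte-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .read_processing import ADAPTER3, ADAPTER5
from .repeat_annotation import RepeatConsensus
from .seqio import canonical_dna

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

STR_UNIT = "TGTCTGTT"          # DNA form of the UGUCUGUU motif
STR_COPIES = 7
TE_CONSENSUS_LENGTH = 2007
TE_CONSENSUS_ID = "TE_LNCR_like_NoCat"

STAGES = ("eggs", "L2", "pupae")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

@dataclass
class MemberTruth:
    """One planted rasiRNA: its sequence, placement and per-stage abundance."""

    member_id: str
    cluster: int
    sequence: str
    offset: int
    length: int
    counts: dict[str, int]


@dataclass
class Scenario:
    """Every knob of the simulator; the defaults are the study conditions."""

    stage_totals: dict[str, int] = field(
        default_factory=lambda: {"eggs": 20_000, "L2": 25_000, "pupae": 15_000})
    rdna_fraction: float = 0.123
    trna_fraction: float = 0.023
    homopolymer_fraction: float = 0.01
    low_quality_fraction: float = 0.02
    no_adapter_fraction: float = 0.01
    too_short_fraction: float = 0.01
    sequencing_error_rate: float = 0.0
    background_length: list[int] = field(default_factory=lambda: [18, 40])
    read_length_cap: int = 44
    base_quality: int = 37
    degraded_quality: int = 8
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    n_per_category: dict[str, int] = field(
        default_factory=lambda: {"TIR": 3, "MITE": 2, "LINE": 2, "SSR": 1,
                                 "Helitron": 1, "NoCat": 3})
    member_profile: Optional[list[dict]] = None   # override of the default truth table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_member_profile() -> list[dict]:
    """The default per-member abundance truth table across the three stages.

    Mirrors the observed developmental pattern: an eggs-predominant block, an
    eggs+L2 block, a large L2-exclusive block, a small pupae-exclusive block
    of shorter (33-nt) members in cluster 1, and the same structure in the
    9-member cluster 2.
    """
    profile = []
    for i in range(1, 6):
        profile.append({"member": i, "cluster": 1, "length": 36,
                        "counts": {"eggs": 60, "L2": 6, "pupae": 0}})
    for i in range(6, 11):
        profile.append({"member": i, "cluster": 1, "length": 36,
                        "counts": {"eggs": 30, "L2": 30, "pupae": 0}})
    for i in range(11, 34):
        profile.append({"member": i, "cluster": 1, "length": 36,
                        "counts": {"eggs": 0, "L2": 40, "pupae": 0}})
    for i in range(34, 38):
        profile.append({"member": i, "cluster": 1, "length": 33,
                        "counts": {"eggs": 0, "L2": 0, "pupae": 8}})
    for i in range(38, 41):
        profile.append({"member": i, "cluster": 2, "length": 36,
                        "counts": {"eggs": 50, "L2": 5, "pupae": 0}})
    for i in range(41, 47):
        profile.append({"member": i, "cluster": 2, "length": 36,
                        "counts": {"eggs": 0, "L2": 35, "pupae": 0}})
    return profile


# member placement on the TE consensus: cluster 1 spans an 87-nt window,
# cluster 2 a 66-nt window straddling the STR block.
_C1_WINDOW_START = 800
_STR_START = 1941
_STR_END = _STR_START + len(STR_UNIT) * STR_COPIES        # 1997


def _cluster1_offsets() -> list[int]:
    offsets36 = [_C1_WINDOW_START + (k * 51) // 32 for k in range(33)]
    offsets33 = [_C1_WINDOW_START + d for d in (10, 22, 38, 54)]
    return offsets36 + offsets33


def _cluster2_offsets() -> list[int]:
    left = [_STR_START - 5 + k for k in range(5)]          # 1936..1940
    right = [1962, 1963, 1964, 1966]
    return left + right


@dataclass
class SimulationTruth:
    """Everything the generator planted, for truth-aware tests."""

    seed: int
    scenario: Scenario
    consensi: list[RepeatConsensus]
    te_consensus_id: str
    members: list[MemberTruth]
    rdna: str
    trna: list[str]
    cluster_spans: dict[int, tuple[int, int]]

    def members_of(self, cluster: int) -> list[MemberTruth]:
        return [m for m in self.members if m.cluster == cluster]

    def stage_member_counts(self, stage: str) -> dict[str, int]:
        return {m.member_id: m.counts.get(stage, 0) for m in self.members
                if m.counts.get(stage, 0) > 0}


# ---------------------------------------------------------------------------
# repeat library and genome
# ---------------------------------------------------------------------------

def make_te_consensus(rng: np.random.Generator, adapter3: str = ADAPTER3,
                      profile: Optional[list[dict]] = None
                      ) -> tuple[str, list[MemberTruth]]:
    """The TE-LNCR-like consensus (2007 nt, STR block at one end) plus members.

    The random portion is redrawn until every planted member window is free
    of the 3'-adapter 6-mer prefix (so a member read can never be
    mis-clipped), all member sequences are distinct and each occurs exactly
    once in the consensus.
    """
    profile = profile or default_member_profile()
    c1 = _cluster1_offsets()
    c2 = _cluster2_offsets()
    adapter_seed = canonical_dna(adapter3)[:6]
    str_block = STR_UNIT * STR_COPIES
    for _attempt in range(200):
        seq = list(random_dna(rng, TE_CONSENSUS_LENGTH))
        seq[_STR_START:_STR_END] = str_block
        # flanks must break the STR periodicity so the array is exactly 7 copies
        if seq[_STR_START - 1] == STR_UNIT[-1]:
            seq[_STR_START - 1] = "A" if STR_UNIT[-1] != "A" else "C"
        if seq[_STR_END] == STR_UNIT[0]:
            seq[_STR_END] = "A" if STR_UNIT[0] != "A" else "C"
        consensus = "".join(seq)
        members = []
        ok = True
        c1_iter = iter(c1)
        c2_iter = iter(c2)
        for spec_row in profile:
            offset = next(c1_iter) if spec_row["cluster"] == 1 else next(c2_iter)
            m_seq = consensus[offset: offset + spec_row["length"]]
            members.append(MemberTruth(
                member_id=f"rasiRNA_{spec_row['member']:02d}",
                cluster=spec_row["cluster"], sequence=m_seq, offset=offset,
                length=spec_row["length"], counts=dict(spec_row["counts"]),
            ))
        seqs = [m.sequence for m in members]
        if len(set(seqs)) != len(seqs):
            ok = False
        if ok and any(adapter_seed in s for s in seqs):
            ok = False
        if ok and any(_count_occurrences(consensus, s) != 1 for s in seqs):
            ok = False
        if ok:
            return consensus, members
    raise RuntimeError("could not draw a consensus satisfying the member constraints")


def _count_occurrences(haystack: str, needle: str) -> int:
    """Occurrence count allowing overlaps (str.count does not)."""
    n = 0
    start = haystack.find(needle)
    while start != -1:
        n += 1
        start = haystack.find(needle, start + 1)
    return n


def make_repeat_library(seed: int | np.random.Generator,
                        n_per_category: Optional[dict[str, int]] = None,
                        adapter3: str = ADAPTER3,
                        profile: Optional[list[dict]] = None
                        ) -> tuple[list[RepeatConsensus], list[MemberTruth]]:
    """Random consensi per category plus the designated TE-LNCR-like element."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per_category = dict(n_per_category
                          if n_per_category is not None
                          else Scenario().n_per_category)
    consensi: list[RepeatConsensus] = []
    te_seq, members = make_te_consensus(rng, adapter3, profile)
    consensi.append(RepeatConsensus(TE_CONSENSUS_ID, "NoCat", te_seq))
    for category in sorted(n_per_category):
        for i in range(n_per_category[category]):
            length = int(rng.integers(500, 3001))
            if category == "SSR":
                unit = random_dna(rng, int(rng.integers(2, 5)))
                reps = max(2, length // len(unit))
                seq = (unit * reps)[:length]
            else:
                seq = random_dna(rng, length)
            consensi.append(RepeatConsensus(f"{category}_{i + 1:02d}", category, seq))
    return consensi, members


def make_genome(seed: int | np.random.Generator, te_sequence: str,
                n_insertions: int = 18, total_length: int = 4_626_000,
                degeneration_rate: float = 0.0, n_truncated: int = 0
                ) -> tuple[str, pd.DataFrame]:
    """Background genome with TE copies inserted at recorded positions.

    Degeneration applies point substitutions at the given per-base rate;
    ``n_truncated`` copies are shortened (emulating rearranged insertions).
    Returns the genome string and a truth feature table with 0-based
    half-open insertion coordinates on the final genome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    te = canonical_dna(te_sequence)
    copies = []
    for i in range(n_insertions):
        seq = te
        truncated = i < n_truncated
        if truncated:
            keep = int(rng.integers(len(te) // 4, len(te) // 2))
            seq = seq[:keep]
        if degeneration_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(len(arr)) < degeneration_rate
            shift = rng.integers(1, 4, size=mask.sum())
            lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
            idx = np.flatnonzero(mask)
            chars = list(seq)
            for pos, s in zip(idx, shift):
                chars[pos] = lut[arr[pos]][s - 1]
            seq = "".join(chars)
        copies.append((seq, truncated))
    insert_total = sum(len(s) for s, _ in copies)
    background_length = total_length - insert_total
    if background_length < n_insertions:
        raise ValueError("genome too short for the requested insertions")
    cut_points = np.sort(rng.choice(background_length, size=n_insertions, replace=False))
    background = random_dna(rng, background_length)
    parts = []
    rows = []
    prev = 0
    genome_pos = 0
    for (seq, truncated), cut in zip(copies, cut_points):
        parts.append(background[prev:cut])
        genome_pos += cut - prev
        rows.append({"start": genome_pos, "end": genome_pos + len(seq),
                     "strand": "+", "truncated": truncated, "length": len(seq)})
        parts.append(seq)
        genome_pos += len(seq)
        prev = cut
    parts.append(background[prev:])
    genome = "".join(parts)
    assert len(genome) == total_length
    return genome, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            options = [b for b in "ACGT" if b != chars[i]]
            chars[i] = options[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_small_rna_library(rng: np.random.Generator, truth: SimulationTruth,
                               stage: str
                               ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """One stage library: (read_id, sequence, quality-string) triples + truth.

    Member reads are emitted at exactly the planted per-stage counts; the
    remaining budget is split into rDNA / tRNA degradation products,
    homopolymer artifacts, quality casualties, adapter-less reads,
    sub-length inserts and random background, at the scenario fractions.
    """
    sc = truth.scenario
    if stage not in sc.stage_totals:
        raise ValueError(f"stage {stage!r} not in scenario totals")
    total = sc.stage_totals[stage]
    adapter = canonical_dna(sc.adapter3)
    cap = sc.read_length_cap
    q_good = chr(sc.base_quality + 33)
    q_bad = chr(sc.degraded_quality + 33)

    entries: list[tuple[str, str, str, str]] = []   # (source, member, insert, quality_char)
    for m in truth.members:
        for _ in range(m.counts.get(stage, 0)):
            entries.append(("member", m.member_id, m.sequence, q_good))
    n_member = len(entries)
    if n_member > total:
        raise ValueError(f"stage {stage!r}: planted member copies exceed the library total")
    rest = total - n_member
    n_rdna = int(round(sc.rdna_fraction * rest))
    n_trna = int(round(sc.trna_fraction * rest))
    n_homo = int(round(sc.homopolymer_fraction * rest))
    n_lowq = int(round(sc.low_quality_fraction * rest))
    n_noad = int(round(sc.no_adapter_fraction * rest))
    n_short = int(round(sc.too_short_fraction * rest))
    n_background = rest - (n_rdna + n_trna + n_homo + n_lowq + n_noad + n_short)
    if n_background < 0:
        raise ValueError("scenario fractions exceed the library budget")

    for _ in range(n_rdna):
        length = int(rng.integers(15, 23))
        start = int(rng.integers(0, len(truth.rdna) - length + 1))
        entries.append(("rDNA", "", truth.rdna[start:start + length], q_good))
    for _ in range(n_trna):
        ref = truth.trna[int(rng.integers(0, len(truth.trna)))]
        length = 20
        start = int(rng.integers(0, len(ref) - length + 1))
        frag = ref[start:start + length]
        if rng.random() < 0.5:
            pos = int(rng.integers(0, length))
            repl = [b for b in "ACGT" if b != frag[pos]][int(rng.integers(0, 3))]
            frag = frag[:pos] + repl + frag[pos + 1:]
        entries.append(("tRNA", "", frag, q_good))
    for _ in range(n_homo):
        base = "ACGT"[int(rng.integers(0, 4))]
        entries.append(("homopolymer", "", base * int(rng.integers(15, 31)), q_good))
    bg_lo, bg_hi = sc.background_length
    for _ in range(n_lowq):
        entries.append(("low_quality", "",
                        random_dna(rng, int(rng.integers(bg_lo, bg_hi + 1))), q_bad))
    for _ in range(n_noad):
        entries.append(("no_adapter", "", random_dna(rng, int(rng.integers(25, 45))), q_good))
    for _ in range(n_short):
        entries.append(("too_short", "", random_dna(rng, int(rng.integers(5, 11))), q_good))
    for _ in range(n_background):
        entries.append(("background", "",
                        random_dna(rng, int(rng.integers(bg_lo, bg_hi + 1))), q_good))

    order = rng.permutation(len(entries))
    reads = []
    truth_rows = []
    for out_idx, entry_idx in enumerate(order, start=1):
        source, member, insert, qchar = entries[entry_idx]
        if source == "no_adapter":
            read = insert[:cap]
        else:
            read = (insert + adapter)[:cap]
        read = _mutate(rng, read, sc.sequencing_error_rate)
        read_id = f"{stage}_{out_idx:07d}"
        reads.append((read_id, read, qchar * len(read)))
        truth_rows.append({"read_id": read_id, "stage": stage, "source": source,
                           "member_id": member, "insert": insert})
    return reads, pd.DataFrame(truth_rows)


def build_truth(seed: int, scenario: Optional[Scenario] = None) -> SimulationTruth:
    """Materialize the planted world (library, members, contaminants)."""
    scenario = scenario or Scenario()
    rng = np.random.default_rng(seed)
    consensi, members = make_repeat_library(rng, scenario.n_per_category,
                                            scenario.adapter3, scenario.member_profile)
    rdna = random_dna(rng, 2000)
    trna = [random_dna(rng, 75) for _ in range(5)]
    spans = {}
    for cl in (1, 2):
        ms = [m for m in members if m.cluster == cl]
        spans[cl] = (min(m.offset for m in ms),
                     max(m.offset + m.length for m in ms))
    return SimulationTruth(seed=seed, scenario=scenario, consensi=consensi,
                           te_consensus_id=TE_CONSENSUS_ID, members=members,
                           rdna=rdna, trna=trna, cluster_spans=spans)


def simulate_libraries(truth: SimulationTruth, rng: np.random.Generator
                       ) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """All stage libraries in the fixed stage order, plus combined truth."""
    libraries = {}
    frames = []
    for stage in STAGES:
        if stage not in truth.scenario.stage_totals:
            continue
        reads, df = simulate_small_rna_library(rng, truth, stage)
        libraries[stage] = reads
        frames.append(df)
    return libraries, pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

@dataclass
class QpcrDesign:
    """Ground truth for the qPCR / ChIP simulator."""

    primer_efficiencies: dict[str, float] = field(
        default_factory=lambda: {"Sf_L37": 1.0, "LNCR_1": 0.95,
                                 "LNCR_2": 0.9, "rDNA": 0.85})
    intercepts: dict[str, float] = field(default_factory=dict)
    dilution_quantities: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    ct_noise_sd: float = 0.1
    control_primer: str = "Sf_L37"
    stages: tuple[str, ...] = ("eggs", "L2", "pupae", "adults")
    antibodies: tuple[str, ...] = ("H3", "H3K4me2", "H3K9me2", "mock")
    control_percent_input: dict[str, float] = field(
        default_factory=lambda: {"H3": 5.0, "H3K4me2": 2.0,
                                 "H3K9me2": 0.5, "mock": 0.05})
    true_enrichment: dict[tuple[str, str, str], float] = field(default_factory=dict)
    replicates: int = 3
    input_fraction: float = 0.1
    chromatin_quantity: float = 50.0
    genomic_copies: float = 1800.0
    genomic_replicates: int = 6

    def __post_init__(self) -> None:
        for primer, eff in self.primer_efficiencies.items():
            if not (0.5 < eff <= 1.1):
                raise ValueError(f"efficiency for {primer!r} outside (0.5, 1.1]")
            self.intercepts.setdefault(primer, 35.0)
        if self.ct_noise_sd < 0:
            raise ValueError("Ct noise sd must be >= 0")
        if not self.true_enrichment:
            self.true_enrichment = self._default_enrichment()

    def _default_enrichment(self) -> dict[tuple[str, str, str], float]:
        # a dynamic heterochromatin profile: the repeat loci gain H3K9me2 in
        # L2 and adults, lose it in eggs/pupae; H3K4me2 stays mildly high at
        # the control-like loci.
        table = {}
        k9 = {"eggs": 1.2, "L2": 8.0, "pupae": 1.5, "adults": 6.0}
        k4 = {"eggs": 1.3, "L2": 0.8, "pupae": 1.1, "adults": 2.0}
        for stage in self.stages:
            for primer in self.primer_efficiencies:
                if primer == self.control_primer:
                    continue
                is_repeat = primer.startswith("LNCR") or primer == "rDNA"
                table[(primer, "H3", stage)] = 1.1
                table[(primer, "H3K4me2", stage)] = k4[stage] if is_repeat else 1.0
                table[(primer, "H3K9me2", stage)] = k9[stage] if is_repeat else 1.0
                table[(primer, "mock", stage)] = 1.0
        return table


def _ct_from_quantity(quantity: float, efficiency: float, intercept: float) -> float:
    slope = -1.0 / np.log10(1.0 + efficiency)
    return intercept + slope * np.log10(quantity)


def simulate_dilution_series(rng: np.random.Generator, design: QpcrDesign
                             ) -> pd.DataFrame:
    """Per-primer standard-curve points (primer_set, quantity, ct)."""
    rows = []
    for primer in sorted(design.primer_efficiencies):
        eff = design.primer_efficiencies[primer]
        b = design.intercepts[primer]
        for q in design.dilution_quantities:
            ct = _ct_from_quantity(q, eff, b) + rng.normal(0.0, design.ct_noise_sd)
            rows.append({"primer_set": primer, "quantity": q, "ct": ct})
    return pd.DataFrame(rows)


def simulate_chip_samples(rng: np.random.Generator, design: QpcrDesign
                          ) -> pd.DataFrame:
    """Tidy ChIP Ct table (primer_set, antibody, stage, replicate, ct)."""
    rows = []
    for stage in design.stages:
        for primer in sorted(design.primer_efficiencies):
            eff = design.primer_efficiencies[primer]
            b = design.intercepts[primer]
            input_q = design.input_fraction * design.chromatin_quantity
            for rep in range(1, design.replicates + 1):
                ct = _ct_from_quantity(input_q, eff, b) + rng.normal(0.0, design.ct_noise_sd)
                rows.append({"primer_set": primer, "antibody": "input",
                             "stage": stage, "replicate": rep, "ct": ct})
            for antibody in design.antibodies:
                if primer == design.control_primer:
                    pct = design.control_percent_input[antibody]
                else:
                    pct = (design.control_percent_input[antibody]
                           * design.true_enrichment[(primer, antibody, stage)])
                ip_q = pct / 100.0 * design.chromatin_quantity
                for rep in range(1, design.replicates + 1):
                    ct = _ct_from_quantity(ip_q, eff, b) + rng.normal(0.0, design.ct_noise_sd)
                    rows.append({"primer_set": primer, "antibody": antibody,
                                 "stage": stage, "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)


def simulate_genomic_qpcr(rng: np.random.Generator, design: QpcrDesign
                          ) -> pd.DataFrame:
    """Replicate (Ct_reference, Ct_repeat) pairs from a known copy number.

    The single-copy reference amplifies from quantity 1, the repeat from
    quantity equal to its per-genome copy number, both at efficiency 1, so
    the noiseless delta-Ct is log2(copies).
    """
    b = design.intercepts[design.control_primer]
    rows = []
    for rep in range(1, design.genomic_replicates + 1):
        ct_ref = _ct_from_quantity(1.0, 1.0, b) + rng.normal(0.0, design.ct_noise_sd)
        ct_te = _ct_from_quantity(design.genomic_copies, 1.0, b) \
            + rng.normal(0.0, design.ct_noise_sd)
        rows.append({"replicate": rep, "ct_reference": ct_ref, "ct_target": ct_te})
    return pd.DataFrame(rows)


def simulate_densitometry(rng: np.random.Generator,
                          stages: Sequence[str] = ("E1", "E2", "L1", "L2", "P", "A"),
                          noise_sd: float = 0.05) -> pd.DataFrame:
    """Band-volume table (stage x protein) with mild multiplicative noise."""
    h3_true = {s: 1.0 + 0.2 * i for i, s in enumerate(stages)}
    k9_rel = {s: v for s, v in zip(stages, (1.0, 1.1, 1.4, 2.2, 1.2, 2.0))}
    k4_rel = {s: v for s, v in zip(stages, (1.0, 1.3, 1.1, 0.9, 1.0, 1.1))}
    rows = {}
    for s in stages:
        noise = lambda: float(np.exp(rng.normal(0.0, noise_sd)))
        h3 = h3_true[s] * noise()
        rows[s] = {"H3": h3, "H3K9me2": k9_rel[s] * h3_true[s] * noise(),
                   "H3K4me2": k4_rel[s] * h3_true[s] * noise()}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_all(seed: int, scenario: Optional[Scenario] = None,
                 outdir: Optional[str | Path] = None,
                 qpcr_design: Optional[QpcrDesign] = None) -> dict:
    """Generate every pipeline input; optionally write them under ``outdir``.

    Returns a dict with the truth object, in-memory libraries, combined
    read-truth table and the qPCR tables.
    """
    truth = build_truth(seed, scenario)
    rng = np.random.default_rng(seed + 1)
    libraries, read_truth = simulate_libraries(truth, rng)
    design = qpcr_design or QpcrDesign()
    qrng = np.random.default_rng(seed + 2)
    dilutions = simulate_dilution_series(qrng, design)
    chip = simulate_chip_samples(qrng, design)
    genomic = simulate_genomic_qpcr(qrng, design)
    densito = simulate_densitometry(qrng)
    result = {"truth": truth, "libraries": libraries, "read_truth": read_truth,
              "qpcr_design": design, "dilutions": dilutions, "chip": chip,
              "genomic": genomic, "densitometry": densito}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .repeat_annotation import write_repeat_library

        write_repeat_library(truth.consensi, outdir / "repeats.fa",
                             outdir / "repeat_categories.tsv")
        with open(outdir / "rdna.fa", "w") as fh:
            fh.write(f">rDNA_1\n{truth.rdna}\n")
        with open(outdir / "trna.fa", "w") as fh:
            for i, t in enumerate(truth.trna, start=1):
                fh.write(f">tRNA_{i}\n{t}\n")
        for stage, reads in libraries.items():
            write_fastq(reads, outdir / f"{stage}.fastq")
        read_truth.to_csv(outdir / "read_truth.tsv", sep="\t", index=False)
        members_df = pd.DataFrame([
            {"member_id": m.member_id, "cluster": m.cluster, "offset": m.offset,
             "length": m.length, "sequence": m.sequence,
             **{f"count_{s}": m.counts.get(s, 0) for s in STAGES}}
            for m in truth.members
        ])
        members_df.to_csv(outdir / "member_truth.tsv", sep="\t", index=False)
        dilutions.to_csv(outdir / "qpcr_dilutions.tsv", sep="\t", index=False)
        chip.to_csv(outdir / "qpcr_chip.tsv", sep="\t", index=False)
        genomic.to_csv(outdir / "qpcr_genomic.tsv", sep="\t", index=False)
        densito.to_csv(outdir / "densitometry.tsv", sep="\t", index_label="stage")
        truth.scenario.to_yaml(outdir / "scenario.yaml")
    return result
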