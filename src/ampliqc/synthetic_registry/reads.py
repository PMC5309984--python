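"""Paired-read simulation for one donor sample.

Per sample, the on-target read count is drawn Poisson around the
saturation-law mean R = C/(C + K_m) * R_max; primer-dimer and
off-target reads are layered on top so their expected fractions of the
total match the configured rates. Heterozygous amplicons emit
single-crossover chimeras with a uniform breakpoint between the
outermost informative sites; alleles drop out at low concentration;
every emitted base is independently substituted at the configured
error rate. Ground truth for each read is recorded exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .._util import child_rng, revcomp
from ..adapters import ADAPTER_R1, ADAPTER_R2
from .config import RegistryConfig
from .panel import AllelePanel

__all__ = ["DonorSample", "ReadPair", "ReadTruth", "TruthTables", "simulate_reads"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

# quality model: template bases ~ N(36, 3), runoff/adapter bases
# uniform Q2..Q15; only the direction (more dimers -> lower %Q30) is
# constrained by observation, the shapes are modelling choices
_TEMPLATE_Q_MEAN, _TEMPLATE_Q_SD = 36.0, 3.0
_RUNOFF_Q_LO, _RUNOFF_Q_HI = 2, 15
_MAX_PD_FRACTION = 0.995


@dataclass(frozen=True)
class DonorSample:
    """One donor: provenance, both swab concentrations (ng/ul), the
    true genotype (unordered allele-name pair per locus) and the
    workflow assigned from conc_swab1."""

    sample_id: str
    provenance: str
    conc_swab1: float
    conc_swab2: float
    genotype: Mapping[str, tuple[str, str]]
    workflow: str

    def __post_init__(self) -> None:
        if self.conc_swab1 < 0 or self.conc_swab2 < 0:
            raise ValueError("concentrations must be non-negative")
        if self.workflow not in ("fluidigm", "plate384", "rejected"):
            raise ValueError(f"unknown workflow {self.workflow!r}")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    truth_class: str  # on_target | primer_dimer | chimera | off_target
    amplicon: Optional[str] = None
    allele: Optional[str] = None
    parent_a: Optional[str] = None
    parent_b: Optional[str] = None
    breakpoint: Optional[int] = None


@dataclass
class TruthTables:
    """Exact ground truth for a simulated read set."""

    sample_id: str
    reads: list[ReadTruth] = field(default_factory=list)
    on_target_counts: dict[str, int] = field(default_factory=dict)
    dropout_events: list[tuple[str, str]] = field(default_factory=list)  # (locus, allele)
    novel_carried: list[tuple[str, str]] = field(default_factory=list)  # (locus, allele)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.reads:
            counts[t.truth_class] = counts.get(t.truth_class, 0) + 1
        return counts


def _mutate(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution at ``error_rate``; an error
    always changes the base."""
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err)
    out[pos] = _BASES[(_BASE_INDEX[out[pos]] + shift) % 4]
    return out


def _template_quals(n: int, rng: np.random.Generator) -> np.ndarray:
    q = np.rint(rng.normal(_TEMPLATE_Q_MEAN, _TEMPLATE_Q_SD, size=n))
    return np.clip(q, 2, 40).astype(np.int64)


def _phred(quals: np.ndarray) -> str:
    return (quals + 33).astype(np.uint8).tobytes().decode()


def _seq_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


class _PairBuilder:
    """Assembles read pairs for one sample; inserts shorter than the
    read length run off into adapter plus a low-quality random tail."""

    _QPOOL = 64  # full-length template quality strings are drawn from
    # a per-sample pool; per-base draws would dominate runtime

    def __init__(self, sample_id: str, read_length: int, error_rate: float,
                 rng: np.random.Generator) -> None:
        self.sample_id = sample_id
        self.read_length = read_length
        self.error_rate = error_rate
        self.rng = rng
        self.serial = 0
        self.adapter1 = np.frombuffer(ADAPTER_R1.encode(), dtype=np.uint8)
        self.adapter2 = np.frombuffer(ADAPTER_R2.encode(), dtype=np.uint8)
        self._qpool = [
            _phred(_template_quals(read_length, rng)) for _ in range(self._QPOOL)
        ]

    def next_id(self) -> str:
        rid = f"{self.sample_id}:{self.serial:06d}"
        self.serial += 1
        return rid

    def _one_mate(self, insert: np.ndarray, adapter: np.ndarray) -> tuple[str, str]:
        L = self.read_length
        rng = self.rng
        if len(insert) >= L:
            seq = _mutate(insert[:L], self.error_rate, rng)
            return _seq_str(seq), self._qpool[rng.integers(self._QPOOL)]
        else:
            tail_len = L - len(insert)
            runoff = np.concatenate(
                [adapter, rng.choice(_BASES, size=max(0, tail_len - len(adapter)))]
            )[:tail_len]
            seq = np.concatenate([insert, runoff])
            quals = np.concatenate(
                [
                    _template_quals(len(insert), rng),
                    rng.integers(_RUNOFF_Q_LO, _RUNOFF_Q_HI + 1, size=tail_len),
                ]
            )
        seq = _mutate(seq, self.error_rate, rng)
        return _seq_str(seq), _phred(quals)

    def build(self, rid: str, insert: str) -> ReadPair:
        fwd = np.frombuffer(insert.encode(), dtype=np.uint8)
        rev = np.frombuffer(revcomp(insert).encode(), dtype=np.uint8)
        s1, q1 = self._one_mate(fwd, self.adapter1)
        s2, q2 = self._one_mate(rev, self.adapter2)
        return ReadPair(read_id=rid, seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def _chimera_breakpoints(a: str, b: str) -> tuple[int, int] | None:
    """Valid single-crossover range (k_lo, k_hi] such that both sides
    of the breakpoint contain >= 1 informative (differing) site."""
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if len(diffs) < 2:
        return None
    return diffs[0], diffs[-1]


def simulate_reads(
    sample: DonorSample,
    panels: Mapping[str, AllelePanel],
    config: RegistryConfig,
    seed: Optional[int] = None,
    emit_reads: bool = True,
) -> tuple[list[ReadPair], TruthTables]:
    """Simulate the paired FASTQ content of one donor sample.

    Returns the read pairs (deterministic for a given seed + config +
    emit_reads flag) and exact truth tables. ``emit_reads=False``
    skips sequence/quality construction and returns an empty read list
    with complete truth tables (fast path for count-level studies).
    Rejected samples are never sequenced.
    """
    if sample.workflow == "rejected":
        raise ValueError("rejected samples are not sequenced")
    rng = child_rng(config.seed if seed is None else seed, "reads", sample.sample_id)
    truth = TruthTables(sample_id=sample.sample_id)
    builder = _PairBuilder(sample.sample_id, config.read_length, config.error_rate, rng)
    reads: list[ReadPair] = []

    conc = sample.conc_swab1
    mm = config.mm_truth
    mean_on = conc / (conc + mm.km) * mm.rmax if conc > 0 else 0.0
    n_on = int(rng.poisson(mean_on)) if mean_on > 0 else 0

    pd_frac = min(
        config.pd_model.fraction(conc, sample.workflow), _MAX_PD_FRACTION
    )
    n_pd = int(rng.poisson(n_on * pd_frac / (1.0 - pd_frac))) if n_on else 0
    ot = config.off_target_rate
    n_off = int(rng.poisson(n_on * ot / (1.0 - ot))) if n_on and ot > 0 else 0

    # allelic dropout: per distinct allele per locus
    surviving: dict[str, list[str]] = {}
    p_drop = config.dropout_model.probability(conc, sample.workflow)
    for locus in sorted(sample.genotype):
        alleles = sorted(set(sample.genotype[locus]))
        alive = [a for a in alleles if rng.random() >= p_drop]
        for a in alleles:
            if a not in alive:
                truth.dropout_events.append((locus, a))
            if not panels[locus].entries[a].known:
                truth.novel_carried.append((locus, a))
        surviving[locus] = alive

    # distribute on-target reads uniformly over amplicons of live loci
    amp_cells = [
        (locus, amp)
        for locus in sorted(sample.genotype)
        if surviving[locus]
        for amp in sorted(panels[locus].amplicons)
    ]
    if amp_cells and n_on:
        amp_counts = rng.multinomial(n_on, np.full(len(amp_cells), 1.0 / len(amp_cells)))
    else:
        amp_counts = np.zeros(len(amp_cells), dtype=int)

    for (locus, amp), n_amp in zip(amp_cells, amp_counts):
        if n_amp == 0:
            continue
        panel = panels[locus]
        alive = surviving[locus]
        spans = {a: panel.amplicon_seq(a, amp) for a in alive}
        n_chim = 0
        if len(alive) == 2:
            a1, a2 = alive
            bk_range = _chimera_breakpoints(spans[a1], spans[a2])
            if bk_range is not None:
                n_chim = rng.binomial(n_amp, config.chimera_model.rate(amp))
        n_clean = n_amp - n_chim
        if len(alive) == 2:
            n_first = rng.binomial(n_clean, 0.5)
            allele_counts = {alive[0]: n_first, alive[1]: n_clean - n_first}
        else:
            allele_counts = {alive[0]: n_clean}
        for allele in alive:
            for _ in range(allele_counts.get(allele, 0)):
                rid = builder.next_id()
                if emit_reads:
                    reads.append(builder.build(rid, spans[allele]))
                truth.reads.append(
                    ReadTruth(rid, "on_target", amplicon=amp, allele=allele)
                )
        for _ in range(n_chim):
            pa, pb = (a1, a2) if rng.random() < 0.5 else (a2, a1)
            lo, hi = bk_range
            k = int(rng.integers(lo + 1, hi + 1))
            rid = builder.next_id()
            if emit_reads:
                insert = spans[pa][:k] + spans[pb][k:]
                reads.append(builder.build(rid, insert))
            truth.reads.append(
                ReadTruth(
                    rid, "chimera", amplicon=amp,
                    parent_a=pa, parent_b=pb, breakpoint=k,
                )
            )
        truth.on_target_counts[amp] = int(n_amp)

    # primer-dimer reads: short primer-concatenation insert
    primer_rng = child_rng(config.seed, "primers")
    primer_f = _seq_str(primer_rng.choice(_BASES, size=20))
    primer_r = _seq_str(primer_rng.choice(_BASES, size=20))
    dimer_insert = primer_f + revcomp(primer_r)
    for _ in range(n_pd):
        rid = builder.next_id()
        if emit_reads:
            reads.append(builder.build(rid, dimer_insert))
        truth.reads.append(ReadTruth(rid, "primer_dimer"))

    # off-target reads: unrelated random template spanning the read
    for _ in range(n_off):
        rid = builder.next_id()
        if emit_reads:
            insert = _seq_str(rng.choice(_BASES, size=config.read_length + 50))
            reads.append(builder.build(rid, insert))
        truth.reads.append(ReadTruth(rid, "off_target"))

    return reads, truth
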