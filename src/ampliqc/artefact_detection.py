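"""Read-artefact classification: primer dimers, chimeras, off-target.

Every read pair is pushed through a fixed pipeline — adapter scan,
amplicon assignment by shared k-mers with identity confirmation,
then per-amplicon chimera calling against the two most abundant
consensus parents. Classification is deterministic and independent of
read order.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .adapters import DEFAULT_ADAPTERS
from .synthetic_registry.panel import AllelePanel
from .synthetic_registry.reads import ReadPair

__all__ = [
    "AdapterHit",
    "ChimeraCall",
    "ReadClass",
    "RunMetrics",
    "detect_primer_dimer",
    "detect_chimera",
    "classify_pairs",
    "classify_run",
]


@dataclass(frozen=True)
class AdapterHit:
    mate: int  # 1 or 2
    position: int
    adapter: str


@dataclass(frozen=True)
class ChimeraCall:
    breakpoint: int
    order: str  # "ab": left side from parent_a; "ba": the reverse
    score: int


@dataclass(frozen=True)
class ReadClass:
    """Final per-read verdict."""

    read_id: str
    label: str  # on_target | primer_dimer | chimera | off_target
    amplicon: Optional[str] = None
    parents: Optional[tuple[str, str]] = None
    breakpoint: Optional[int] = None
    mismatch_score: int = 0

    def __post_init__(self) -> None:
        is_chimera = self.label == "chimera"
        if (self.breakpoint is not None) != is_chimera or (
            self.parents is not None
        ) != is_chimera:
            raise ValueError("breakpoint/parents set iff label is chimera")
        if self.amplicon is not None and self.label not in ("on_target", "chimera"):
            raise ValueError("amplicon set only for on_target/chimera reads")


@dataclass(frozen=True)
class RunMetrics:
    n_reads: int
    pd_rate: float
    on_target_rate: float
    off_target_rate: float
    chimera_rate: float
    chimera_rate_per_amplicon: Mapping[str, float]
    pct_q30: float

    def __post_init__(self) -> None:
        total = (
            self.pd_rate
            + self.on_target_rate
            + self.off_target_rate
            + self.chimera_rate
        )
        if self.n_reads and abs(total - 1.0) > 1e-9:
            raise ValueError(f"class rates must sum to 1, got {total}")


def detect_primer_dimer(
    read_pair: ReadPair | tuple[str, str],
    adapter_sequences: Sequence[str] = DEFAULT_ADAPTERS,
    min_match: int = 12,
    max_mismatches: int = 1,
) -> Optional[AdapterHit]:
    """Scan both mates for an internal adapter start.

    Reports the leftmost offset at which the first ``min_match`` bases
    of any adapter match with at most ``max_mismatches`` substitutions
    (a qualifying longer prefix implies a qualifying ``min_match`` one,
    so only that window need be scored). Positions are found by
    pigeonhole seeding — the seed window is split into
    ``max_mismatches + 1`` chunks, one of which must match exactly —
    then verified by direct mismatch counting, which keeps the result
    identical to an exhaustive scan. Returns None when no mate
    qualifies; ties across mates go to mate 1.
    """
    if not adapter_sequences:
        raise ValueError("adapter set must be non-empty")
    if min_match < 8:
        raise ValueError("min_match must be >= 8")
    if isinstance(read_pair, tuple):
        mates = read_pair
    else:
        mates = (read_pair.seq1, read_pair.seq2)

    best: Optional[AdapterHit] = None
    for mate_no, read in enumerate(mates, start=1):
        for adapter in adapter_sequences:
            if len(adapter) < min_match:
                raise ValueError("adapter shorter than min_match")
            window = adapter[:min_match]
            pos = _approx_find_leftmost(read, window, max_mismatches)
            if pos is not None and (best is None or pos < best.position):
                best = AdapterHit(mate=mate_no, position=pos, adapter=adapter)
    return best


def _approx_find_leftmost(
    read: str, window: str, max_mismatches: int
) -> Optional[int]:
    """Leftmost offset where ``window`` matches with <= max_mismatches,
    windows truncated by the read end excluded."""
    m = len(window)
    limit = len(read) - m
    if limit < 0:
        return None
    n_chunks = max_mismatches + 1
    bounds = np.linspace(0, m, n_chunks + 1).astype(int)
    candidates: set[int] = set()
    for ci in range(n_chunks):
        lo, hi = bounds[ci], bounds[ci + 1]
        chunk = window[lo:hi]
        start = 0
        while True:
            j = read.find(chunk, start)
            if j == -1:
                break
            p = j - lo
            if 0 <= p <= limit:
                candidates.add(p)
            start = j + 1
    for p in sorted(candidates):
        mm = sum(a != b for a, b in zip(read[p : p + m], window))
        if mm <= max_mismatches:
            return p
    return None


def _mismatch_prefix(read: np.ndarray, parent: np.ndarray) -> np.ndarray:
    """cum[k] = mismatches of read[:k] vs parent[:k], length L+1."""
    cum = np.zeros(len(read) + 1, dtype=np.int64)
    np.cumsum(read != parent, out=cum[1:])
    return cum


def detect_chimera(
    read: str,
    parent_a: str,
    parent_b: str,
    min_flank: int = 3,
    margin: int = 2,
) -> Optional[ChimeraCall]:
    """Single-crossover test of ``read`` against two aligned parents.

    Every breakpoint k and both parent orders are scored as
    mismatches(read[:k], left parent) + mismatches(read[k:], right
    parent); the best split is called iff it beats the better pure
    parent by more than ``margin`` mismatches and each side of the
    breakpoint spans at least ``min_flank`` informative (parent-
    differing) positions. Ties prefer the smaller breakpoint, then the
    a->b order. Swapping the parents maps the call to the mirrored
    order with the same breakpoint.
    """
    if not (len(read) == len(parent_a) == len(parent_b)):
        raise ValueError("read and parents must have equal length")
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    a = np.frombuffer(parent_a.encode(), dtype=np.uint8)
    b = np.frombuffer(parent_b.encode(), dtype=np.uint8)

    cum_a = _mismatch_prefix(r, a)
    cum_b = _mismatch_prefix(r, b)
    pure = int(min(cum_a[-1], cum_b[-1]))

    info = np.zeros(len(r) + 1, dtype=np.int64)
    np.cumsum(a != b, out=info[1:])
    total_info = info[-1]
    # breakpoints with >= min_flank informative sites on each side
    ks = np.arange(len(r) + 1)
    valid = (info >= min_flank) & (total_info - info >= min_flank)
    if not valid.any():
        return None
    score_ab = cum_a + (cum_b[-1] - cum_b)
    score_ba = cum_b + (cum_a[-1] - cum_a)

    best: Optional[ChimeraCall] = None
    for order, score in (("ab", score_ab), ("ba", score_ba)):
        sc = np.where(valid, score, np.iinfo(np.int64).max)
        k = int(np.argmin(sc))
        s = int(sc[k])
        if best is None or s < best.score or (s == best.score and k < best.breakpoint):
            best = ChimeraCall(breakpoint=k, order=order, score=s)
    if best.score + margin < pure:
        return best
    return None


@dataclass
class _AmpliconIndex:
    """Shared-k-mer index over all amplicon references for assignment."""

    k: int
    kmer_to_amp: dict[str, set[str]]
    ref_matrix: dict[str, np.ndarray]  # amplicon -> (n_alleles, L) uint8
    ref_names: dict[str, list[str]]
    span_len: dict[str, int]


def _build_index(panels: Mapping[str, AllelePanel], k: int = 15) -> _AmpliconIndex:
    kmer_to_amp: dict[str, set[str]] = defaultdict(set)
    ref_matrix: dict[str, np.ndarray] = {}
    ref_names: dict[str, list[str]] = {}
    span_len: dict[str, int] = {}
    for locus in sorted(panels):
        panel = panels[locus]
        for amp in sorted(panel.amplicons):
            names = sorted(panel.entries)
            seqs = [panel.amplicon_seq(n, amp) for n in names]
            ref_names[amp] = names
            ref_matrix[amp] = np.vstack(
                [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
            )
            span_len[amp] = len(seqs[0])
            for s in seqs:
                for i in range(len(s) - k + 1):
                    kmer_to_amp[s[i : i + k]].add(amp)
    return _AmpliconIndex(
        k=k,
        kmer_to_amp=dict(kmer_to_amp),
        ref_matrix=ref_matrix,
        ref_names=ref_names,
        span_len=span_len,
    )


def _assign_amplicon(
    seq: str, index: _AmpliconIndex, identity_threshold: float
) -> Optional[str]:
    k = index.k
    votes: Counter[str] = Counter()
    for i in range(0, len(seq) - k + 1, k):  # non-overlapping probes suffice
        for amp in index.kmer_to_amp.get(seq[i : i + k], ()):
            votes[amp] += 1
    if not votes:
        return None
    top = max(votes.values())
    amp = min(a for a, v in votes.items() if v == top)  # lexicographic tie-break
    L = index.span_len[amp]
    r = np.frombuffer(seq[:L].encode(), dtype=np.uint8)
    if len(r) < L:
        return None
    best_mm = int((index.ref_matrix[amp] != r).sum(axis=1).min())
    if 1.0 - best_mm / L < identity_threshold:
        return None
    return amp


def _sample_of(read_id: str) -> str:
    return read_id.rsplit(":", 1)[0] if ":" in read_id else ""


def classify_pairs(
    pairs: Iterable[ReadPair],
    panels: Mapping[str, AllelePanel],
    adapter_sequences: Sequence[str] = DEFAULT_ADAPTERS,
    min_match: int = 12,
    max_mismatches: int = 1,
    identity_threshold: float = 0.8,
    parent_ratio: float = 1.0,
    min_flank: int = 3,
    margin: int = 2,
    kmer_size: int = 15,
) -> tuple[list[ReadClass], RunMetrics]:
    """Classify in-memory read pairs; see :func:`classify_run`."""
    pairs = sorted(pairs, key=lambda p: p.read_id)  # order-independence
    index = _build_index(panels, k=kmer_size)

    q30_hits = 0
    q30_total = 0
    provisional: dict[str, str] = {}  # read_id -> label
    assigned_amp: dict[str, str] = {}
    by_group: dict[tuple[str, str], list[ReadPair]] = defaultdict(list)

    for pair in pairs:
        for qual in (pair.qual1, pair.qual2):
            q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
            q30_hits += int((q >= 30).sum())
            q30_total += len(q)
        if detect_primer_dimer(pair, adapter_sequences, min_match, max_mismatches):
            provisional[pair.read_id] = "primer_dimer"
            continue
        amp = _assign_amplicon(pair.seq1, index, identity_threshold)
        if amp is None:
            provisional[pair.read_id] = "off_target"
            continue
        provisional[pair.read_id] = "on_target"
        assigned_amp[pair.read_id] = amp
        by_group[(_sample_of(pair.read_id), amp)].append(pair)

    # per-sample, per-amplicon chimera calling against top-2 consensus parents
    chimera_info: dict[str, tuple[tuple[str, str], int, int]] = {}
    for (sample, amp), group in by_group.items():
        L = index.span_len[amp]
        seq_counts = Counter(p.seq1[:L] for p in group)
        top = seq_counts.most_common()
        if len(top) < 2:
            continue
        # deterministic top-2: count desc, then sequence lexicographic
        ranked = sorted(seq_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        (p1, n1), (p2, n2) = ranked[0], ranked[1]
        names = index.ref_names[amp]
        mat = index.ref_matrix[amp]

        def _parent_name(seq: str, fallback: str) -> str:
            r = np.frombuffer(seq.encode(), dtype=np.uint8)
            hits = np.nonzero((mat == r).all(axis=1))[0]
            return names[hits[0]] if len(hits) else fallback

        name1 = _parent_name(p1, f"{amp}:cons1")
        name2 = _parent_name(p2, f"{amp}:cons2")
        calls: list[tuple[str, ChimeraCall]] = []
        for pair in group:
            seq = pair.seq1[:L]
            if seq == p1 or seq == p2:
                continue
            call = detect_chimera(seq, p1, p2, min_flank=min_flank, margin=margin)
            if call is not None:
                calls.append((pair.read_id, call))
        # parents must not be outnumbered: each parent's support must
        # reach parent_ratio x the number of putative chimeras
        if calls and min(n1, n2) >= parent_ratio * len(calls):
            for rid, call in calls:
                parents = (name1, name2) if call.order == "ab" else (name2, name1)
                chimera_info[rid] = (parents, call.breakpoint, call.score)

    table: list[ReadClass] = []
    for pair in pairs:
        rid = pair.read_id
        label = provisional[rid]
        if rid in chimera_info:
            parents, bk, score = chimera_info[rid]
            table.append(
                ReadClass(
                    rid, "chimera", amplicon=assigned_amp[rid],
                    parents=parents, breakpoint=bk, mismatch_score=score,
                )
            )
        else:
            table.append(
                ReadClass(rid, label, amplicon=assigned_amp.get(rid))
            )

    n = len(table)
    counts = Counter(rc.label for rc in table)
    per_amp_chim: dict[str, float] = {}
    for amp in index.span_len:
        n_chim = sum(
            1 for rc in table if rc.label == "chimera" and rc.amplicon == amp
        )
        n_on = sum(
            1 for rc in table if rc.label == "on_target" and rc.amplicon == amp
        )
        if n_chim + n_on:
            per_amp_chim[amp] = n_chim / (n_chim + n_on)
    metrics = RunMetrics(
        n_reads=n,
        pd_rate=counts["primer_dimer"] / n if n else 0.0,
        on_target_rate=counts["on_target"] / n if n else 0.0,
        off_target_rate=counts["off_target"] / n if n else 0.0,
        chimera_rate=counts["chimera"] / n if n else 0.0,
        chimera_rate_per_amplicon=per_amp_chim,
        pct_q30=q30_hits / q30_total if q30_total else 0.0,
    )
    return table, metrics


def classify_run(
    r1_path,
    r2_path,
    panels: Mapping[str, AllelePanel],
    **kwargs,
) -> tuple[list[ReadClass], RunMetrics]:
    """Classify a paired FASTQ run against a panel set.

    Pipeline: adapter (dimer) scan -> amplicon assignment by shared
    k-mers with identity confirmation (off_target below threshold) ->
    per-sample/per-amplicon chimera calls against the two most
    abundant consensus parents, retained only while the parents are
    not outnumbered (each parent count >= parent_ratio x chimera
    count; otherwise chimeric reads stay on_target, mimicking
    detection failure). Returns the per-read class table and run
    metrics over all reads.
    """
    from .io import read_fastq_pairs

    return classify_pairs(read_fastq_pairs(r1_path, r2_path), panels, **kwargs)
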