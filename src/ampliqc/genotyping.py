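"""Simplified per-locus genotype calling from classified on-target
reads.

Reads are grouped by exact sequence after a per-base quality gate;
surviving consensus clusters are matched exactly against the panel and
paired consistently across the exon amplicons. A consensus matching no
reference allele raises the novel-allele signature. This is
deliberately a crisp stand-in for a production caller: simulator error
rates are low, so errors form minor clusters that the cluster-fraction
threshold removes, and "novel" means exactly "consensus differs from
every reference".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Mapping, Optional, Sequence

import numpy as np

from .synthetic_registry.panel import AllelePanel

__all__ = [
    "ConsensusCluster",
    "LocusResult",
    "cluster_reads",
    "call_genotype",
    "genotype_classified_reads",
]

MIN_BASE_QUALITY = 10
DEFAULT_MIN_DEPTH = 100
DEFAULT_MIN_BALANCE = 0.25
DEFAULT_MIN_ON_TARGET = 0.5


@dataclass(frozen=True)
class ConsensusCluster:
    amplicon: str
    consensus: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster must be supported by >= 1 read")


@dataclass(frozen=True)
class LocusResult:
    """Per-locus call: genotype (or None), per-amplicon depth, allele
    balance (minor/major read ratio; 1.0 when effectively homozygous)
    and QC flags."""

    locus: str
    genotype: Optional[tuple[str, str]]
    depth: Mapping[str, int]
    balance: float
    flags: frozenset[str]
    sample_id: Optional[str] = None
    novel_consensus: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.balance <= 1.0:
            raise ValueError("balance must lie in [0, 1]")


def cluster_reads(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    amplicon: str,
    min_cluster_frac: float = 0.1,
) -> list[ConsensusCluster]:
    """Exact-sequence clustering of one amplicon's reads.

    ``reads`` are (sequence, phred_string) pairs — or bare sequences,
    in which case the quality gate is skipped. Reads with any base
    below Q10 are discarded first; clusters supported by fewer than
    ``min_cluster_frac`` of the surviving reads are dropped. Clusters
    are ordered by count (descending), then consensus (lexicographic),
    so the result is independent of read order.
    """
    if not 0 <= min_cluster_frac <= 1:
        raise ValueError("min_cluster_frac must lie in [0, 1]")
    kept: list[str] = []
    for item in reads:
        if isinstance(item, str):
            kept.append(item)
            continue
        seq, qual = item
        q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
        if len(q) and q.min() < MIN_BASE_QUALITY:
            continue
        kept.append(seq)
    if not kept:
        return []
    counts = Counter(kept)
    cutoff = min_cluster_frac * len(kept)
    survivors = [
        ConsensusCluster(amplicon=amplicon, consensus=seq, count=n)
        for seq, n in counts.items()
        if n >= cutoff
    ]
    return sorted(survivors, key=lambda c: (-c.count, c.consensus))


def call_genotype(
    clusters_by_amplicon: Mapping[str, Sequence[ConsensusCluster]],
    panel: AllelePanel,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_balance: float = DEFAULT_MIN_BALANCE,
    on_target_rate: Optional[float] = None,
    min_on_target: float = DEFAULT_MIN_ON_TARGET,
    sample_id: Optional[str] = None,
) -> LocusResult:
    """Call a genotype for one locus from per-amplicon clusters.

    The top two clusters per amplicon are matched exactly against the
    panel's amplicon sequences; the genotype is the allele pair whose
    predicted sequences equal the observed consensus set in *every*
    amplicon (a single cluster everywhere yields a homozygous call —
    deliberately, a silently dropped allele produces a technically
    valid homozygous genotype for the QC layer to catch). Ties between
    consistent pairs are broken by higher summed panel frequency, then
    lexicographically.

    Flags: ``low_total_reads`` (any amplicon depth < min_depth),
    ``low_on_target`` (only when an on-target rate is supplied),
    ``imbalance`` (minor/major < min_balance in any two-cluster
    amplicon), ``excess_alleles`` (> 2 surviving clusters anywhere),
    ``novel_signature`` (a top consensus matches no reference; the
    divergent consensus is attached), ``no_genotype`` (no consistent
    pairing for other reasons).
    """
    if not panel.entries:
        raise ValueError("panel must be non-empty")
    flags: set[str] = set()
    depth: dict[str, int] = {}
    balance = 1.0
    novel: dict[str, str] = {}
    top2: dict[str, list[ConsensusCluster]] = {}

    for amp in sorted(clusters_by_amplicon):
        clusters = sorted(
            clusters_by_amplicon[amp], key=lambda c: (-c.count, c.consensus)
        )
        depth[amp] = sum(c.count for c in clusters)
        if depth[amp] < min_depth:
            flags.add("low_total_reads")
        if len(clusters) > 2:
            flags.add("excess_alleles")
        top2[amp] = clusters[:2]
        if len(top2[amp]) == 2:
            major, minor = top2[amp][0].count, top2[amp][1].count
            balance = min(balance, minor / major)
    if balance < min_balance:
        flags.add("imbalance")
    if on_target_rate is not None and on_target_rate < min_on_target:
        flags.add("low_on_target")

    # exact matching of consensi against the panel
    candidates: set[str] = set()
    for amp, clusters in top2.items():
        for c in clusters:
            hits = [
                name
                for name in panel.entries
                if panel.amplicon_seq(name, amp) == c.consensus
            ]
            if hits:
                candidates.update(hits)
            else:
                flags.add("novel_signature")
                novel[amp] = c.consensus

    genotype: Optional[tuple[str, str]] = None
    if "novel_signature" not in flags and candidates and top2:
        consistent: list[tuple[str, str]] = []
        for a, b in combinations_with_replacement(sorted(candidates), 2):
            ok = True
            for amp, clusters in top2.items():
                observed = {c.consensus for c in clusters}
                predicted = {
                    panel.amplicon_seq(a, amp),
                    panel.amplicon_seq(b, amp),
                }
                if observed != predicted:
                    ok = False
                    break
            if ok:
                consistent.append((a, b))
        if consistent:
            genotype = min(
                consistent,
                key=lambda pair: (
                    -(
                        panel.entries[pair[0]].frequency
                        + panel.entries[pair[1]].frequency
                    ),
                    pair,
                ),
            )
    if genotype is None and "novel_signature" not in flags:
        flags.add("no_genotype")

    return LocusResult(
        locus=panel.locus,
        genotype=genotype,
        depth=depth,
        balance=balance,
        flags=frozenset(flags),
        sample_id=sample_id,
        novel_consensus=novel,
    )


def genotype_classified_reads(
    pairs,
    classes,
    panels: Mapping[str, AllelePanel],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_balance: float = DEFAULT_MIN_BALANCE,
    min_cluster_frac: float = 0.1,
) -> dict[tuple[str, str], LocusResult]:
    """Genotype every (sample, locus) in a classified read set.

    ``pairs`` are the read pairs and ``classes`` the matching per-read
    verdicts from artefact classification; only on-target reads enter
    clustering (dimer/chimera/off-target reads are filtered artefacts,
    but they do lower the per-sample on-target rate passed to the
    caller). Samples are recovered from the read-id prefix. A locus
    with no reads at all still yields a LocusResult (flagged).
    """
    by_id = {rc.read_id: rc for rc in classes}
    amp_to_locus = {
        amp: locus for locus, p in panels.items() for amp in p.amplicons
    }
    grouped: dict[tuple[str, str], dict[str, list[tuple[str, str]]]] = {}
    label_counts: dict[str, Counter] = {}
    for pair in pairs:
        rc = by_id[pair.read_id]
        sample = pair.read_id.rsplit(":", 1)[0]
        label_counts.setdefault(sample, Counter())[rc.label] += 1
        if rc.label != "on_target" or rc.amplicon is None:
            continue
        locus = amp_to_locus[rc.amplicon]
        panel = panels[locus]
        s, t = panel.amplicons[rc.amplicon]
        span = t - s
        grouped.setdefault((sample, locus), {}).setdefault(
            rc.amplicon, []
        ).append((pair.seq1[:span], pair.qual1[:span]))

    results: dict[tuple[str, str], LocusResult] = {}
    for sample, counts in sorted(label_counts.items()):
        total = sum(counts.values())
        on_rate = counts["on_target"] / total if total else 0.0
        for locus, panel in sorted(panels.items()):
            amps = grouped.get((sample, locus), {})
            clusters = {
                amp: cluster_reads(reads, amp, min_cluster_frac=min_cluster_frac)
                for amp, reads in amps.items()
            }
            results[(sample, locus)] = call_genotype(
                clusters,
                panel,
                min_depth=min_depth,
                min_balance=min_balance,
                on_target_rate=on_rate,
                sample_id=sample,
            )
    return results
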