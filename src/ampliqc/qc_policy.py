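"""Routing, repeat-typing and novel-allele verification rules.

A pure decision engine: every function maps explicit inputs to an
auditable verdict with machine-readable reason codes, so replaying a
results table always reproduces the same decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "REPEAT_FLAGS",
    "HLA_LOCI",
    "QCPolicy",
    "RepeatDecision",
    "NovelVerification",
    "route_workflow",
    "locus_repeat_decision",
    "sample_repeat_decision",
    "confirm_novel",
]

#: Locus-level flags that trigger a repeat typing of that locus.
REPEAT_FLAGS = frozenset(
    {
        "low_total_reads",
        "low_on_target",
        "imbalance",
        "excess_alleles",
        "no_genotype",
        "novel_signature",
    }
)

#: The six loci that count towards the sample-level failure rule.
HLA_LOCI = ("A", "B", "C", "DRB1", "DQB1", "DPB1")


@dataclass(frozen=True)
class QCPolicy:
    """Thresholds governing routing and repeat decisions.

    ``reject_below``/``plate384_below`` are strict upper bounds in
    ng/ul: concentrations below ``reject_below`` are rejected outright
    (second-swab extraction path); concentrations in
    [reject_below, plate384_below) go to the 384-well 2-PCR workflow;
    everything else stays on the nanofluidic workflow.

    ``max_failing_loci`` is the largest tolerated number of failing
    HLA loci; strictly more triggers a full-sample repeat.

    ``overrides`` is a hook for analyst-discretion repeats: a
    collection of (sample_id, locus) pairs forced to repeat with
    reason ``analyst_override``.
    """

    reject_below: float = 2.0
    plate384_below: float = 18.0
    max_failing_loci: int = 4
    hla_loci: Sequence[str] = HLA_LOCI
    overrides: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 <= self.reject_below < self.plate384_below):
            raise ValueError(
                "thresholds must satisfy 0 <= reject_below < plate384_below"
            )


@dataclass(frozen=True)
class RepeatDecision:
    """A repeat-typing verdict for a locus or an entire sample."""

    scope: str  # "locus" | "sample"
    reasons: tuple[str, ...]
    triggered_by: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scope not in ("locus", "sample"):
            raise ValueError(f"invalid scope {self.scope!r}")
        if not self.reasons:
            raise ValueError("a repeat decision must carry at least one reason")


@dataclass(frozen=True)
class NovelVerification:
    """Outcome of verifying a putative novel consensus by a second,
    independent PCR and typing."""

    first: str
    second: Optional[str]
    status: str  # "pending" | "confirmed" | "artefact"


def route_workflow(conc: float, policy: QCPolicy = QCPolicy()) -> str:
    """Route a sample by its initial DNA concentration (ng/ul).

    Returns one of ``rejected`` (below the exclusion threshold;
    handled via a second extraction), ``plate384`` (low-concentration
    2-PCR 2-primer workflow) or ``fluidigm``. Both thresholds are
    strict ("lower than").
    """
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if conc < policy.reject_below:
        return "rejected"
    if conc < policy.plate384_below:
        return "plate384"
    return "fluidigm"


def locus_repeat_decision(result, policy: QCPolicy = QCPolicy()) -> Optional[RepeatDecision]:
    """Locus-level repeat decision from a genotyping ``LocusResult``.

    A repeat is requested iff any repeat-triggering flag is set (or an
    analyst override matches); the reasons echo the flags.
    """
    reasons = sorted(set(result.flags) & REPEAT_FLAGS)
    sample_id = getattr(result, "sample_id", None)
    if sample_id is not None and (sample_id, result.locus) in policy.overrides:
        reasons.append("analyst_override")
    if not reasons:
        return None
    return RepeatDecision(
        scope="locus", reasons=tuple(reasons), triggered_by=(result.locus,)
    )


def sample_repeat_decision(
    locus_decisions: Mapping[str, Optional[RepeatDecision]],
    conc: float,
    policy: QCPolicy = QCPolicy(),
) -> Optional[RepeatDecision]:
    """Escalate to a full-sample repeat when warranted.

    A full repeat (second DNA extraction) fires iff the initial
    concentration is below the exclusion threshold or strictly more
    than ``max_failing_loci`` HLA loci fail to produce credible
    results ("credible" operationalised as: no repeat-triggering
    flag). Otherwise locus decisions pass through unchanged and this
    returns ``None``.
    """
    missing = [l for l in policy.hla_loci if l not in locus_decisions]
    if missing:
        raise ValueError(f"decisions missing for HLA loci: {missing}")
    failing = tuple(
        l for l in policy.hla_loci if locus_decisions[l] is not None
    )
    reasons: list[str] = []
    if conc < policy.reject_below:
        reasons.append("low_concentration")
    if len(failing) > policy.max_failing_loci:
        reasons.append("excess_failed_loci")
    if not reasons:
        return None
    return RepeatDecision(scope="sample", reasons=tuple(reasons), triggered_by=failing)


def confirm_novel(
    first: str, second: Optional[str], panel_sequences: Iterable[str]
) -> NovelVerification:
    """Verify a putative novel consensus against its independent repeat.

    ``confirmed`` iff the second consensus is byte-identical to the
    first and still matches no reference sequence; any disagreement,
    or a second consensus matching a known allele, marks the original
    deviation as a PCR/sequencing artefact. Absent second -> pending.
    """
    if second is None:
        return NovelVerification(first=first, second=None, status="pending")
    known = set(panel_sequences)
    if second == first and second not in known:
        status = "confirmed"
    else:
        status = "artefact"
    return NovelVerification(first=first, second=second, status=status)
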