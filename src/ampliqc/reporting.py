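"""Summary statistics over results and ledgers, plus the packaged
per-locus novel-allele count fixture.

Aggregation stays in exact integer arithmetic until the final
printed-precision rounding (half away from zero); rerunning on the
fixture is byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import round_half_away

__all__ = [
    "CLASS_I",
    "CLASS_II",
    "DEFAULT_ALLELES_TYPED",
    "DEFAULT_FLAGGED",
    "LocusNovelCounts",
    "NovelAlleleSummary",
    "SlopeEstimate",
    "load_novel_counts_fixture",
    "novel_allele_summary",
    "pcr_error_rate",
    "masking_probability",
    "pd_concentration_slope",
    "render_report",
]

CLASS_I = ("A", "B", "C")
CLASS_II = ("DRB1", "DQB1", "DPB1")

#: Operational totals for the same 17-month window as the packaged
#: fixture: HLA alleles typed, and alleles flagged with a potential
#: novel-allele signature (triggering verification by repeat typing).
DEFAULT_ALLELES_TYPED = 17_184_548
DEFAULT_FLAGGED = 13_835


@dataclass(frozen=True)
class LocusNovelCounts:
    locus: str
    samples: int
    total_novel: int
    distinct_novel: int

    def __post_init__(self) -> None:
        if self.distinct_novel > self.total_novel:
            raise ValueError(
                f"{self.locus}: distinct ({self.distinct_novel}) cannot "
                f"exceed total ({self.total_novel})"
            )


@dataclass(frozen=True)
class NovelAlleleSummary:
    """Per-class and overall novel-allele accounting with derived
    rates at printed precision. ``class_ratio`` is class II : class I
    confirmed totals (None when undefined)."""

    per_locus: tuple[LocusNovelCounts, ...]
    n_alleles_typed: int
    n_flagged: int
    total_novel: int
    distinct_novel: int
    class1_total: int
    class1_distinct: int
    class2_total: int
    class2_distinct: int
    flagged_rate_pct: float
    confirmed_fraction_pct: Optional[float]
    class1_distinct_pct: Optional[float]
    class2_distinct_pct: Optional[float]
    class_ratio: Optional[float]
    max_pcr_error_rate_pct: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def load_novel_counts_fixture() -> dict[str, LocusNovelCounts]:
    """Load the packaged per-locus novel-allele count table."""
    text = (resources.files("ampliqc.data") / "table2.tsv").read_text()
    rows: dict[str, LocusNovelCounts] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, fields))
        rows[rec["locus"]] = LocusNovelCounts(
            locus=rec["locus"],
            samples=int(rec["samples"]),
            total_novel=int(rec["total_novel"]),
            distinct_novel=int(rec["distinct_novel"]),
        )
    return rows


def pcr_error_rate(
    n_flagged: int, n_confirmed: int, n_alleles_typed: int,
    ndigits: Optional[int] = None,
) -> float:
    """Upper bound on the per-typing PCR error rate, in percent:
    100 * (flagged - confirmed) / typed.

    Every flagged-but-unconfirmed signature is attributed to PCR or
    sequencing error, hence "maximum". Optionally rounded half away
    from zero to ``ndigits`` decimals.
    """
    if not (0 <= n_confirmed <= n_flagged <= n_alleles_typed):
        raise ValueError(
            "require 0 <= n_confirmed <= n_flagged <= n_alleles_typed"
        )
    rate = 100.0 * (n_flagged - n_confirmed) / n_alleles_typed
    return round_half_away(rate, ndigits) if ndigits is not None else rate


def masking_probability(
    error_rate_per_typing: float,
    allele_length: int = 730,
    substitution_alphabet: int = 4,
) -> float:
    """Probability that a single artefactual substitution masks a true
    novel allele by landing on its one divergent position and restoring
    the reference base: err * 1/length * 1/(alphabet-1)."""
    if error_rate_per_typing < 0 or allele_length <= 0 or substitution_alphabet < 2:
        raise ValueError("inputs must be positive (alphabet >= 2)")
    return error_rate_per_typing / (allele_length * (substitution_alphabet - 1))


def novel_allele_summary(
    per_locus: Mapping[str, LocusNovelCounts] | Mapping[str, tuple],
    n_alleles_typed: int = DEFAULT_ALLELES_TYPED,
    n_flagged: int = DEFAULT_FLAGGED,
) -> NovelAlleleSummary:
    """Aggregate per-locus novel-allele counts into class and overall
    rates.

    Requires all six loci. Percentages are rounded at printed
    precision: flagged rate to three decimals, class distinct/total
    fractions and confirmed fraction to one, the PCR error bound to
    two. Undefined ratios (zero denominators) are reported as None.
    """
    missing = [l for l in CLASS_I + CLASS_II if l not in per_locus]
    if missing:
        raise ValueError(f"missing loci: {missing}")
    recs: dict[str, LocusNovelCounts] = {}
    for locus in CLASS_I + CLASS_II:
        v = per_locus[locus]
        recs[locus] = (
            v if isinstance(v, LocusNovelCounts) else LocusNovelCounts(locus, *v)
        )

    c1t = sum(recs[l].total_novel for l in CLASS_I)
    c1d = sum(recs[l].distinct_novel for l in CLASS_I)
    c2t = sum(recs[l].total_novel for l in CLASS_II)
    c2d = sum(recs[l].distinct_novel for l in CLASS_II)
    total, distinct = c1t + c2t, c1d + c2d

    def pct(num: int, den: int, nd: int) -> Optional[float]:
        return round_half_away(100.0 * num / den, nd) if den else None

    return NovelAlleleSummary(
        per_locus=tuple(recs[l] for l in CLASS_I + CLASS_II),
        n_alleles_typed=n_alleles_typed,
        n_flagged=n_flagged,
        total_novel=total,
        distinct_novel=distinct,
        class1_total=c1t,
        class1_distinct=c1d,
        class2_total=c2t,
        class2_distinct=c2d,
        flagged_rate_pct=pct(n_flagged, n_alleles_typed, 3) or 0.0,
        confirmed_fraction_pct=pct(total, n_flagged, 1),
        class1_distinct_pct=pct(c1d, c1t, 1),
        class2_distinct_pct=pct(c2d, c2t, 1),
        class_ratio=(c2t / c1t) if c1t else None,
        max_pcr_error_rate_pct=pcr_error_rate(
            n_flagged, min(total, n_flagged), n_alleles_typed, ndigits=2
        ),
    )


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of PD rate on DNA concentration in the
    low-concentration stratum, reported as percentage points of PD per
    ng/ul *less* (sign-flipped), with a 95% confidence interval."""

    slope: float
    ci_low: float
    ci_high: float
    n: int


def pd_concentration_slope(
    records: Sequence[tuple[float, float]] | np.ndarray,
    conc_ceiling: float = 18.0,
    min_records: int = 100,
) -> SlopeEstimate:
    """Estimate how fast the primer-dimer rate grows as input DNA
    drops, restricted to concentrations below ``conc_ceiling`` ng/ul.

    ``records`` are (concentration ng/ul, PD rate in percent) pairs.
    The OLS slope is sign-flipped so a positive value reads "percentage
    points of PD per ng/ul less DNA"; the CI is the t-based 95%
    interval from the slope standard error.
    """
    arr = np.asarray(records, dtype=float)
    mask = arr[:, 0] < conc_ceiling
    arr = arr[mask]
    if len(arr) < min_records:
        raise ValueError(
            f"need >= {min_records} records below {conc_ceiling} ng/ul, "
            f"got {len(arr)}"
        )
    if np.ptp(arr[:, 0]) == 0:
        raise ValueError("degenerate concentration variance")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    tcrit = stats.t.ppf(0.975, len(arr) - 2)
    # sign flip: slope per ng/ul *less*
    return SlopeEstimate(
        slope=-res.slope,
        ci_low=-res.slope - tcrit * res.stderr,
        ci_high=-res.slope + tcrit * res.stderr,
        n=int(len(arr)),
    )


def render_report(summary: NovelAlleleSummary) -> str:
    """Human-readable text table for a novel-allele summary."""
    lines = [
        "Novel-allele summary",
        "=" * 60,
        f"{'locus':<8}{'samples':>12}{'total':>10}{'distinct':>10}",
    ]
    for rec in summary.per_locus:
        lines.append(
            f"{rec.locus:<8}{rec.samples:>12}{rec.total_novel:>10}"
            f"{rec.distinct_novel:>10}"
        )
    lines += [
        "-" * 60,
        f"alleles typed:            {summary.n_alleles_typed:>12,}",
        f"flagged signatures:       {summary.n_flagged:>12,}",
        f"flagged rate:             {summary.flagged_rate_pct}%",
        f"confirmed novel (total):  {summary.total_novel}",
        f"confirmed fraction:       {summary.confirmed_fraction_pct}%"
        " (recomputed from counts)",
        f"distinct novel:           {summary.distinct_novel}",
        f"class I  total/distinct:  {summary.class1_total}/{summary.class1_distinct}"
        f" ({summary.class1_distinct_pct}% distinct)",
        f"class II total/distinct:  {summary.class2_total}/{summary.class2_distinct}"
        f" ({summary.class2_distinct_pct}% distinct)",
        f"class II : class I ratio: "
        + (
            f"{summary.class_ratio:.2f}"
            if summary.class_ratio is not None
            else "NA"
        ),
        f"max PCR error rate:       {summary.max_pcr_error_rate_pct}%",
    ]
    return "\n".join(lines)
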