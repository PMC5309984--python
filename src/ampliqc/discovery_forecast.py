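"""Novel-allele discovery curves and decay-model extrapolation.

The accumulation of distinct novel alleles over typed samples is
estimated by repeatedly permuting the processing order, binning
samples into fixed-size batches and counting first-ever observations
per batch. The declining per-batch discovery rate is fitted with a
3-parameter exponential decay r(n) = c + a*exp(-b*n) whose nonzero
asymptote c drives near-linear long-horizon growth, and the fitted
rate is integrated to forecast distinct counts at larger sample
numbers. An independent closed-form accumulation expectation,
sum_j (1 - (1 - p_j)^(m*n)), serves as the validation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DiscoveryLedger",
    "DiscoveryCurve",
    "DecayModel",
    "ForecastTable",
    "discovery_curve",
    "oracle_expected_distinct",
    "fit_decay",
    "project",
]


@dataclass(frozen=True)
class DiscoveryLedger:
    """Ordered first-occurrence record of novel-allele observations.

    ``events`` are (sample_index, allele_id) pairs sorted by sample
    index; the same allele id may recur (re-observations of a
    previously discovered sequence). ``total_samples`` counts all
    samples processed, including those carrying no novel allele.
    """

    locus: str
    events: tuple[tuple[int, str], ...]
    total_samples: int

    def __post_init__(self) -> None:
        idx = [s for s, _ in self.events]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be non-decreasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.total_samples):
            raise ValueError("event sample indices out of range")

    @property
    def distinct_alleles(self) -> int:
        return len({a for _, a in self.events})


@dataclass(frozen=True)
class DiscoveryCurve:
    """Mean (+/- SD over permutation replicates) count of newly seen
    distinct alleles per consecutive bin of ``bin_size`` samples."""

    bin_size: int
    n_reps: int
    mean_new: np.ndarray
    sd_new: np.ndarray
    total_samples: int

    @property
    def n_bins(self) -> int:
        return len(self.mean_new)


@dataclass(frozen=True)
class DecayModel:
    """r(n) = c + a*exp(-b*n): per-bin discovery rate at cumulative
    sample count n. ``bin_size`` carries the rate's denominator."""

    a: float
    b: float
    c: float
    bin_size: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.c < 0:
            raise ValueError("require a >= 0, b > 0, c >= 0")

    def rate(self, n) -> np.ndarray:
        return self.c + self.a * np.exp(-self.b * np.asarray(n, dtype=float))


@dataclass(frozen=True)
class ForecastTable:
    """Expected distinct novel alleles at the requested sample counts."""

    locus: str
    observed_distinct: int
    observed_n: int
    projections: dict[int, float] = field(default_factory=dict)

    def rounded(self) -> dict[int, int]:
        return {n: int(np.rint(v)) for n, v in self.projections.items()}


def discovery_curve(
    ledger: DiscoveryLedger, bin_size: int, n_reps: int = 30, seed: int | None = None
) -> DiscoveryCurve:
    """Permutation-resampled discovery curve.

    Each replicate randomly permutes the full sample set (without
    replacement), partitions it into floor(total/bin_size) consecutive
    bins and records, per bin, how many distinct allele ids are seen
    there for the first time. The curve is the per-bin mean over
    replicates. Samples beyond the last full bin are discarded, as are
    first occurrences falling there.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    total = ledger.total_samples
    if total < 2 * bin_size:
        raise ValueError("need at least two full bins of samples")
    n_bins = total // bin_size
    rng = np.random.default_rng(seed)

    # group event sample-indices by allele id once
    alleles: dict[str, list[int]] = {}
    for s, a in ledger.events:
        alleles.setdefault(a, []).append(s)
    carriers = [np.asarray(v) for v in alleles.values()]

    counts = np.zeros((n_reps, n_bins))
    for rep in range(n_reps):
        pos = rng.permutation(total)  # pos[i] = shuffled position of sample i
        for samp in carriers:
            b = int(pos[samp].min()) // bin_size
            if b < n_bins:
                counts[rep, b] += 1
    return DiscoveryCurve(
        bin_size=bin_size,
        n_reps=n_reps,
        mean_new=counts.mean(axis=0),
        sd_new=counts.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(n_bins),
        total_samples=total,
    )


def oracle_expected_distinct(
    frequencies: Sequence[float], alleles_per_sample: int, n_samples: int
) -> float:
    """Closed-form expected number of distinct alleles observed after
    ``n_samples`` samples of ``alleles_per_sample`` independent draws:
    sum_j (1 - (1 - p_j)^(m*n))."""
    p = np.asarray(frequencies, dtype=float)
    if np.any(p < 0) or p.sum() > 1 + 1e-9:
        raise ValueError("frequencies must be non-negative with sum <= 1")
    if alleles_per_sample < 1:
        raise ValueError("alleles_per_sample must be >= 1")
    return float(np.sum(1.0 - (1.0 - p) ** (alleles_per_sample * n_samples)))


def _decay(n, a, b, c):
    return c + a * np.exp(-b * n)


def fit_decay(curve: DiscoveryCurve, abscissa: str = "samples") -> DecayModel:
    """Least-squares fit of the 3-parameter decay to the curve.

    Abscissae are bin midpoints, either on the cumulative-sample scale
    (default) or the bin-index scale. Starting values come from the
    curve: a0 = first - last rate, c0 = last rate, b0 from the
    log-ratio of the first two detrended rates. Non-negativity is
    enforced by bounds. A non-decaying curve yields the degenerate
    constant model a=0, c=mean rate, with a warning.
    """
    if curve.n_bins < 4:
        raise ValueError("need at least 4 bins to fit 3 parameters")
    if abscissa == "samples":
        x = (np.arange(curve.n_bins) + 0.5) * curve.bin_size
    elif abscissa == "index":
        x = np.arange(curve.n_bins) + 0.5
    else:
        raise ValueError(f"unknown abscissa {abscissa!r}")
    y = curve.mean_new.astype(float)

    a0 = y[0] - y[-1]
    c0 = max(y[-1], 0.0)
    if a0 <= 0:
        warnings.warn(
            "discovery curve does not decay; returning constant-rate model",
            stacklevel=2,
        )
        return DecayModel(
            a=0.0, b=1.0 / max(x[-1], 1.0), c=float(max(y.mean(), 0.0)),
            bin_size=curve.bin_size, degenerate=True,
        )
    d0, d1 = y[0] - c0, y[1] - c0
    if d0 > 0 and d1 > 0 and d1 < d0:
        b0 = np.log(d0 / d1) / (x[1] - x[0])
    else:
        b0 = 1.0 / (x[-1] - x[0])
    try:
        popt, _ = curve_fit(
            _decay,
            x,
            y,
            p0=(a0, b0, c0),
            bounds=([0.0, 1e-300, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        # near-step curves can defeat the local optimiser; profile b on
        # a log grid, solving (a, c) by non-negative linear LS at each b
        popt = _profile_fit(x, y)
    return DecayModel(
        a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), bin_size=curve.bin_size
    )


def _profile_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    best = None
    for b in np.logspace(np.log10(0.01 / x[-1]), np.log10(50.0 / x[0]), 200):
        basis = np.column_stack([np.exp(-b * x), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        a, c = max(coef[0], 0.0), max(coef[1], 0.0)
        sse = float(((y - _decay(x, a, b, c)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, a, b, c)
    _, a, b, c = best
    return a, b, c


def project(
    model: DecayModel,
    observed_distinct: int,
    observed_n: int,
    targets: Sequence[int],
    locus: str = "",
    method: str = "integral",
) -> ForecastTable:
    """Forecast distinct novel alleles at larger sample counts.

    ``integral`` evaluates observed + (1/bin_size) * int_{n0}^{N} r(n) dn
    in closed form; ``discrete`` sums the fitted rate over whole bins,
    matching a bin-by-bin accumulation (difference is O(bin_size)).
    """
    projections: dict[int, float] = {}
    a, b, c, w = model.a, model.b, model.c, float(model.bin_size)
    for target in targets:
        if target <= observed_n:
            raise ValueError(f"target {target} must exceed observed_n {observed_n}")
        if method == "integral":
            gain = c * (target - observed_n) + (a / b) * (
                np.exp(-b * observed_n) - np.exp(-b * target)
            )
            projections[int(target)] = observed_distinct + gain / w
        elif method == "discrete":
            mids = np.arange(observed_n + w / 2, target, w)
            projections[int(target)] = observed_distinct + float(
                model.rate(mids).sum()
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    return ForecastTable(
        locus=locus,
        observed_distinct=observed_distinct,
        observed_n=observed_n,
        projections=projections,
    )
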