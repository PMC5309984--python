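"""Saturation model of read yield vs input DNA and pooling correction.

Final read count per sample saturates with initial DNA concentration
following a Michaelis-Menten law, R = C/(C + K_m) * R_max. Fitting
(K_m, R_max) to observed (concentration, reads) pairs lets the pooled
volume per sample be scaled inversely to its predicted yield, removing
most of the concentration-driven coverage imbalance without any
post-PCR quantification step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MMModel",
    "PoolingPlan",
    "fit_mm",
    "predict_reads",
    "pooling_volumes",
    "NOT_COMPENSABLE_BELOW",
]

#: Below this concentration (ng/ul) too little PCR product is made for
#: volume scaling to fully compensate the yield deficit.
NOT_COMPENSABLE_BELOW = 5.0


def _mm(c: np.ndarray, km: float, rmax: float) -> np.ndarray:
    return c / (c + km) * rmax


@dataclass(frozen=True)
class MMModel:
    """Fitted saturation model: half-saturation constant ``km``
    (ng/ul), asymptotic read count ``rmax``, and fit diagnostics."""

    km: float
    rmax: float
    residual_sd: float = float("nan")
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (self.km > 0 and self.rmax > 0):
            raise ValueError("K_m and R_max must both be positive")

    def predict(self, conc) -> np.ndarray | float:
        return predict_reads(conc, self)


@dataclass(frozen=True)
class PoolingPlan:
    """Per-sample pooled-volume multipliers, clamped to [1, max_factor].

    ``not_compensable`` flags samples whose input concentration is too
    low for any volume increase to equalise their final read count.
    """

    factors: np.ndarray
    not_compensable: np.ndarray
    reference_conc: float
    max_factor: float


def fit_mm(
    observations: Sequence[tuple[float, float]] | np.ndarray,
    trim_frac: float = 0.005,
    tol: float = 1e-8,
) -> MMModel:
    """Nonlinear least-squares fit of (K_m, R_max) to (C_i, R) pairs.

    Starting values come from the data: R_max0 is the 95th percentile
    of observed reads, K_m0 the concentration at half of R_max0 by
    interpolation of the concentration-sorted yields. After an initial
    fit, the top and bottom ``trim_frac`` of residuals are dropped and
    the model refit once (soft outlier trimming); set ``trim_frac=0``
    to disable.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be (C_i, R) pairs")
    if len(obs) < 10:
        raise ValueError("need at least 10 observations")
    c, r = obs[:, 0], obs[:, 1]
    cspan = c.max() / max(c.min(), np.finfo(float).tiny)
    if np.ptp(c) == 0 or cspan < 4:
        raise ValueError(
            "concentrations must span at least a 4-fold range for the "
            "model to be identifiable"
        )

    rmax0 = float(np.percentile(r, 95))
    if rmax0 <= 0:
        raise ValueError("read counts must contain positive values")
    order = np.argsort(c)
    km0 = float(np.interp(rmax0 / 2.0, np.maximum.accumulate(r[order]), c[order]))
    km0 = max(km0, 1e-6)

    def _fit(cc, rr, p0):
        popt, _ = curve_fit(
            _mm,
            cc,
            rr,
            p0=p0,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=tol,
            maxfev=20000,
        )
        return popt

    popt = _fit(c, r, (km0, rmax0))
    if trim_frac > 0:
        resid = r - _mm(c, *popt)
        lo, hi = np.quantile(resid, [trim_frac, 1 - trim_frac])
        keep = (resid >= lo) & (resid <= hi)
        if keep.sum() >= 10 and np.ptp(c[keep]) > 0:
            popt = _fit(c[keep], r[keep], tuple(popt))
            c, r = c[keep], r[keep]
    resid = r - _mm(c, *popt)
    return MMModel(
        km=float(popt[0]),
        rmax=float(popt[1]),
        residual_sd=float(np.std(resid, ddof=2)) if len(resid) > 2 else float("nan"),
        n_obs=int(len(c)),
    )


def predict_reads(conc, model: MMModel):
    """Expected read count at concentration ``conc`` (ng/ul):
    C/(C + K_m) * R_max. Vectorised over array input."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = _mm(c, model.km, model.rmax)
    return float(out) if np.isscalar(conc) or out.ndim == 0 else out


def pooling_volumes(
    concs: Sequence[float] | np.ndarray,
    model: MMModel,
    max_factor: float = 4.0,
    reference_quantile: float = 0.90,
) -> PoolingPlan:
    """Per-sample pooled-volume multipliers equalising expected reads.

    The reference yield is the prediction at the concentration where
    the saturation curve reaches ``reference_quantile`` of R_max
    (C_ref = K_m * q/(1-q)); each factor is
    clamp(R_ref / predict(C_i), 1, max_factor). The reference choice
    only shifts all factors by a constant before clamping.
    """
    if max_factor < 1:
        raise ValueError("max_factor must be >= 1")
    c = np.asarray(concs, dtype=float)
    q = reference_quantile
    c_ref = model.km * q / (1.0 - q)
    r_ref = predict_reads(c_ref, model)
    with np.errstate(divide="ignore"):
        raw = r_ref / _mm(c, model.km, model.rmax)
    factors = np.clip(raw, 1.0, max_factor)
    factors[~np.isfinite(raw)] = max_factor  # C_i = 0: nothing to pool anyway
    return PoolingPlan(
        factors=factors,
        not_compensable=c < NOT_COMPENSABLE_BELOW,
        reference_conc=float(c_ref),
        max_factor=float(max_factor),
    )
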