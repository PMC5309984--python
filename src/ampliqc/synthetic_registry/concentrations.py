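"""Per-provenance DNA-concentration draws for both swabs.

Extraction yields are modelled log-normally per provenance, calibrated
so the sample median and 5%/95% quantiles approximate the configured
triple. The second swab is drawn jointly with the first on the log
scale at the configured correlation (the first extraction predicts the
second well).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .config import ConcentrationModel

__all__ = ["lognormal_params", "sample_concentrations"]

_Z95 = norm.ppf(0.95)  # 1.6449...


def lognormal_params(model: ConcentrationModel) -> tuple[float, float]:
    """(mu, sigma) of the log-normal calibrated to the model triple.

    mu = log(median) exactly; sigma is the least-squares solution of
    the two quantile equations log(lo) = mu - z*sigma and
    log(hi) = mu + z*sigma (z = Phi^-1(0.95)), i.e.
    sigma = (log(hi) - log(lo)) / (2 z). A printed range that is not
    log-symmetric about the median cannot be matched exactly; the
    residual misfit is split evenly between the two tails.
    """
    mu = float(np.log(model.median))
    sigma = float((np.log(model.hi) - np.log(model.lo)) / (2.0 * _Z95))
    return mu, sigma


def sample_concentrations(
    n: int,
    provenance: str,
    conc_model: ConcentrationModel,
    seed=None,
    swab2_r: float = 0.79,
) -> np.ndarray:
    """Draw ``n`` (conc_swab1, conc_swab2) pairs in ng/ul.

    Both swabs share the provenance's log-normal marginal; their log
    concentrations are jointly Gaussian with correlation ``swab2_r``.
    ``seed`` may be an int or a ``numpy.random.Generator``. Returns an
    (n, 2) array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1 <= swab2_r <= 1:
        raise ValueError("swab2_r must lie in [-1, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mu, sigma = lognormal_params(conc_model)
    z1 = rng.standard_normal(n)
    z2 = swab2_r * z1 + np.sqrt(1.0 - swab2_r**2) * rng.standard_normal(n)
    return np.exp(mu + sigma * np.column_stack([z1, z2]))
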