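"""Configuration schema for the synthetic registry generator."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "ConcentrationModel",
    "PrimerDimerModel",
    "ChimeraModel",
    "DropoutModel",
    "MMTruth",
    "RegistryConfig",
    "DEFAULT_CONC_MODELS",
]


@dataclass(frozen=True)
class ConcentrationModel:
    """Log-normal DNA-yield model for one provenance, parameterised by
    its median and 90% central range (5th/95th percentiles) in ng/ul.

    The log-normal cannot match an asymmetric printed range exactly;
    sigma is the least-squares compromise between the two quantile
    equations (see ``concentrations.lognormal_params``).
    """

    median: float
    lo: float  # 5th percentile
    hi: float  # 95th percentile

    def __post_init__(self) -> None:
        if not (self.lo > 0 and self.median > 0 and self.hi > 0):
            raise ValueError("concentration quantiles must be positive")
        degenerate = self.lo == self.median == self.hi
        if not degenerate and not (self.lo < self.median < self.hi):
            raise ValueError("require lo < median < hi (or all equal)")


#: Published per-provenance buccal-swab yield distributions.
DEFAULT_CONC_MODELS: dict[str, ConcentrationModel] = {
    "DE": ConcentrationModel(median=26.5, lo=4.8, hi=83.7),
    "PL": ConcentrationModel(median=33.5, lo=5.5, hi=101.0),
    "UK": ConcentrationModel(median=18.7, lo=3.9, hi=62.7),
}


@dataclass(frozen=True)
class PrimerDimerModel:
    """Primer-dimer fraction vs input concentration, per workflow.

    Below ``knee`` ng/ul the PD fraction rises linearly with every
    ng/ul less DNA; above it only the baseline remains:
    pd(C) = clip(baseline + slope * max(0, knee - C), 0, 1).
    Default slopes: 3.4%/ng/ul (fluidigm) and 2.7%/ng/ul (plate384).
    """

    baseline: Mapping[str, float] = field(
        default_factory=lambda: {"fluidigm": 0.03, "plate384": 0.009}
    )
    slope: Mapping[str, float] = field(
        default_factory=lambda: {"fluidigm": 0.034, "plate384": 0.027}
    )
    knee: float = 30.0

    def fraction(self, conc: float, workflow: str) -> float:
        pd = self.baseline[workflow] + self.slope[workflow] * max(
            0.0, self.knee - conc
        )
        return float(np.clip(pd, 0.0, 1.0))


@dataclass(frozen=True)
class ChimeraModel:
    """Per-amplicon single-crossover chimera rates among reads of
    heterozygous amplicons; ``default_rate`` applies to amplicons not
    listed. The packaged default calibrates HLA-C exon 3 to its
    observed median of 15.2%."""

    rates: Mapping[str, float] = field(
        default_factory=lambda: {"C_ex3": 0.152}
    )
    default_rate: float = 0.03

    def rate(self, amplicon: str) -> float:
        return float(self.rates.get(amplicon, self.default_rate))


@dataclass(frozen=True)
class DropoutModel:
    """Per-allele dropout probability as a decreasing logistic function
    of concentration: p(C) = p_max * expit((c50 - C)/scale).

    The functional form is a modelling choice (only the direction —
    dropout worsens at low concentration, nanofluidic workflow worst —
    is constrained); parameters are per workflow.
    """

    p_max: Mapping[str, float] = field(
        default_factory=lambda: {"fluidigm": 0.20, "plate384": 0.05}
    )
    c50: Mapping[str, float] = field(
        default_factory=lambda: {"fluidigm": 5.0, "plate384": 2.0}
    )
    scale: Mapping[str, float] = field(
        default_factory=lambda: {"fluidigm": 2.0, "plate384": 1.0}
    )

    def probability(self, conc: float, workflow: str) -> float:
        return float(
            self.p_max[workflow]
            * expit((self.c50[workflow] - conc) / self.scale[workflow])
        )


@dataclass(frozen=True)
class MMTruth:
    """Ground-truth saturation parameters used for yield simulation."""

    km: float = 10.0
    rmax: float = 60000.0

    def __post_init__(self) -> None:
        if not (self.km > 0 and self.rmax > 0):
            raise ValueError("K_m and R_max must be positive")


@dataclass(frozen=True)
class RegistryConfig:
    """Everything needed to generate a synthetic registry."""

    n_donors: int = 100
    provenance_mix: Mapping[str, float] = field(
        default_factory=lambda: {"DE": 0.6, "PL": 0.25, "UK": 0.15}
    )
    conc_models: Mapping[str, ConcentrationModel] = field(
        default_factory=lambda: dict(DEFAULT_CONC_MODELS)
    )
    swab2_correlation: float = 0.79
    reject_below: float = 2.0
    plate384_below: float = 18.0
    pd_model: PrimerDimerModel = field(default_factory=PrimerDimerModel)
    chimera_model: ChimeraModel = field(default_factory=ChimeraModel)
    error_rate: float = 0.001
    dropout_model: DropoutModel = field(default_factory=DropoutModel)
    mm_truth: MMTruth = field(default_factory=MMTruth)
    off_target_rate: float = 0.0
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        mix = self.provenance_mix
        if any(not 0 <= p <= 1 for p in mix.values()) or abs(
            sum(mix.values()) - 1.0
        ) > 1e-9:
            raise ValueError("provenance_mix must be proportions summing to 1")
        for name, rate in (
            ("error_rate", self.error_rate),
            ("off_target_rate", self.off_target_rate),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.reject_below < self.plate384_below:
            raise ValueError("require 0 <= reject_below < plate384_below")
        if not -1 <= self.swab2_correlation <= 1:
            raise ValueError("swab2_correlation must lie in [-1, 1]")
        missing = set(mix) - set(self.conc_models)
        if missing:
            raise ValueError(f"conc_models missing for provenances: {missing}")
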