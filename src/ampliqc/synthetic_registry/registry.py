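"""Whole-registry sampling: donors, genotypes and per-sample reads."""

from __future__ import annotations

from typing import Iterator, Mapping, Optional

import numpy as np

from .._util import child_rng
from ..qc_policy import QCPolicy, route_workflow
from .concentrations import sample_concentrations
from .config import RegistryConfig
from .panel import AllelePanel
from .reads import DonorSample, ReadPair, TruthTables, simulate_reads

__all__ = ["sample_donors", "simulate_registry"]


def sample_donors(
    config: RegistryConfig,
    panels: Mapping[str, AllelePanel],
    seed: Optional[int] = None,
) -> list[DonorSample]:
    """Draw ``config.n_donors`` donors: provenance, both swab
    concentrations, a genotype per locus (two independent draws from
    the panel frequency spectrum) and the workflow routed from the
    first-swab concentration."""
    master = config.seed if seed is None else seed
    rng = child_rng(master, "donors")
    provenances = sorted(config.provenance_mix)
    mix = np.array([config.provenance_mix[p] for p in provenances])
    policy = QCPolicy(
        reject_below=config.reject_below, plate384_below=config.plate384_below
    )
    freq_cache = {
        locus: panels[locus].frequencies() for locus in sorted(panels)
    }

    donors: list[DonorSample] = []
    prov_draws = rng.choice(len(provenances), size=config.n_donors, p=mix)
    for i in range(config.n_donors):
        prov = provenances[prov_draws[i]]
        conc = sample_concentrations(
            1,
            prov,
            config.conc_models[prov],
            seed=rng,
            swab2_r=config.swab2_correlation,
        )[0]
        genotype = {}
        for locus, (names, freqs) in freq_cache.items():
            pair = rng.choice(len(names), size=2, p=freqs)
            genotype[locus] = (names[pair[0]], names[pair[1]])
        donors.append(
            DonorSample(
                sample_id=f"D{i:06d}",
                provenance=prov,
                conc_swab1=float(conc[0]),
                conc_swab2=float(conc[1]),
                genotype=genotype,
                workflow=route_workflow(float(conc[0]), policy),
            )
        )
    return donors


def simulate_registry(
    config: RegistryConfig,
    panels: Mapping[str, AllelePanel],
    seed: Optional[int] = None,
) -> Iterator[tuple[DonorSample, list[ReadPair], Optional[TruthTables]]]:
    """Yield (donor, reads, truth) for every donor; rejected donors
    yield empty read lists and no truth."""
    for donor in sample_donors(config, panels, seed=seed):
        if donor.workflow == "rejected":
            yield donor, [], None
        else:
            reads, truth = simulate_reads(donor, panels, config, seed=seed)
            yield donor, reads, truth
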