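"""Simulator behaviour: yields, artefact fractions, truth bookkeeping."""

import numpy as np
import pytest

from ampliqc.synthetic_registry import (
    DonorSample,
    MMTruth,
    PrimerDimerModel,
    RegistryConfig,
)
from ampliqc.synthetic_registry.reads import simulate_reads

from conftest import make_noise_free_config


def make_sample(panels, conc=40.0, workflow="fluidigm", het=True, locus=None):
    genotype = {}
    for name, panel in panels.items():
        if locus is not None and name != locus:
            continue
        known = panel.known_alleles
        genotype[name] = (known[0], known[1] if het else known[0])
    return DonorSample(
        sample_id="S0",
        provenance="DE",
        conc_swab1=conc,
        conc_swab2=conc,
        genotype=genotype,
        workflow=workflow,
    )


class TestNoiseFree:
    def test_every_read_matches_an_allele_amplicon(self, small_panels):
        config = make_noise_free_config()
        sample = make_sample(small_panels, het=True)
        reads, truth = simulate_reads(sample, small_panels, config)
        expected = {
            panel.amplicon_seq(a, amp)
            for panel in small_panels.values()
            for amp in panel.amplicons
            for a in panel.known_alleles[:2]
        }
        assert reads, "noise-free config must emit reads"
        for pair in reads:
            assert pair.seq1 in expected
        counts = truth.class_counts()
        assert set(counts) == {"on_target"}

    def test_zero_concentration_yields_zero_reads(self, small_panels):
        config = make_noise_free_config()
        sample = make_sample(small_panels, conc=0.0, workflow="plate384")
        reads, truth = simulate_reads(sample, small_panels, config)
        assert reads == [] and truth.reads == []


class TestYield:
    def test_half_saturation_mean(self, small_panels):
        # C = K_m -> mean on-target reads ~ R_max/2; replicate count
        # kept modest via the truth-only fast path
        n_reps = 15
        config = make_noise_free_config(mm_truth=MMTruth(km=10.0, rmax=60_000.0))
        sample = make_sample(small_panels, conc=10.0, workflow="plate384")
        counts = []
        for rep in range(n_reps):
            _, truth = simulate_reads(
                sample, small_panels, config, seed=rep, emit_reads=False
            )
            counts.append(sum(1 for t in truth.reads if t.truth_class == "on_target"))
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(n_reps)
        assert abs(counts.mean() - 30_000) <= 3 * se

    def test_mean_on_target_monotone_in_concentration(self, small_panels):
        config = make_noise_free_config(mm_truth=MMTruth(km=10.0, rmax=5_000.0))
        means = []
        for conc in [2.0, 5.0, 12.0, 30.0, 80.0]:
            reps = []
            for rep in range(20):
                sample = make_sample(small_panels, conc=conc, workflow="plate384")
                _, truth = simulate_reads(
                    sample, small_panels, config, seed=rep, emit_reads=False
                )
                reps.append(len(truth.reads))
            means.append(np.mean(reps))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestPrimerDimers:
    def test_configured_pd_fraction_recovered(self, small_panels):
        # flat PD model at 0.20 above the knee; ~50k reads
        config = make_noise_free_config(
            mm_truth=MMTruth(km=10.0, rmax=48_000.0),
            pd_model=PrimerDimerModel(
                baseline={"fluidigm": 0.20, "plate384": 0.0},
                slope={"fluidigm": 0.0, "plate384": 0.0},
            ),
        )
        sample = make_sample(small_panels, conc=50.0, workflow="fluidigm")
        _, truth = simulate_reads(sample, small_panels, config, emit_reads=False)
        counts = truth.class_counts()
        frac = counts["primer_dimer"] / len(truth.reads)
        assert 0.19 <= frac <= 0.21

    def test_pd_fraction_decreasing_in_concentration_below_knee(self, small_panels):
        config = make_noise_free_config(
            mm_truth=MMTruth(km=10.0, rmax=4_000.0),
            pd_model=PrimerDimerModel(),  # defaults: knee 30, slope 3.4%/ng/ul
        )
        fracs = []
        for conc in [5.0, 10.0, 15.0, 20.0, 25.0]:
            sample = make_sample(small_panels, conc=conc, workflow="fluidigm")
            _, truth = simulate_reads(sample, small_panels, config, emit_reads=False)
            counts = truth.class_counts()
            fracs.append(counts.get("primer_dimer", 0) / len(truth.reads))
        assert all(a > b for a, b in zip(fracs, fracs[1:]))

    def test_q30_strictly_decreases_with_pd_fraction(self, small_panels):
        q30s = []
        for baseline in [0.0, 0.15, 0.35]:
            config = make_noise_free_config(
                mm_truth=MMTruth(km=10.0, rmax=3_000.0),
                pd_model=PrimerDimerModel(
                    baseline={"fluidigm": baseline, "plate384": 0.0},
                    slope={"fluidigm": 0.0, "plate384": 0.0},
                ),
            )
            sample = make_sample(small_panels, conc=60.0, workflow="fluidigm")
            reads, _ = simulate_reads(sample, small_panels, config)
            hits = total = 0
            for pair in reads:
                for qual in (pair.qual1, pair.qual2):
                    q = np.frombuffer(qual.encode(), dtype=np.uint8) - 33
                    hits += int((q >= 30).sum())
                    total += len(q)
            q30s.append(hits / total)
        assert q30s[0] > q30s[1] > q30s[2]


class TestTruthBookkeeping:
    def test_truth_classes_partition_reads(self, small_panels):
        config = RegistryConfig(
            seed=5, mm_truth=MMTruth(km=10, rmax=5_000), off_target_rate=0.01
        )
        sample = make_sample(small_panels, conc=8.0, workflow="plate384")
        reads, truth = simulate_reads(sample, small_panels, config)
        assert len(reads) == len(truth.reads)
        assert {t.read_id for t in truth.reads} == {r.read_id for r in reads}
        assert sum(truth.class_counts().values()) == len(reads)

    def test_chimera_truth_fields(self, small_panels):
        config = make_noise_free_config(mm_truth=MMTruth(km=10, rmax=4_000))
        config = RegistryConfig(
            seed=11,
            error_rate=0.0,
            mm_truth=MMTruth(km=10, rmax=4_000),
        )
        sample = make_sample(small_panels, conc=100.0, workflow="fluidigm")
        _, truth = simulate_reads(sample, small_panels, config, emit_reads=False)
        chims = [t for t in truth.reads if t.truth_class == "chimera"]
        assert chims, "default chimera rates should produce chimeras"
        for t in chims:
            assert t.parent_a != t.parent_b
            assert t.breakpoint is not None and t.breakpoint > 0

    def test_dropout_recorded_and_reads_single_allele(self, small_panels):
        from ampliqc.synthetic_registry import DropoutModel

        config = make_noise_free_config(
            mm_truth=MMTruth(km=10, rmax=1_000),
            dropout_model=DropoutModel(
                p_max={"fluidigm": 1.0, "plate384": 1.0},
                c50={"fluidigm": 1e9, "plate384": 1e9},
                scale={"fluidigm": 1.0, "plate384": 1.0},
            ),
        )
        sample = make_sample(small_panels, conc=40.0, workflow="fluidigm")
        reads, truth = simulate_reads(sample, small_panels, config)
        # p_drop = p_max/ (1+exp(-huge)) -> 1: every allele drops
        assert reads == []
        assert len(truth.dropout_events) == 4  # 2 loci x 2 distinct alleles

    def test_rejected_sample_refused(self, small_panels):
        config = make_noise_free_config()
        sample = make_sample(small_panels, conc=1.0)
        sample = DonorSample(
            sample_id="S1",
            provenance="DE",
            conc_swab1=1.0,
            conc_swab2=1.0,
            genotype=sample.genotype,
            workflow="rejected",
        )
        with pytest.raises(ValueError):
            simulate_reads(sample, small_panels, config)


class TestReproducibility:
    def test_same_seed_byte_identical(self, small_panels):
        config = RegistryConfig(seed=21, mm_truth=MMTruth(km=10, rmax=2_000))
        sample = make_sample(small_panels, conc=25.0, workflow="fluidigm")
        r1, _ = simulate_reads(sample, small_panels, config)
        r2, _ = simulate_reads(sample, small_panels, config)
        assert r1 == r2

    def test_different_seed_differs(self, small_panels):
        config = RegistryConfig(seed=21, mm_truth=MMTruth(km=10, rmax=2_000))
        sample = make_sample(small_panels, conc=25.0, workflow="fluidigm")
        r1, _ = simulate_reads(sample, small_panels, config, seed=1)
        r2, _ = simulate_reads(sample, small_panels, config, seed=2)
        assert r1 != r2
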