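"""Detectors vs independent brute-force oracles, plus classifier
round trips against simulator truth."""

import numpy as np
import pytest

from ampliqc.adapters import ADAPTER_R1, DEFAULT_ADAPTERS
from ampliqc.artefact_detection import (
    classify_pairs,
    detect_chimera,
    detect_primer_dimer,
)
from ampliqc.synthetic_registry import MMTruth, PrimerDimerModel, RegistryConfig
from ampliqc.synthetic_registry.reads import ReadPair, simulate_reads

from conftest import make_noise_free_config
from test_reads import make_sample

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def rand_seq(rng, n) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------- oracles


def oracle_adapter_scan(read, adapters, min_match, max_mismatches):
    """Exhaustive sliding window: score every offset of every adapter."""
    best = None
    for adapter in adapters:
        window = adapter[:min_match]
        for p in range(len(read) - min_match + 1):
            mm = sum(a != b for a, b in zip(read[p : p + min_match], window))
            if mm <= max_mismatches and (best is None or p < best):
                best = p
    return best


def oracle_chimera(read, pa, pb, min_flank, margin):
    """Exhaustive search over all breakpoints and parent orders."""
    L = len(read)
    info = [i for i in range(L) if pa[i] != pb[i]]
    pure = min(
        sum(r != p for r, p in zip(read, pa)),
        sum(r != p for r, p in zip(read, pb)),
    )
    best = None  # (score, k, order)
    for k in range(L + 1):
        left_info = sum(1 for i in info if i < k)
        if left_info < min_flank or len(info) - left_info < min_flank:
            continue
        for order, (l, r) in (("ab", (pa, pb)), ("ba", (pb, pa))):
            s = sum(x != y for x, y in zip(read[:k], l[:k])) + sum(
                x != y for x, y in zip(read[k:], r[k:])
            )
            if best is None or (s, k) < (best[0], best[1]):
                best = (s, k, order)
    if best is not None and best[0] + margin < pure:
        return best[1]
    return None


# ------------------------------------------------------------ primer dimer


class TestDetectPrimerDimer:
    def test_clean_read_absent(self):
        rng = np.random.default_rng(0)
        read = rand_seq(rng, 200)
        # random 200-mers essentially never contain the adapter window
        assert oracle_adapter_scan(read, DEFAULT_ADAPTERS, 12, 1) is None
        assert detect_primer_dimer((read, read)) is None

    def test_constructed_positive_at_position_20(self):
        rng = np.random.default_rng(1)
        read = rand_seq(rng, 20) + ADAPTER_R1 + rand_seq(rng, 100)
        hit = detect_primer_dimer((read, rand_seq(rng, 150)))
        assert hit is not None and hit.position == 20 and hit.mate == 1

    def test_empty_read_absent(self):
        assert detect_primer_dimer(("", "")) is None

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            detect_primer_dimer(("ACGT", "ACGT"), adapter_sequences=[])
        with pytest.raises(ValueError):
            detect_primer_dimer(("ACGT", "ACGT"), min_match=4)

    def test_matches_oracle_with_mismatches(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            read = list(rand_seq(rng, 80))
            if rng.random() < 0.6:
                pos = int(rng.integers(0, 60))
                ad = list(ADAPTER_R1[:20])
                for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
                    i = int(rng.integers(0, len(ad)))
                    ad[i] = "ACGT"[int(rng.integers(0, 4))]
                read[pos : pos + 20] = ad
            read = "".join(read[:80])
            expected = oracle_adapter_scan(read, DEFAULT_ADAPTERS, 12, 1)
            got = detect_primer_dimer((read, ""), DEFAULT_ADAPTERS, 12, 1)
            assert (got.position if got else None) == expected


# ----------------------------------------------------------------- chimera


class TestDetectChimera:
    def test_pure_parent_absent(self):
        rng = np.random.default_rng(4)
        pa = rand_seq(rng, 60)
        pb = "".join(
            c if rng.random() > 0.3 else "ACGT"[int(rng.integers(0, 4))] for c in pa
        )
        assert detect_chimera(pa, pa, pb, min_flank=2, margin=1) is None

    def test_forced_breakpoint(self):
        call = detect_chimera(
            "AAAACCCC", "AAAAAAAA", "CCCCCCCC", min_flank=2, margin=1
        )
        assert call is not None and call.breakpoint == 4 and call.order == "ab"

    def test_swapped_parents_mirror(self):
        call = detect_chimera(
            "AAAACCCC", "CCCCCCCC", "AAAAAAAA", min_flank=2, margin=1
        )
        assert call is not None and call.breakpoint == 4 and call.order == "ba"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_chimera("AAA", "AAAA", "AAAA")

    def test_equivalent_to_bruteforce_on_random_triples(self):
        # 1,000 random (parents, read) triples, exhaustive oracle
        rng = np.random.default_rng(5)
        L = 40
        for trial in range(1_000):
            pa = rand_seq(rng, L)
            pb = "".join(
                c if rng.random() > 0.4 else "ACGT"[int(rng.integers(0, 4))]
                for c in pa
            )
            kind = trial % 3
            if kind == 0:  # true chimera + noise
                k = int(rng.integers(1, L))
                read = list(pa[:k] + pb[k:])
            elif kind == 1:  # pure parent + noise
                read = list(pa)
            else:  # unrelated
                read = list(rand_seq(rng, L))
            for _ in range(int(rng.integers(0, 3))):
                read[int(rng.integers(0, L))] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            min_flank, margin = 3, 2
            expected = oracle_chimera(read, pa, pb, min_flank, margin)
            got = detect_chimera(read, pa, pb, min_flank=min_flank, margin=margin)
            assert (got.breakpoint if got else None) == expected


# ------------------------------------------------------------ classify run


class TestClassifyPairs:
    def test_noise_free_homozygous_all_on_target(self, small_panels):
        config = make_noise_free_config()
        sample = make_sample(small_panels, het=False)
        reads, _ = simulate_reads(sample, small_panels, config)
        table, metrics = classify_pairs(reads, small_panels)
        assert metrics.on_target_rate == 1.0
        assert metrics.chimera_rate == 0.0
        assert metrics.pd_rate == 0.0

    def test_pd_rate_round_trip(self, small_panels):
        # configured truth PD fraction 0.20, ~50k reads
        config = make_noise_free_config(
            mm_truth=MMTruth(km=10.0, rmax=40_000.0),
            pd_model=PrimerDimerModel(
                baseline={"fluidigm": 0.20, "plate384": 0.0},
                slope={"fluidigm": 0.0, "plate384": 0.0},
            ),
            error_rate=0.001,
        )
        sample = make_sample(small_panels, conc=50.0, workflow="fluidigm")
        reads, truth = simulate_reads(sample, small_panels, config)
        _, metrics = classify_pairs(reads, small_panels)
        true_frac = truth.class_counts()["primer_dimer"] / len(reads)
        assert metrics.pd_rate == pytest.approx(true_frac, abs=0.02)
        assert metrics.pd_rate == pytest.approx(0.20, abs=0.02)

    def test_rates_partition(self, small_panels):
        config = RegistryConfig(
            seed=9, mm_truth=MMTruth(km=10, rmax=5_000), off_target_rate=0.01
        )
        sample = make_sample(small_panels, conc=12.0, workflow="plate384")
        reads, _ = simulate_reads(sample, small_panels, config)
        table, metrics = classify_pairs(reads, small_panels)
        total = (
            metrics.pd_rate
            + metrics.on_target_rate
            + metrics.off_target_rate
            + metrics.chimera_rate
        )
        assert total == pytest.approx(1.0, abs=1e-9)
        assert len(table) == len(reads)

    def test_order_invariance(self, small_panels):
        config = RegistryConfig(seed=13, mm_truth=MMTruth(km=10, rmax=2_000))
        sample = make_sample(small_panels, conc=30.0, workflow="fluidigm")
        reads, _ = simulate_reads(sample, small_panels, config)
        t1, m1 = classify_pairs(reads, small_panels)
        t2, m2 = classify_pairs(list(reversed(reads)), small_panels)
        assert t1 == t2 and m1 == m2

    def test_outnumbered_parents_suppress_chimera_calls(self, small_panels):
        # 2 parents with 2 reads each vs 6 distinct-breakpoint
        # chimeras -> with parent_ratio=1 the parents are outnumbered
        # and all calls must be dropped (reads stay on_target)
        panel = small_panels["A"]
        amp = sorted(panel.amplicons)[0]
        a0, a1 = panel.known_alleles[:2]
        pa, pb = panel.amplicon_seq(a0, amp), panel.amplicon_seq(a1, amp)
        diffs = [i for i, (x, y) in enumerate(zip(pa, pb)) if x != y]
        breakpoints = diffs[5:35:5]  # distinct interior breakpoints
        assert len(breakpoints) == 6
        chims = [pa[:k] + pb[k:] for k in breakpoints]
        qual = "I" * len(pa)
        pairs = [
            ReadPair(f"S:{i:06d}", seq, qual, seq, qual)
            for i, seq in enumerate([pa, pa, pb, pb] + chims)
        ]
        _, metrics = classify_pairs(pairs, small_panels, parent_ratio=1.0)
        assert metrics.chimera_rate == 0.0  # left on_target
        _, metrics2 = classify_pairs(pairs, small_panels, parent_ratio=0.3)
        assert metrics2.chimera_rate > 0.0

    def test_q30_decreases_with_pd_rate(self, small_panels):
        q30, pd = [], []
        for baseline in [0.05, 0.25, 0.5]:
            config = make_noise_free_config(
                mm_truth=MMTruth(km=10.0, rmax=3_000.0),
                pd_model=PrimerDimerModel(
                    baseline={"fluidigm": baseline, "plate384": 0.0},
                    slope={"fluidigm": 0.0, "plate384": 0.0},
                ),
            )
            sample = make_sample(small_panels, conc=60.0, workflow="fluidigm")
            reads, _ = simulate_reads(sample, small_panels, config)
            _, metrics = classify_pairs(reads, small_panels)
            q30.append(metrics.pct_q30)
            pd.append(metrics.pd_rate)
        assert pd[0] < pd[1] < pd[2]
        assert q30[0] > q30[1] > q30[2]

    def test_hla_c_exon3_chimera_calibration_recovered(self, small_panels):
        # default per-amplicon calibration: C exon-3 chimera rate 0.152;
        # reported per-amplicon rate must land within +-3 percentage
        # points of the configured truth
        config = make_noise_free_config(
            mm_truth=MMTruth(km=10.0, rmax=20_000.0),
            chimera_model=RegistryConfig().chimera_model,  # packaged default
            error_rate=0.001,
        )
        assert config.chimera_model.rate("C_ex3") == 0.152
        sample = make_sample(small_panels, conc=80.0, workflow="fluidigm", locus="C")
        reads, truth = simulate_reads(sample, small_panels, config)
        _, metrics = classify_pairs(reads, small_panels)
        reported = metrics.chimera_rate_per_amplicon["C_ex3"]
        assert reported == pytest.approx(0.152, abs=0.03)
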