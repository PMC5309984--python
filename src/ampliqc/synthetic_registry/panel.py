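"""Synthetic allele panels: reference sequences, hidden novel alleles
and a long-tailed population frequency spectrum.

No real immunogenetics reference sequences are shipped; every panel is
generated from a seed. All alleles of a locus share a common frame
(equal length, identical amplicon coordinates), so amplicon sequences
can be compared positionally without alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .._util import child_rng

__all__ = ["AlleleEntry", "AllelePanel", "FrequencySpec", "build_allele_panel"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleEntry:
    sequence: str
    frequency: float
    known: bool


@dataclass(frozen=True)
class AllelePanel:
    """Per-locus allele reference: name -> (sequence, frequency, known
    flag) plus shared 0-based half-open amplicon spans."""

    locus: str
    entries: Mapping[str, AlleleEntry]
    amplicons: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("panel must contain at least one allele")
        total = sum(e.frequency for e in self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1, got {total}")
        for name, e in self.entries.items():
            if not e.sequence:
                raise ValueError(f"allele {name} has an empty sequence")
            for amp, (s, t) in self.amplicons.items():
                if not (0 <= s < t <= len(e.sequence)):
                    raise ValueError(
                        f"amplicon {amp} span ({s}, {t}) outside sequence "
                        f"bounds of allele {name}"
                    )

    @property
    def known_alleles(self) -> tuple[str, ...]:
        return tuple(n for n, e in self.entries.items() if e.known)

    @property
    def novel_alleles(self) -> tuple[str, ...]:
        return tuple(n for n, e in self.entries.items() if not e.known)

    def amplicon_seq(self, allele: str, amplicon: str) -> str:
        s, t = self.amplicons[amplicon]
        return self.entries[allele].sequence[s:t]

    def frequencies(self) -> tuple[tuple[str, ...], np.ndarray]:
        names = tuple(self.entries)
        return names, np.array([self.entries[n].frequency for n in names])


@dataclass(frozen=True)
class FrequencySpec:
    """Named frequency law for the allele spectrum.

    ``power_law``: frequency of the rank-j allele proportional to
    j**(-exponent), optionally jittered by a Dirichlet draw with
    concentration ``dirichlet_alpha`` (0 disables) and re-sorted so
    rank-frequency stays monotone. ``uniform``: equal frequencies.
    """

    law: str = "power_law"
    exponent: float = 1.5
    dirichlet_alpha: float = 0.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.law == "uniform":
            return np.full(n, 1.0 / n)
        if self.law != "power_law":
            raise ValueError(f"unknown frequency law {self.law!r}")
        freqs = np.arange(1, n + 1, dtype=float) ** (-self.exponent)
        freqs /= freqs.sum()
        if self.dirichlet_alpha > 0:
            freqs = rng.dirichlet(freqs * self.dirichlet_alpha)
            freqs = np.sort(freqs)[::-1]
        return freqs


def _default_spans(
    locus: str, seq_length: int, amplicon_length: int
) -> dict[str, tuple[int, int]]:
    if seq_length < 2 * amplicon_length + 80:
        raise ValueError(
            f"seq_length {seq_length} too short for two {amplicon_length} nt "
            "amplicons with 40 nt flanks"
        )
    return {
        f"{locus}_ex2": (40, 40 + amplicon_length),
        f"{locus}_ex3": (seq_length - 40 - amplicon_length, seq_length - 40),
    }


def build_allele_panel(
    locus: str,
    n_known: int,
    n_novel: int = 0,
    freq_spec: FrequencySpec = FrequencySpec(),
    seq_length: int = 730,
    seed: int = 0,
    amplicon_length: int = 250,
    n_polymorphic: int = 48,
) -> AllelePanel:
    """Generate a frame-aligned allele panel for one locus.

    The most frequent ``n_known`` alleles are flagged known (the
    reference database); ``n_novel`` rarer alleles are flagged as
    hidden novel sequences awaiting discovery. Each amplicon span
    carries ``n_polymorphic`` shared polymorphic columns at which every
    allele draws an independent uniform base — mimicking the dense
    polymorphism of the target exons — plus a base-4 encoding of the
    allele index at dedicated tag positions, which guarantees that
    every pair of alleles differs by at least one substitution inside
    *each* amplicon span.
    """
    if n_known < 2:
        raise ValueError("n_known must be >= 2")
    if n_novel < 0:
        raise ValueError("n_novel must be >= 0")
    n_total = n_known + n_novel
    rng = child_rng(seed, "panel", locus)
    spans = _default_spans(locus, seq_length, amplicon_length)

    width = int(np.ceil(np.log(n_total) / np.log(4))) if n_total > 1 else 1
    if width + n_polymorphic > amplicon_length - 10:
        raise ValueError(
            "seq_length/amplicon too short to host the requested diversity"
        )

    backbone = rng.choice(_BASES, size=seq_length)
    # positions reserved for the pairwise-distinctness encoding
    tag_pos = {amp: np.arange(s + 5, s + 5 + width) for amp, (s, _) in spans.items()}
    reserved = set(int(p) for pos in tag_pos.values() for p in pos)
    # shared polymorphic columns per span
    poly_pos: dict[str, np.ndarray] = {}
    for amp, (s, t) in spans.items():
        free = np.array([p for p in range(s + 10, t - 10) if p not in reserved])
        poly_pos[amp] = np.sort(rng.choice(free, size=n_polymorphic, replace=False))

    freqs = freq_spec.draw(n_total, rng)
    entries: dict[str, AlleleEntry] = {}
    for j in range(n_total):
        seq = backbone.copy()
        digits = [(j >> (2 * k)) & 3 for k in range(width)]
        for pos in tag_pos.values():
            seq[pos] = _BASES[digits]
        for pos in poly_pos.values():
            seq[pos] = rng.choice(_BASES, size=len(pos))
        known = j < n_known
        name = f"{locus}*{j + 1:03d}" if known else f"{locus}*nov{j - n_known + 1:03d}"
        entries[name] = AlleleEntry(
            sequence=seq.tobytes().decode(), frequency=float(freqs[j]), known=known
        )
    # exact renormalisation against float drift
    total = sum(e.frequency for e in entries.values())
    entries = {
        n: AlleleEntry(e.sequence, e.frequency / total, e.known)
        for n, e in entries.items()
    }
    return AllelePanel(locus=locus, entries=entries, amplicons=spans)
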