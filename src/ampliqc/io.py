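"""File interchange: FASTQ pairs, panel FASTA + span TSV, sample
sheets, truth tables, class tables and discovery ledgers.

FASTQ and FASTA go through Biopython; tabular files are plain
tab-separated text with a header row (schemas documented per writer).
Gzip output is chosen by the ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery_forecast import DiscoveryLedger
from .synthetic_registry.panel import AlleleEntry, AllelePanel
from .synthetic_registry.reads import DonorSample, ReadPair, TruthTables

__all__ = [
    "write_fastq_pair",
    "read_fastq_pairs",
    "write_panel",
    "read_panel",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth_table",
    "write_class_table",
    "write_ledger",
    "read_ledger",
]


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pair(reads: Iterable[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq`` (Sanger
    Phred+33). Returns the two paths."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with _open_text(p1, "w") as f1, _open_text(p2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.read_id}\n{r.seq2}\n+\n{r.qual2}\n")
    return p1, p2


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate synchronised read pairs from two FASTQ files."""

    def _records(path):
        with _open_text(Path(path), "r") as handle:
            yield from SeqIO.parse(handle, "fastq")

    for i, (rec1, rec2) in enumerate(zip(_records(r1_path), _records(r2_path))):
        if rec1.id != rec2.id:
            raise ValueError(
                f"record {i}: mate ids disagree ({rec1.id!r} vs {rec2.id!r})"
            )
        yield ReadPair(
            read_id=rec1.id,
            seq1=str(rec1.seq),
            qual1="".join(
                chr(q + 33) for q in rec1.letter_annotations["phred_quality"]
            ),
            seq2=str(rec2.seq),
            qual2="".join(
                chr(q + 33) for q in rec2.letter_annotations["phred_quality"]
            ),
        )


def write_panel(
    panels: Mapping[str, AllelePanel], fasta_path, spans_path
) -> None:
    """Panel FASTA with ``locus|allele|freq|known`` headers plus a TSV
    span table (columns: locus, amplicon, start, end; 0-based
    half-open)."""
    records = []
    rows = []
    for locus in sorted(panels):
        panel = panels[locus]
        for name, e in panel.entries.items():
            rid = f"{locus}|{name}|{e.frequency:.10g}|{int(e.known)}"
            records.append(SeqRecord(Seq(e.sequence), id=rid, description=""))
        for amp, (s, t) in sorted(panel.amplicons.items()):
            rows.append({"locus": locus, "amplicon": amp, "start": s, "end": t})
    with _open_text(Path(fasta_path), "w") as handle:
        SeqIO.write(records, handle, "fasta")
    pd.DataFrame(rows).to_csv(spans_path, sep="\t", index=False)


def read_panel(fasta_path, spans_path) -> dict[str, AllelePanel]:
    spans = pd.read_csv(spans_path, sep="\t")
    amp_by_locus: dict[str, dict[str, tuple[int, int]]] = {}
    for row in spans.itertuples():
        amp_by_locus.setdefault(row.locus, {})[row.amplicon] = (
            int(row.start),
            int(row.end),
        )
    entries: dict[str, dict[str, AlleleEntry]] = {}
    with _open_text(Path(fasta_path), "r") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            locus, name, freq, known = rec.id.split("|")
            entries.setdefault(locus, {})[name] = AlleleEntry(
                sequence=str(rec.seq), frequency=float(freq), known=bool(int(known))
            )
    return {
        locus: AllelePanel(
            locus=locus, entries=entries[locus], amplicons=amp_by_locus[locus]
        )
        for locus in sorted(entries)
    }


_SHEET_COLS = [
    "sample_id",
    "provenance",
    "conc_swab1",
    "conc_swab2",
    "workflow",
]


def write_sample_sheet(donors: Iterable[DonorSample], path) -> None:
    """Sample sheet TSV: sample_id, provenance, conc_swab1, conc_swab2,
    workflow, then one ``genotype_<locus>`` column per locus holding
    ``allele1/allele2``."""
    rows = []
    for d in donors:
        row = {
            "sample_id": d.sample_id,
            "provenance": d.provenance,
            "conc_swab1": d.conc_swab1,
            "conc_swab2": d.conc_swab2,
            "workflow": d.workflow,
        }
        for locus in sorted(d.genotype):
            row[f"genotype_{locus}"] = "/".join(d.genotype[locus])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[DonorSample]:
    df = pd.read_csv(path, sep="\t")
    loci = [c[len("genotype_") :] for c in df.columns if c.startswith("genotype_")]
    donors = []
    for row in df.itertuples():
        genotype = {
            locus: tuple(getattr(row, f"genotype_{locus}").split("/"))
            for locus in loci
        }
        donors.append(
            DonorSample(
                sample_id=row.sample_id,
                provenance=row.provenance,
                conc_swab1=float(row.conc_swab1),
                conc_swab2=float(row.conc_swab2),
                genotype=genotype,
                workflow=row.workflow,
            )
        )
    return donors


def write_truth_table(truths: Iterable[TruthTables], path) -> None:
    """Per-read truth TSV: sample_id, read_id, truth_class, amplicon,
    allele, parent_a, parent_b, breakpoint."""
    rows = []
    for t in truths:
        for r in t.reads:
            rows.append(
                {
                    "sample_id": t.sample_id,
                    "read_id": r.read_id,
                    "truth_class": r.truth_class,
                    "amplicon": r.amplicon or "",
                    "allele": r.allele or "",
                    "parent_a": r.parent_a or "",
                    "parent_b": r.parent_b or "",
                    "breakpoint": "" if r.breakpoint is None else r.breakpoint,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_class_table(table, path) -> None:
    """Per-read classification TSV: read_id, label, amplicon, parent_a,
    parent_b, breakpoint, mismatch_score."""
    rows = [
        {
            "read_id": rc.read_id,
            "label": rc.label,
            "amplicon": rc.amplicon or "",
            "parent_a": rc.parents[0] if rc.parents else "",
            "parent_b": rc.parents[1] if rc.parents else "",
            "breakpoint": "" if rc.breakpoint is None else rc.breakpoint,
            "mismatch_score": rc.mismatch_score,
        }
        for rc in table
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ledger(ledger: DiscoveryLedger, path) -> None:
    """Discovery ledger TSV: locus, sample_index, allele_id; the total
    sample count is recorded in a ``#total_samples=`` header line."""
    with _open_text(Path(path), "w") as f:
        f.write(f"#total_samples={ledger.total_samples}\n")
        f.write("locus\tsample_index\tallele_id\n")
        for s, a in ledger.events:
            f.write(f"{ledger.locus}\t{s}\t{a}\n")


def read_ledger(path) -> DiscoveryLedger:
    total = None
    events: list[tuple[int, str]] = []
    locus = ""
    with _open_text(Path(path), "r") as f:
        for line in f:
            line = line.rstrip("\n")
            if line.startswith("#total_samples="):
                total = int(line.split("=", 1)[1])
                continue
            if not line or line.startswith("locus\t"):
                continue
            locus, idx, allele = line.split("\t")
            events.append((int(idx), allele))
    if total is None:
        total = events[-1][0] + 1 if events else 0
    return DiscoveryLedger(locus=locus, events=tuple(events), total_samples=total)
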