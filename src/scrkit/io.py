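"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython; tables are tab-delimited with a header
row and '#' comments; intervals are emitted BED-like (0-based half-open).
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import pandas as pd

from .errors import ParseError
from .ribo import FootprintRead
from .topology import StopTopology, TranscriptRecord


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Read a multi-record FASTA as (id, description, sequence) tuples.

    Multi-line records and CRLF endings are fine; an empty sequence or a
    duplicate id raises :class:`ParseError`.
    """
    records = []
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if not str(rec.seq):
                raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, rec.description, str(rec.seq)))
    if not records:
        # distinguish empty file from a truncated header-only record
        with _open_text(path) as fh:
            for line in fh:
                if line.strip():
                    raise ParseError(f"{path}: no parseable FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, wrap: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA with fixed-width line wrapping."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def read_fastq(path) -> Iterator[FootprintRead]:
    """Stream 4-line FASTQ records (plain or gzip) as :class:`FootprintRead`.

    Record-level validation (sequence/quality length mismatch, truncated
    final record) raises :class:`ParseError` carrying the record index.
    """
    with _open_text(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\r\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise ParseError(f"{path}: record {idx}: header does not start with '@'")
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not qual and not plus:
                raise ParseError(f"{path}: record {idx}: truncated record")
            if not plus.startswith("+"):
                raise ParseError(f"{path}: record {idx}: missing '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {idx}: sequence/quality length mismatch"
                )
            yield FootprintRead(header[1:].split()[0], seq, qual)
            idx += 1


def write_fastq(reads: Iterable[FootprintRead], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_cds_table(path) -> dict[str, tuple[int, int]]:
    """TSV sidecar with columns id, cds_start, cds_end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "cds_start", "cds_end"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: CDS table needs columns {sorted(required)}")
    return {
        str(row.id): (int(row.cds_start), int(row.cds_end)) for row in df.itertuples()
    }


def load_transcripts(fasta_path, cds_path) -> list[TranscriptRecord]:
    """Join a FASTA with its CDS coordinate sidecar into transcript records."""
    cds = read_cds_table(cds_path)
    out = []
    for rec_id, _, seq in read_fasta(fasta_path):
        if rec_id not in cds:
            raise ParseError(f"transcript {rec_id!r} missing from CDS table")
        start, end = cds[rec_id]
        out.append(TranscriptRecord(rec_id, seq, start, end))
    return out


def topology_table(entries: list[tuple[str, StopTopology]]) -> pd.DataFrame:
    """Tabular topology report (one row per transcript)."""
    rows = [
        {
            "id": tid,
            "stop1": t.stop1,
            "isr1_len": t.isr1_len,
            "stop2": t.stop2,
            "isr2_len": t.isr2_len,
            "stop3": t.stop3,
        }
        for tid, t in entries
    ]
    return pd.DataFrame(rows, columns=["id", "stop1", "isr1_len", "stop2", "isr2_len", "stop3"])


def topology_bed(tid: str, topology: StopTopology) -> pd.DataFrame:
    """BED-like intervals (0-based half-open) for ISR1/ISR2/distal UTR."""
    rows = [
        (tid, *topology.isr1, "ISR1"),
        (tid, *topology.stop2_interval, "stop2"),
        (tid, *topology.isr2, "ISR2"),
        (tid, *topology.stop3_interval, "stop3"),
        (tid, *topology.distal_utr, "distal_UTR"),
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
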