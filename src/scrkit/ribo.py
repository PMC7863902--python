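"""Ribosome-profiling read-through caller.

The positivity statistic: a dataset supports stop-codon read-through of a
transcript when ribosome footprints cover at least half of the inter-stop
regions (ISR1 and ISR2) *and* footprint density drops at least 4-fold after
the last in-frame stop (distal 3'UTR vs the ISRs). The distal UTR serves as
the background-read control.

Processing is deliberately desk-scale: 3' adapters are removed by exact
prefix-suffix matching, and reads of at least 24 nt are mapped by exact
substring search against the single transcript (equivalent to keeping
perfect matches from a transcriptome aligner when only one locus is
analyzed). Reads matching at two or more positions are discarded as
ambiguous. Footprint span coverage is used directly; no P-site offsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULTS, RunConfig
from .topology import StopTopology, TranscriptRecord


@dataclass(frozen=True)
class FootprintRead:
    """A (possibly adapter-containing) sequencing read; quality is carried, not used."""

    id: str
    seq: str
    qual: str = ""

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"{self.id}: empty read")
        if self.qual and len(self.qual) != len(self.seq):
            raise ValueError(f"{self.id}: quality/sequence length mismatch")


@dataclass
class RegionStats:
    coverage_fraction: float
    density: float  # overlapping footprints per nt of region
    n_overlapping: int
    length: int
    degenerate: bool = False  # zero-length region reported by convention


@dataclass
class FootprintProfile:
    transcript_id: str
    per_position_cover: np.ndarray
    n_mapped: int
    n_discarded_short: int
    n_discarded_ambiguous: int
    n_unmapped: int
    region_stats: dict[str, RegionStats] = field(default_factory=dict)


@dataclass(frozen=True)
class ReadthroughCall:
    """Positive/negative read-through call with the thresholds applied."""

    isr_coverage: float  # combined ISR1+stop2+ISR2 region
    isr1_coverage: float
    isr2_coverage: float
    isr_density: float
    utr_density: float
    fold_drop: float  # may be inf
    positive: bool
    thresholds_used: dict


def trim_adapter(
    read: FootprintRead,
    adapter3: str = DEFAULTS.ribo_adapter3,
    min_overlap: int = DEFAULTS.ribo_min_overlap,
) -> FootprintRead:
    """Remove a 3' adapter by exact prefix-suffix matching.

    The read is truncated at the leftmost position where either the full
    adapter occurs, or a prefix of the adapter of length >= ``min_overlap``
    runs to the end of the read. Returns the read unchanged when no match.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    seq = read.seq
    n, m = len(seq), len(adapter3)
    for i in range(n):
        tail_len = n - i
        if tail_len >= m:
            if seq.startswith(adapter3, i):
                return FootprintRead(read.id, seq[:i], read.qual[:i]) if i else _empty_ok(read)
        elif tail_len >= min_overlap and adapter3.startswith(seq[i:]):
            return FootprintRead(read.id, seq[:i], read.qual[:i])
    return read


def _empty_ok(read: FootprintRead) -> FootprintRead:
    # Adapter at position 0: the insert is empty. Keep a placeholder read of
    # length 0 via a sentinel that downstream counts as too short.
    return FootprintRead(read.id, "N", "!" if read.qual else "")


def map_exact(read_seq: str, transcript_seq: str, min_len: int = DEFAULTS.ribo_min_len) -> list[int]:
    """All exact-substring start positions of a read in the transcript.

    Returns an empty list for reads shorter than ``min_len``; the caller is
    responsible for bookkeeping them as discarded-short.
    """
    if len(read_seq) < min_len:
        return []
    positions = []
    start = transcript_seq.find(read_seq)
    while start != -1:
        positions.append(start)
        start = transcript_seq.find(read_seq, start + 1)
    return positions


def build_profile(
    mapped: list[tuple[int, int]],
    topology: StopTopology,
    transcript_len: int,
    transcript_id: str = "",
    cds_start: int = 0,
    counts: tuple[int, int, int, int] = (0, 0, 0, 0),
) -> FootprintProfile:
    """Per-position coverage and per-region summaries from mapped footprints.

    ``mapped`` holds (start, length) pairs. For each region,
    ``coverage_fraction`` is the fraction of region positions covered by at
    least one footprint and ``density`` is the number of footprints
    overlapping the region by >= 1 nt divided by the region length.
    """
    cover = np.zeros(transcript_len, dtype=np.int64)
    for pos, length in mapped:
        cover[pos : pos + length] += 1

    regions = {
        "cds": (cds_start, topology.cds_end),
        "isr1": topology.isr1,
        "stop2": topology.stop2_interval,
        "isr2": topology.isr2,
        "isr_combined": topology.isr_combined,
        "distal_utr": topology.distal_utr,
    }
    n_mapped, n_short, n_ambig, n_unmapped = counts
    profile = FootprintProfile(
        transcript_id=transcript_id,
        per_position_cover=cover,
        n_mapped=n_mapped or len(mapped),
        n_discarded_short=n_short,
        n_discarded_ambiguous=n_ambig,
        n_unmapped=n_unmapped,
    )
    for name, (lo, hi) in regions.items():
        length = hi - lo
        if length <= 0:
            profile.region_stats[name] = RegionStats(1.0, 0.0, 0, 0, degenerate=True)
            continue
        covered = int(np.count_nonzero(cover[lo:hi]))
        n_overlap = sum(1 for pos, ln in mapped if pos < hi and pos + ln > lo)
        profile.region_stats[name] = RegionStats(
            coverage_fraction=covered / length,
            density=n_overlap / length,
            n_overlapping=n_overlap,
            length=length,
        )
    return profile


def call_readthrough(
    profile: FootprintProfile,
    min_cov: float = DEFAULTS.ribo_min_cov,
    min_fold: float = DEFAULTS.ribo_min_fold,
) -> ReadthroughCall:
    """Apply the coverage / fold-drop positivity rule to a profile.

    Positive requires BOTH ISR1 and ISR2 coverage >= ``min_cov`` and
    ``isr_density / utr_density >= min_fold``, where ISR density is computed
    over the combined ISR1+stop2+ISR2 region and UTR density over the distal
    3'UTR. A zero UTR density with nonzero ISR density gives an infinite
    fold drop; zero ISR density is negative with fold drop 0.
    """
    rs = profile.region_stats
    isr = rs["isr_combined"]
    utr = rs["distal_utr"]
    if isr.density == 0:
        fold = 0.0
    elif utr.density == 0:
        fold = float("inf")
    else:
        fold = isr.density / utr.density
    cov1 = rs["isr1"].coverage_fraction
    cov2 = rs["isr2"].coverage_fraction
    positive = cov1 >= min_cov and cov2 >= min_cov and fold >= min_fold
    return ReadthroughCall(
        isr_coverage=isr.coverage_fraction,
        isr1_coverage=cov1,
        isr2_coverage=cov2,
        isr_density=isr.density,
        utr_density=utr.density,
        fold_drop=fold,
        positive=positive,
        thresholds_used={"min_cov": min_cov, "min_fold": min_fold},
    )


def process_reads(
    reads,
    transcript: TranscriptRecord,
    topology: StopTopology,
    config: RunConfig = DEFAULTS,
) -> tuple[ReadthroughCall, FootprintProfile]:
    """Trim, map, profile and call an iterable of :class:`FootprintRead`."""
    mapped: list[tuple[int, int]] = []
    n_short = n_ambig = n_unmapped = 0
    tseq = transcript.sequence
    for read in reads:
        trimmed = trim_adapter(read, config.ribo_adapter3, config.ribo_min_overlap)
        if len(trimmed.seq) < config.ribo_min_len:
            n_short += 1
            continue
        positions = map_exact(trimmed.seq, tseq, config.ribo_min_len)
        if not positions:
            n_unmapped += 1
        elif len(positions) > 1:
            n_ambig += 1
        else:
            mapped.append((positions[0], len(trimmed.seq)))
    profile = build_profile(
        mapped,
        topology,
        len(tseq),
        transcript_id=transcript.id,
        cds_start=transcript.cds_start,
        counts=(len(mapped), n_short, n_ambig, n_unmapped),
    )
    call = call_readthrough(profile, config.ribo_min_cov, config.ribo_min_fold)
    return call, profile


def run_dataset(
    fastq_path,
    transcript: TranscriptRecord,
    topology: StopTopology,
    config: RunConfig = DEFAULTS,
) -> tuple[ReadthroughCall, FootprintProfile]:
    """End-to-end: FASTQ -> trim -> exact map -> profile -> call."""
    from .io import read_fastq

    return process_reads(read_fastq(fastq_path), transcript, topology, config)
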