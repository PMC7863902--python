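"""Stop-codon topology of a transcript and read-through isoform derivation.

A transcript whose 3'UTR carries in-frame stop codons downstream of the
canonical stop can, under programmed stop-codon read-through (SCR), produce
C-terminally extended protein isoforms. With two downstream in-frame stops
the mRNA encodes three proteins: the canonical isoform (termination at
stop 1), a single-read-through isoform ``x`` (termination at stop 2, adding
one recoded residue plus the peptide encoded by the first inter-stop region,
ISR1), and a double-read-through isoform ``xx`` (termination at stop 3,
additionally adding a second recoded residue plus the ISR2 peptide).

Coordinates are 0-based half-open in transcript space, and the CDS interval
*includes* the canonical stop codon (GenBank convention), so ISR1 starts
exactly at ``cds_end``. Downstream stop offsets are measured from the end of
the canonical stop codon to the start of the downstream stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from Bio.Seq import Seq

from .errors import (
    AmbiguousSequenceError,
    FrameError,
    MalformedSequenceError,
    TopologyIncompleteError,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_IUPAC = set("ACGTURYSWKMBDHVN")
_ACGT = set("ACGT")


class NormalizedSeq(NamedTuple):
    """A normalized nucleotide string plus an ambiguity flag."""

    sequence: str
    ambiguous: bool


def normalize_sequence(raw: str) -> NormalizedSeq:
    """Uppercase a nucleotide string and map U to T.

    IUPAC ambiguity codes (N, R, Y, ...) are preserved and reported via the
    ``ambiguous`` flag; any other character raises
    :class:`MalformedSequenceError` naming the offending position.
    """
    up = raw.upper()
    for i, c in enumerate(up):
        if c not in _IUPAC:
            raise MalformedSequenceError(i, raw[i])
    seq = up.replace("U", "T")
    ambiguous = any(c not in _ACGT for c in seq)
    return NormalizedSeq(seq, ambiguous)


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with CDS coordinates.

    ``cds_end`` is exclusive and the CDS includes the canonical stop codon,
    so ``sequence[cds_end - 3:cds_end]`` is one of TAA/TAG/TGA.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self):
        seq = normalize_sequence(self.sequence).sequence
        object.__setattr__(self, "sequence", seq)
        if not (0 <= self.cds_start < self.cds_end <= len(seq)):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"transcript of length {len(seq)}"
            )
        n = self.cds_end - self.cds_start
        if n <= 0 or n % 3:
            raise ValueError(f"{self.id}: CDS length {n} not a positive multiple of 3")
        if self.stop1 not in STOP_CODONS:
            raise ValueError(f"{self.id}: CDS does not end in a stop codon ({self.stop1})")

    @property
    def stop1(self) -> str:
        return self.sequence[self.cds_end - 3 : self.cds_end]

    @property
    def utr3(self) -> str:
        """The 3'UTR, starting immediately after the canonical stop codon."""
        return self.sequence[self.cds_end :]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


@dataclass(frozen=True)
class StopTopology:
    """Three in-frame stop codons and the two inter-stop regions (ISRs).

    Intervals are 0-based half-open in transcript coordinates and contiguous:
    ISR1 starts at ``cds_end``, stop 2 immediately follows ISR1, ISR2
    immediately follows stop 2, stop 3 immediately follows ISR2, and the
    distal UTR runs from the end of stop 3 to the transcript end.
    """

    stop1: str
    isr1: tuple[int, int]
    stop2: str
    isr2: tuple[int, int]
    stop3: str
    distal_utr: tuple[int, int]

    def __post_init__(self):
        for name in ("stop1", "stop2", "stop3"):
            if getattr(self, name) not in STOP_CODONS:
                raise ValueError(f"{name} = {getattr(self, name)!r} is not a stop codon")
        if self.isr1_len % 3 or self.isr2_len % 3:
            raise ValueError("ISR lengths must be multiples of 3")
        if self.isr2[0] != self.isr1[1] + 3:
            raise ValueError("ISR2 must start immediately after stop 2")
        if self.distal_utr[0] != self.isr2[1] + 3:
            raise ValueError("distal UTR must start immediately after stop 3")

    @property
    def cds_end(self) -> int:
        return self.isr1[0]

    @property
    def isr1_len(self) -> int:
        return self.isr1[1] - self.isr1[0]

    @property
    def isr2_len(self) -> int:
        return self.isr2[1] - self.isr2[0]

    @property
    def stop2_interval(self) -> tuple[int, int]:
        return (self.isr1[1], self.isr1[1] + 3)

    @property
    def stop3_interval(self) -> tuple[int, int]:
        return (self.isr2[1], self.isr2[1] + 3)

    @property
    def isr_combined(self) -> tuple[int, int]:
        """ISR1 + stop 2 + ISR2 as one interval."""
        return (self.isr1[0], self.isr2[1])

    @classmethod
    def from_lengths(
        cls,
        cds_end: int,
        isr1_len: int,
        isr2_len: int,
        transcript_len: int | None = None,
        stops: tuple[str, str, str] = ("TGA", "TAG", "TAA"),
    ) -> "StopTopology":
        """Build a topology directly from region lengths."""
        isr1 = (cds_end, cds_end + isr1_len)
        isr2 = (isr1[1] + 3, isr1[1] + 3 + isr2_len)
        end = isr2[1] + 3
        if transcript_len is None:
            transcript_len = end
        return cls(stops[0], isr1, stops[1], isr2, stops[2], (end, transcript_len))


class IsoformSet(NamedTuple):
    """Canonical and read-through protein sequences for one transcript."""

    canonical: str
    x: str
    xx: str
    recoded_residues: tuple[str, str]


def find_inframe_stops(
    transcript: TranscriptRecord, max_scan_nt: int | None = None
) -> list[tuple[int, str]]:
    """Scan frame 0 of the 3'UTR for in-frame stop codons.

    Returns ``(offset_nt, codon)`` pairs with offsets measured from the end
    of the canonical stop codon to the start of each downstream stop, so a
    stop beginning immediately after the CDS has offset 0. The scan proceeds
    codon by codon and ends at the transcript end or after ``max_scan_nt``
    nucleotides of UTR, whichever comes first.
    """
    utr = transcript.utr3
    if max_scan_nt is not None:
        utr = utr[:max_scan_nt]
    hits = []
    for off in range(0, len(utr) - 2, 3):
        codon = utr[off : off + 3]
        if codon in STOP_CODONS:
            hits.append((off, codon))
    return hits


def build_topology(
    transcript: TranscriptRecord, max_scan_nt: int | None = None
) -> StopTopology:
    """Locate the first two downstream in-frame stops and build the topology.

    Raises :class:`TopologyIncompleteError` (carrying whatever stops were
    found) when fewer than two downstream in-frame stops exist in range.
    """
    stops = find_inframe_stops(transcript, max_scan_nt)
    if len(stops) < 2:
        raise TopologyIncompleteError(stops)
    (off2, stop2), (off3, stop3) = stops[0], stops[1]
    e = transcript.cds_end
    return StopTopology(
        stop1=transcript.stop1,
        isr1=(e, e + off2),
        stop2=stop2,
        isr2=(e + off2 + 3, e + off3),
        stop3=stop3,
        distal_utr=(e + off3 + 3, len(transcript.sequence)),
    )


def extension_lengths(topology: StopTopology) -> tuple[int, int]:
    """Extra C-terminal residues of the single- and double-read-through isoforms.

    Each read-through event adds one recoded residue (the decoded stop codon)
    plus the peptide encoded by the following ISR:
    ``n_x = |ISR1|/3 + 1`` and ``n_xx = |ISR1|/3 + |ISR2|/3 + 2``.
    """
    n_x = topology.isr1_len // 3 + 1
    n_xx = n_x + topology.isr2_len // 3 + 1
    return n_x, n_xx


def translate_frame0(region: str) -> str:
    """Translate a nucleotide region in frame 0 with the standard code.

    Internal stop codons are rendered as ``'*'`` (a warning is emitted);
    ambiguity codes abort with :class:`AmbiguousSequenceError` rather than
    guessing a residue; a length that is not a multiple of 3 raises
    :class:`FrameError`.
    """
    seq, ambiguous = normalize_sequence(region)
    if len(seq) % 3:
        raise FrameError(f"region length {len(seq)} is not a multiple of 3")
    if ambiguous:
        raise AmbiguousSequenceError("region contains ambiguity codes; not translated")
    if not seq:
        return ""
    pep = str(Seq(seq).translate())
    if "*" in pep:
        warnings.warn("stop codon in translated region", stacklevel=2)
    return pep


def isoform_sequences(
    transcript: TranscriptRecord,
    topology: StopTopology,
    recode_policy: dict[str, str] | None = None,
) -> IsoformSet:
    """Derive canonical, single- and double-read-through protein sequences.

    ``recode_policy`` maps a stop codon (e.g. ``"TGA"``) to the amino acid
    inserted when it is read through; unmapped stops get the placeholder
    ``'X'`` because which near-cognate residue the ribosome inserts is not
    predicted here.
    """
    recode_policy = recode_policy or {}
    seq = transcript.sequence
    canonical = translate_frame0(seq[transcript.cds_start : transcript.cds_end - 3])
    isr1_pep = translate_frame0(seq[topology.isr1[0] : topology.isr1[1]])
    isr2_pep = translate_frame0(seq[topology.isr2[0] : topology.isr2[1]])
    if "*" in canonical or "*" in isr1_pep or "*" in isr2_pep:
        raise ValueError("internal stop codon inside CDS/ISR translation; topology is wrong")
    r1 = recode_policy.get(topology.stop1, "X")
    r2 = recode_policy.get(topology.stop2, "X")
    x = canonical + r1 + isr1_pep
    xx = x + r2 + isr2_pep
    return IsoformSet(canonical, x, xx, (r1, r2))


def readthrough_cassette_length(isr1_len: int, isr2_prefix_nt: int = 12) -> int:
    """Length in nt of the ISR1 + stop2 + ISR2-prefix reporter cassette.

    The proximal-UTR cassette used in single-read-through reporter constructs
    comprises ISR1, the second stop codon, and the first ``isr2_prefix_nt``
    nucleotides of ISR2 (the cis-acting read-through signal).
    """
    return isr1_len + 3 + isr2_prefix_nt


def deletion_product_size(wt_amplicon_bp: int, deletion_bp: int) -> int:
    """Predicted PCR product size after a genomic deletion within an amplicon."""
    if deletion_bp < 0 or deletion_bp > wt_amplicon_bp:
        raise ValueError("deletion length must be within the amplicon")
    return wt_amplicon_bp - deletion_bp
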