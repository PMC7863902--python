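"""Read-through proteoform databases, tryptic digestion and peptide mapping.

For MS evidence of double read-through, the search database must contain the
extended isoform with every possible residue at the two recoded stop
positions (the ribosome inserts a near-cognate amino acid whose identity is
unknown a priori): 20 x 20 = 400 double-read-through variants, or 20
single-read-through variants. Identified peptides are then classified by
which isoform landmarks their residue interval covers (peptides spanning a
recoded stop position, or both, are the read-through-specific evidence), and
checked for uniqueness against a background proteome so they cannot derive
from any other locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # 20 standard residues, lexicographic

REGION_CLASSES = (
    "CDS_only",
    "spans_stop1",
    "ISR1_only",
    "spans_stop2",
    "ISR2_only",
    "spans_both",
)


@dataclass(frozen=True)
class ProteoformRecord:
    """A variant protein sequence with its recoded-stop substitutions."""

    id: str
    sequence: str
    substitutions: tuple[tuple[int, str], ...]  # (stop_index in {1,2}, residue)

    def __post_init__(self):
        if "*" in self.sequence:
            raise ValueError(f"{self.id}: proteoform contains a stop symbol")
        for _, res in self.substitutions:
            if res not in AMINO_ACIDS:
                raise ValueError(f"{self.id}: non-standard residue {res!r}")


@dataclass(frozen=True)
class Peptide:
    """A digestion product with 0-based half-open coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class PeptideHit:
    """An identified peptide with its region class and uniqueness status."""

    sequence: str
    region_class: str
    unique_to_locus: bool

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")


def generate_xx_db(
    canonical: str, isr1_pep: str, isr2_pep: str, name: str = "prot"
) -> list[ProteoformRecord]:
    """All 400 double-read-through variants.

    Each record is ``canonical + a1 + isr1_pep + a2 + isr2_pep`` for every
    ordered pair of standard amino acids ``(a1, a2)``, in lexicographic
    order; ids follow ``{name}_xx_{a1}_{a2}``.
    """
    records = []
    for a1 in AMINO_ACIDS:
        for a2 in AMINO_ACIDS:
            records.append(
                ProteoformRecord(
                    id=f"{name}_xx_{a1}_{a2}",
                    sequence=canonical + a1 + isr1_pep + a2 + isr2_pep,
                    substitutions=((1, a1), (2, a2)),
                )
            )
    return records


def generate_x_db(canonical: str, isr1_pep: str, name: str = "prot") -> list[ProteoformRecord]:
    """All 20 single-read-through variants (``canonical + a1 + isr1_pep``)."""
    return [
        ProteoformRecord(
            id=f"{name}_x_{a1}",
            sequence=canonical + a1 + isr1_pep,
            substitutions=((1, a1),),
        )
        for a1 in AMINO_ACIDS
    ]


def cleavage_sites(protein: str, suppress_before_P: bool = True) -> list[int]:
    """Internal tryptic cleavage positions (cut *after* K or R, not before P)."""
    sites = []
    for i in range(len(protein) - 1):
        if protein[i] in "KR" and not (suppress_before_P and protein[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def tryptic_digest(
    protein: str, max_missed: int = 5, suppress_before_P: bool = True
) -> list[Peptide]:
    """In-silico tryptic digestion allowing up to ``max_missed`` missed cleavages.

    Fragments are the runs between consecutive cleavage sites (cut after K/R,
    suppressed before proline when ``suppress_before_P``); peptides are all
    runs of 1..max_missed+1 consecutive fragments, including the protein's
    N- and C-terminal peptides. Ordered by start, then missed cleavages.
    """
    if not protein:
        return []
    bounds = [0] + cleavage_sites(protein, suppress_before_P) + [len(protein)]
    peptides = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for m in range(0, max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start, end = bounds[i], bounds[j]
            peptides.append(Peptide(protein[start:end], start, end, m))
    return peptides


def classify_peptide(
    peptide_interval: tuple[int, int],
    landmarks: dict,
) -> str:
    """Region class of a peptide from its residue interval in xx coordinates.

    ``landmarks`` holds ``stop1_pos`` and ``stop2_pos`` (residue indices of
    the two recoded positions) and ``isr1``/``isr2`` spans (half-open residue
    intervals). A peptide covering both recoded residues is ``spans_both``;
    covering one is ``spans_stop1``/``spans_stop2``; otherwise containment in
    an ISR span gives ``ISR1_only``/``ISR2_only``, else ``CDS_only``.
    """
    start, end = peptide_interval
    if start >= end:
        raise ValueError("empty peptide interval")
    covers1 = start <= landmarks["stop1_pos"] < end
    covers2 = start <= landmarks["stop2_pos"] < end
    if covers1 and covers2:
        return "spans_both"
    if covers1:
        return "spans_stop1"
    if covers2:
        return "spans_stop2"
    i1lo, i1hi = landmarks["isr1"]
    i2lo, i2hi = landmarks["isr2"]
    if i1lo <= start and end <= i1hi:
        return "ISR1_only"
    if i2lo <= start and end <= i2hi:
        return "ISR2_only"
    return "CDS_only"


def xx_landmarks(canonical_len: int, isr1_len: int, isr2_len: int) -> dict:
    """Landmark coordinates in the double-read-through isoform.

    Residue layout: ``[0, canonical_len)`` canonical, then recoded stop 1,
    then ISR1 peptide, then recoded stop 2, then ISR2 peptide.
    """
    stop1 = canonical_len
    isr1 = (stop1 + 1, stop1 + 1 + isr1_len)
    stop2 = isr1[1]
    isr2 = (stop2 + 1, stop2 + 1 + isr2_len)
    return {"stop1_pos": stop1, "isr1": isr1, "stop2_pos": stop2, "isr2": isr2}


def uniqueness_check(
    peptide: str, background: Iterable[str], collapse_IL: bool = False
) -> bool:
    """True iff the peptide occurs in no background protein.

    With ``collapse_IL`` the isobaric residues I and L are treated as
    indistinguishable (both mapped to L) before the substring search, as MS
    cannot tell them apart. The background must exclude the locus's own
    proteoforms.
    """
    pep = peptide.replace("I", "L") if collapse_IL else peptide
    for prot in background:
        hay = prot.replace("I", "L") if collapse_IL else prot
        if pep in hay:
            return False
    return True


def classify_peptides_in_proteoform(
    peptides: Sequence[Peptide], landmarks: dict
) -> list[str]:
    """Vector convenience: classify each digestion product of one proteoform."""
    return [classify_peptide((p.start, p.end), landmarks) for p in peptides]
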