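"""Multi-species proximal-3'UTR conservation screen for read-through candidates.

A transcript is a double-read-through candidate when, across species, the
3'UTR carries an in-frame stop codon at a consistent position (a conserved
"stop 2") and the peptide potentially encoded between the canonical stop and
that downstream stop (the ISR1 peptide) is well conserved. The screen
translates each species' UTR in frame 0, splits at stop codons, aligns the
inter-stop peptides to a reference species with Needleman-Wunsch global
alignment assembled into a star MSA, and scores per-column identity against
the reference row.

Alignment here is deliberately simple (linear gap penalty, star topology):
the screen only needs identity fractions over short peptides, not a full
progressive aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULTS
from .errors import InsufficientDataError
from .topology import STOP_CODONS, normalize_sequence, translate_frame0

GAP = "-"


@dataclass(frozen=True)
class SpeciesUtr:
    """One species' 3'UTR, starting immediately after the canonical stop."""

    species: str
    utr: str

    def __post_init__(self):
        seq = normalize_sequence(self.utr).sequence
        if not seq:
            raise ValueError(f"{self.species}: empty UTR")
        object.__setattr__(self, "utr", seq)


@dataclass(frozen=True)
class Msa:
    """A gapped multiple alignment with a designated reference row."""

    names: tuple[str, ...]
    rows: tuple[str, ...]
    reference_index: int = 0

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class CandidateCall:
    """Outcome of the conservation screen, with the thresholds applied."""

    has_conserved_stop2: bool
    stop2_inframe_fraction: float
    mean_isr1_identity: float
    mean_isr2_identity: float
    is_candidate: bool
    thresholds: dict


def utr_peptide_segments(utr: str) -> list[str]:
    """In-frame translation of a UTR split at stop codons.

    Returns the peptide segments between successive frame-0 stops, in order;
    a trailing partial codon is ignored. ``"GGGTAGCCC"`` gives ``["G", "P"]``.
    """
    seq = normalize_sequence(utr).sequence
    seq = seq[: len(seq) - len(seq) % 3]
    segments: list[str] = []
    current: list[str] = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            segments.append("".join(current))
            current = []
        else:
            current.append(translate_frame0(codon))
    segments.append("".join(current))
    return segments


def inframe_stop_offsets(utr: str) -> list[int]:
    """Nucleotide offsets of frame-0 stop codons within a UTR."""
    seq = normalize_sequence(utr).sequence
    return [i for i in range(0, len(seq) - 2, 3) if seq[i : i + 3] in STOP_CODONS]


def pairwise_align_global(
    a: str,
    b: str,
    match: float = DEFAULTS.align_match,
    mismatch: float = DEFAULTS.align_mismatch,
    gap: float = DEFAULTS.align_gap,
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Traceback is deterministic with tie-break order diagonal > up > left
    (up consumes a residue of ``a``). Returns the two gapped strings and the
    optimal score.
    """
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        ai = a[i - 1]
        row_prev = score[i - 1]
        row = score[i]
        for j in range(1, m + 1):
            d = row_prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            u = row_prev[j] + gap
            l = row[j - 1] + gap
            row[j] = max(d, u, l)
    # traceback, tie-break diagonal > up > left
    ga: list[str] = []
    gb: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            ga.append(a[i - 1])
            gb.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and s == score[i - 1, j] + gap:
            ga.append(a[i - 1])
            gb.append(GAP)
            i -= 1
        else:
            ga.append(GAP)
            gb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ga)), "".join(reversed(gb)), float(score[n, m])


def star_msa(ref: str, others: list[str], names: list[str] | None = None, **scores) -> Msa:
    """Star multiple alignment: every sequence aligned pairwise to ``ref``.

    Pairwise gaps are projected into a common frame under the usual
    "once a gap, always a gap" rule.
    """
    if names is None:
        names = ["ref"] + [f"seq{i + 1}" for i in range(len(others))]
    # master: positions of ref residues in the growing gapped frame
    aligned_pairs = [pairwise_align_global(ref, o, **scores)[:2] for o in others]

    # Merge: master ref row accumulates every gap any pairwise alignment opened.
    # Track, per alignment, where each ref residue sits; then rebuild rows.
    master_gaps = [0] * (len(ref) + 1)  # gaps before ref residue k (and trailing)
    per_aln_gaps = []
    for ga, _ in aligned_pairs:
        gaps = [0] * (len(ref) + 1)
        k = 0
        for c in ga:
            if c == GAP:
                gaps[k] += 1
            else:
                k += 1
        per_aln_gaps.append(gaps)
        for k in range(len(ref) + 1):
            master_gaps[k] = max(master_gaps[k], gaps[k])

    def project(row: str, gaps: list[int]) -> str:
        # row is gapped against ref with `gaps[k]` gaps before ref residue k;
        # pad each slot out to master_gaps[k].
        out: list[str] = []
        it = iter(row)
        for k in range(len(ref) + 1):
            slot = [next(it) for _ in range(gaps[k])]
            slot += [GAP] * (master_gaps[k] - gaps[k])
            out.extend(slot)
            if k < len(ref):
                out.append(next(it))
        return "".join(out)

    ref_gapped = project(ref, [0] * (len(ref) + 1))
    rows = [ref_gapped]
    for (ga, gb), gaps in zip(aligned_pairs, per_aln_gaps):
        rows.append(project(gb, gaps))
    return Msa(tuple(names), tuple(rows), reference_index=0)


def column_identity(msa: Msa) -> list[float]:
    """Per-column fraction of rows matching the reference symbol.

    Gaps never match, in the reference row or elsewhere; the reference row
    counts itself, so a fully conserved column scores 1.0.
    """
    ref = msa.rows[msa.reference_index]
    n = len(msa.rows)
    out = []
    for c in range(msa.n_columns):
        r = ref[c]
        if r == GAP:
            out.append(0.0)
        else:
            out.append(sum(1 for row in msa.rows if row[c] == r) / n)
    return out


def score_candidate(
    species_utrs: list[SpeciesUtr],
    stop2_fraction: float = DEFAULTS.conserve_stop2_fraction,
    isr_identity: float = DEFAULTS.conserve_isr_identity,
    slack_codons: int = DEFAULTS.conserve_stop2_slack_codons,
    reference_index: int = 0,
) -> CandidateCall:
    """Call a read-through candidate from multi-species UTRs.

    A species supports the conserved stop 2 when its first frame-0 UTR stop
    lies within ``slack_codons`` codons of the reference species' first stop
    offset. ISR identities are means over star-MSA columns of the
    fraction-matching-reference statistic, for the peptide before the first
    stop (ISR1) and between the first and second stops (ISR2).
    """
    if len(species_utrs) < 2:
        raise InsufficientDataError("conservation screen needs >= 2 species")
    ref = species_utrs[reference_index]
    ref_offsets = inframe_stop_offsets(ref.utr)
    if not ref_offsets:
        # no downstream stop in the reference: nothing to be conserved
        return CandidateCall(False, 0.0, 0.0, 0.0, False, _thresh(stop2_fraction, isr_identity, slack_codons))
    ref_off = ref_offsets[0]

    n_consistent = 0
    for sp in species_utrs:
        offs = inframe_stop_offsets(sp.utr)
        if any(abs(o - ref_off) <= 3 * slack_codons for o in offs):
            n_consistent += 1
    frac = n_consistent / len(species_utrs)
    has_stop2 = frac >= stop2_fraction

    def region_identity(segment_index: int) -> float:
        ref_segs = utr_peptide_segments(ref.utr)
        if segment_index >= len(ref_segs) or not ref_segs[segment_index]:
            return 0.0
        ref_pep = ref_segs[segment_index]
        others, names = [], []
        for i, sp in enumerate(species_utrs):
            if i == reference_index:
                continue
            segs = utr_peptide_segments(sp.utr)
            others.append(segs[segment_index] if segment_index < len(segs) else "")
            names.append(sp.species)
        msa = star_msa(ref_pep, others, names=[ref.species] + names)
        cols = column_identity(msa)
        return float(np.mean(cols)) if cols else 0.0

    isr1_id = region_identity(0)
    isr2_id = region_identity(1)
    is_candidate = has_stop2 and isr1_id >= isr_identity
    return CandidateCall(
        has_conserved_stop2=has_stop2,
        stop2_inframe_fraction=frac,
        mean_isr1_identity=isr1_id,
        mean_isr2_identity=isr2_id,
        is_candidate=is_candidate,
        thresholds=_thresh(stop2_fraction, isr_identity, slack_codons),
    )


def _thresh(stop2_fraction, isr_identity, slack_codons):
    return {
        "stop2_fraction": stop2_fraction,
        "isr_identity": isr_identity,
        "slack_codons": slack_codons,
    }
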