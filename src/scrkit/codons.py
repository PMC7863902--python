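"""Rare-codon context scanning near the stop codon.

Slow-translating (rare) codons upstream of a stop codon can pause ribosomes,
and ribosomal pausing is associated with stop-codon read-through; a stretch
of rare codons just before the canonical stop is therefore a plausible
secondary read-through signal. Rarity is measured by relative synonymous
adaptiveness w = f(codon) / max f(synonym) from a codon-usage table, scanned
with a sliding-window mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .errors import ScrkitError
from .topology import STOP_CODONS, normalize_sequence

# standard-code synonym families (stop codons excluded)
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = tuple(sorted(_CODE))


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon usage frequencies and derived relative adaptiveness w.

    ``frequency`` may be per-thousand or fractional; w is scale-free:
    w(c) = f(c) / max f over c's synonyms, so w in (0, 1] for every sense
    codon and the most frequent synonym of each family has w = 1.
    """

    frequency: dict[str, float]
    w: dict[str, float] = field(init=False)

    def __post_init__(self):
        missing = [c for c in SENSE_CODONS if c not in self.frequency]
        if missing:
            raise ScrkitError(f"codon table lacks sense codons: {missing[:5]} ...")
        bad = [c for c, f in self.frequency.items() if c in _CODE and f <= 0]
        if bad:
            raise ScrkitError(f"non-positive frequency for codons: {bad[:5]}")
        fam_max: dict[str, float] = {}
        for codon, aa in _CODE.items():
            fam_max[aa] = max(fam_max.get(aa, 0.0), self.frequency[codon])
        object.__setattr__(
            self, "w", {c: self.frequency[c] / fam_max[_CODE[c]] for c in SENSE_CODONS}
        )

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Read a two-column TSV (codon, frequency); '#' comments allowed."""
        freq = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, value = line.split("\t")[:2]
                if codon.lower() == "codon":
                    continue
                freq[normalize_sequence(codon).sequence] = float(value)
        return cls(freq)

    @classmethod
    def human(cls) -> "CodonUsageTable":
        """The built-in human codon-usage table (per-thousand frequencies)."""
        ref = resources.files("scrkit.data") / "human_codon_usage.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def adaptiveness_profile(cds: str, table: CodonUsageTable) -> list[float]:
    """Per-codon w values over a CDS, excluding the terminal stop codon."""
    seq = normalize_sequence(cds).sequence
    if len(seq) % 3 or len(seq) < 6:
        raise ScrkitError("CDS length must be a multiple of 3 with at least two codons")
    if seq[-3:] not in STOP_CODONS:
        raise ScrkitError("CDS must end in a stop codon")
    profile = []
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if codon not in table.w:
            raise ScrkitError(f"codon {codon} absent from usage table (position {i})")
        profile.append(table.w[codon])
    return profile


def rare_windows(
    profile: list[float], window: int = 5, threshold: float = 0.3
) -> list[tuple[int, int]]:
    """Maximal codon-index intervals where the sliding-window mean w <= threshold.

    Every length-``window`` window whose mean adaptiveness is at or below the
    threshold is marked; overlapping or adjacent marked windows are merged
    into maximal half-open intervals. A window longer than the profile
    returns no intervals.
    """
    if window < 1:
        raise ScrkitError("window must be >= 1")
    n = len(profile)
    if window > n:
        import warnings

        warnings.warn("window longer than profile; no scan performed", stacklevel=2)
        return []
    marked = []
    acc = sum(profile[:window])
    if acc / window <= threshold:
        marked.append(0)
    for i in range(1, n - window + 1):
        acc += profile[i + window - 1] - profile[i - 1]
        if acc / window <= threshold:
            marked.append(i)
    intervals: list[tuple[int, int]] = []
    for i in marked:
        lo, hi = i, i + window
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((lo, hi))
    return intervals


def distance_to_stop(intervals: list[tuple[int, int]], profile_len: int) -> int | None:
    """Codon distance from the nearest rare interval to the stop codon (0 = abuts it)."""
    if not intervals:
        return None
    return min(profile_len - hi for _, hi in intervals)
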