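"""Seeded generators of ground-truth inputs for every pipeline stage.

Each generator takes an explicit integer seed (no global random state),
is byte-deterministic for identical parameters, and returns or writes a
machine-readable "truth" record of the planted parameters alongside its
output, so analysis results can be checked against known ground truth
without any external download.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .config import DEFAULT_ADAPTER3
from .conservation import SpeciesUtr
from .proteoforms import Peptide, ProteoformRecord, classify_peptide, tryptic_digest
from .reporter import ReporterPlate
from .ribo import FootprintRead
from .topology import STOP_CODONS, StopTopology, TranscriptRecord, build_topology

#: the 61 sense codons of the standard code
SENSE = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def sim_transcript(
    seed: int,
    cds_codons: int = 100,
    isr1_len: int = 30,
    isr2_len: int = 72,
    utr_len: int = 300,
    stops: tuple[str, str, str] = ("TGA", "TAG", "TAA"),
) -> TranscriptRecord:
    """A transcript with a planted two-downstream-stop topology.

    ``cds_codons`` counts CDS codons excluding the canonical stop; ISR bodies
    are sampled from sense codons only (no accidental in-frame stops), so
    the planted topology is recovered exactly by ``build_topology``. The
    default geometry (ISR1 30 nt, ISR2 72 nt) gives downstream stops at
    offsets 30 and 105 nt. ``utr_len`` is the distal UTR after stop 3.
    """
    if isr1_len % 3 or isr2_len % 3:
        raise ValueError("ISR lengths must be multiples of 3")
    if cds_codons < 1:
        raise ValueError("need at least one CDS codon")
    rng = _rng(seed)

    def sense_run(n_codons):
        return "".join(rng.choice(SENSE, size=n_codons)) if n_codons else ""

    cds_body = "ATG" + sense_run(cds_codons - 1)
    isr1 = sense_run(isr1_len // 3)
    isr2 = sense_run(isr2_len // 3)
    distal = "".join(rng.choice(list("ACGT"), size=utr_len))
    seq = cds_body + stops[0] + isr1 + stops[1] + isr2 + stops[2] + distal
    return TranscriptRecord(
        id=f"sim_tx_seed{seed}",
        sequence=seq,
        cds_start=0,
        cds_end=len(cds_body) + 3,
    )


def sim_species_set(
    seed: int,
    base: TranscriptRecord,
    n_species: int = 10,
    isr_sub_rate: float = 0.05,
    other_sub_rate: float = 0.05,
    preserve_stops: bool = True,
) -> list[SpeciesUtr]:
    """Mutated copies of a transcript's 3'UTR emulating cross-species variation.

    The first record is the unmutated base (the reference species). Each
    other species receives independent per-site substitutions: positions
    inside ISR1/ISR2 at ``isr_sub_rate``, all other UTR positions at
    ``other_sub_rate``. With ``preserve_stops`` the downstream stop codons
    are never mutated (the conserved-topology regime); switching it off
    plants conservation-screen negatives.
    """
    rng = _rng(seed)
    topo = build_topology(base)
    utr = base.utr3
    off = base.cds_end
    isr_pos = set(range(topo.isr1[0] - off, topo.isr1[1] - off)) | set(
        range(topo.isr2[0] - off, topo.isr2[1] - off)
    )
    stop_pos = set(range(topo.isr1[1] - off, topo.isr1[1] - off + 3)) | set(
        range(topo.isr2[1] - off, topo.isr2[1] - off + 3)
    )
    out = [SpeciesUtr("species00", utr)]
    alphabet = "ACGT"
    for s in range(1, n_species):
        chars = list(utr)
        for i, c in enumerate(chars):
            if preserve_stops and i in stop_pos:
                continue
            rate = isr_sub_rate if i in isr_pos else other_sub_rate
            if rng.random() < rate:
                chars[i] = alphabet[(alphabet.index(c) + rng.integers(1, 4)) % 4]
        out.append(SpeciesUtr(f"species{s:02d}", "".join(chars)))
    return out


@dataclass
class FootprintTruth:
    """Planted parameters of a simulated footprint dataset."""

    seed: int
    densities: dict
    fold_drop: float
    n_reads: dict
    read_len: tuple[int, int]
    adapter3: str
    frac_short: float
    expected_positive: bool


def sim_footprints(
    seed: int,
    transcript: TranscriptRecord,
    topology: StopTopology,
    densities: dict[str, float],
    read_len: tuple[int, int] = (24, 35),
    adapter3: str = DEFAULT_ADAPTER3,
    frac_short: float = 0.0,
) -> tuple[list[FootprintRead], FootprintTruth]:
    """Simulated ribosome footprints at planted per-region densities.

    ``densities`` maps ``cds``/``isr``/``utr`` to expected reads per nt
    (``isr`` covers the combined ISR1+stop2+ISR2 region, ``utr`` the distal
    UTR). Region read counts are Poisson(density x length); footprint
    midpoints are uniform in the region (start clipped to the transcript);
    lengths are uniform on ``read_len``; the 3' adapter is appended to every
    read; a ``frac_short`` fraction of inserts is truncated below 24 nt.
    """
    rng = _rng(seed)
    seq = transcript.sequence
    regions = {
        "cds": (transcript.cds_start, topology.cds_end),
        "isr": topology.isr_combined,
        "utr": topology.distal_utr,
    }
    reads: list[FootprintRead] = []
    n_reads = {}
    k = 0
    for name, (lo, hi) in regions.items():
        dens = densities.get(name, 0.0)
        n = int(rng.poisson(dens * (hi - lo))) if dens > 0 else 0
        n_reads[name] = n
        for _ in range(n):
            length = int(rng.integers(read_len[0], read_len[1] + 1))
            mid = rng.integers(lo, hi)
            start = int(np.clip(mid - length // 2, 0, len(seq) - length))
            insert = seq[start : start + length]
            if frac_short > 0 and rng.random() < frac_short:
                insert = insert[: int(rng.integers(15, 24))]
            full = insert + adapter3
            reads.append(FootprintRead(f"sim_read_{k}", full, "I" * len(full)))
            k += 1
    isr_d, utr_d = densities.get("isr", 0.0), densities.get("utr", 0.0)
    fold = math.inf if utr_d == 0 and isr_d > 0 else (isr_d / utr_d if utr_d else 0.0)
    truth = FootprintTruth(
        seed=seed,
        densities=dict(densities),
        fold_drop=fold,
        n_reads=n_reads,
        read_len=read_len,
        adapter3=adapter3,
        frac_short=frac_short,
        expected_positive=isr_d > 0 and fold >= 4,
    )
    return reads, truth


def write_fastq_with_truth(reads, truth: FootprintTruth, fastq_path, truth_path=None):
    """Write simulated reads as 4-line FASTQ plus a JSON truth sidecar."""
    from .io import write_fastq

    write_fastq(reads, fastq_path)
    if truth_path is None:
        truth_path = str(fastq_path) + ".truth.json"
    with open(truth_path, "w") as fh:
        d = asdict(truth)
        d["fold_drop"] = None if math.isinf(truth.fold_drop) else truth.fold_drop
        json.dump(d, fh, indent=2)
        fh.write("\n")


def _lognormal_noise(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise at coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def sim_reporter(
    seed: int,
    true_percent: float,
    cv: float = 0.05,
    n_replicates: int = 3,
    negative_percent: float = 0.0,
    base_control: float = 1000.0,
) -> tuple[ReporterPlate, ReporterPlate, ReporterPlate]:
    """(test, nostop, negative) dual-reporter plates at a planted efficiency.

    Each replicate draws a control-reporter signal and a test-reporter signal
    whose planted ratio is ``true_percent/100`` of the no-stop construct's
    ratio, under independent multiplicative log-normal noise at the given CV.
    """
    rng = _rng(seed)

    def plate(name, ratio):
        ctrl = base_control * _lognormal_noise(rng, cv, n_replicates)
        test = ratio * base_control * _lognormal_noise(rng, cv, n_replicates)
        return ReporterPlate(name, tuple(zip(test.tolist(), ctrl.tolist())))

    return (
        plate("test", true_percent / 100.0),
        plate("nostop", 1.0),
        plate("negative", negative_percent / 100.0),
    )


def sim_peptides(
    seed: int,
    proteoform: ProteoformRecord,
    landmarks: dict,
    n: int = 50,
    span_bias: float = 0.0,
    max_missed: int = 5,
) -> list[tuple[Peptide, str]]:
    """Peptides sampled from a proteoform's true tryptic digest, with truth classes.

    ``span_bias`` is the fraction of draws forced to come from peptides
    covering at least one recoded stop residue (when any exist); the rest are
    uniform over the whole digest. Returns (peptide, true region class).
    """
    rng = _rng(seed)
    digest = tryptic_digest(proteoform.sequence, max_missed=max_missed)
    if not digest or n == 0:
        return []
    spanning = [
        p
        for p in digest
        if p.start <= landmarks["stop1_pos"] < p.end
        or p.start <= landmarks["stop2_pos"] < p.end
    ]
    out = []
    for _ in range(n):
        pool = spanning if (spanning and rng.random() < span_bias) else digest
        pep = pool[int(rng.integers(len(pool)))]
        out.append((pep, classify_peptide((pep.start, pep.end), landmarks)))
    return out


def sim_decay(
    seed: int,
    t_half: float,
    times,
    noise_cv: float = 0.0,
    i0: float = 1.0,
) -> list[tuple[float, float]]:
    """Exponential-decay time course with multiplicative noise.

    ``t_half`` may be ``math.inf`` for a stable protein (flat curve).
    Returns (time, intensity) pairs.
    """
    rng = _rng(seed)
    t = np.asarray(times, dtype=float)
    decay = np.ones_like(t) if math.isinf(t_half) else 2.0 ** (-t / t_half)
    intens = i0 * decay * _lognormal_noise(rng, noise_cv, len(t))
    return list(zip(t.tolist(), intens.tolist()))
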