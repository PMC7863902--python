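# Methods

This note documents the models and procedures `scrkit` implements, the
defaults that matter, the synthetic data the tests run on, and the design
choices made where the design was genuinely open.

## Stop topology and isoforms

Coordinates are 0-based half-open in transcript space. The CDS interval
*includes* the canonical stop codon (GenBank convention), so the first
inter-stop region (ISR1) begins exactly at `cds_end`. Downstream in-frame
stops are found by a codon-by-codon scan of frame 0 of the 3′UTR; offsets
are reported from the *end* of the canonical stop to the *start* of the
downstream stop. With this convention the reference geometry — downstream
stops at 30 and 105 nt — decomposes as ISR1 = 30 nt, stop 2 = 3 nt,
ISR2 = 72 nt (30 + 3 + 72 = 105), and the isoform extensions are
n_x = 30/3 + 1 = 11 and n_xx = 30/3 + 72/3 + 2 = 36 residues.

The scan has no arbitrary cap by default (`topology_max_scan_nt = None`,
i.e. to the transcript end). Which amino acid the ribosome inserts at a
recoded stop is not predicted: isoform sequences carry the placeholder `X`
there unless a per-stop-codon `recode_policy` is supplied. Ambiguity codes
(N, R, Y, …) are preserved by normalization and flagged; translation over a
region containing them aborts with an error rather than guessing, and
internal stops translate to `*` with a warning.

Two pieces of construct arithmetic live with the topology code: the
single-read-through reporter cassette (ISR1 + stop 2 + the first 12 nt of
ISR2, the cis-acting read-through signal; 30 + 3 + 12 = 45 nt for the
reference geometry) and the predicted PCR product after a genomic deletion
(wild-type amplicon minus deletion length, e.g. 488 − 69 = 419 bp).

## Conservation screen

The screen asks two questions of a multi-species set of 3′UTRs (each
starting immediately after the canonical stop): is there an in-frame stop
at a position consistent with the reference species, and is the peptide
potentially encoded before it (ISR1) conserved?

Each UTR is translated in frame 0 and split at stops; segment *k* is the
peptide between stops *k* and *k+1*. Positional consistency of stop 2 means
the species' first frame-0 stop offset equals the reference offset within
`slack_codons` (default 0) codons. Peptide conservation is scored on a star
MSA: every species' segment is globally aligned to the reference segment
with Needleman–Wunsch (match +1, mismatch −1, linear gap −2, deterministic
traceback with tie-break diagonal > up > left) and gaps are projected into
a common frame ("once a gap, always a gap"). Column identity is the
fraction of rows matching the reference symbol (gaps never match; the
reference row counts itself), and the region identity is the mean over
columns. A full progressive aligner is unnecessary here: the statistic is
an identity fraction over short peptides, for which star alignment to the
reference is adequate and exactly reproducible.

Candidate rule: `is_candidate = (stop2 fraction ≥ 0.8) AND (mean ISR1
identity ≥ 0.5)`. Both thresholds are unstandardised in the literature;
they are configurable, reported with every call, and chosen so that the
synthetic positive regime (≈5% per-site divergence) and negative regime
(≈50–70% divergence, stops free to mutate) separate cleanly. Nucleotide-
level identity can be computed with the same machinery but does not enter
the call. No phylogenetic weighting is applied.

## Ribosome-profiling caller

Reads are 3′-adapter trimmed by exact matching: the read is truncated at
the leftmost occurrence of the full adapter, or of an adapter prefix of at
least `min_overlap = 6` nt running to the read end (the default adapter is
the TruSeq small-RNA 3′ adapter prefix `AGATCGGAAGAGC`). No error tolerance
is needed because the caller is designed for exact-match mapping anyway.

Trimmed reads of at least 24 nt are mapped by exact substring search
against the single target transcript — for perfect matches this is
equivalent to transcriptome alignment followed by a perfect-match filter,
at single-locus scale. Reads matching at two or more positions are
discarded as ambiguous; shorter reads are counted as discarded-short.
Antisense matching is not attempted (ribosome-profiling inserts are
sense-strand by construction). No P-site offsetting is applied: coverage
and density use the full footprint span.

Per region (CDS, ISR1, stop 2, ISR2, combined ISR1+stop2+ISR2, distal
3′UTR): `coverage_fraction` = fraction of region positions covered ≥ 1×,
and `density` = footprints overlapping the region by ≥ 1 nt per nt of
region. Density has no standard formula; the overlap-count-per-nt choice is
reported alongside raw counts so alternatives can be recomputed.
Zero-length regions report coverage 1.0 and density 0 by convention,
flagged as degenerate.

Positivity: ISR1 coverage ≥ 0.5 **and** ISR2 coverage ≥ 0.5 (the strict
reading; the combined-region coverage is also reported) **and**
`isr_density / utr_density ≥ 4`, where ISR density is computed over the
combined region and UTR density over the distal 3′UTR. Zero UTR density
with nonzero ISR density is an infinite fold drop (positive if coverage
passes); zero ISR density is negative with fold drop 0. The call is
monotone in ISR reads by construction.

## Proteoform databases and peptide mapping

The double-read-through search database is
`canonical + a1 + ISR1pep + a2 + ISR2pep` for every ordered pair `(a1, a2)`
of the 20 standard residues — 400 records in deterministic lexicographic
order (20 for the single-read-through analogue). Tryptic digestion cuts
after K/R, suppressed before proline by default, with up to 5 missed
cleavages; peptides are all runs of ≤ 6 consecutive fragments with parent
coordinates attached. PSM scoring and FDR control are out of scope (the
search engine's job); the digestion parameters are what matter for
coverage of the recoded positions.

Peptides are classified by their residue interval against the xx-isoform
landmarks: covering both recoded positions → `spans_both` (the
double-read-through evidence class), one → `spans_stop1`/`spans_stop2`,
otherwise containment gives `ISR1_only`/`ISR2_only`/`CDS_only`. Uniqueness
against a background proteome is plain substring search, with an optional
I/L collapse (off by default, reported) since MS cannot distinguish the
isobaric pair.

## Reporter quantification

Efficiency = 100 × (R_test − B)/(R_nostop − B) on means of per-replicate
test/control ratios. Background subtraction (B = negative-control mean) is
off by default — whether published efficiencies subtract background is
generally ambiguous — and both modes are available. SEs propagate by the
first-order delta method on the ratio of independent means; an SD
(= SE·√n) is also emitted because conventions differ across assays.

Half-life: ordinary least squares of ln(intensity) on time;
t½ = ln 2/(−slope). Non-positive intensities are excluded; fewer than 3
usable points is an error. Results are censored as "> t_max" (default
36 h, a typical chase duration) when the slope is non-negative or the
fitted t½ exceeds t_max — reporting bounds rather than extrapolating
beyond the observation window. The model is single-exponential; no
plateau/two-phase fitting.

2^−ΔΔCt uses condition means of target and reference Ct. The JC-1 ratio is
I(594 nm)/I(538 nm) with linear interpolation between spectrum points.
t-tests implement the pooled-variance Student form and the Welch form with
Satterthwaite df; two identical zero-variance samples return t = 0, p = 1
by convention. Two-way ANOVA is not implemented.

## Codon context

Relative adaptiveness w(c) = f(c)/max f over c's synonyms, from a codon
usage table (a standard human table, per-1000 frequencies, ships as
package data; any two-column TSV can be substituted). The profile covers
every CDS codon except the stop. Rare stretches are maximal merged
intervals of sliding windows (default length 5 codons) whose mean w is ≤
the threshold (default 0.3); the distance from the nearest interval to the
stop codon is reported. "Rare" has no canonical cutoff — the threshold is
configurable and echoed with every result. tAI/CAI with tRNA copy numbers
and dwell-time modeling are out of scope.

## Synthetic data

All generators take an explicit integer seed (numpy `default_rng`; no
global state), are byte-deterministic, and emit machine-readable truth.

- **Transcripts**: CDS body and ISRs are sampled from the 61 sense codons
  only, so the planted topology is the exact truth. Default geometry
  mirrors the reference case (100 CDS codons, ISR1 = 30 nt, ISR2 = 72 nt,
  300 nt distal UTR).
- **Species sets**: per-site substitutions at separate ISR and non-ISR
  rates; the downstream stop codons are optionally immutable
  (`preserve_stops`), which plants screen positives; freeing them plants
  negatives.
- **Footprints**: per-region read counts ~ Poisson(density × length),
  footprint midpoints uniform in the region (starts clipped into the
  transcript so every read is a perfect substring), lengths uniform on
  24–35 nt (the typical monosome footprint range), 3′ adapter appended,
  and an optional fraction of inserts truncated below 24 nt. The truth
  sidecar records densities, counts and the planted fold drop.
- **Reporter plates / decay / peptides**: multiplicative mean-one
  log-normal noise at a stated CV on planted ratios or decay curves;
  peptide samples are drawn from the true digest with a controllable bias
  toward stop-spanning peptides; truth classes are recorded.

What the simulations do *not* model: sequencing errors, dwell-time
heterogeneity (read starts are uniform within a region), library-prep
biases, splice variants, or cross-locus multi-mapping. Passing tests
therefore demonstrate the correctness of the decision rules and estimators
under their stated assumptions, not robustness to real-data artifacts.

## Test and simulation scales

The suite's statistical checks use: caller label recovery over 100 seeded
simulations (planted fold drops 8 vs 1, ISR density 2 reads/nt ≈ 210 ISR
reads, ≥ 95% correct required); efficiency recovery at planted
{5, 11, 27, 59}% over 500 seeds at 5% CV with triplicates (|bias| < 1.5
points); half-life recovery at planted 0.5 h, 10% noise, 50 seeds (median
within 20%); and exhaustive small-instance oracle equivalence for
digestion (all proteins ≤ 5 over {A,K,R,P}), global alignment (all pairs
≤ 4 over {A,R} against full enumeration, plus spot checks against an
independent aligner), and peptide classification (every interval of a
small layout). These sizes give comfortable statistical margins while
keeping the default test run fast.

## Known limitations

- Single-transcript scope: no genome alignment, splice awareness, or
  transcriptome-wide uniqueness handling in the caller (the screen's
  premise is that the ISR sequences are locus-unique).
- Star MSA is reference-anchored; insertions shared by non-reference
  species are not co-aligned against each other.
- The caller's density statistic ignores read-length variation inside a
  region (a footprint counts equally however much of it overlaps).
- Efficiency SEs assume independent replicates and small relative errors
  (first-order propagation).
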