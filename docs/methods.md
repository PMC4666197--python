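# Methods

This note documents the models and procedures implemented in `tcrseek`,
the assumptions they make, the defaults and why, and what the synthetic
benchmarks do and do not demonstrate about real data.

## Germline references and coordinates

A reference is a set of gene segments (V/D/J/C per chain) with two
annotations per V and J segment: the 0-based offset of the conserved
anchor codon (cysteine for V; the phenylalanine/tryptophan of the
[FW]-G-X-G motif for J) and a frame offset putting the recombined
transcript in frame. Anchors live in an explicit TSV sidecar rather than
being parsed from gapped alignment numbering: the format stays trivial and
download-free while preserving the standard CDR3 boundary convention.
Coordinates are 0-based with half-open intervals everywhere, and the CDR3
includes both anchor codons, so "a 45-nt CDR3" spans Cys through Phe/Trp
inclusive.

The fixture generator emulates the human TCR loci at a coarse level:
V segments of ~270–320 nt with the Cys anchor 15 nt from the 3′ end,
J segments of 45–60 nt, D segments of 10–16 nt, a 300-nt C segment. The J
anchor offset is 15 nt for beta and 24 nt for alpha — alpha J genes
contribute more sequence to the CDR3, which compensates for the alpha
locus having no D segment and keeps simulated alpha CDR3 lengths
realistic. Coding regions are generated stop-free in frame so that the
productivity of a simulated transcript is decided by its junctions, not by
the scaffold; segments are resampled until all same-type pairs are < 80 %
identical outside the anchors, so that segment assignment is well-posed.

## Junction model

Empirical repertoire-derived trimming/insertion frequencies are not
available in a reusable printed form, so the default model is a fully
specified stand-in chosen for realism of the resulting CDR3 length
distribution: per-end deletions ~ truncated geometric(p = 0.25) on 0..12
(mean ≈ 2.7 nt), per-junction insertion counts ~ truncated Poisson(λ = 4)
on 0..15, insertion bases uniform. All three distributions can be replaced
from a TSV. Beta transcripts draw V–D and D–J insertions independently;
alpha transcripts, lacking D, insert the rounded (half-up) mean of one V–D
draw and one D–J draw at their single V–J junction. With the fixture
reference these defaults give beta CDR3 lengths with a mode at 42–45 nt —
the canonical beta mode — and alpha slightly shorter. Segment usage is
uniform ("chosen randomly" is read literally; real gene-usage frequencies
are non-uniform, a documented simplification).

Deletion support is validated against single-end-trimmed segments (V, J);
D segments are trimmed at both ends and infeasible draws (d5 + d3 >
len(D)) are resampled with a bounded retry, allowing a fully trimmed D.
Productivity = in frame from the V frame offset through the C start with
no stop codon, plus an annotatable Cys…[FW] CDR3 at the stringent 20/20
alignment setting; rejection sampling keeps exactly the requested number
of productive transcripts and aborts if acceptance falls below 1 % (a
broken reference or model). Typical acceptance is ~25–30 %, dominated by
the 1-in-3 frame restoration and stop codons in the junction.

## The extractor

Matching is ungapped, seed-and-extend (8-mer seeds, maximal exact
extension, optional per-alignment mismatch budget, default 0; N never
matches). A V candidate must cover its Cys anchor codon; a J candidate its
[FW] anchor codon. Per chain the longest anchor-covering V and J matches
are chosen (ties: lexicographic segment name, then leftmost read
position); a call requires the V anchor strictly before the J anchor, the
two anchors in the same reading frame, and both match lengths at or above
the configured minima. The CDR3 is the anchor-to-anchor span including
both codons. Stop-containing calls are kept but flagged; a separate filter
removes them together with frameshifted entries, and a separate collapse
step merges nucleotide variants per amino-acid CDR3 (convergent
recombination). Clonotype identity is nucleotide-level at extraction.

Two deliberate design choices make the caller's behaviour analyzable:

* **Threshold-free candidate selection.** Which V/J (and which strand:
  both orientations are scored and the larger total match length wins,
  with deterministic tie-breaks) is decided *before* the minimum-alignment
  thresholds are applied. Consequently call sets are exactly nested as
  thresholds rise, and the full 19×19 parameter grid can be computed from
  a single extraction pass at the grid minimum by thresholding each call's
  recorded (V-length, J-length). Tests verify this equals per-cell
  extraction.
* **No indels.** The tunable parameters of interest are minimum alignment
  lengths and the control reads are error-free; a gapped aligner would add
  complexity without changing what the benchmark measures. For reads with
  sequencing errors a mismatch budget (≈1 per 25 nt) is available, with a
  correspondingly shorter seed.

Read preprocessing keeps reads strictly longer than 40 nt consisting of
standard (ACGTN) bases, and depth normalization is uniform subsampling
without replacement that refuses (rather than pads) too-shallow inputs.

## Controls and the operating-point benchmark

Positive controls are one error-free read per transcript with the CDR3
midpoint at the read midpoint (floor conventions; windows clipped inward
at transcript edges). At 50 nt this is the hard case: a 45-nt CDR3 leaves
2–3 nt of flank, so recovery is limited by junction trimming depth and by
CDR3s longer than the read — never recoverable, the structural sensitivity
ceiling.

The negative control replaces pooled TCR-negative cell-line libraries with
synthesized decoys in three modes: windows of unrecombined germline
segments, dinucleotide-shuffled segments, and chimeric reads. Chimeras
carry a short V-like fragment and a short J-like fragment (8–14 nt,
bracketing the caller's default 12-nt minimum — mimicking the short,
low-similarity TCR-like matches that cause real false positives). Half of
them order the fragments so anchor geometry can never be satisfied (hard
negatives for the geometry check); the other half are anchor-valid and in
frame but carry a stop codon planted inside the pseudo-CDR3, so they
trigger *nonproductive* bogus calls at low stringency while never
containing a productive CDR3. Fragment boundaries are mismatch-guarded so
the spurious alignment length equals the planted length. Every decoy read
is verified at generation: germline/shuffled reads must produce no call at
8/8; chimeric reads no productive call.

The optimizer scores every (minV, minJ) pair by truth-CDR3 recoveries on
the positive set and distinct bogus CDR3s on the negative set, normalizes
recovery by the grid maximum (relative sensitivity), and — since the
acceptable false-discovery level is binarized — selects, among cells at or
below a maximum bogus count (default 0), the highest-recovery pair,
breaking ties by minV+minJ, then minV, then minJ. On the packaged
benchmark (1,200 productive transcripts per chain, 10⁵ decoys: 60 %
germline / 20 % shuffled / 20 % chimeric) the zero-bogus selection
typically lands at a J threshold of 15 (one above the longest chimeric
fragment) and achieves chain-averaged relative sensitivity of ~95–98 %,
alpha paying almost nothing (its J segments contribute 27 nt to the CDR3)
and beta a few percent.

What this does *not* show: performance on real reads with sequencing
error, on transcriptome-scale negative diversity, or under non-uniform
gene usage. The decoy modes reproduce the adversarial *structure* of the
false-positive problem, not its genomic breadth.

## Detection model

Detection records come from expression-weighted simulations: transcripts
(TCR + random background) receive log-normal expression (σ = 1.5);
reads are uniform error-free fragments with per-transcript counts
proportional to transcript abundance (no length or positional bias — a
simplification of library construction). Records are eligible for
modelling only if the transcript is expressed (TPM > 0) and the read is
longer than the CDR3; ineligible records are kept in a side table. The
logistic model is fit by IRLS (statsmodels GLM) on a seeded random half,
with validation sensitivity/specificity reported at a 0.5 probability
cutoff on the other half. Depth enters as depth/10⁷ exactly as the
published coefficients are scaled; required-depth queries invert the
linear predictor in closed form and round up at 10⁷-read granularity.
Parameter recovery on self-simulated records (n = 50,000, covariates
spanning 0.1–10⁴ TPM, 10⁴–10⁸ reads, 50/76/101-nt reads, 30–60-nt CDR3s)
is within 10 % for every coefficient across seeds. The default benchmark
grid is scaled down (depths 10⁴–10⁶, 3 replicates) relative to a full
10⁴–10⁸ × 10 replicate design; coefficients refit at desk scale are
therefore illustrative, while the published set is shipped as a named
constant for the applied arithmetic.

The TIL converter assumes whole blood carries a TCR transcript fraction of
1.5×10⁻⁴ (≈150 TPM at ~1 kb transcripts), lymphocytes are 30 % of white
blood cells (midpoint of 20–40 %), and tumor-infiltrating lymphocytes
resemble peripheral ones — hence pure lymphocytes ≈ 5×10⁻⁴ (one transcript
in 2,000) and a 2 %-TIL tumor ≈ 1×10⁻⁵. The package standardizes on TPM =
transcript fraction × 10⁶.

## Sharing analytics

The α–β co-occurrence test counts distinct (α, β) amino-acid pairs present
in ≥ 2 individuals, where each individual contributes all pairwise
combinations of its chains (distinct pairs, no within-individual
multiplicity). The null permutes beta-repertoire ownership with alpha
fixed (permuting both is available behind a flag); the p value is the
plain proportion of ≥-observed null statistics, so its floor is
1/n_iterations (default 100). Calibration on independent-repertoire null
cohorts gives an approximately uniform p distribution (slightly
conservative due to ties, as expected for a discrete statistic).

Clustering is greedy and incremental: sequences sorted longest-first join
the first-founded cluster whose representative they match at ≥ 95 %
identity, else found a new one; sequences of length ≤ 5 are discarded.
Identity is matches over the shorter length under an N-terminal-anchored
ungapped comparison — for short, length-similar CDR3s this coincides with
a global identity, and it keeps the acceptance path free of an external
clustering binary; the divergence from that tool's internal definition is
the known trade-off. A 5-mer shared-word prefilter skips hopeless
comparisons; the member–representative identity bound is still enforced
exactly.

The pMHC test counts multi-individual clusters in which at least two
members also share a peptide-MHC, estimates by resampling (default 10⁶
pairs, vectorized over an individual×pMHC incidence matrix) the chance
that two random individuals share a pMHC, and multiplies that fraction by
the number of multi-individual clusters (Bonferroni-style, capped at 1).

## Numerical and engineering choices

* All randomness flows through explicit `numpy.random.Generator` objects;
  identical seeds give byte-identical artifacts (asserted for the pipeline).
* Grid results are exact integer counts; relative sensitivity is the only
  derived float.
* Degenerate inputs fail loudly: missing anchors, non-ACGT references,
  distributions not summing to 1 (tolerance 10⁻⁹), subsampling beyond
  depth, logistic separation, empty pMHC tables.
* The end-to-end pipeline defaults (10 V / 2 D / 6 J per chain, 1,000
  positives per chain, 10⁵ decoys, depths 10⁴–10⁶ with 3 replicates) are
  desk-scale choices that keep a full run in the low minutes on one core
  while preserving every structural feature of the full-scale design.

## Known limitations

No somatic hypermutation, allelic exclusion or thymic selection; uniform
segment usage; error-free control reads by default; single-end fragments
(paired ends are treated as independent reads, consistent with read-by-read
CDR3 calling); no D-segment assignment in output; no quality-guided error
correction or clonotype clustering of sequencing errors; Wald-style
uncertainty only for the logistic fit.
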