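# Methods

## The problem

mtDNA is a small circular genome present in hundreds to thousands of copies
per cell. Two practical complications dominate its analysis by short-read
sequencing: (1) linearizing the circle for alignment destroys evidence near
the chosen origin, and (2) nuclear insertions of mtDNA-derived sequence
(NUMTs) can masquerade as low-frequency heteroplasmies when sample
preparations contain nuclear DNA. `circmt` implements an analysis chain that
addresses both, and a generative model of the inputs so that every stage can
be checked by parameter recovery.

## Read model (simulator)

Fragments of fixed length (default 2 × read length = 500 bp) start uniformly
on the circle, so they wrap across the origin and carry the wrapped
sequence. Fragment counts are Poisson-distributed around
`depth · L / fragment_length`, giving coverage realistic counting noise.
Each planted variant is carried by a fragment independently with probability
equal to its allele fraction (fixed per variant by default; a Beta mode with
configurable concentration adds molecule-level dispersion). Substitution
errors are injected at a flat per-base rate after variant injection; base
qualities are a single high value because the caller thresholds on counts,
not qualities. Mate 1 is the first `read_len` bases of the fragment, mate 2
the reverse complement of the last `read_len`, so both strands are always
represented.

The default per-base error rate is 2×10⁻⁴, representing the effective
substitution error of quality-filtered modern short reads (≈Q37). The
generator treats depth as a free parameter with a 500× default, matching the
high-coverage regime the analysis is designed for.

The nuclear background is a random sequence (default 50 kb at 42% GC)
carrying NUMT copies: segments (default 4 × 800 bp) copied from random arcs
of the circle with substitutions at a configurable per-site divergence
(default 5%). Unpurified samples add nuclear fragments at their own depth;
purified samples contain mt fragments only. The mt and nuclear fragment
streams are seeded independently, so a purified and an unpurified run with
the same seed share an identical mt read stream and differ only by the
nuclear additions — a perfectly paired design.

What the simulator does **not** model: indels, GC or fragment-length bias,
platform-specific error spectra, PCR duplicates, linked heteroplasmies, or
mtDNA copy-number variation among cells. Passing recovery tests therefore
demonstrates correctness of the analysis logic under idealized sampling, not
robustness to every artifact of real libraries.

## Mapping and the rotate-and-patch rule

The mapper is k-mer seeded (k = 31, effectively unique in a 16 kb genome;
seeds at the start, middle and end of each orientation), ungapped and
substitution-only, scoring placements by Hamming distance with a mismatch
budget of 2% of the read length. Placement policy:

- `best_unique` (default): a read maps only to a *unique* minimum-mismatch
  placement; co-optimal ties are discarded rather than randomly assigned.
- `best_random`: random choice among co-optimal placements.
- `any_random`: random choice among **all** placements within the budget — a
  deliberately naive policy used as a negative control.

Mapping runs against the linearized mt reference **plus** the nuclear
background as a decoy. This is what real pipelines do by aligning to the
whole genome, and it is load-bearing twice: the sequencing copy-number
estimator needs nuclear coverage from the same alignment run, and NUMT-origin
reads place strictly better on their true nuclear locus than on the mt
circle, which is what keeps them out of the mt pileup. At the default 5%
NUMT divergence a 250 bp NUMT read carries ~12.5 mismatches against mt —
outside the mismatch budget even without a decoy.

Reads spanning the linear end of the circular reference cannot be placed and
come back unmapped. Consequently coverage tapers over the terminal
`read_len − 1` positions of the linearization, and calling there is
unreliable *on that alignment*. The caller therefore excludes columns within
one read length of a linear end (`edge_exclusion`, auto-set to the longest
contributing read minus one). The repair is the second alignment against a
reference rotated by 8,000 bp: positions 1–500 and 15,800–16,299 (1-based,
closed) are patched from the rotated alignment after remapping
`orig = ((rot − 1 + rotation) mod L) + 1`, while every other position is
taken exclusively from the primary alignment. The patch windows comfortably
contain the excluded edge zones, and the rotated alignment's own edge zone
(around position 8,000) lies outside the windows, so the patched call set
has no blind spots.

## Variant calling

Pileups are built after downsampling to at most 5 reads per (start, strand);
excess reads are dropped in read-id order, which is deterministic without
seed plumbing. The caller emits one call per (position, alternate allele)
passing all thresholds — multiple alternates at one column yield multiple
calls — with defaults:

| parameter            | default | rationale                                        |
|----------------------|---------|--------------------------------------------------|
| min_alt_reads        | 3       | floor against isolated errors                    |
| min_allele_fraction  | 0.005   | heteroplasmy detection floor (0.5%)              |
| min_depth            | 20      | avoids calls from sparse columns                 |
| max_reads_per_start  | 5       | caps library/start-position duplicates           |
| min_strand_support   | 1/strand when both strands covered | minimal strand-bias guard |
| edge_exclusion       | auto (max read length − 1) | linearization-edge artifact mask |

At 500× depth and error 2×10⁻⁴ the expected number of false calls per
genome is ≈0.3 (binomial tail across 3 alternates × L positions, with the
strand rule); at error 10⁻³ it rises to ≈25, which the specificity test
bounds with the same closed-form oracle. Sensitivity for a variant at
fraction *f* and depth *d* is the binomial probability of drawing ≥3 alt
reads that do not all land on one strand; at *f* = 0.05, *d* = 500× this is
indistinguishable from 1.

Calls are keyed by (position, alt). The same key called in every tissue of
an animal is *germline*, anything else *somatic*; with two tissues this is
the shared-between-tissues rule, and the strict exact-key reading is used
because no tolerance on allele fraction is defensible without a model of
between-tissue drift.

## Rate and load

Rate counts distinct mutated positions over L; multi-allelic positions count
once. Load is read-weighted by default — the sum of alternate-supporting
reads over total aligned mt bases — because only a read-weighted numerator
makes load measure the *spread* of mutations: a near-fixed germline variant
contributes ~90× more load than a 1% somatic variant at equal depth while
contributing identically to rate. A record-weighted numerator
(`numerator="events"`) is available for comparison. The load denominator is
the total mt-aligned bases of the primary alignment; patched calls carry
alt/depth counts from the rotated alignment, a <3% inconsistency at the
default window sizes.

## qPCR model and copy number

Cq for template amount N and per-cycle amplification factor f is
`log_f(threshold / N)` plus Gaussian well noise. Ten-fold dilution series
(four quintuplicate levels by default) are fit by OLS of Cq on log10
concentration; `efficiency = −1 + 10^(−1/slope)`. The copy-number formula
exponentiates the **amplification factor** `f = efficiency + 1`, not the
efficiency itself: a perfect assay has efficiency 1 and 1^Cq is degenerate,
so the factor form (the standard efficiency-corrected ΔCq method) is the
only computable reading. At zero noise the round trip
simulate → fit → copy number returns the input mt:nuclear ratio exactly,
for any pair of amplification factors.

Error budget: because the formula raises f̂ to the absolute Cq, a relative
slope error δ inflates the estimate by ≈ exp(Cq · ln10 · δ/|slope|). With
the default design (calibration well noise 0.1 cycles over 4×5 wells,
slope SE ≈ 0.02) and the default Cq scale — calibrator template set so the
single-copy nuclear assay reads Cq ≈ 17 — the standard-curve contribution is
≈7% and triplicate sample wells at 0.15 cycles contribute ≈8%, giving a
median recovery error under 10% for the qPCR estimator. This sensitivity to
the absolute Cq scale is intrinsic to the exponentiated-factor formula and
is the main caveat of the method.

The sequencing estimator divides mean per-base mt depth by mean per-base
nuclear depth from the same alignment run, optionally scaled by a nuclear
ploidy factor (default 1, i.e. copies per haploid genome equivalent; set 2
for per-diploid-cell units).

## Experiments

**Concordance** (default panel): 12 samples with true ratios log-uniform in
[100, 3000]; sequencing at 50× mt depth with nuclear depth 50/ratio over a
1 Mb nuclear decoy, so nuclear fragment counts (≈30–1000 per sample) are the
dominant, realistic noise source of the coverage estimator; qPCR as above
with one standard curve per panel. Both estimators are computed per sample
and compared by Pearson correlation and relative recovery error.

**Purification**: 6 animals sharing one reference and background, somatic
burdens spread from 60 to 260 positions (mimicking between-animal variation
in mutator mice), 500× mt depth, unpurified runs adding 30× nuclear
background with 4 × 800 bp NUMTs at 5% divergence. Because the mt stream is
shared within an animal and the default policy excludes NUMT reads, the
purified and unpurified call sets are *identical* — the between-condition
correlation is exactly 1 and the paired difference exactly 0, reported as
t = 0, p = 1. The negative control (`any_random` placement, 0.5% divergence)
shows this equivalence is a property of the placement policy, not of absent
contamination: divergent NUMT reads then reach the mt pileup and produce
robust false calls at NUMT divergent sites in every animal. Since those
sites are shared across animals, the rate shifts by a near-constant and its
correlation may remain ≈1; the degradation shows reliably in the *load*
correlation, whose contaminating alt-read counts carry per-animal sampling
noise, and in the per-animal false-call excess.

Group summaries report mean ± SEM (sd/√n) and paired two-sided t statistics
on within-animal contrasts; mixed-model ANOVA machinery for real animal
cohorts is out of scope.

## Numerical and engineering choices

- Internal coordinates are 0-based half-open; all emitted coordinates (SAM,
  VCF, variant tables) are 1-based per those standards.
- All randomness flows through `numpy` generators seeded from
  `SeedSequence([seed, stream_salt])`; identical seeds reproduce
  byte-identical FASTQ, truth, Cq, and experiment TSV outputs.
- Ties and ambiguities are resolved deterministically everywhere except the
  explicitly random placement policies, which require a caller-supplied
  generator.
- Degenerate inputs raise `ValueError` early: rotation outside (0, L),
  positions outside [1, L], non-positive denominators, single-tissue
  classification, fewer than 3 dilutions/samples, zero-variance correlation
  inputs.
- SAM output is minimal but standard (parses with pysam/samtools); only
  ungapped `<n>M` records are representable on re-import. VCF 4.2 output
  round-trips bit-exactly.
- Problem sizes of the shipped experiment defaults (panel depths, decoy
  lengths, replicate counts) are the package's chosen desk-scale operating
  points; all are config fields.

## Known limitations

- Substitution-only: indel heteroplasmies are invisible to the mapper, the
  caller, and the simulator alike.
- The mapper's seed heuristic can miss a placement whose three sampled
  k-mers all overlap mismatches; at the default error and divergence
  settings this is negligible, but heavily divergent references should be
  mapped externally and imported as SAM.
- The threshold caller has no base-quality model; with quality-degraded real
  data its false-positive rate is governed entirely by the count thresholds.
- The qPCR estimator's accuracy depends on the absolute Cq scale as
  described above; comparisons across instruments/scales should rely on the
  concordance analysis rather than absolute agreement.
- Germline/somatic classification assumes planted truth positions are
  distinct and tissues are sequenced deeply enough that a germline variant
  is not missed in one tissue; a missed germline call demotes the variant to
  somatic in the other tissue.
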