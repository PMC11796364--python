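# Methods

## The dual-barcode model

Each plasmid in the library carries two adjacent identifiers inside one
PCR amplicon: an 11-nt region with exactly one substitution relative to
a fixed reference (the *SNP barcode*; 11 positions × 3 alternative
bases = 33 sequences) and a fully random 10-nt region (the *10N
barcode*; 4¹⁰ = 1,048,576 sequences). Jointly they span
33 × 1,048,576 = 34,603,008 distinct barcodes, or 8,650,752 if one 10N
position is allowed to match — the space within which two barcodes
still differ by more than one random-region nucleotide.

Both statistics that drive the design assume barcodes are drawn
independently and uniformly:

* **SNP collision.** The probability that at least two of k plasmids
  in one cell share a SNP barcode is the birthday probability
  `1 − ∏_{i=0}^{k−1}(S−i)/S` over S = 33, defined as "at least one pair
  matches". This definition reproduces 3/9/17/27/38% for k = 2…6 after
  rounding. Uniformity over the 33 sequences is an assumption about
  library construction; the nucleotide-frequency audit
  (`curation.nucleotide_frequency_audit`) is the empirical check.
* **10N enumeration accuracy.** The estimator "maximum number of
  distinct bases at any random-region position" equals k exactly when
  some position shows all k members with k different bases. Per
  position that has probability `d(k)/4^k` with `d(k) = 4!/(4−k)!`
  (ordered k-tuples, all distinct), so over L = 10 independent
  positions the accuracy is `1 − (1 − d(k)/4^k)^L`: 1, 0.999999,
  0.990905 and 0.626337 for k = 1…4. (The k = 4 value is the exact
  closed form `1 − (230/256)^... = 1 − (1 − 24/256)^10 = 0.6263`, which
  prints as 63%.) The estimator cannot exceed 4, so k ≥ 5 raises a
  saturation error rather than returning a number.
* **Sanger ceiling.** A secondary peak is callable only above a
  fractional-intensity threshold t, so at most `⌊1/t⌋` equally abundant
  variants fit above it: 6 at the default t = 0.15. The practical
  ceiling quoted for this chemistry is "5–6"; the package exposes t and
  returns the arithmetic value 6, leaving any noise-derating to the
  caller.

Every closed form has a Monte-Carlo twin
(`barcode_model.monte_carlo_accuracy`, one `numpy` generator per call,
single integer seed) used as an independent cross-check in the tests
and the acceptance script, never as the implementation.

## Trace calling

Traces are tabular profiles — per-position fractions over (A, C, G, T)
summing to 1 ± 0.01 — on the sequencing strand, with position 0 at the
start of the upstream anchor. AB1 signal processing and base calling
are upstream of this package; an IUPAC ambiguity string may be supplied
instead and is expanded to equal fractions. Callers use fractions only,
so uniform rescaling of raw intensities cannot change a call.

One threshold (default 0.15) is applied in both barcode regions: the
chemistry producing the peaks is the same, and a single exposed
parameter is easier to calibrate than two. Members of a colony are
assumed equally represented (equal plasmid copy number); the simulator
can render unequal Dirichlet-style weights, but the callers make no
abundance correction.

Combination logic: the 10N call decides the 1–3 range (it is the more
accurate rule there); a saturated 10N call (≥ 4) is resolved by the SNP
count as `max(4, snp_count)`. Two edge cases are flagged rather than
guessed: a silent SNP region (`empty_or_deleted_barcode`, e.g. empty
vector background) leaves the 10N call standing, and a SNP count ≥ 4
against an unsaturated 10N call returns the SNP count with
`low_confidence` — on noise-free traces the SNP count is a lower bound
on multiplicity, since every intact molecule contributes exactly one
SNP. Disagreements of more than one inside the 1–3 range also flag
`low_confidence` while keeping the 10N value.

Deletion-carrying members shift every base downstream of the deletion,
so the otherwise invariant downstream-anchor positions acquire
secondary peaks; `detect_degradation` flags any anchor position with a
non-anchor base above threshold and reports the mean off-anchor
fraction as an estimate of the frame-shifted share. Mixtures of intact
and frame-shifted members are flagged, not auto-resolved — how such
colonies should be adjudicated is an analyst's decision.

## NGS curation

1. **Quality filter.** Reads with arithmetic-mean Phred score < 35 are
   removed. The mean is taken in score space, not error-probability
   space, because "average base-calling quality" conventionally means
   the former; the threshold is a parameter.
2. **Extraction, counting, coverage.** The barcode is the sequence
   between the two anchors (exact match, then a one-mismatch fallback);
   lengths down to 3 nt below design length are accepted, matching the
   library's small-deletion class. Distinct sequences under 200×
   coverage are dropped as PCR/sequencing background.
3. **Cross-library curation.** A sequence present identically in
   another library is `identical`; otherwise, within unit-cost edit
   distance 1 of another library's sequence, `near_identical` (for
   equal lengths this is exactly Hamming ≤ 1; for lengths differing by
   one, exactly a single indel — the documented choice for comparing
   the deletion classes). `identical` takes precedence so the
   categories are disjoint and `uncertain = identical +
   near_identical` is additive per library and in total. Comparisons
   are made *across* libraries only; an optional within-library
   collapse exists but is off by default, following the stated
   cross-library definition of "uncertain". The reported range
   `(total − uncertain, total)` brackets the most probable number of
   distinct plasmids per library.

The near-identical scan uses `edlib` with an early cut-off at the
distance bound; the test suite checks it against a brute-force
Levenshtein DP over all pairs.

## The simulator

`simulate` generates what the laboratory produces, with known truth:

* **Library** — SNPs uniform over the 33 combinations, 10N iid
  uniform; deletion classes at fractions 0.20 (> 3 nt lost) and 0.125
  (1–3 nt), the midpoints of the observed 15–25% and 10–15% ranges.
  Deletions are contiguous, position-uniform; large deletions span
  4–12 nt (the class is defined by "> 3 nt", its length profile is not
  otherwise constrained).
* **Colonies** — multiplicity k is drawn from a configurable
  distribution (default ≈ 65% mono, a mild-heat-shock-like profile;
  the distribution is an experimental outcome, hence an input, not a
  model), then k *distinct* molecules uniformly without replacement.
* **Traces** — equal-weight averages of member base indicators over
  the amplicon, optionally Dirichlet/explicit weights, plus truncated
  Gaussian noise renormalised per position. Deleted members are padded
  with a fixed backbone-context sequence, which is what corrupts the
  anchor window. Peak-shape/electropherogram physics is not modelled.
* **Reads** — per molecule, depth is Poisson(mean 500×) or fixed; each
  read takes PCR substitutions as a single
  `Binomial(cycles × length, 8 × 10⁻⁶)` draw (the expected variant load
  of a branching lineage at these rates, at a fraction of the cost —
  lineage structure only matters when single PCR duplications must be
  traced), sequencing substitutions at 0.7% per base (inside the
  quoted 0.2–1.2% window), and a quality string from a two-class
  mixture (40% of reads at mean Q30, the rest at Q40, SD 2) — only the
  mean-Q threshold matters downstream, so a richer quality model would
  add parameters without adding test power. Index hopping reassigns
  single reads to a uniformly chosen other library (default 1%, inside
  the quoted 0.2–6%); cross-well contamination injects whole foreign
  templates amplified to full depth (default rate 0.01 events per pool
  molecule), because a contaminating template that enters the PCR early
  is amplified like a native one — this is the artifact class that
  survives the coverage filter and must be caught by cross-library
  curation, whereas hopped single reads fall below 200× and vanish at
  step 2.

What passing simulated tests does **not** show: real traces have
correlated, context-dependent noise and dye blobs rather than iid
Gaussian perturbations; real quality strings degrade along the read;
PCR errors are lineage-correlated (an early error is shared by many
reads); plasmid copy number within a colony is not exactly equal; and
real multiplicity distributions are not known in advance. The
round-trip results therefore validate the *logic and its statistics*,
not instrument-level robustness.

## Numerical and interface choices

* Coordinates 0-based half-open everywhere; traces and reads on the
  sequencing strand only (colony PCR fixes orientation).
* `max_detectable_snps` adds 1e-9 before flooring so binary-float
  thresholds like 0.1 give 10, not 9.
* Trace row sums are validated to 1 ± 0.01; `from_intensities`
  normalises instead of validating.
* All generators draw from a caller-supplied or config-seeded
  `numpy.random.default_rng`; identical seeds give bit-identical
  libraries, colonies, traces and FASTQ files. Run logs carry
  parameters/seed/version but no timestamp, so CLI reruns are
  byte-identical.
* Problem sizes in the test suite: 100,000 Monte-Carlo replicates for
  the probability cross-checks; 10,000 colonies per k for the 10N
  round trip (disjoint library slices so colonies are iid); 1,000
  colonies for the mono-fraction and k = 4 recovery checks; 3 × 30
  molecules at 250× for the error-free NGS round trip; ≤ 500 sequences
  for the brute-force curation oracle. All statistical comparisons use
  3 binomial standard errors.

## Known limitations

* No phasing: the caller reports how many plasmids a colony holds, not
  which SNP travels with which 10N sequence.
* The SNP caller assumes the configured reference; a library built on
  a different backbone needs its reference and anchors in the config
  (there is no universal default worth trusting).
* Colonies mixing intact and frame-shifted members are flagged
  (`degraded_frameshift`) but their counts are taken from the composite
  trace as-is; with heavy degradation the SNP region inherits shifted
  10N bases and the SNP count becomes an overestimate — the flag, not
  the number, is the signal to re-examine such colonies.
* Demultiplexing, paired-end handling and instrument QC are out of
  scope; inputs are one FASTQ per library.
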