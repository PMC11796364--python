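# plasmux

Dual-barcode enumeration of **plasmid multiplicity of transformation** —
how many distinct plasmid molecules a single cell took up during one
transformation event.

When a cell library is built by electroporating a barcoded plasmid pool
into yeast, individual cells frequently take up several distinct
plasmids, which destroys the one-genotype-per-cell assumption that
library screens rely on. `plasmux` implements a genotyping strategy
that measures this multiplicity directly, per colony, from a single
colony-PCR product. Each plasmid carries a *dual barcode*:

* an 11-nt **SNP region** with exactly one substitution per molecule —
  11 positions × 3 alternative bases = 33 possible sequences, enough
  for precise variant calling in a mixed Sanger trace;
* a fully random 10-nt region (**10N**) with 4¹⁰ = 1,048,576
  sequences, enough that two co-transformed plasmids essentially never
  match.

The package provides:

* **`plasmux.barcode_model`** — the design's closed-form statistics.
  The probability that at least two of *k* co-transformed plasmids share
  a SNP barcode is the birthday-collision probability over S = 33
  uniform outcomes, `1 − ∏_{i=0}^{k−1} (S−i)/S` (3%, 9%, 17%, 27%, 38%
  for k = 2…6). The 10N read-out takes, over its L = 10 positions, the
  maximum number of distinct bases; for k iid uniform regions it equals
  k with probability `1 − (1 − d(k)/4^k)^L`, `d(k) = 4!/(4−k)!` —
  > 99% for k ≤ 3 and ≈ 63% for k = 4, where it saturates. A seeded
  Monte-Carlo estimator cross-checks every closed form.
* **`plasmux.sanger`** — the colony caller. Composite trace profiles
  (per-position A/C/G/T intensity fractions) are scored with a 15%
  calling threshold: the SNP rule counts non-reference bases in the SNP
  region (ceiling `⌊1/0.15⌋ = 6`), the 10N rule counts distinct bases
  per random position, and the combination logic lets the 10N call
  decide the 1–3 range while the SNP call resolves saturated (≥ 4)
  colonies. Frame-shifted mixture members (barcode deletions) are
  detected from secondary peaks in the downstream anchor.
* **`plasmux.curation`** — the NGS arm. Per-condition amplicon FASTQ
  files are curated in three steps: drop reads with mean Phred < Q35;
  extract the barcode between its two anchors and drop sequences under
  200× coverage; flag sequences found identically — or within 1 nt
  (substitution or indel) — in another library as *uncertain*
  (index hopping, cross-well contamination, PCR/sequencing error).
  Each library is then reported as a most-probable-plasmid-count range
  `(total − uncertain, total)`, plus a per-position nucleotide
  frequency audit of the barcode region.
* **`plasmux.simulate`** — a generator for the whole experiment:
  barcoded libraries (with the observed 1–3-nt and >3-nt deletion
  classes), colonies with a configurable multiplicity distribution,
  noise-free or noisy composite traces, and FASTQ reads with PCR error,
  sequencing error, a two-class quality mixture, index hopping and
  cross-well contamination — so every claim is testable on synthetic
  data with a known truth.

## Worked example

Design statistics (`plasmux probabilities`):

```
k	snp_collision	tenN_accuracy
1	0.000000	1.000000
2	0.030303	0.999999
3	0.089073	0.990905
4	0.171884	0.626337
5	0.272262	NA
6	0.382525	NA
```

Column two is the probability that k plasmids share a SNP barcode
(3%…38% for k = 2…6): the chance of an undercount by the SNP rule.
Column three is the probability the 10N rule counts k plasmids exactly;
`NA` marks saturation (five plasmids can never show five bases).

A full synthetic experiment, called and curated:

```sh
plasmux simulate --seed 5 --outdir sim/
plasmux call-sanger --traces sim/traces.tsv --out calls.tsv
plasmux curate-ngs --libraries sim/reads_cond1.fastq \
    --libraries sim/reads_cond2.fastq --libraries sim/reads_cond3.fastq \
    --out curation.tsv
```

`calls.tsv` holds one row per colony:

```
colony_id	snp_count	tenN_count	final_count	flags
colony00000	3	4	4	degraded_frameshift,saturated
colony00003	1	1	1	degraded_frameshift
```

colony00000 shows a position with all four bases (10N saturated at ≥ 4)
and three SNPs, so it carried at least four plasmids; colony00003 is
mono-transformed. `degraded_frameshift` marks traces in which a
deletion-carrying member corrupts the downstream anchor — with default
settings roughly a third of library molecules carry deletions, as in
the real library.

`curation.tsv` mirrors the per-library NGS summary:

```
library	total	identical	near_identical	uncertain	range_low	range_high
reads_cond1	28	0	0	0	28	28
reads_cond2	30	1	0	1	29	30
reads_cond3	35	1	0	1	34	35
TOTAL	93	2	0	2	91	93
```

Here two cross-well contamination events placed a barcode in a second
condition; both copies are flagged `identical`, and each affected
library's most probable plasmid count becomes a range (e.g. 29–30)
rather than a single number.

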