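# Methods

## Problem and model

ABO phenotype (O, A, B, AB) is determined by the diploid pair of alleles at
the ABO glycosyltransferase locus. `abotype` classifies a sample from the
observed base/deletion fractions at five diagnostic positions in exons 6
and 7 (c.261, c.796, c.802, c.803, c.805). Each allele class — O1, O2, O3,
A, B — has a fixed symbol at each position; a diploid genotype's expected
state is the per-position union of its two allele patterns. All 15 unordered
genotypes yield pairwise-distinct five-position state vectors (asserted
exhaustively in the tests), so exact set-equality matching is a well-defined
classifier. On the reduced 3-SNV panel (c.261/c.796/c.803) only 6 rules over
{O, A, B} exist and O2/O3 carriers collapse onto A — the known failure mode
that motivates the five-position panel.

Two modelling simplifications are deliberate:

* **c.804dupG is read as the base at offset 431.** The O3-defining
  duplication shifts the downstream readout so position 431 reads G instead
  of T; the knowledge base, the simulator and the classifier all treat it as
  a substitution at offset 431 rather than as a literal insertion event.
  Classification depends only on the observed base at that column.
* **Genotype labels are unordered pairs.** The package prints one fixed
  convention: non-O letters first (A before B), then O subtypes in numeric
  order — `AO`, `BO`, `AB`, `OO`; `AO1`, `BO2`, `O1O2`. In 3-SNV mode no
  subtype information exists, so the extended genotype equals the simple
  genotype.

## Position calling and sample status

A position with pooled depth *d* and symbol fractions *f* is called as the
set `{s : f(s) >= het_threshold}` with `het_threshold = 0.20` (inclusive: an
exact 80:20 split is still a heterozygote — "up to 80:20" is read as 80:20
remaining classifiable). One passing symbol is homozygous, two heterozygous,
three or more ambiguous. Depth below `min_depth = 20` blocks the call.

Sample status is the total function {ok, low_coverage, unknown}: any
low-coverage position flags the sample `low_coverage` (precedence over
`unknown`, because the remedy — repeat testing — differs from manual
review); otherwise any ambiguous position, or a state vector matching no
rule, yields `unknown` with the fraction audit trail retained; otherwise the
unique matching rule supplies phenotype/genotype/extended genotype.

The depth that gates a sample, and the read count behind its reliability
tier (Very Low <20, Low 20–49, Moderate 50–499, Robust ≥500), is the
**minimum pileup depth across the panel's diagnostic positions** for the
mode in use. A per-position minimum is the conservative choice when the two
exon amplicons have unequal coverage; it is configurable via `min_depth`.
The unnamed 50–499 band is labelled Moderate.

## Alignment

Reads are aligned to each exon reference with local affine-gap alignment
(match +2, mismatch −4, a gap of length *k* costs −4 − 2*k*), implemented on
Bio.Align.PairwiseAligner; the references are ≤ ~700 bp so full dynamic
programming is cheap and deterministic, and the test suite checks score
equality against an independent brute-force Gotoh DP oracle on hundreds of
random pairs. After traceback, indels are shifted left within homopolymer
runs (the normalisation convention of standard variant callers), which pins
the O1 deletion to the diagnostic exon 6 column; the synthetic reference
generator additionally forbids a homopolymer around that column so the gap
placement is score-unique.

An alignment is accepted if its identity (matches / alignment columns,
gap columns included) is ≥ `min_identity = 0.7` — tolerant of ~10–15 %
long-read error while rejecting junk — and it covers ≥ `min_window_cov =
0.9` of the exon's diagnostic window, defined as the span from the first to
the last diagnostic offset padded by 10 bp (exon 6: 12–32, exon 7: 412–441).
Each read is aligned to both exon references and every passing hit is kept;
single-exon amplicon reads pass on exactly one reference, while a read
genuinely spanning both exons would legitimately contribute to both pileups.
A plain-text SAM export provides the seam for substituting an external
mapper.

In the pileup, each accepted read contributes exactly one symbol per
reference position within its aligned extent — its base on aligned columns,
`DEL` on reference positions skipped by a deletion; insertions create no
columns. Deletion evidence therefore counts toward depth, as it must for
the O1O1 homozygote (100 % DEL at c.261).

## Read simulator

The simulator emulates demultiplexed, quality-filtered per-exon amplicon
reads from one diploid sample: each read is a contiguous substring of one
allele haplotype (default full-span, `min_span = max_span = 1.0`), with
i.i.d. per-base errors. Defaults — 100 reads per exon, 5 % substitutions,
2 % insertions, 2 % deletions — approximate post-filter long-read amplicon
data. Substitutions draw uniformly from the three alternative bases;
insertions duplicate the current base and deletions drop it, biasing indels
toward homopolymer events as nanopore chemistry does. The allele-of-origin
split is the deterministic rounding of `n_reads × allele_ratio` rather than
a binomial draw, so expected heterozygous fractions are exact; read names
encode the allele of origin for truth tracking, and base qualities are a
constant Q20 placeholder (filtering uses mean quality only).

What the simulator does **not** model: raw pre-filter read populations,
realistic per-base quality, chimeric or barcode-hopping reads, strand
biases, coverage imbalance between alleles beyond the fixed mixing ratio,
and rare alleles outside the five-position panel. Passing tests therefore
demonstrate the correctness of the computational pipeline under its stated
error model, not the wet-lab performance of an assay on human samples;
cohort-level concordance figures require real data and are out of scope.

## Numerical and degenerate-input choices

* Fractions are exact ratios of small integer counts; the ≥ threshold
  comparison at 0.20 is exact for count data (20/100 passes, 19/100 fails).
* Zero-depth positions carry empty fraction maps and depth 0, and gate the
  sample as low-coverage; an exon with no FASTQ behaves the same way.
* Alignment tie-breaks are fixed by the aligner's deterministic traceback
  plus left-alignment, so identical inputs give byte-identical outputs; run
  logs omit timestamps under `--no-timestamps` for byte-level comparisons.
* Synthetic references default to 135 bp (exon 6) and 691 bp (exon 7),
  mimicking the real exon sizes; lengths are configurable and validated
  against the diagnostic offsets.
* Concordance metrics are one-vs-rest per phenotype; ratios with empty
  denominators and the accuracy of an empty evaluation set are NaN rather
  than 0, and non-ok calls or samples missing from the truth table are
  excluded and counted.

## Test scale

End-to-end checks run all 15 genotypes × 5 seeds at 100 reads per exon with
the default error model (75 samples, ~2 minutes on one CPU); the boundary
scans in `scripts/acceptance.py` use 1–30 zero-error reads and a 50-point
allele-balance sweep at depth 100. These sizes exercise every rule and both
boundaries while keeping the suite quick.

## Known limitations

Rare ABO alleles outside the five-position panel (including A1/A2
subtyping) are not detectable and surface as `unknown` or as the nearest
common genotype, mirroring the clinical workflow's manual-review path. The
80:20 rule and 20× gate are deliberately conservative; lowering either is
possible through configuration but shifts errors from "flagged" to "wrong".
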