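# Methods

## The assay and its model

Restriction-tag DGE counts transcripts by a single 21-mer per molecule: the
bead-bound 3' cDNA fragment is cut by NlaIII at `CATG` and released 17 bp
downstream by MmeI, so the sequenced tag is the `CATG`+17 window at the
3'-most NlaIII site of the transcript.  Expression is the tag's copy number
in the library.  Two consequences shape the whole analysis:

- a transcript without a CATG site followed by 17 bases is invisible to the
  assay, whatever its abundance;
- a tag shared by several transcripts cannot be attributed and must be
  dropped from counting (it is still accounted for in the mapping report).

The *virtual index* deliberately holds **all** CATG+17 tags of each
transcript, not only the 3'-most one: incomplete digestion and internal
priming produce upstream tags in real libraries, and indexing every site
lets them map.  The simulator, by contrast, emits mostly 3'-most tags — the
same asymmetry a real experiment has, which leaves realistic unused
reference tags in the index.

Antisense tags are produced by running the identical extractor on the
reverse complement of each transcript and are stored in the same map with a
strand label, so observed-tag lookup is a single hash probe with no
reverse-complementing at query time, and strand symmetry is directly
testable (reverse-complementing every input swaps the sense and antisense
tag sets exactly).

Coordinates are 0-based; offsets point at the first base of `CATG` on the
indexed strand.  A tag occurring at several offsets of one gene is one
distinct tag and stays unambiguous — ambiguity is defined across genes.

## Tag cleaning

Filters are applied per distinct tag, in order: tags containing `N`;
adaptor/empty entries; low-complexity tags; copy number < 2.  Each tag is
charged to the first rule it trips, so the ledger partitions the removed
mass and `raw_total = clean_total + removed_total` holds exactly on every
input (this is asserted, not assumed).  Details and open choices:

- *Adaptor recognition.*  In read mode, a read with no `CATG` after the
  adaptor prefix (or too short to supply 17 bases after it) never yields a
  tag and is tallied as adaptor/empty.  In tag-table mode no read context
  exists; a tag not beginning with `CATG` is classified adaptor/empty
  (configurable via `require_catg_prefix`).  Both mechanisms feed the same
  ledger row.
- *Low complexity* has no standard definition in tag QC; here a tag is
  low-complexity when one nucleotide occupies ≥ 90 % of its 21 positions
  (i.e. ≥ 19 of 21).  The threshold is configurable and the rule can be
  disabled (`low_complexity_fraction=None`); its removals are ledgered
  separately so the rule's effect is always visible.
- *Singletons* (copy number < 2) are removed as presumptive sequencing
  errors; with per-base error rate e, an erroneous copy of an abundant tag
  is almost always unique, so this filter removes most error mass at the
  cost of genuinely rare tags.
- Reported percentages are rounded half-away-from-zero to two decimals;
  internal arithmetic is full precision.

## Mapping

Exact hash lookup first; only tags with no exact hit are compared against
their 63 single-substitution neighbors (substitution only — tags are fixed
length, so indels cannot occur).  Neighbors are generated at all 21
positions, including the `CATG` anchor, because a sequencing error can hit
any base of the observed tag.  Consequences of tier priority: a tag matching
one gene perfectly and a second gene at distance 1 is *unambiguous* — the
mismatch candidate is discarded before multiplicity is assessed.  When the
winning tier spans both strands the assignment is labeled sense (the
conservative choice for an assay whose signal is predominantly sense) and
the event is counted in a diagnostic both-strand tally so no information is
lost.  Copy numbers never influence mapping, only downstream counting.

The mapping summary reports, for each tier × strand × multiplicity category
and six aggregate rows, the number of distinct genes receiving ≥ 1 tag and
its percentage of the reference gene count.  Aggregates are unions of gene
sets, never sums, so genes reached through several categories are not
double-counted.

## Quantification and saturation

count(g) sums copy numbers of unambiguous *sense* assignments of g; TPM(g) =
10^6 · count(g)/N with N the library's total clean tag count.  The
denominator is configurable to unambiguous-only counts because both readings
of "per million clean tags" exist in practice; the default is the full clean
total.  Antisense unambiguous counts are tabulated in a parallel column for
reporting and never enter TPM or the DE test.

Saturation curves subsample the copy-expanded library without replacement:
one shuffle per seed, prefixes taken at each grid size, so subsamples are
nested and monotonicity of the detected-gene count is exact rather than
statistical.  A gene is "detected" at ≥ 1 unambiguously mapped tag on either
strand.

## The two-library test

With x tags of a gene among N1, the count y among N2 has predictive
distribution

    p(y|x) = (N2/N1)^y (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) ),

the negative-binomial form obtained by integrating the Poisson rate out
under a flat prior (equivalently NB(x+1, N1/(N1+N2)) — used as an
independent cross-check in the tests, never as the implementation).  The
exponent on the bracket is essential: without it the pmf does not normalize;
normalization to 1e-9 is unit-tested.

Two-sided p-value: p = 2·min(S, 1−S), S = Σ_{i=0..y} p(i|x), capped into
(0,1].  This branch convention is *exactly* symmetric under exchanging the
libraries because Σ_{i≤y} p(i|x; N1,N2) + Σ_{i≤x} p(i|y; N2,N1) = 1 (a
regularized incomplete-beta identity), and it gives p = 1 when x = y at
equal depths.  Numerically, p(i|x) is evaluated in log space (gammaln); when
S > 1/2 the complement is obtained by summing the strict upper tail directly
rather than by subtraction, which preserves ~1e-10 relative accuracy against
an exact-rational oracle for x, y ≤ 100.

Calling rule: BH-FDR ≤ 0.001 together with |log2(TPM2/TPM1)| ≥ 1.  Genes
with x = y = 0 cannot inform the comparison and are excluded; the
multiple-testing family is the tested set.  TPM values are floored at a
pseudo-TPM (default 0.001) before the ratio so genes detected in only one
library get large finite ratios instead of infinities.  The FDR procedure is
Benjamini–Hochberg (via statsmodels); no dispersion modeling is attempted —
the assay pools replicates per condition before sequencing, and the test is
exactly the classical two-library comparison, not a replicate-aware model.

## Enrichment and qPCR

Term enrichment is the upper hypergeometric tail P(X ≥ k) (scipy, checked
against exhaustive enumeration for backgrounds ≤ 12), with BH q-values
across the testable terms; terms empty after background intersection are
dropped before multiple testing.  Annotations are taken as given — no
ontology propagation.  The background must be supplied explicitly (the
pipeline uses the tested-gene universe of the comparison).

qPCR analysis is the standard 2^-ΔΔCt: technical replicates are averaged
per gene × condition before differencing, amplification efficiency is fixed
at 2, and the calibrator condition has fold 1 by construction.  Concordance
with DGE is sign agreement of log2 fold vs log2 ratio.

## The synthetic study

The generator emulates the study design this pipeline targets: a control
plus two stress conditions, with defaults chosen as a desk-scale version of
a real tag-sequencing experiment:

| parameter | default | rationale |
|---|---|---|
| n_genes | 2,000 | desk-scale stand-in for a ~38k-transcript reference |
| catg_fraction | 0.62 | fraction of transcripts with a taggable site in insect transcriptomes of this kind |
| depth | 5·10^5 per library | desk scale; raise to 6·10^6 to match full-scale libraries |
| length | lognormal, median ≈ 730 nt, clipped to [100, 8000] | typical assembled-transcript lengths |
| expression | lognormal(0, 1) rates | spans ~3 orders of magnitude, as bulk libraries do |
| de_fraction | 0.10 of site-bearing genes | sizeable but minority response |
| fold_range | 2–8, log-uniform | covers the calling threshold up to strong inductions |
| up_fraction | HS 0.59 / CS 0.32 | heat responses skew up, cold responses skew down |
| error_rate | 0.001 per base | short-read substitution error scale |
| n_rate / adaptor_rate | 0.005 each | minor contamination classes |
| incomplete_digestion | 0.05 | upstream-site emissions |
| antisense_rate | 0.05 of sense emissions | populates antisense categories without dominating |

Site-bearing status is exact by construction: designated site-free genes are
scrubbed of `CATG`, and a site is injected into any designated site-bearing
gene that failed to acquire one by chance, so the realized fraction equals
round(catg_fraction·n_genes)/n_genes.  Per-gene emissions are
Poisson(λ_g·depth/Σλ) over site-bearing genes.  Substitution errors are
applied per emitted copy with the exact conditional error-count distribution
given ≥ 1 error; `N` bases are injected inside the tag body (positions
4–20), since an N inside the anchor makes a read unextractable and thus
indistinguishable from an empty read.  Every draw is recorded in the truth
manifest, and `emitted(sense) + emitted(antisense) = raw library total`
exactly; adaptor reads are ledgered separately.

What the simulator does *not* model — and hence what passing tests do not
show about real data: base-quality structure, PCR duplication beyond copy
counts, isoform structure and alternative polyadenylation, reads from
noncoding RNA or unassembled genes (a major source of unmapped tags in real
libraries), and biological replicate dispersion.  The recovery results on
synthetic data are therefore an upper bound on real-data performance.

## Problem sizes and verification harnesses

The bundled verification runs use 2,000 genes at depth 5·10^5 (the
generator's defaults): a 20-seed null calibration (two libraries drawn from
one rate vector; fraction of genes at p < 0.05 compared with 0.05 at three
binomial standard errors) and a 5-seed spike-in recovery harness at 4–8-fold
(sensitivity among spikes with ≥ 20 expected tags in the higher library —
weaker spikes are genuinely undecidable at these depths and are reported but
not counted against sensitivity — and observed false-discovery proportion
among calls).  Structural checks (Hamming-mapper equivalence, hypergeometric
enumeration, QC ledgers, saturation monotonicity) run on small seeded
instances where brute-force oracles are exact.

## Known limitations

- 1-mismatch mapping cannot rescue tags with two or more errors; at the
  default error rate this loses ~0.02 % of copies, far below counting noise.
- Multi-gene tags are dropped rather than rescued by expectation-
  maximization; gene families therefore undercount.
- The test assumes Poisson counting noise only; with biological replicates a
  dispersion-aware model would be required.
- `pct` percentages are display values (two decimals); downstream arithmetic
  should use the underlying counts.
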