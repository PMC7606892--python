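# Methods

## Retention scoring

A locus's IES Retention Score is the fraction of junction-informative
reads carrying the IES, `IRS = k_ies / (k_ies + k_mac)`. Reads are
classified by exact substring match against three junction strings per
locus, each spanning a breakpoint with `min_flank` (default 10) bases
of context on both sides: the MAC junction of the excised form and the
two IES+ boundaries of the retained form. A read — or its reverse
complement — containing an IES+ boundary is IES+; containing the MAC
junction, MAC; evidence of both forms, or junction hits at two
different loci, makes the read ambiguous and it is never counted as
support anywhere. A read spanning both boundaries of a short IES
counts once. No mismatches are tolerated: the scheme is deliberately
transparent and is intended for synthetic or high-quality data, not as
a replacement for an aligner-based pipeline on real reads.

Study-wide locus filters: at least 20 supporting reads and an
eliminated-segment length of at least 26 nt. Filtered records are kept
with machine-readable reasons (`low_coverage`, `short_ies`,
`no_reads`) for audit. IRS > 0.1 defines the "incompletely excised"
(somatic) set; 0.05 is available where more power is needed.

### Coordinate and boundary conventions

IES boundaries are TA-bounded and one TA survives excision. The stored
IES sequence carries both flanking TAs; the eliminated segment is the
sequence minus its final TA, so the somatic form is
`left_flank + TA + right_flank` and splicing the eliminated segment in
front of the retained TA reconstructs the germline form exactly (the
round trip is property-tested). The reported IES length is the
eliminated-segment length (`len(sequence) − 2`); published data do not
pin down whether lengths include flanking TAs, so the convention is
fixed here and the ≥26 nt filter applies to it. Coordinates are
0-based half-open internally and 1-based inclusive in GFF3; the
conversion happens only at the I/O boundary.

## Transition testing

For each locus the F0 counts define a two-sided confidence interval on
the F0 retention proportion; its bounds are the reference nulls for
one-sided exact binomial tests on the F1 counts (upper bound for
upward transitions, lower bound for downward). Choices that the
procedure leaves open were resolved as follows:

* **CI method** — Clopper–Pearson exact, level 0.75. Exact bounds are
  conservative and well defined at k0 ∈ {0, n0}; Wilson is available
  by flag.
* **Multiple testing** — Benjamini–Hochberg per direction over all
  tested loci, alpha 0.05. Raw P-values are always reported and
  `adjust="none"` is selectable.
* **Ties** — an F1 IRS exactly on a reference bound is direction
  "none": calls require strict bound crossing.

The procedure is calibrated by construction: with F1 resampled at F0's
true retention (10,000 loci, coverage 100) the raw-alpha significant
fraction is ~0.001, far below alpha — the CI-referenced nulls make the
test conservative. Calls at a wider reference interval nest inside
calls at a narrower one.

## PTC annotation

Retention splices the eliminated segment into the host CDS in genome
space; minus-strand genes use the reverse complement of the plus-strand
construction. Translation uses the ciliate nuclear code (NCBI table 6;
TGA sole stop, TAA/TAG → Gln) — calling PTCs in *P. tetraurelia* with
the standard table would be biologically wrong — with the standard code
available for contrast. The native stop is located by coordinate
arithmetic (`cds_length − 3 + inserted_length` in the retained CDS),
never by sequence search. Consequences: `PTC_INDUCING` (a stop strictly
upstream of the native one, whatever the frame), `ORF_INTACT`
(in-frame insertion, no premature stop), `FRAMESHIFT_NO_STOP`
(frame-shifted but no premature stop). The published binary
PTC-inducing vs ORF-intact contrast corresponds to `PTC_INDUCING`
versus the other two classes; the three-way call is preserved in all
outputs. PTC enrichment of an observed IES set against its stratum
uses a permutation null (draws of equal size from the stratum,
one-sided empirical P with +1 correction, default 10,000 draws).

## Stratified statistics

* **Expression classes** — HEG/WEG are the top/bottom quartile of the
  log2 expression distribution over positively expressed genes;
  quartiles use linear-interpolation quantiles; values exactly on a
  boundary go to "mid"; zero-expression genes are "unexpressed" and
  never enter quartiles. Labels are rank-based, hence invariant under
  monotone transforms (property-tested).
* **Size classes** — the frequent classes 26–30, 44–45, 46–50, 54–60,
  64–70, 74–80, 84–90, 94–100 nt, inclusive bounds; lengths between
  classes are "unbinned". The small/large boundary is not defined in
  the published analyses; here `small_max_length = 32` (end of the
  first class), configurable and flagged as a package choice.
* **Two-proportion test** — chi-squared equality of proportions with
  Yates continuity correction, two-sided by default. This variant
  reproduces the published P-values on the printed Table counts
  (2.3e-11, 9.5e-10, 0.0033), which the uncorrected z-test does not.
  The one-sided variant reports the signed square root of the corrected
  statistic on the normal tail.
* **Fisher one-tail** — hypergeometric upper tail for enrichment of
  cell `a`; checked against exhaustive enumeration.
* **Count ratios and median IRS by size class** — computed on
  incompletely excised loci per frequent class; classes with fewer
  than 3 such loci in either condition are dropped; pooled small and
  large ratios sum the surviving classes on each side of the boundary.
* **cis-signal score** — a position-frequency profile over the
  terminal 8 nt of each IES end, trained on a reference IES set; the
  score is the mean per-position observed frequency normalized by the
  per-position maximum, so a consensus-matching terminus scores 1.

## Synthetic cohort

The generator emulates the cross-generational temperature design: one
parental line (F0 at 25 °C), a same-temperature control (F1 at 25 °C),
two shifted lines (18 °C, 32 °C) and a parental-heat-shock line. What
it reproduces: an AT-rich (70%) somatic reference; single-CDS genes
with clean ciliate-code translation; TA-bounded insertion points
strictly inside coding exons or in intergenic spacers; a peaked IES
size distribution over the frequent classes plus a uniform background;
log-normal expression with a zero-expression fraction; and per-locus,
per-condition true retention probabilities.

Baseline retention is a mixture: 90% of background loci are fully
excised (retention 0) and the rest draw from a thin Beta(0.5, 20)
tail, so somatic IESs are rare at baseline as in real data. Responsive
(planted-effect) loci instead draw their baseline from a scale-free
reciprocal distribution on [0.02, 0.30] (density ∝ 1/p²) — the
incompletely excised regime the cross-generational effects act on.
Two properties motivated this choice: multiplicative shifts on the
near-zero background are undetectable at realistic coverage (a
4-fold change of 0.003 is invisible at coverage 1000, and a 4-fold
decrease of a locus that is already at 0 is meaningless), and under a
1/p² density the count of loci above the somatic threshold scales
roughly with the multiplier, so count ratios behave like the planted
fold changes.

Planted roles: small exon IESs gain retention in shifted conditions
(×4 at 18 °C, ×5 at 32 °C, ×2.5 in the heat-shock line), with
responsiveness boosted for DCL2/3-sensitive loci and highly expressed
hosts; large exon IESs either lose retention (×0.25 / ×0.20 / ×0.50;
DCL5- and WEG-boosted) or gain mildly (×2 / ×2.5 / ×1.2); intergenic
IESs of all sizes gain mildly and uniformly, so no size-dependent
pattern appears outside genes. Responsive small exon IESs carry
planted in-frame TGAs at a higher rate (0.85 vs 0.45), so the retained
set shows a PTC excess over its stratum. Probabilities pushed outside
[0, 1] by a multiplier are clamped, with the clamp count recorded in
the truth record and the report.

Read counts are n ~ Poisson(coverage) with IES+ reads Binomial(n, p);
a beta-binomial option (config `overdispersion`) is off by default.
The read simulator draws reads uniformly from the local excised or
retained form, encodes the generative origin in the read name for
oracle checks, and emits either orientation.

What the generator does **not** emulate: sequencing errors, indels,
paired ends, mapping ambiguity against a full genome, multi-exon gene
structures, locus-to-locus coverage correlation, or germline variation.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated generative model, not
performance on raw sequencing data, which additionally requires
alignment-based read classification.

## Problem sizes and reproducibility

Default cohorts use 3,000 IESs in 600 genes (the real genome carries
~45,000 IESs; the simulation is scaled down, with sizes chosen so each
stratum keeps enough loci for stable per-class counts). Calibration
checks use 10,000 simulated loci at coverage 100; power checks use the
default cohort at coverage 1000, where planted increases are recovered
with power ~1.0 and decreases with power ~0.9. One mandatory seed
drives every stochastic stage through independently spawned substreams,
so adding a stage never perturbs earlier draws; two runs with the same
config and seed produce byte-identical reports (the config hash in the
report metadata excludes output paths).

## Known limitations

Exact-match junction classification underestimates coverage on
error-prone reads and cannot resolve loci whose junction contexts are
repeated elsewhere (such reads are dropped as ambiguous rather than
miscounted). The transition test conditions on the F0 interval rather
than modeling joint uncertainty, making it conservative; replicate-
aware or more-than-two-generation designs are out of scope. The
small/large size boundary and the exact test variants behind the
published summary statistics are package choices, documented above.
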