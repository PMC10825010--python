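# Methods

## Model and procedure

The unit of analysis is the haplotype count: a table of haplotype strings
over m biallelic SNP sites with real-valued case and control counts
(real-valued because frequencies are typically EM-estimated upstream and
arrive as frequency × n). Frequency-mode input is normalized per column and
converted once to pseudo-counts at load, so every statistic downstream sees
one representation.

For three sites the pipeline is:

1. **Parental selection.** The haplotype with the largest pooled
   (case + control) count; ties break to the lexicographically smallest
   string. Pooling is used rather than either arm alone so that the anchor
   does not depend on phenotype.
2. **Recoding.** Site i's parental base maps to the i-th uppercase letter
   (A, B, C), the alternate base to the lowercase letter. The parental
   haplotype is all-uppercase by construction and the map is a bijection on
   the observed haplotypes. Monomorphic and multi-allelic sites are errors
   at this stage (the dissection driver removes multi-allelic sites before
   reaching it).
3. **Sister pairing.** Sister = full case complement (`swapcase`), an
   involution. The four pairs partition the 8 genotype strings into the
   three-point-cross classes P1 {ABC, abc}, P2 {ABc, abC} (crossover in
   interval 2), P3 {Abc, aBC} (interval 1), P4 {AbC, aBc} (double). Which
   member of a pair is "unprimed" is the one whose first letter is
   uppercase; the collapse is invariant to that choice.
4. **Class collapse.** P_i = (count(h_i) + count(sister))/n per population;
   `overall` pools case and control counts (not the mean of the two
   frequency vectors — see Discrepancies). Unobserved haplotypes contribute
   zero; no pseudo-counts.
5. **RD test.** Dr = P1·P4 − P2·P3 = P4 − R1·R2 with R1 = P3+P4,
   R2 = P2+P4. The test is the df=1 chi-square for independence of
   crossover events in the two intervals: goodness-of-fit of the four class
   counts against E = n·(margin products), identical to
   n·Dr²/(R1(1−R1)R2(1−R2)) (asserted to 1e-9 as a property test). No
   continuity correction here. Degenerate margins (R ∈ {0,1}) raise rather
   than return 0/∞.
6. **Association.** Per sister pair, the 2×2 table (rows case/control,
   columns h1/h2 with h1 the member carrying more parental alleles):
   odds ratio a·d/(b·c) (NA when a·d or b·c is 0; optional
   Haldane–Anscombe +0.5 behind a flag), Wald Z = |ln OR|/SE with
   SE² = 1/a+1/b+1/c+1/d, and the Yates chi-square
   N·(max(0, |ad−bc|−N/2))²/(r1·r2·c1·c2), with the uncorrected statistic
   reported alongside for diagnostics. Raw p-values by default;
   Benjamini–Hochberg adjustment behind a flag (relevant once dissection
   multiplies tests).

For m > 3 sites, every C(m,3) triplet is projected (rows merged, counts
conserved) and quality-controlled: 8 observed classes → analysed; exactly
7 → the uniquely determined missing class is imputed with the
per-population minimum positive count (count tables grow their totals;
frequency-derived tables renormalize back to the original n); ≤ 6 →
excluded, since six haplotypes cannot form a valid sister-pair system.
The "minimum positive count" rule is this package's concretization of
assigning a rare-haplotype frequency to the missing class; an average of
rare classes or a fixed small frequency would be equally defensible, and the
QC status flags every imputed triplet prominently.

## RD statistic dialect

Legacy reports print the RD formula with a factor 4 (4·p1·p4 − p2·p3) on
per-gamete frequencies, yet every RD value actually printed in those
reports reproduces from P1·P4 − P2·P3 on the sister-collapsed class
frequencies — and none reproduces from the factor-4 form. This package
therefore uses P1·P4 − P2·P3 as the definition (it is also the form
satisfying Dr = P4 − R1·R2 and Dr = (c−1)·R1·R2); the factor-4 variant is
available as `rd_statistic(P, factor4=True)` and via `analyze --compat-dr4`
strictly for comparison.

Similarly, the RD chi-squares printed alongside those legacy values do not
follow from the printed class frequencies under the independence test or
any standard variant tried (e.g. 26.52 here vs 27.54278 printed for the
IL-13 case arm); the independence/goodness-of-fit statistic is the
canonical test with this null and is what the package reports.

## Simulator

`sisterhap.simulate` draws haplotype tables from the classical three-point
model: P4 = c·r1·r2, P3 = r1 − c·r1·r2, P2 = r2 − c·r1·r2,
P1 = 1 − r1 − r2 + c·r1·r2, each class split between its two sisters by
`sister_split` (default 0.5), controls multinomial from the resulting
8-haplotype frequencies, cases from the same frequencies reweighted by a
per-haplotype relative risk and renormalized. Defaults: r1 = 0.1, r2 = 0.2,
c = 1, all risks 1, 500 haplotypes per arm — moderate linkage with no
interference and no association, the natural null.

Sampling is at the haplotype level because the analyses count haplotypes;
the generator therefore does not emulate diploid individuals,
Hardy-Weinberg structure, phasing/EM estimation error in the input counts,
or population processes (drift, selection, gene conversion) that can also
produce RD in real data. Passing calibration against this generator shows
the statistics behave as designed under the stated crossover model; it does
not certify robustness to those unmodelled features.

Calibration helpers (vectorized, used by the test suite):

* `dr_recovery` — mean simulated Dr versus the closed form (c−1)·r1·r2;
  run at r1=0.1, r2=0.2, c=2, n=10 000, 2000 replicates (mean within 3
  standard errors of 0.02).
* `rd_type_i_error` — rejection rate at α=0.05 under c=1, n=500, 2000
  replicates (observed 0.045).
* `assoc_type_i_error` — per-pair rejection rates under equal risks,
  reported for both the plain and Yates statistics. The calibration runs at
  r1=0.2, r2=0.3 so the rarest class expects 30 haplotypes per arm of 500 —
  large enough for the asymptotic (plain) statistic to be meaningful. The
  plain rate is the calibrated one (observed 0.050–0.067 per pair); Yates
  is conservative by construction and is asserted only as ≤ the plain rate.
  At smaller expected counts Yates's conservatism grows; this is a property
  of the correction, not a defect of the implementation.

These sizes keep the whole suite under a few seconds; they were chosen as
the smallest runs whose Monte-Carlo error is well inside the asserted
bands.

## Numerical conventions

* Counts are floats throughout; nothing assumes integrality.
* Reports print 6 significant digits; undefined statistics print `NA`.
* Parental tie-break: lexicographic. 2×2 orientation: h1 = more-uppercase
  member, so the parental-pair OR is case-enrichment of the parental
  haplotype.
* Yates correction clamps at zero when |ad−bc| ≤ N/2.
* Round-trip: `read(write(table))` preserves fields to 1e-12 (counts are
  written with full repr precision).

## Discrepancies in the bundled published tables

The bundled datasets reproduce their sources verbatim, defects included;
tests assert the package's behaviour against both the printed values and
the recomputed ones where they differ:

* The IL-13 control class-frequency vector was printed with denominator 345
  although the control counts sum to 354: count-based control Dr is
  0.019343, the printed-vector Dr 0.020365. Both are asserted.
* The IL-13 "overall" column is the arithmetic mean of the case and control
  columns, not a pooled computation; this package pools counts uniformly.
* One ApoE-region frequency column (M1M3M6, case) sums to 1.125 as printed;
  load-time normalization handles it.
* Two published IL-13 association chi-squares (2.0896, 0.5414) follow from
  the published counts under neither the plain nor the Yates form; the
  other two (0.8649, 1.9380) reproduce the Yates form exactly, which fixed
  the package's default 2×2 dialect.

## Known limitations

* Sister pairing is inherently three-locus; m > 3 is handled only by
  triplet dissection, and no joint multi-interval RD statistic is offered.
* Association is haplotype-level: no diplotype/genotype modelling, no
  covariates, no logistic regression.
* The RD chi-square is asymptotic; very sparse double-crossover classes
  (expected count ≲ 5) deserve caution, and the dissection QC's imputation
  makes such triplets more common, not less.
* "Overall" pooling assumes the two arms are measured on the same haplotype
  space; tables with arm-specific missing classes are pooled as-is.
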