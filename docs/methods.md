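# Methods

## Population model

All estimators assume an asynchronous population in steady exponential
growth: cell number grows as e^{αt} with α = ln 2 / T, every cell divides
exactly at age T, and phase lengths are shared by all cells.  Under these
assumptions the age distribution is stationary with density
f(a) = 2α·e^{−αa} on [0, T] — newborns are twice as frequent as dividing
cells.  The probability of observing a cell in an age window [a_lo, a_hi)
is 2(e^{−α·a_lo} − e^{−α·a_hi}); every closed form below is this integral
in one guise or another.

The phase order within the cycle is G1 → S → G2 → M → C, with
Z = G2 + M + C.

## Phase-duration estimation

Inputs (all per culture): doubling time T (hours), fraction of cells in
cytokinesis f_C, fraction in mitosis-or-cytokinesis f_MC, fraction
EdU-labeled L after a pulse of t hours, and the minimum chase time t_2N at
which a single cell shows two labeled nuclei.

The computation runs strictly in the order C → M → G2 → S → G1:

1. x(y) = −ln(1 − y/2)/α maps the cumulative cell fraction y up to a phase
   boundary to the cumulative time to that boundary; C = T − x(1 − f_C)
   and M = (T − x(1 − f_MC)) − C.
2. G2 = t_2N − M.  Only M (not M + C) is subtracted: the two-nuclei
   criterion is taken to mark the completion of nuclear division, before
   cytokinesis.
3. S = (1/α)·ln(L + e^{αZ}) − (Z + t).
4. G1 = T − (S + Z).

Design choices:

* **Hours internally, everywhere.**  Minute-valued inputs are converted at
  the CLI only.
* **Fractions only at the library surface.**  Percent forms ("5", "5%")
  are normalized by the CLI before any computation.
* **Errors, never clamping.**  f = 1, L outside [0, 1], t_2N < M, or a
  negative computed duration raise named errors whose messages identify
  the two observations in conflict.  A negative phase is evidence of
  miscounted microscopy data; truncating it to 0 would hide that.
* **Display rounding only.**  The CLI prints hours to 2 decimals and ccu
  to 3; full double precision is kept internally and in TSV/JSON output
  of the library.

The ccu (cell-cycle unit) breakdown divides each phase by T and must sum
to 1 within 1e-9, which doubles as a consistency check on the estimate.

### Published-value consistency

The three published phase tables satisfy G1 = T − S − Z exactly at their
printed precision.  Recomputing ccu values from the printed hours matches
the printed ccu only to within one unit in the last printed decimal place
(e.g. 3.37/8.5 = 0.3965 vs a printed 0.397, and 1.78/10.5 = 0.1695 vs a
printed 0.16): the printed hours are themselves rounded, and the original
ccu values were evidently computed from unrounded intermediates.  The
acceptance test therefore asserts agreement at printed precision ±1 ulp —
the sharpest claim the printed inputs support.

## The population simulator

`orimin.popsim` is the estimator's independent oracle: it plants known
phase durations, samples n cell ages from the stationary density by
inverse CDF (a = −ln(1 − u/2)/α, u uniform), classifies each age against
the cumulative phase boundaries (half-open [lo, hi) intervals, so
zero-length phases are never reported), and emits the empirical
observables.

**Labeling convention.**  The population is censused at the start of the
pulse, and a cell counts as labeled iff it is in S at any moment of the
pulse — ages in (G1 − t, G1 + S].  With this convention the expected
labeled fraction is exactly the closed form e^{α(S+Z+t)} − e^{αZ} that the
S-phase estimator inverts, so round-trip tests are sharp.  The alternative
convention (census at pulse end) differs by a factor e^{−αt} because the
population grows during the pulse; the closed form itself neglects that
growth, and a simulator using the end-census convention would show a
systematic ~e^{αt} bias against it (≈ −0.13 h on S for T = 24 h, t = 0.5 h
— roughly 4 Monte-Carlo standard errors at n = 10⁵, i.e. detectable).
Consistency with the estimator's equation was chosen; the discrepancy is a
property of the classical short-pulse approximation, not of either code
path.

Preconditions enforced (violations raise `UnsupportedConfigurationError`):
S > 0, 0 < t ≤ Z (a labeled cell must not divide during the pulse) and
t ≤ G1 (otherwise the labeling window truncates at age 0 and the closed
form no longer inverts exactly).  t_2N is emitted noiselessly as G2 + M —
it is treated as a directly measured scalar, matching how the chase
experiment reports it.  An optional detection probability (default 1.0)
thins labeled cells to emulate imperfect EdU detection; the closed-form
model corresponds to 1.0.

**Recovery standard errors.**  The observed (f_C, f_MC, L) are indicator
means over the same cells with exact covariance: Var = p(1−p)/n,
Cov(f_C, f_MC) = f_C(1 − f_MC)/n (cytokinesis cells are a subset of M+C
cells), and Cov with L is −p·L/n (the labeling window, ending at G1 + S,
is disjoint from the M+C ages).  A central-difference Jacobian of the
estimation pipeline propagates this covariance to per-phase standard
errors (delta method).  The round-trip acceptance test demands recovery of
every phase within 3 such SEs at n = 10⁵ over a 3 × 3 grid: doubling times
{8.5, 10.5, 24} h crossed with G1-dominated, S-dominated and balanced
splits, bracketing the organisms studied, with a 0.25 h pulse.  Sample
size and grid were sized so the whole grid runs in a few seconds while
leaving each SE small enough (≲ 0.04 h) to detect any real bias in either
code path.

**What the simulator does not emulate** — and hence what a green round
trip does not prove about real cultures: cell-to-cell variability in phase
lengths, death/quiescence, partial synchrony, detection noise in f_C and
f_MC themselves, and growth during the pulse.  It validates the estimator
under exactly the assumptions the estimator makes, no more.

## Minimum origins

MO = ⌈N / (2·v·S)⌉ with N in bp, v in kb/min (×1000 → bp/min) and S in
minutes.  Numerical choices:

* **Exact rational arithmetic** (`fractions.Fraction`).  Rates and
  durations are decimal strings (3.06, 138.6, 591.6); floats are converted
  through their shortest decimal representation, so 3.06 means exactly
  306/100.  Several published cells sit within 0.5 % of a ceiling
  boundary (e.g. 622,644/(2·(2.44/3)·192·1000) = 1.9936), where binary
  floating point could flip the ceiling.  The ceiling applies only to true
  fractions — an exact integer quotient is not bumped.
* **Stress scales the rate, never S.**  Mild = 2/3, harsh = 1/3, kept as
  exact rationals (never pre-rounded to 0.81 or 0.53); the S-phase is held
  fixed under stress (the robustness assumption), so MO under stress is
  always ≥ the base MO.
* kb → bp is exactly 1000; combing counts are Oc = ⌈N/IOD⌉ with IOD in kb.

### Errata in the published tables

Thirteen published cells disagree with the formula evaluated exactly at
the stated parameters (`orimin.karyotype_io.ERRATA`); the implementation
reproduces all 295 others bit-exactly and annotates these rather than
reproducing them:

| cells | printed → formula | likely cause |
| --- | --- | --- |
| *T. cruzi* XXV, XXVII base | 2 → 1 | typo; the stress table's base column and the surrounding text both say 1 |
| *T. cruzi* XXXIX–XLI harsh | 2 → 3 | the mild-column values appear duplicated into the harsh column |
| *L. major* XIV harsh | 3 → 2 | matches only if 2.44/3 is rounded to 0.81 before use (quotient 2.0018 vs 1.9936) |
| *T. brucei* V, IX, XI base | 2,4,6 → 3,5,7 | consistent with a slightly different rate (≈3.3 kb/min) or older assembly; the same rows' mild/harsh cells match the stated 3.06 exactly |
| *S. cerevisiae* V (all three) | 7,10,19 → 6,9,18 | size typo: printed 574.86 kb, the real chromosome V is 576,874 bp, which reproduces all three printed counts |
| *S. cerevisiae* XIII harsh | 30 → 29 | rate 1.6/3 rounded to 0.53 before use |

## Karyotype fixtures and I/O

The five bundled karyotypes store bp integers in printed order, verbatim —
including non-monotonic neighbours such as *T. cruzi* XX < XIX.  The
*S. cerevisiae* sizes were printed in kb with a decimal comma
("230,19" = 230.19 kb); the fixtures store 230,190 bp etc.  Chromosome
name matching is exact-string everywhere (no "chr"-prefix normalization):
silent aliasing corrupts cross-method joins, and an explicit rename is
cheap.  `.fai` readers take name + length and ignore the byte-offset
columns; BED input is 0-based half-open and only the chromosome field
matters for per-chromosome tallies.

## Trend lines and fold-over-minimum

Per-method trend lines are plain unweighted OLS with intercept
(y = a·x + b) on (chromosome length bp, origin count) points, fitted on a
centred design for conditioning; a method whose counts are all equal is
the constant line y = c with slope exactly 0 and a `constant_flag`.  The
fold-over-minimum is the slope ratio method/MO — scale-invariant in x, so
bp vs kb does not matter.  When every chromosome has MO = 1 the MO line is
y = 1 and the ratio is reported as an explicit infinite marker (serialized
`"inf"`, never a float overflow).  The published per-organism ratios
(≈4.9–5.1 for trypanosomatids, 2.12 and 1.44 for the yeasts) depend on
per-chromosome combing counts that live in the cited primary studies and
are not bundled here; the machinery is validated by planting known slopes
in synthetic profiles and recovering the ratio to 1e-9.

A sufficiency report flags chromosomes where a method's count falls below
MO (count < MO exactly); any deficit means that method alone cannot
account for replication of the whole genome within S — in practice a
statement about the method's resolution (MFA-seq, microarray) rather than
the cell's biology.

## Known limitations

* The growth model has no cell death, quiescence or phase-length
  dispersion; all estimators and the simulator inherit this.
* The G2 estimate subtracts only M from t_2N; if cytokinesis-stage cells
  were excluded from the two-nuclei criterion in a given experiment, G2
  absorbs that convention.
* MO is a deterministic lower bound: no origin licensing, firing-time
  stochasticity or replication-timing structure is modelled.
* Stress scenarios change only the mean fork rate; a real stress response
  also changes origin usage and possibly S-phase length.
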