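# Methods

## Model

Thermodynamic arguments and ample panel data support a linear relation
between the retention times of the same compounds on two reversed-phase
systems run under one elution program: `t_R(col i) = a · t_R(col j) + b`.
Averaging a compound's time over a panel of n columns defines its standard
retention time, `St_R = Σ t_Rᵢ / n`; linearity between columns implies
linearity of every column against this consensus axis, `t_R = a·St_R + b`,
and the consensus is less noisy than any single column (conceptually,
averaging amounts to pooling the panel's stationary phases). Empirically the
per-column correlation against St_R exceeds the column-to-column
correlations; on the bundled panel the 30 fits average r ≈ 0.9992.

Prediction on a new target column proceeds in three stages:

1. **Two-point prediction.** The two reference substances are injected on
   the target column; the unique line through `(St_R1, t1)` and
   `(St_R2, t2)` maps every analyte's St_R to a predicted time. This is
   algebraically identical to interpolating with the calibrated retention
   `CR = (St_R − St_R1)/(St_R2 − St_R1)` (a property test pins the
   equivalence at 1e−9 min). Relative retention is the degenerate
   calibration whose lower anchor is the origin (unadjusted) or the dead
   time (adjusted) — a one-parameter line, which is why its transfer error
   is dominated by the intercepts real column pairs have.
2. **Window matching.** Each analyte takes the observed peak with the least
   |observed − predicted| among the peaks inside `t_pre ± t_R_W`.
   Ties go to the earlier peak. A peak may serve one analyte; when two
   non-series analytes claim the same peak, the smaller deviation keeps it
   and the loser is reported unassigned (assignment states are reported, not
   raised). **Sequential rule:** analytes whose predictions are closer than
   `series_gap` *and* whose windows share a candidate peak form a series;
   the series is assigned order-preservingly — earlier prediction to earlier
   peak — because least-deviation matching provably swaps or orphans close
   peaks. With more candidates than members, the order-preserving assignment
   maximising the number of matches and then minimising total deviation is
   computed by dynamic programming (ties prefer taking the earlier peak);
   with fewer, trailing analytes stay unassigned. Series components are
   connected components under the closeness + shared-candidate relation.
3. **Multi-point validation.** The (St_R, t_mea) points of the references
   *and* the matched analytes are refitted by ordinary least squares with
   vertical residuals (St_R is the low-noise abscissa), one pass, keeping
   the stage-2 peak assignment fixed; only the deviations are recomputed.
   The prediction succeeds iff every analyte is assigned and every refined
   deviation is ≤ its `t_R_L`. The ≤ comparison (with a 1e−12 guard) is
   deliberate; deviations are reported so callers can re-threshold.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `t_r_window` (t_R_W) | 1.2 | min | peak search half-window; recommended working range 0.8–2.0 |
| `t_r_limit` (t_R_L) | 0.5 | min | pass/fail deviation limit; recommended range 0.5–1.5; window ≥ limit enforced |
| `series_gap` | 2.0 | min | prediction closeness below which shared-candidate analytes form a series |
| `r_min` | 0.99 | — | minimum **signed** Pearson r of a column's fit against St_R |
| `resid_max` | 1.5 | min | residual bound for screening (midpoint of the 1–2 min working heuristic) |
| `compound_fraction` | 0.25 | — | fraction of columns on which a compound must be voted an outlier to be excluded |
| `coverage_min` | 0.8 | — | minimum span coverage for a candidate reference pair |

Window and limit accept per-compound overrides for peaks known to drift
more. Defaults sit inside the recommended working ranges; the worked
example uses 0.6/0.5 as its study did.

## Panel quality control

Compounds are screened before columns, per column, with a least-trimmed-
squares style rule: among all leave-one-compound-out lines the one with the
smallest SSE is the column's clean fit, and the left-out compound is voted
an outlier when it deviates more than `resid_max` from that clean line; a
compound voted on more than `compound_fraction` of columns is excluded.
Plain residuals cannot do this job: a compound offset on a minority of
columns drags its own consensus value along (shrinking every residual), and
at high leverage an outlier hides in the fit while inflating its
neighbours' residuals. For the same reason the screening abscissa is a
*robust* consensus — each column's fitted affine map is removed before a
per-compound median is taken across columns — rather than the plain mean,
which the outliers under test contaminate. The trimmed screen needs at
least four compounds; with fewer it is skipped. Columns are then screened
against the robust axis restricted to retained compounds: excluded when the
signed r falls below `r_min` (signed, because a time-reversed column is
perfectly *anti*-linear and an |r| check would wave it through) or any
residual exceeds `resid_max`. One pass, then the final St_R is recomputed
as the plain mean over retained compounds and columns; on a clean panel the
pass is a no-op and the final consensus equals the initial one.

Reference-pair selection: (1) keep pairs whose St_R-span coverage
`(St_R2 − St_R1)/(St_Rlast − St_Rfirst)` is ≥ `coverage_min` — high
coverage puts the references near both ends, where interpolation error is
smallest; (2) drop pairs containing excluded compounds; (3) return the pair
minimising the mean two-point deviation over all panel columns and all
non-reference compounds (scored at the two-point stage only). The full
ranking is returned alongside.

Consensus-size study: for each panel size k, distinct column subsets are
drawn without replacement (counts capped at C(N, k)); the consensus is
computed on the subset, all N columns are refitted against it, and the mean
absolute regression residual over all compounds × columns is recorded per
draw, summarised as mean ± sd per k. The default schedule is
k = 1, 5, 10, 15, 20, 25, 30 with 30, 100, 100, 100, 100, 100, 1 draws. On
the bundled panel the curve drops from ≈0.235 min (k = 1) and flattens by
k = 5 (≈0.19 min vs ≈0.179 min for the full panel), which is why five to
fifteen columns are the practical consensus size.

## Method comparison

`compare_all` lets every panel column play the target: reference measured
times are read from the table and the pending compounds (all non-reference
compounds of each method — three for the one-reference RR variants, two for
the two-reference calibration on the bundled panel) are predicted and scored
by `Δt_R`. A column is *positive* when every pending deviation is within
`t_R_L`; the chromatographic-resolution half of the full positive-column
definition needs raw chromatograms and is flagged as not evaluated.
The bundled RR values are used as distributed, not recomputed. Adjusted RR
requires a dead time `t0`, which is an input, never estimated from the
retention data; where no measured hold-up times exist, the bundled column
geometry supports a nominal estimate `t0 = 0.65·π·r²·L/F` (2.70 min for
4.6 × 250 mm, 1.62 min for 4.6 × 150 mm columns at 1.0 mL/min) — with it,
the bundled panel orders the methods multi-point (0.218 min mean) <
two-point (0.307) < unadjusted RR (0.436) ≤ adjusted RR (0.446), and the
ordering is insensitive to any reasonable t0. The adjusted variant's
in-theory advantage is eaten by the uncertainty of the anchor, consistent
with probe-compound measurement error.

## Synthetic panels

`generate_panel` draws `t[i, j] = a_j·St_i + b_j + ε` with
`a_j ~ N(1, 0.07)`, `b_j ~ N(0, 1)` min, `ε ~ N(0, 0.05)` min over four
compounds at 19.8/22.1/30.3/33.0 min on 30 columns — the scale and spread of
the bundled panel. Two plantable contaminations: a non-identity shuffle of
a column's times (destroyed linearity) and a constant offset (+3 min by
default) of one compound on a fraction (0.4) of columns. All randomness
flows through one `numpy` generator seeded by the mandatory spec seed.

What the generator does *not* emulate: gradient-program nonlinearity at the
extremes of a run, retention drift within a sequence, peak overlap/
co-elution (peaks are point times, not signal traces), heteroscedastic
noise, and structurally induced deviations that are smooth rather than
constant offsets. Passing synthetic tests therefore demonstrates correct
recovery under the method's own model assumptions, not robustness to every
real-world failure mode; the bundled real panel covers the latter only at
its own 4 × 30 size.

Validation studies sized for routine runs: parameter recovery uses 200
panels (6 000 column fits), judged against the sampling standard errors
implied by the generator's known σ (`SE_a = σ/√Sxx`,
`SE_b = σ·√(1/n + x̄²/Sxx)`); with only four points per fit a
residual-estimated SE would have two degrees of freedom and |t₂| < 3 covers
only ~90%, so the known-σ normal SE (3-SE coverage 99.7%) is the meaningful
yardstick. Outlier detection uses 200 panels per contamination type,
planted separately for clean attribution.

## Numerical choices and degenerate inputs

* All internal computation is full precision; printed coefficients are a
  display convention. Comparisons against 3-d.p. reference values round
  half-to-even at the comparison boundary only.
* Two-point fits with equal St_R raise; least squares needs ≥ 2 distinct
  abscissae; two-point least squares reduces exactly to interpolation.
* A column missing any compound is excluded from St_R, never imputed.
* Degenerate reference pairs (equal St_R) have coverage 0 and are invalid.
* Matching uses a 1e−12 tolerance on window/limit comparisons so that
  boundary peaks are inside; the unassigned-analyte penalty in the series
  DP (1e9) dwarfs any realistic deviation sum, making assignment count the
  primary objective.
* Subsampling rejects duplicate subsets; draws are capped at C(N, k).

## Data provenance notes

The bundled Paridis matrix is carried verbatim at its printed 3-d.p.
precision. Its saponin II cells average 30.3195 min, which rounds to
30.320 while the distributed consensus row lists 30.319 — a 0.0005 min
internal inconsistency of the source data that this package does not paper
over: `compute_strt` returns the matrix mean. Likewise the distributed
reference list gives saponin VI as 22.156 min where the matrix mean is
22.110; the matrix is authoritative throughout (the worked example is
consistent with 22.110). The Psoraleae per-column matrix was never
distributed, so only its reference lists ship and no Psoraleae panel
statistics are reproduced.

## Known limitations

* The method presumes a shared elution program; transferring between
  different gradients is out of scope.
* Peak inputs are retention times; no peak detection, areas, or spectra —
  ambiguities that UV/MS would resolve are out of reach.
* Multi-point validation runs once and does not re-match peaks after
  refitting; an assignment wrong at stage 2 can at best be flagged, not
  repaired, by stage 3.
* The RR comparison inherits whatever convention produced the distributed
  RR values (ratio of consensus times vs mean of per-column ratios is not
  distinguishable from the data shipped).
* Positive-column counts ignore chromatographic resolution (flagged in the
  report), so they upper-bound the fully qualified counts.
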