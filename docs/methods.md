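# Methods

## Scope and model

`bekit` treats an in vitro bioequivalence study as two coupled arms.

The **dissolution arm** converts per-timepoint assay responses into
cumulative percent-released profiles and compares a test formulation to a
reference with the f1/f2 fit factors. Two detection routes are modelled
because they measure different things when insoluble drug–excipient
aggregates form: direct UV absorbance quantifies only the freely dissolved
drug, while reversed-phase HPLC (whose organic mobile phase dissolves the
aggregates) quantifies free plus aggregated drug. Divergence between the
two routes is therefore itself a signal, and the combined report flags it.

The **permeability arm** models the PAMPA sandwich as two well-stirred
compartments (donor volume V_d, receptor V_r) exchanging by passive
diffusion across a membrane of area S with permeability Pe and no
membrane retention:

    dM_d/dt = −Pe·S·(C_d − C_a),   dM_r/dt = +Pe·S·(C_d − C_a)

with C_d = M_d/V_d, C_a = M_r/V_r. The solution gives percent transport
%T(t) = %T_eq·(1 − exp(−Pe·S·t·(V_d+V_r)/(V_d·V_r))) with equilibrium
ceiling %T_eq = 100·V_r/(V_d+V_r); the analysis inverts this to Pe. Note
the receptor volume sets the ceiling: with %T defined as the acceptor
amount over the initial donor amount, equilibrium places a V_r/(V_d+V_r)
share of the drug in the acceptor. Published forms of the equation often
write V_d there, which is indistinguishable at the standard symmetric
geometry V_d = V_r; the V_r form is the one that agrees with the ODE
model at every geometry, and the package uses it throughout.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| V_d, V_r | 0.18 | cm³ | 180 µl per compartment of the 96-well sandwich |
| S | 0.266 | cm² | filter area of the 96-well plate |
| incubation t | input | s | accepted in hours at the CLI, stored in seconds |
| theoretical max conc. | 1.5 | µg/ml | a fully dissolved 1.5 mg tablet in 1000 ml of medium |
| f1_max / f2_min | 15 / 50 | — | conventional similarity band; configurable, never hard-coded |
| alpha | 0.05 | — | two-sided Welch test significance level |
| QC panel r² | 0.95 | — | minimum correlation against literature Pe for assay validation |
| stability drift | 0.05 | fraction | relative absorbance drift tolerated over the screen |
| sampling | 3 of 1000 | ml | paddle-apparatus withdrawal per timepoint |

Calibration regression is unweighted OLS of response on concentration; no
weighting scheme is assumed. LoD/LoQ use 3.3σ/slope and 10σ/slope with σ
the intercept standard error — the only uncertainty a calibration fit
itself provides. Inverse prediction outside the calibrated range warns
but returns the value, since early dissolution samples legitimately sit
near zero.

The f1 statistic is asymmetric (its denominator is the reference profile's
total release); f2 is symmetric. The f2 logarithm is base 10 — the only
base for which identical profiles score exactly 100. An optional
guidance-style rule truncates the point set after the first time the
reference exceeds 85 % released; it is off by default because no point
selection rule is assumed for input data.

The withdrawal correction c'_k = c_k + (v_s/V)·Σ_{j<k} c_j restores
analyte removed by earlier samplings when withdrawals are replaced with
fresh medium. It is off by default (measured data are taken as reported)
and available for simulator output where ground truth is known.

The average release rate to plateau is dose·(v*/100)/t*, where t* is the
first sampling at which the profile reaches 95 % of the theoretical dose
and v* the value there. The threshold is relative to the dose, not the
profile's own maximum, so a formulation that never approaches complete
release is reported as "not at plateau" rather than assigned a rate.

Group comparison uses Welch's unequal-variance t-test: replicate RSD%
differs grossly between conditions in this assay class, so pooling
variances is not defensible. The choice of test is an assumption of the
package, stated here because source reports of this assay class often
omit the procedure behind their p-values.

## Synthetic data generator

The generator emulates the two-formulation study design with known ground
truth.

* Total released mass follows first-order kinetics
  F(t) = 1 − exp(−k·t) toward the dose (Weibull
  F(t) = 1 − exp(−(k·t)^b) when a shape b is given). The brand-like
  default is k = ln(20)/45 min⁻¹ (95 % released at 45 min); the
  generic-like default is k = ln(20)/60 min⁻¹ with a 30 % aggregate
  fraction.
* A fraction f_a of the instantaneous release enters an insoluble
  aggregate pool that redissolves first-order at k_agg (default
  0.01 min⁻¹): A(t) = f_a·∫₀ᵗ F'(s)·exp(−k_agg(t−s)) ds, closed-form for
  first-order release, quadrature for Weibull. UV-mode output is
  100·(F − A); HPLC-mode output is 100·F. The aggregate kinetics are a
  deliberately minimal mechanism — formation proportional to release plus
  first-order redissolution — chosen so that the defaults open a
  ~20-percentage-point UV-vs-HPLC gap at 45 min that closes at long
  times. The defaults keep the two formulations' *total* (HPLC-visible)
  release similar (f2 > 50) while the UV-visible release differs
  (f2 < 50), the qualitative pattern the combined analysis exists to
  detect.
* Measurement noise is multiplicative lognormal (median 1) with a
  configurable CV, applied per sample to dissolution values and to both
  plate absorbances — dispersion in these assays is relative, which is
  why RSD% is the reporting currency. Optional well-to-well permeability
  spread draws each well's Pe from a lognormal with median `true_pe`.
* Plate wells are generated by the %T closed form and inverted back to
  absorbances (A_r = A_d0·%T·V_d/(100·V_r)); the donor absorbance comes
  from a 15 µg/ml donor concentration — the highest level that passes the
  stability screen — through the UV calibration slope.
* A single seed drives everything; each (purpose, label) pair derives an
  independent substream, so regenerating one table never perturbs
  another.

What the generator does **not** emulate: temperature effects, membrane
degradation at long incubations (excess RSD% at 2 h in real plates),
unstirred water layers or membrane retention, UV spectral interference
from excipients, and HPLC peak integration. Passing tests therefore show
that the analysis recovers parameters under the stated noise model, not
that real plates are free of these artefacts.

## Numerical choices

* The RK4 oracle integrates the two-compartment ODEs with a fixed step
  (default 10⁴ steps) and conserves donor+acceptor mass to round-off by
  construction; it exists to verify the closed form independently and is
  never on the analysis path.
* Wells at or beyond the equilibrium ceiling are excluded and counted
  (`n_excluded`), never clamped: clamping would fabricate permeability.
  A group whose wells are all excluded is returned flagged invalid with
  NaN statistics.
* Percent-released values are never rounded internally; display rounds to
  one decimal. Profile values are clipped to [0, 120] (assay overshoot
  above 100 % is tolerated; beyond that is rejected as invalid).
* The calibration range check tolerates 1e-9 relative round-off at the
  edges so that forward-then-inverse at a boundary standard does not warn.
* CSV input is strict: UTF-8, header required, dot decimal separator.
  Comma decimals are rejected with line numbers rather than silently
  misparsed.

## Problem sizes

The test suite and acceptance script use desk-scale designs chosen to
match the study layout: 3 dissolution replicates on a 7-point grid
(15–150 min), 4 wells per plate condition, 200 simulation repeats for
parameter-recovery distributions and 1000 repeats for the type-I-error
calibration of the Welch test.

## Known limitations

* The report compares formulations pairwise against one reference; no
  multiplicity correction is applied across incubation times, matching
  single-comparison reporting practice.
* The HPLC percent-released route implements the external-standard
  formula with its fixed dilution factor (20) and theoretical tablet
  assay (1.5); other assay designs need the concentration route.
* Published LoD/LoQ values for this assay class are not always derivable
  from the printed calibration coefficients; `detection_limits` commits
  to the ICH σ-of-blank convention and documents it, rather than
  reverse-engineering any particular printed pair.
* f1/f2 verdicts use the conventional f1 ≤ 15 and f2 ≥ 50 band. Reports
  exist that declare profiles different at f2 above 50; the thresholds
  are therefore configuration, and the raw f1/f2 always accompany the
  verdict.
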