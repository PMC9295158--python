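# Methods

## Model

The toggle switch is modeled with six states: `mRNA_LacI`, `mRNA_TetR`,
`LacI`, `TetR` (arbitrary fluorescence units), and the intracellular inducer
pools `aTc_in` (ng/mL) and `IPTG_in` (mM). Transcription of each gene is
repressed by the opposing protein through a decreasing Hill function
`h(x, θ, η) = 1/(1 + (x/θ)^η)`, with the repressor's effective concentration
itself attenuated by its inducer: TetR·h(aTc_in, θ_aTc, η_aTc) regulates LacI
production and LacI·h(IPTG_in, θ_IPTG, η_IPTG) regulates TetR production
(the convention of the source model for this circuit; the threshold group
labels are ambiguous on their own and this pairing is the one fixed
throughout the package). Translation and degradation/dilution are first
order. Inducers cross the membrane at a rate proportional to the
outside-inside difference, with different influx and efflux rate constants.
All rates are per minute; nominal parameter values are the
`ToggleParams` defaults. aTc is held at 25 ng/mL in every closed-loop
experiment; IPTG (0–1 mM) is the control input and bifurcation parameter.

The stochastic variant is a chemical Langevin equation over the eight
biochemical pseudoreactions (2 transcription, 2 translation, 4 degradation):
`dX = S a(X) dt + S diag(√a(X)) dW` with eight independent Wiener increments,
integrated by Euler–Maruyama with `dt = 0.1 min`. States are clamped at zero
after each step and the number of clamped excursions is reported. The
inducer-exchange states carry no noise term (no pseudoreaction is associated
with transport). The intrinsic-noise scale is fixed by the propensities
themselves; there are no extra noise knobs. Zero-noise runs reduce exactly to
fixed-step deterministic Euler.

At any equilibrium the internal inducers equal the external levels, so
steady states live on the 4-dimensional biochemical subsystem; the full
6-state Jacobian is block-triangular, and stability is decided by the 4×4
biochemical block (the two exchange eigenvalues are always negative).

## Numerical continuation

The reference curve TetR(IPTG) is traced by pseudo-arclength
predictor–corrector continuation of the 4-state equilibrium system, starting
from the unique equilibrium at IPTG = 0 and following the curve upward.
Coordinates are scaled (mRNAs by their maximal levels, proteins by their
dynamic range, IPTG by 0.25 mM) so arclength steps are balanced; steps start
at 0.01, are halved on corrector failure down to 1e-5, and capped at 0.05.
Correction is a bordered Newton solve to residual 1e-11, so every stored
point satisfies the steady-state residual invariant with wide margin. When
the parameter leaves its bounds the final point is re-solved exactly on the
boundary. Folds are detected as sign changes of the tangent's parameter
component and then refined by a Moore–Spence bordered system
(`F = 0`, `J v = 0`, `‖v‖ = 1`) solved by Newton, which localizes each fold
far below the 1e-5 parameter resolution the detection bracket guarantees;
detection-by-bisection along the curve would work but the bordered solve is
sharper and costs one small root-solve. With nominal parameters at
aTc = 25 the curve has exactly two folds (IPTG ≈ 0.2365 and 0.3827 mM)
bounding a connected unstable branch, verified structurally in the tests and
against a multi-start root-finding oracle on an IPTG grid.

## Control-based continuation loop

The loop follows the experimental protocol: references step linearly through
the output range (30 values, 1800→0 a.u. for the proportional controller,
1200→0 for MPC, whose steady-state error is much smaller and needs no
reference overshoot); the controller output is held constant over each 5-min
sampling interval; a point is collected after a fixed dwell of 9 h 55 min, or
in `detect` mode as soon as the least-squares slopes of the error and control
signals over the trailing 12 samples drop below tolerance (checked only
after a 3-h minimum). Collected values are 12-sample averages of the output
and the applied input. Slope tolerances default to 0.5 a.u./sample (error)
and 1e-4 mM/sample (control) on the deterministic plant and 5× larger on the
stochastic plant; the protocol itself states only that the tolerance is
user-set, so these are package choices sized to the respective noise floors.
The initial plant state is the equilibrium at IPTG = 0 (a concrete choice
where the protocol says only that an initial guess is supplied). An
optional actuation delay exists in the configuration surface but defaults to
off. Because the input is the bifurcation parameter, a settled input is
noninvasive and each collected pair is an open-loop equilibrium; this is
verified explicitly by open-loop replay (5 h at the settled input stays
within 2% of the collected output).

The membrane-exchange kink (influx vs efflux rate constant switching exactly
at the equilibrium condition external = internal) makes every linearization
at a collected point one-sided. The package consistently uses the efflux
branch at equality, in the vector field, the Jacobian and the gain tuner
`tune_kp`. The closed loop is in truth a switched system; the switching
between the slow influx and fast efflux sides is itself stabilizing in
simulation, which is why the published proportional gain works on branch
segments where the one-sided influx linearization alone is marginally
unstable. `tune_kp` bisects the lower stability boundary of the closed-loop
spectral abscissa; the stabilizing gains form an interval (the root locus
re-destabilizes at high gain), so the scan brackets the lower edge first.

## System identification and MPC

Identification data are seeded stochastic pulse-response experiments:
random pulses of both inducers, amplitudes spanning the operational ranges
(IPTG 0–1 mM, aTc 0–50 ng/mL), pulse lengths 60–400 min, total record
6000 min sampled at 5 min. Pulse lengths were chosen to reach into the slow
protein time scales: with much shorter pulses the identified steady-state
gains come out with the wrong sign and mislead the predictive controller.

The model is a continuous-time innovation-form LTI system
(`x' = Ax + Bu + K(y − Cx)`, `D = 0`) in deviation coordinates around the
record means (stored as offsets on the model). Estimation is a
subspace projection (N4SID-style oblique projection, SVD, shift invariance,
then linear regression for B) followed by prediction-error minimization.
By default only the Kalman gain K is refined and the subspace (A, B, C) is
kept: joint refinement of all matrices reaches slightly lower one-step error
but, because input transitions are sparse in a pulse record, leaves B poorly
constrained and corrupts the input sensitivity that the controller depends
on. The refinement rejects predictors that are not strictly stable — the
marginal ones overfit the training record and diverge on held-out data.
Model order defaults to 2: higher orders fit held-out data no better and
tend to produce unstable open-loop A blocks or inverse-response artifacts in
the input channel, both of which break the predictive controller. Held-out
prediction fits with the order-2 model are ≈98% (LacI) and ≈95% (TetR).

The MPC cost is `J(u) = Σ_{k=1..N} (N−k+1) e(i+k)²` over a candidate input
held constant across the horizon, predicted open-loop from the current
Kalman state estimate; the feasible set is the input bounds intersected with
the relative band `[(1−γ)u_ss, (1+γ)u_ss]` around the previously registered
steady-state input (γ = 0.3; the band is what keeps the action noninvasive,
replacing an input-increment penalty). The scalar optimization runs a seeded
differential-evolution (genetic) algorithm, population 40, 30 generations,
vectorized and locally polished. The horizon is N = 144 steps (12 h). This
is deliberately long: the plant's slowest time constants blow up near the
saddle-nodes, and with the front-loaded error weighting a short horizon
over-weights the model's necessarily crude short-term input gain, giving an
effectively too-aggressive sampled feedback that limit-cycles around the
branch; lengthening the horizon shifts weight onto the quasi-static gain and
yields well-damped tracking. The Kalman state is advanced once per sample
with the applied input and fresh measurement; at the first reference the
band centers on `u_init = 1 mM` so the loop can reach the high-TetR branch
from the IPTG = 0 initial state.

## Parameter estimation

The analytic equilibrium inverse maps a TetR level to the IPTG input that
makes it an equilibrium: TetR fixes mRNA_TetR; the transcription relation
fixes the required Hill repression value `v`, valid only for `0 < v < 1`;
inverting the Hill function gives the effective LacI; LacI itself follows
from its own steady state given TetR and aTc; a final Hill inversion yields
IPTG, valid only when LacI exceeds the effective level. Any domain violation
marks the candidate point invalid (NaN), and candidate parameter sets whose
whole grid is invalid are discarded with a penalty cost — complex-valued
inversions never enter the cost. The inverse reproduces the numerically
continued nominal curve to better than 1e-6 relative, which is the
cross-validation gate for using it inside the cost.

The cost sums, over measured points, the squared Euclidean distance in
normalized coordinates to the nearest point of the candidate's predicted
curve, evaluated on a 400-point TetR grid spanning the measured range. IPTG
is normalized by the maximum applied input (1 mM) and TetR by the maximum
measured level — the protocol fixes only that the input is normalized into
[0, 1], so the TetR normalization is a package decision, made so both
coordinates are O(1). Predicted points whose required input exceeds the
normalization constant fall outside the explored range and are dropped.

The 14 free parameters (leakage and regulated transcription rates,
translation rates, all Hill thresholds and coefficients) are searched with a
seeded differential-evolution run, bounds 0.1×–10× nominal for rates and
thresholds (searched in log space) and [1, 4] for Hill coefficients;
degradation/dilution rates stay pinned to nominal. Default budget:
~105 individuals for 80 generations. `check_bistability` re-runs
continuation on a fitted parameter set and asks for exactly two folds.
Fits to deterministic CBC point sets (which include the unstable branch)
recover bistability in 10 of 10 seeded runs; fitted parameter values
themselves are not expected to match nominal — the steady-state curve does
not identify all 14 parameters.

The open-loop sweep baseline settles the plant at fixed IPTG levels visited
in ascending and then descending order (state carrying over), exposing the
hysteresis loop; its points lie only on stable branches by construction.

## Synthetic data scope

All data are generated internally: the deterministic and chemical-Langevin
plants are the experiment. The stochastic model captures intrinsic reaction
noise but not cell growth and division, cell-to-cell variability, spatial
inducer gradients, actuation delay or measurement noise; passing tests
therefore demonstrate the method's correctness against its own simulated
plant, not performance under microscopy/microfluidics conditions. Protocol
sizes used by the test suite are the published ones (30 points, 9 h 55 min
dwell) for the deterministic runs; the stochastic property is checked with
3 seeded repetitions in detect-dwell mode, a scaled-down version of the
10-repetition experiment, with the identification and experiment seeds fixed
in the test fixtures.

## Numerical choices and limitations

- ODE integration: LSODA, rtol 1e-7 / atol 1e-9; sampled trajectories are
  clipped of roundoff-level negative excursions.
- Newton equilibrium solves go through a smooth even extension of the Hill
  function (h(|x|)) so intermediate iterates may momentarily step below zero
  without leaving the domain; physical results are unaffected.
- The fold normal-form testbed integrates with fixed-step RK4 at 0.01 time
  units and samples at 0.05: the normal form's unit-rate divergence must be
  sampled well below its own time scale, unlike the toggle switch whose
  hour-scale dynamics make 5-min sampling comfortable.
- The MPC's identified model is a global LTI surrogate of a bistable plant;
  residual model bias concentrates the hardest tracking near the folds,
  where closed-loop settling is slowest. Identification quality varies
  across data-generation seeds; the default protocol seed is fixed in the
  configuration, and regenerating the model from a fresh seed can require
  revisiting the model order.
- DE-based "genetic algorithm" optimization is used both in MPC and in
  estimation; both are fully seeded and deterministic given a seed.
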