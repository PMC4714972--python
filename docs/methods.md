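# Methods

## Model and assumptions

The core object is a deterministic ODE model of an n-gene repression ring
in a well-mixed reactor.  Each gene G_i is transcribed at rate
β_i g · K_{i−1}^ν_i / (K_{i−1}^ν_i + p_{i−1}^ν_i) (Hill repression by the
upstream protein), mRNA is translated at c_i per unit mRNA, and both
species are first-order degraded (a_i, b_i) and diluted at the reactor
rate μ.  Assumptions inherited from this formulation:

- transcription-factor binding is at quasi-steady state (Hill kinetics);
- the template concentration g is constant — the reactor feed replenishes
  DNA, so dilution does not deplete the template;
- no resource competition (polymerase/ribosome loading), no inducer
  kinetics, no stochasticity; inducer pulses are represented purely as
  initial conditions;
- degradation-tag effects enter only through the protein degradation rate
  b (tagged: half-life 90 min; untagged: b = 0, removal by dilution only).

Units are nM and minutes everywhere; file formats carry units in column
names.  Index convention: the repressor of gene G_i is protein P_{i−1}
(node 0 ≡ node n), and K_{i−1} is the constant of that interaction.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| a | mRNA degradation | ln2/8 | 1/min |
| b | protein degradation (tagged) | ln2/90 | 1/min |
| c | translation rate | 0.5 | 1/min per nM mRNA |
| β | transcription rate | 0.4 | nM/min per nM template |
| K | half-repression constant | 5.0 | nM |
| ν | Hill coefficient | 2.0 | – |
| g | template concentration | 5.0 | nM |
| μ | dilution rate | ln2/t_d, t_d ∈ 15–85 | 1/min |

The weakened-operator fixture (`or2_star`) raises one node's K to 25 nM and
lowers its ν to 1.5; the true magnitude of that mutation is not known, so
both are exposed as knobs.

## Numerics

**Integration.**  LSODA with the analytic Jacobian, rtol 1e-8, atol
1e-10 nM.  Large ν or small K makes the system stiff; the supplied
Jacobian keeps the implicit branch cheap.  Discrete-dilution mode
integrates with μ = 0 between steps and applies x ← (1−dil)·x at each
step boundary; it converges to the continuous mode as steps shrink at
fixed rate (regression-tested at 1% of signal amplitude).

**Default problem sizes.**  Simulation horizon min(200·t_d, 20 000) min —
chosen so that, after discarding the first 40% as transient, at least
eight periods remain for the slowest case studied (5-node ring at
t_d = 85 min, period ≈ 18 h).  Sampling interval: one fifth of the
fastest decay timescale 1/max(a+μ, b+μ).

**Equilibria.**  The 2n-dimensional fixed point reduces to a scalar fixed
point of the loop map Φ (composition of the per-node monotone decreasing
steady-state maps).  For odd n, Φ is decreasing, so Φ(x) = x has exactly
one root, bracketed in [0, max c β g/((a+μ)(b+μ))] and solved by Brent's
method to xtol 1e-14.  For even n, Φ is increasing and sigmoid-shaped;
all fixed points (up to three for the 4-node switch) are located by a
600-point sign-change scan plus Brent refinement.  Stability is read from
the analytic Jacobian's eigenvalues (ordering: r_1..r_n, p_1..p_n —
part of the public contract).

**Oscillation classification.**  A trace (one species, post-transient
window, resampled to uniform spacing if needed) is *oscillatory* when all
three hold:

1. the mean-subtracted autocorrelation, unbiased-normalized to remove the
   triangular overlap taper (which otherwise drags peak positions toward
   zero lag), has a local maximum at τ > 0 with prominence ≥ 5% of R(0);
   the period is that first peak's lag, parabolic-refined;
2. the settled amplitude (peak-to-trough over the second half of the
   window) exceeds 1% of the signal mean;
3. the oscillation is sustained: second-half amplitude ≥ 75% of the
   first-half amplitude.

Criterion 3 exists because near a Hopf boundary on the stable side,
transients decay arbitrarily slowly and masquerade as oscillations over
any finite horizon; a limit cycle holds the ratio at 1, a damped ring
does not.  With it, the simulation classifier agrees with the Jacobian
eigenvalue sign and with the closed-form conditions at every cell of a
10×10 (t_d × transcription-scale) grid.  The 1% and 75% cutoffs are this
package's conventions; the underlying criterion gives no quantitative
threshold.  The peak-to-peak estimator (used for experimental-style
traces) applies light Savitzky–Golay smoothing before prominence-filtered
(10% of range) peak detection and averages successive peak intervals.

**Closed-form conditions.**  Q is implemented as the geometric-to-
arithmetic mean ratio of the two effective decay rates, which keeps
Q ∈ (0,1] and recovers the classical secant bound W(n,1) = 2/(1+cos(π/n));
the synthesis condition's left side is evaluated as c·β·g since the
model's maximal transcription rate is β·g (dimensionally consistent with
the right side's K(a+μ)(b+μ)).  The conditions are stated for symmetric
rings only; asymmetric networks go through the eigenvalue route.  In all
grids tested the closed form and the eigenvalue sign agree exactly.

**Hill fitting.**  Orthogonal-distance regression (scipy.odr/ODRPACK)
with 9% relative standard deviations on both coordinates, applied
per-point; the y-error is floored at 9% of 1e-3 to keep near-zero points
finite-weighted.  Start values: ymin = min y, K_M from interpolating the
half-maximal crossing, n = 2.  ODR runs unconstrained; a solution outside
the plausibility box (K_M ∈ (0, 10·max x], n ∈ (0.3, 10], ymin ∈ [0, 0.9])
or a failed run falls back to bounded weighted least squares and is
flagged in the results.  Fits are refused (with the reason) when fewer
than 6 points survive filtering or when the curve never drops below ~55%
of its maximum, since K_M is then outside the measured range.

## Synthetic data: what it emulates, and what it does not

The generator forward-iterates the dark/fluorescent reporter step
recursion (synthesis → dark pool → maturation → fluorescent pool, with a
fractional volume exchange per step) at the device's protocol scale:
15% exchange every 8 min, 180 steps (24 h), repressor template ramped
0 → 2.5 → 0 nM (rise over 40% of the run, fall over 40%, zero tail 20%
so the repressor washes out and the descending branch reaches its
plateau).  Maturation rates are ln2/15 per min for the repressor reporter
and ln2/29 per min for the promoter reporter, the measured maturation
times of the two reporters.  The per-nM-template expression rate is
calibrated once so the standard 2.5 nM ramp drives the repressor to ~10
K_M.

Measurement noise is multiplicative lognormal with CV 9%, modeled as a
slowly drifting calibration factor (AR(1) in log space, correlation time
480 min) times a 1% iid photometric component.  The decomposition
matters: the maturation/dilution inversion is a double finite difference,
which amplifies *white* noise by roughly 1/(mat·Δt) and 1/dil (≈ 25–40×
here), so a hypothetical 9% iid per-step error would make the inference
problem unsolvable for any method; a drifting calibration error of the
same magnitude is what reactor fluorescence data actually carry, and the
pipeline handles it.  Correspondingly, curve assembly smooths the traces
(Savitzky–Golay, quadratic, 9-step window; 7-step on the inferred dark
series) and estimates v_max as the median synthesis over unrepressed
samples (total repressor < 1 nM) — a plain maximum over a drifting run
is biased upward and drags K_M low.  `smooth=False` restores the exact
algebraic inversion for noiseless data.

Not emulated: extract batch variability, chip calibration drift between
(as opposed to within) runs, alternating lysate/buffer feed composition,
resource loading at high template, cell-to-cell variability.  Passing
end-to-end tests therefore demonstrate correctness of the inference
arithmetic and robustness to the stated noise structure — not robustness
to systematic biology-side deviations from the Hill model.

## Design choices where the design was open

- **Oscillatory range reporting**: closed interval of grid points that
  classified oscillatory; boundary behavior between grid points is not
  interpolated.
- **Transient discard**: first 40% of the horizon (the steady-state onset
  time is otherwise unquantified).
- **Negative inferred synthesis** (possible under noise) is clipped to
  zero for curve assembly, preserved in diagnostics.
- **Maturation times are converted to rates** as mat = ln 2 / t_mat
  (half-life convention).
- **b = 0 is allowed** (untagged proteins, removal by dilution only);
  b+μ > 0 always holds since μ > 0.
- The statsmodels-style Model/Results shape is used where a model is fit
  to data (`HillTransferModel` / `HillFitResults`); the mechanistic ring
  side is a dataclass-plus-functions toolkit.

## Known limitations

- The closed-form criterion applies only to symmetric rings; asymmetric
  rings rely on local stability (a positive-real-part eigenvalue at the
  unique equilibrium), which for cyclic negative feedback implies a
  periodic orbit but does not by itself bound its amplitude or period.
- Period estimates are lag-grid limited (one sampling step, ~0.5% at the
  defaults) and assume the post-transient window holds ≥ 4 periods.
- At t_d = 85 min the 3-node ring's simulated period reaches ≈ 8.8 h,
  slightly above the ~8 h ceiling reported for such circuits in
  experiments whose dilution sweeps top out near there; the model carries
  no calibration that would cap it.
- The ODR covariance is a local linearization; for strongly correlated
  (K_M, n) posteriors the standard errors are optimistic.
- Classification very close to a Hopf boundary is horizon-limited: cells
  whose eigenvalues have |Re λ| ≲ 1/horizon can be misread by the
  simulation route (the analytic/eigenvalue routes are exact there).
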