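# ringosc

Simulation and analysis of **ring-oscillator gene circuits under reactor
dilution**, for synthetic biologists prototyping cyclic negative-feedback
networks (repressilator-class circuits) in dilution-controlled cell-free
reactors, plus the **maturation-corrected transfer-function pipeline** used
to characterize repressor–promoter pairs in such devices.

## The model

An *n*-node ring is a cycle of genes in which protein P<sub>i−1</sub>
represses transcription of gene G<sub>i</sub>.  mRNA r<sub>i</sub> and
protein p<sub>i</sub> follow

```
dr_i/dt = −(a_i + μ) r_i + β_i g K_{i−1}^ν / (K_{i−1}^ν + p_{i−1}^ν)
dp_i/dt = −(b_i + μ) p_i + c_i r_i
```

with cyclic indexing; μ is the reactor dilution rate, related to the
dilution time by t_d = ln 2 / μ, and g the plasmid (template)
concentration.  Units are nM and minutes.  Odd rings can sustain limit-cycle
oscillations; even rings behave as multistable switches.  For the symmetric
ring the package evaluates the closed-form oscillation criterion

```
ν > W(n, Q),    c β g > (W/(ν−W))^{1/ν} · (ν/(ν−W)) · K (a+μ)(b+μ)
```

with `Q = √((a+μ)(b+μ)) / ((a+b+2μ)/2)` (geometric/arithmetic mean ratio
of the effective decay rates) and
`W(n,Q) = 2(−cos(π/n) + √(cos²(π/n) + Q² sin²(π/n))) / (Q² sin²(π/n))`,
which reduces to the classical secant bound `2/(1+cos(π/n))` at Q = 1.
Asymmetric rings are classified by the Jacobian eigenvalues at the unique
equilibrium.  Oscillation periods are estimated from the autocorrelation of
the post-transient protein signal or from peak-to-peak intervals.

The transfer-function side inverts discrete-dilution fluorescence traces —
correcting for reporter maturation (dark → fluorescent pool) and step
dilution — into synthesis rates, assembles normalized synthesis vs. total
repressor curves on the descending branch of a repressor-template ramp,
and fits the repressive Hill law
`y = y_min + (1−y_min) K_M^n/(K_M^n + x^n)` by orthogonal-distance
regression with 9% errors on both coordinates.  A seeded synthetic-data
generator emulates the reactor (step recursion, maturation, calibration
drift + photometric noise) so the whole pipeline is testable without a
device.

## Worked example

```python
import ringosc as ro

net = ro.builtin_network("repressilator")          # symmetric 3-node ring
reactor = ro.ReactorSettings.from_dilution_time(40.0)
traj = ro.simulate(net, reactor, ro.RingState.pulse(3))
est = ro.autocorrelation_period(traj.times, traj.species("p1"))
print(f"period: {est.period:.1f} min ({est.period/60:.2f} h)")
print(f"amplitude: {est.amplitude:.1f} nM")

rep = ro.check_conditions(net, reactor.mu)
print(f"Q = {rep.Q:.3f}, W(3, Q) = {rep.W:.3f} -> oscillatory: {rep.oscillatory}")
```

prints

```
period: 344.7 min (5.74 h)
amplitude: 175.9 nM
Q = 0.791, W(3, Q) = 1.484 -> oscillatory: True
```

at a 40-min dilution time the ring oscillates with a ~5.7 h period and
~176 nM peak-to-trough protein swings; the Hill coefficient 2 clears the
threshold W ≈ 1.48, consistent with the simulation.  Fitting a synthetic
transfer experiment (true y_min = 0.05, K_M = 5 nM, n = 2, with 9%
calibration noise):

```python
spec = ro.SynthSpec(seed=42, truth={"ymin": 0.05, "K_M": 5.0, "n": 2.0, "v_max": 1.0})
prom, repr_ = ro.gen_transfer_experiment(spec)[:2]
print(ro.HillTransferModel.from_traces(prom, repr_).fit().summary())
```

```
Hill transfer-function fit
==============================================
method: odr   points: 78   res. var: 0.7562
v_max: 1.084 nM/min (normalization)
----------------------------------------------
   param     estimate      std err
    ymin      0.05494      0.00153
     K_M        4.763        0.155 nM
  n_hill         2.34       0.0924
```

K_M is recovered within 5% and the Hill coefficient within 0.35 under the
stated measurement error.

A command-line interface mirrors the library:
`ringosc simulate|period|sweep|regime|equilibria|transfer|synth --help`.

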