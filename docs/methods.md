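# Methods

## Model and workflow

`cellopt` models the immobilization efficiency of cellulase on Eudragit
L-100 as an unknown smooth function of three process factors — EDC
concentration, NHS concentration and coupling time — sampled with a
rotatable central composite design (CCD) and approximated by a 3-4-1
multilayer perceptron. The trained network is then treated as the
objective of a binary-coded genetic algorithm (GA) that searches the coded
factor cube for the setting with the highest predicted efficiency.

The key assumptions are: the response surface is smooth enough for a
four-hidden-unit tanh network to represent within the design region;
replicate noise is additive and roughly homoscedastic; and the optimum of
interest lies inside the region the design samples (the network is an
interpolator — its behaviour outside the sampled region is unconstrained,
which matters because the search cube's corners lie well outside the
CCD's sampled sphere; see Limitations).

## Design and scaling

Coded level *c* of factor *i* maps to actual units as
`center_i + c·step_i`. The bundled factor geometry is EDC 0.40 ± 0.20 %
w/v, NHS 0.28 ± 0.12 % w/v, time 3.0 ± 1.5 h, with axial distance 1.68.
Axial actual values are kept exact (e.g. 0.40 + 1.68·0.20 = 0.736) and
rounded only for display, so the coded↔actual maps are exactly mutually
inverse. The axial distance is used as configured (1.68) rather than the
rotatable 2^(3/4) ≈ 1.6818: the difference is below every other precision
in the problem and 1.68 matches the bundled design exactly.

Network inputs are min–max scaled to [−1, 1] from the *training-data
extremes* (the axial settings for a CCD), and the scaler is stored inside
the saved model so predictions always use the training-time scaling. For
the bundled symmetric design this reduces to `x* = coded/1.68`. The
response is scaled to [0, 1] by dividing by 100.

## Network and training

Architecture: 3 inputs, 4 tanh hidden units, 1 linear output, biases in
both layers. Biases are not optional: a bias-free tanh/linear network is
an odd function of its inputs and would be forced to predict the scaled
value 0 at the design centre, which the centre-replicate data (≈77 %)
contradict.

Training is full-batch gradient descent with momentum on the mean (not
summed) squared error over the scaled training pairs:

| parameter      | default | why |
|----------------|---------|-----|
| goal MSE       | 1e-4    | RMS of one efficiency point on the 0–1 scale; the level the reference fit attains |
| learning rate  | 0.05    | stable for this problem size; converges in 3–27k epochs |
| momentum       | 0.9     | standard heavy-ball value |
| epoch budget   | 50 000  | tiny network; desk-scale |
| restarts       | 10      | init U(−0.5, 0.5), restart *r* seeded with seed + *r* |

Training returns the first restart that reaches the goal, making results
deterministic given (seed, config, data). If no restart reaches the goal a
convergence error is raised that carries the best model found. The
back-propagated gradient is verified against central finite differences
(<1e-6 relative) in the test suite. The error goal is deliberately a
*stopping* criterion, not a minimum: stopping at the goal keeps the fit at
the noise level of the data instead of interpolating it.

## Fit statistics

For experimental values *y* and fitted values *ŷ* with errors
*e = y − ŷ*: MAE and mean relative error divide by *n*; the error variance
divides by *n − 1* and RMSE is its square root. These denominator
conventions are the unique pair under which the bundled table's published
summary statistics (0.74 / 0.99 / 0.98) are reproduced from its printed
columns; an *n*-denominator RMSE gives 0.96 instead. The ANOVA is a
simple linear regression of the fitted column (dependent) on the
experimental column (predictor) — 1 model df, *n − 2* residual df, p from
the F(1, n−2) upper tail — which is the orientation whose total sum of
squares matches the published table. The relative error uses the
experimental value as denominator. The published mean relative error
(1.18 %) is not recoverable from the 2-dp printed columns (they give
1.22 %) and is not asserted anywhere; likewise the printed error variance
0.98 corresponds to a hand value of 0.9749, so tests require agreement to
one unit in the last printed digit.

## Genetic algorithm

Chromosomes are 3 × 16 bits, MSB first, decoded linearly onto the coded
cube [−1.68, 1.68]³ (resolution ≈ 5e-5 coded units). One generation:
fitness-proportional (roulette) selection on the raw predicted efficiency,
single-point crossover on consecutive pairs with probability 0.4, per-bit
mutation 0.005, and one elite copied unchanged — so the best-fitness trace
is non-decreasing. Defaults: population 20, 50 generations, 50 independent
runs (seeds seed+0 … seed+49) aggregated into per-run maxima / minima /
final-generation averages and the mean of maxima. If every fitness value
is non-positive, selection falls back to uniform (logged); with the
intended efficiency objective this cannot happen.

Two numerical notes. First, roulette selection on raw percentages spans
roughly 40–90 %, so the selection pressure is weak; convergence is driven
mostly by elitism plus mutation, and the search localizes an optimum to
about 0.1–0.2 coded units, not to the decoding resolution. Second, the
per-bit mutation rate implies ≈0.24 expected flips per 48-bit chromosome;
tests that shrink the chromosome (e.g. the 9-bit exhaustive-enumeration
oracle, where all 512 candidates can be enumerated) scale the per-bit rate
up to 0.02 to preserve that per-chromosome rate, otherwise mutation all
but vanishes.

## Synthetic data

`synthetic.SurfaceSpec` defines a full quadratic polynomial in coded units
— the model class the CCD is designed to identify, so end-to-end recovery
failures are attributable to the network or the search rather than to
identifiability. Simulated responses are surface + zero-mean Gaussian
noise (default SD 5 efficiency points, the magnitude of the bundled
table's replicate SDs), clipped to [0, 100] with a log entry. Validation
points are drawn uniformly from the factorial core [−1, 1]³, inside the
region the design samples. `analytic_optimum` returns the surface maximum
over the cube from a 0.01-step grid scan (the oracle of record), replaced
by the exact stationary point when that point is interior, concave and
consistent with the grid.

What the generator does *not* emulate: heteroscedastic or non-Gaussian
noise, model misspecification (a true response that is not quadratic),
factor-setting error, or batch effects. Passing recovery tests therefore
show the ANN-GA machinery is correct under its own assumptions, not that
the method is robust on arbitrary real data.

A note on noise and the training goal: with six centre replicates, noise
of SD σ (in points) puts an expected floor of ≈ 0.25·(σ/100)² on the
attainable scaled training MSE — equal to the 1e-4 goal at σ = 2. Recovery
studies here use σ = 1.5, where the goal is attainable on average but
individual noise draws occasionally place the floor above it; such runs
report a convergence failure rather than silently returning a worse fit.

## Problem sizes

The default test suite retrains the network on ten seeds, runs the
50-run GA aggregation once, uses 40 seeds for the enumeration oracle and
ten simulated datasets for parameter recovery; the acceptance script uses
the same sizes. These are the study's own sizes (10 seeds, 50 GA runs) or
desk-scale choices for the oracles.

## Known limitations

- **Retraining does not reproduce one specific network.** Any network
  that reaches the error goal is a valid fit, and different seeds yield
  visibly different surfaces away from the data. In particular the
  *maximum over the search cube* varies by several efficiency points from
  seed to seed (occasionally spiking at cube corners the design never
  sampled), so the searched optimum — both its height and its location —
  is seed-dependent in a way the training data cannot pin down.
- **The bundled held-out trials disagree with every refit.** Trials 21–22
  of the bundled table report efficiencies ≈20 points above what any
  model fitted to the 20 training trials predicts (a quadratic surface
  included); the nearest training point to trial 21 sits at 54.7 while
  trial 21 reports 76.2. Median worst-case validation error across
  retrained networks is ≈30 %, and the package reports it as computed.
- The GA's weak proportional selection makes it a coarse optimizer; for
  production use on smooth fitted surfaces a gradient or quasi-Newton
  polish of the GA's best point would be more precise. Not included, to
  keep the search procedure exactly the classical binary GA.
- Efficiencies are hard-bounded to [0, 100] at the data layer; synthetic
  clipping can therefore slightly bias noise near the bounds (logged).
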