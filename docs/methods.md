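# Methods

`kinmotif` profiles the kinetic parameter space of a small adaptive enzyme
network: it asks not for the single best-fitting parameter set, but for the
*patterns* in parameter values that any set must follow for the network to
adapt, and for the part of the adaptation dynamics each pattern serves.

## The model

The canonical network is the three-node negative-feedback-loop-with-buffer
(NFBLB) circuit that mirrors E. coli chemotaxis signalling: the input `I`
(chemoattractant) activates node A (the CheA-bound receptor complex), A
activates the buffer node B (CheB) and the output node C (CheY), and B
closes the loop by deactivating A. Constant background enzymes F_B and F_C
(concentration 0.5 each) deactivate B and C. Each node is an enzyme cycling
between an active fraction X and an inactive fraction 1 − X, and every edge
is a saturable Michaelis–Menten conversion, giving for the NFBLB preset

    dA/dt = I·k_IA·(1−A)/((1−A)+K_IA) − B·k_BA·A/(A+K_BA)
    dB/dt = A·k_AB·(1−B)/((1−B)+K_AB) − F_B·k_FBB·B/(B+K_FBB)
    dC/dt = A·k_AC·(1−C)/((1−C)+K_AC) − F_C·k_FCC·C/(C+K_FCC)

with a catalytic rate constant k and a Michaelis constant K per edge. All
quantities are dimensionless. The unit box [0,1]³ is forward-invariant
(activation vanishes at X = 1, deactivation at X = 0), which the test suite
asserts numerically. A generic builder assembles the same term shape for
arbitrary activation/deactivation topologies (e.g. incoherent feed-forward
variants), rejecting topologies in which some node lacks an activation or a
deactivation edge.

## Adaptation scoring

A parameter set is scored on the step response of the output node C to an
input step I1 = 0.5 → I2 = 0.6: from the stable pre-stimulus steady state
O1, the transient peak Op and the post-stimulus steady state O2 give

    sensitivity = (|Op − O1| / O1) / (|I2 − I1| / I1)
    precision   = [ (|O2 − O1| / O1) / (|I2 − I1| / I1) ]⁻¹

Both scores use absolute relative changes, so they are non-negative and
scale-invariant; perfect adaptation (O2 = O1) has infinite precision, which
is carried as `inf` through the analysis (ranks handle it naturally) and
serialized literally. A set is a *kinetic solution* when sensitivity > 1
**and** precision > 10 (strict). At the default protocol these thresholds
have exact analytic meaning: a peak excursion of at least 20% of baseline,
and a residual steady-state shift of at most 2%.

## Numerical strategy

Steady states are found by damped Newton iteration with the analytic
Jacobian, falling back to relaxation by integration when Newton fails or
lands on an unstable root; stability is read off the Jacobian eigenvalues.
Transients are integrated with LSODA (rtol 1e-8, atol 1e-10) over
geometrically growing windows with dense sampling for peak detection (the
sampled peak is refined by local parabolic interpolation). Two documented
shortcuts keep a 10⁵-set screen near four minutes of CPU: once a trajectory
is inside the linear neighbourhood of a stable post-stimulus equilibrium,
the remaining approach is extrapolated from the dominant eigenvalue rather
than integrated to the 10⁴-unit budget; and an unstable spiral equilibrium
with the orbit bounded away from it is classified as a limit cycle
(persistent oscillation) without further integration. Both shortcuts agree
with direct long-horizon integration on random sets in the test suite.

## Trajectory filters

Following the screening protocol this methodology builds on, sets whose
dynamics are unusable are discarded before scoring, with one label each:

* `TINY_STEADY_STATE` — a steady-state concentration is degenerate. The
  published protocol names the category but not its cutoff; the default
  here requires O1, O2 ≥ 0.01 and, at the pre-stimulus steady state, both
  the active and the inactive fraction of every regulatory (non-output)
  node ≥ 0.01 — a node pinned at either boundary has effectively lost one
  of its two forms and its regulation is inoperative.
* `PERSISTENT_OSCILLATION` / `WEAKLY_DAMPED_OSCILLATION` — tail
  oscillation of the output with peak-to-peak amplitude ≥ 1e-4 that is
  non-decaying, or decaying but still above that floor at the end of the
  10⁴-unit budget.
* `LONG_TRANSIENT` — settling (all states within 1e-4 of the final state)
  would exceed the 10⁴-unit budget.
* `NO_CONVERGENCE` / `NUMERICAL_FAILURE` — no stable pre-stimulus steady
  state, or integrator breakdown. Failures are labelled, never raised, so
  a screen always completes.

The degenerate-steady-state floor is the one genuinely free constant of
the reproduction. It was calibrated once against the two published
screen-level statistics — the fraction of sets surviving the filters
(46.7%) and the number of kinetic solutions among 10⁵ sets (74) — and
frozen at 0.01: at full scale this package keeps 39–48% of sets and finds
M ≈ 84 solutions. The two statistics could not be matched simultaneously
with an output-only cutoff at any value, which is the evidence for
extending the floor to the regulatory nodes.

## Sampling

Kinetic parameters are drawn by Latin hypercube sampling on the log10
scale, k-type parameters over [1e-1, 1e1] and K-type over [1e-3, 1e2]
(scipy's `qmc.LatinHypercube`): each parameter's marginal visits n
equal-width log strata exactly once, with independent permutations across
parameters, so with n a multiple of five each decade of a K-type parameter
receives n/5 ± 1 samples. The input-edge pair k_IA, K_IA is fixed at 1.0
by default rather than sampled, so every set experiences the same input
drive and the profiled space is the ten regulatory parameters; this choice
is empirical as well as principled — with the input edge sampled, most
responses are negligible (median relative peak excursion ~0.1%) and the
filter-survival fraction (83%) is far from the published screening regime,
while with it fixed both statistics land where the published screen
reports them. A switch (`sample_input_edge`) restores 12-dimensional
sampling.

## Enrichment and motifs

Each parameter's range is partitioned into decade value classes (five for
K-type; the two occupied classes, [1e-1,1e0] and [1e0,1e1], for k-type;
binning is half-open with the top class closed, and a doubled-resolution
scheme is available). With y of the N sampled values and x of the M
solutions in a class, the enrichment p-value is the strict upper tail
P(X > x) of Hypergeometric(N, y, M). The strict tail (rather than
P(X ≥ x)) is deliberate: on the published count table it reproduces every
printed p-value to two significant figures, and it makes empty classes
(x = 0) maximally non-significant. p-values are floored at 1e-300
internally and reported as "<2.2E-16" below machine epsilon. A class with
p < 1e-3 (raw, no multiple-testing correction) is significant; a
parameter's *kinetic motif* is the union of its significant classes.

## Functional association and cooperation

For each motif parameter, all filter-surviving sets are split into the
motif group (value inside the motif interval) and its complement, and a
tie-corrected normal-approximation Mann–Whitney z (no continuity
correction, positive when the motif group is stochastically larger) is
computed separately for the sensitivity and the precision scores. A motif
is labelled SN and/or PR when the corresponding z exceeds 3.29 (the upper
99.9% critical value); only positive exceedances label, and the labels
form a bipartite motif–functionality network. Group medians are reported
alongside the z-scores. Pairwise cooperation between motif parameters is
Pearson correlation over the solution rows, computed on log10 values by
default (the sampling is log-uniform over up to five decades, so raw-scale
correlation is dominated by the top decade; a raw-scale flag exists), with
p < 0.05 flagging a correlated pair.

## Synthetic fixtures

`generate_fixture` emulates the *output* of a screen without any ODE run:
N rows of log-uniform parameter values, M flagged solutions whose values
for a planted parameter land in a chosen class with a configurable total
probability (so a planting fraction equal to the class marginal is exactly
the null), and unit-variance normal scores with optional location shifts
applied to all rows inside the planted class. This exercises the
enrichment and association layers against known truths — planted classes
must be recovered with ≥95% power, null plantings must stay quiet, and
planted score shifts must produce the corresponding function labels. What
fixtures do not emulate: the real screen's heavy-tailed, strongly
dependent score distributions and cross-parameter correlations, so fixture
tests validate the statistical machinery, not the dynamics.

## Reproducibility and problem sizes

A run is a pure function of its config (model, n, seed, ranges, protocol,
thresholds); identical configs give byte-identical outputs, which the test
suite asserts end-to-end. Long screens checkpoint every 1,000 rows with a
config hash and resume. The test suite runs its full-scale checks on one
10⁵-set screen (about four minutes of CPU) shared across tests; the
calibration analyses behind the frozen defaults used independent 2×10⁴-
and 10⁵-set screens.

## Known limitations

* The published account of this methodology reports the motif→function
  direction with the opposite sign pattern to what this implementation
  computes: its motif/non-motif median columns are internally swapped with
  respect to its own group definition, and the z signs follow. This
  package's directions are corroborated by single-parameter causal sweeps
  of the verified rate equations and are stated as computed; the bipartite
  degrees therefore differ from the published ones (most motifs here
  associate positively with sensitivity, and the sensitivity/precision z
  pair is opposed for every single-label motif, as published).
* The exact rejection thresholds of the original screening programs are
  unpublished; only the filter categories are. All thresholds here are
  explicit, configurable, and calibrated as described above.
* The incoherent-feed-forward preset is structural plumbing: it builds and
  simulates, but no published parameterisation is reproduced for it.
* Oscillation classification relies on sampled extrema and eigenvalue
  reasoning; pathological limit cycles with period near the 10⁴-unit
  budget could in principle be mislabelled as long transients.
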